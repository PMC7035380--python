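"""The 54 time- and frequency-domain features describing one 2-s epoch.

Feature groups, in canonical order:

* time-domain statistics: SD, RMS, skewness, kurtosis (non-excess), IQR,
  Shannon entropy of the 128-bin amplitude histogram (bits);
* Nakagami shape/spread (mu, omega) fitted by method of moments to the
  sample magnitudes, the classical model for scattered-echo envelopes;
* DCT of the Hilbert envelope: the 30 largest-magnitude coefficients in
  descending order, the number of sorted coefficients capturing 98% of the
  energy (L2 sense), the area under the magnitude spectrum over 0..fs/2,
  the peak magnitude, and the total spectral power;
* wavelet-packet relative powers for Haar and Daubechies-10 at decomposition
  levels 1..6 (energy of the lowest-frequency node over the level's total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import fft as _fft
from scipy import signal as _signal
from scipy import stats as _stats

log = logging.getLogger(__name__)

NAKAGAMI_MU_CAP = 1e6
"""Shape estimate reported for degenerate (zero-variance-of-r^2) samples."""

FEATURE_NAMES: tuple[str, ...] = (
    "sd", "rms", "skew", "kurt", "iqr", "entropy",
    "nakagami_mu", "nakagami_omega",
    *[f"dct_c{i:02d}" for i in range(1, 31)],
    "dct_n98", "dct_auc", "dct_peak", "dct_power",
    *[f"haar_l{j}" for j in range(1, 7)],
    *[f"db10_l{j}" for j in range(1, 7)],
)
assert len(FEATURE_NAMES) == 54

META_COLUMNS = ("entity_id", "class_label", "epoch_index")


@dataclass(frozen=True)
class DctSpectrum:
    """Unnormalized DCT-II of the signal envelope, DC term excluded.

    ``coeffs[l-1] = sum_k eps[k] cos(pi l (2k+1) / (2N))`` for l = 1..N-1,
    with frequency axis ``freqs[l-1] = l*fs/(2N)``; ``sorted_mags`` holds
    the coefficient magnitudes ordered descending.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    n: int

    @property
    def sorted_mags(self) -> np.ndarray:
        return np.sort(np.abs(self.coeffs))[::-1]


def time_stats(x: np.ndarray, entropy_bins: int = 128) -> tuple[float, ...]:
    """(sd, rms, skew, kurt, iqr, entropy) of one epoch.

    SD uses the n-1 denominator; kurtosis is the raw standardized fourth
    moment (3 for a Gaussian); entropy is Shannon entropy in bits of the
    equal-width amplitude histogram.  A constant epoch yields skew = kurt = 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("epoch too short for time statistics")
    sd = float(np.std(x, ddof=1))
    rms = float(np.sqrt(np.mean(x * x)))
    # treat numerically-constant epochs (sd at rounding level) as degenerate
    if sd <= 1e-12 * (abs(float(np.mean(x))) + 1.0):
        log.debug("constant epoch: skew/kurt reported as 0")
        skew = kurt = 0.0
    else:
        skew = float(_stats.skew(x))
        kurt = float(_stats.kurtosis(x, fisher=False))
    q1, q3 = np.percentile(x, [25, 75])
    iqr = float(q3 - q1)
    if np.ptp(x) == 0:
        entropy = 0.0
    else:
        counts, _ = np.histogram(x, bins=entropy_bins)
        p = counts[counts > 0] / len(x)
        entropy = float(-np.sum(p * np.log2(p)))
    return sd, rms, skew, kurt, iqr, entropy


def nakagami_fit(x: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Nakagami (mu, omega) fit to the magnitudes |x|.

    mu_hat = (E[r^2])^2 / Var(r^2), omega_hat = E[r^2].  When Var(r^2) = 0
    (e.g. constant |x|) the shape is reported as the documented cap.
    """
    r2 = np.square(np.abs(np.asarray(x, dtype=float)))
    omega = float(np.mean(r2))
    var = float(np.var(r2))
    if var == 0:
        log.debug("degenerate Nakagami sample: mu capped at %g", NAKAGAMI_MU_CAP)
        return NAKAGAMI_MU_CAP, omega
    return omega * omega / var, omega


def dct_spectrum(x: np.ndarray, fs: float) -> DctSpectrum:
    """DCT of the Hilbert envelope of the epoch.

    The envelope is |analytic signal|; coefficients are the plain cosine sums
    (scipy's unnormalized DCT-II halved), excluding the DC term.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    envelope = np.abs(_signal.hilbert(x))
    coeffs = _fft.dct(envelope, type=2, norm=None)[1:] / 2.0
    freqs = np.arange(1, n) * fs / (2.0 * n)
    return DctSpectrum(coeffs=coeffs, freqs=freqs, n=n)


def dct_features(spec: DctSpectrum) -> tuple[float, ...]:
    """(c01..c30, n98, auc, peak, power) from a DCT spectrum.

    c01..c30 are the 30 largest coefficient magnitudes descending; n98 is the
    smallest n whose top-n sorted coefficients reach 98% of the total L2 norm
    (0 for an all-zero spectrum); auc is the trapezoidal integral of the
    magnitude spectrum over its frequency axis; power is the sum of squares.
    """
    if len(spec.coeffs) < 30:
        raise ValueError("epoch too short: fewer than 30 DCT coefficients")
    mags = spec.sorted_mags
    top30 = tuple(float(v) for v in mags[:30])
    total = float(np.sqrt(np.sum(mags * mags)))
    if total == 0.0:
        n98 = 0
    else:
        cum = np.sqrt(np.cumsum(mags * mags)) / total
        n98 = int(np.searchsorted(cum, 0.98 - 1e-12) + 1)
    auc = float(np.trapezoid(np.abs(spec.coeffs), spec.freqs))
    peak = float(mags[0]) if len(mags) else 0.0
    power = float(np.sum(np.square(spec.coeffs)))
    return (*top30, float(n98), auc, peak, power)


def wavelet_relative_powers(
    x: np.ndarray, max_level: int = 6, node: str = "lowest"
) -> tuple[float, ...]:
    """Relative wavelet-packet powers (haar_l1..l6, db10_l1..l6).

    For each mother wavelet and level j, the relative power is the energy of
    a chosen packet node divided by the total energy across all 2^j nodes of
    that level: ``node='lowest'`` takes the lowest-frequency (pure
    approximation) node; ``node='all-details'`` takes the complement.  The
    periodized transform is used so level energies conserve the signal energy.
    A zero-energy level yields 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2**max_level:
        raise ValueError(f"epoch shorter than 2^{max_level} samples")
    if node not in ("lowest", "all-details"):
        raise ValueError("node must be 'lowest' or 'all-details'")
    out: list[float] = []
    for wavelet in ("haar", "db10"):
        wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="periodization", maxlevel=max_level)
        for j in range(1, max_level + 1):
            nodes = wp.get_level(j, order="natural")
            energies = np.array([np.sum(np.square(nd.data)) for nd in nodes])
            total = float(energies.sum())
            if total == 0.0:
                out.append(0.0)
                continue
            approx = float(energies[0])  # 'a'*j is first in natural order
            frac = approx / total
            out.append(frac if node == "lowest" else 1.0 - frac)
    return tuple(out)


def extract_features(
    x: np.ndarray,
    fs: float,
    *,
    entropy_bins: int = 128,
    wp_node: str = "lowest",
) -> np.ndarray:
    """The 54-element feature vector of one accepted epoch, canonical order."""
    ts = time_stats(x, entropy_bins=entropy_bins)
    nak = nakagami_fit(x)
    dct = dct_features(dct_spectrum(x, fs))
    wav = wavelet_relative_powers(x, node=wp_node)
    vec = np.array([*ts, *nak, *dct, *wav], dtype=float)
    assert vec.shape == (54,)
    return vec


def feature_table(epochs, fs: float, **kw) -> pd.DataFrame:
    """One row per accepted epoch: entity_id, class_label, epoch_index + the
    54 features."""
    rows = []
    for e in epochs:
        if not e.accepted:
            continue
        vec = extract_features(e.samples, fs, **kw)
        rows.append((e.entity_id, e.class_label, e.index, *vec))
    return pd.DataFrame(rows, columns=[*META_COLUMNS, *FEATURE_NAMES])
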