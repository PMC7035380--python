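"""Preprocessing of raw acquisitions: high-pass filtering, epoching, artifact
rejection.

The processing chain is the one used at acquisition time: a causal
second-order 500 Hz Butterworth high-pass (removing the 50 Hz grid component
and other low-frequency drift while keeping the 1 kHz carrier band), a split
into non-overlapping 2-s epochs (10,000 samples at 5 kHz), and rejection of
any epoch containing a sample with |z| > 5, where z is computed against the
mean and SD of the whole filtered acquisition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .synthgen import Acquisition

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    hp_cutoff: float = 500.0
    hp_order: int = 2
    epoch_seconds: float = 2.0
    zscore_threshold: float = 5.0
    zscore_reference: str = "acquisition"  # or "epoch"
    zscore_aggregation: str = "max"  # or "mean"

    def __post_init__(self) -> None:
        if self.hp_cutoff <= 0 or self.hp_order < 1 or self.epoch_seconds <= 0:
            raise ValueError("invalid preprocessing configuration")
        if self.zscore_reference not in ("acquisition", "epoch"):
            raise ValueError("zscore_reference must be 'acquisition' or 'epoch'")
        if self.zscore_aggregation not in ("max", "mean"):
            raise ValueError("zscore_aggregation must be 'max' or 'mean'")


@dataclass
class Epoch:
    """One 2-s processed signal portion (a single classification sample)."""

    samples: np.ndarray
    entity_id: str
    class_label: str
    index: int
    accepted: bool = True
    stat_abs_z: float = float("nan")


def highpass(acq: Acquisition, cfg: PreprocessConfig = PreprocessConfig()) -> Acquisition:
    """Single-pass causal Butterworth high-pass; output length equals input."""
    if cfg.hp_cutoff >= acq.fs / 2:
        raise ValueError(
            f"hp_cutoff {cfg.hp_cutoff} Hz is not below Nyquist {acq.fs / 2} Hz"
        )
    sos = _signal.butter(cfg.hp_order, cfg.hp_cutoff, btype="highpass", fs=acq.fs, output="sos")
    filtered = _signal.sosfilt(sos, acq.samples)
    return replace(acq, samples=filtered)


def epoch_split(acq: Acquisition, cfg: PreprocessConfig = PreprocessConfig()) -> list[Epoch]:
    """Consecutive non-overlapping epochs; a trailing remainder is discarded."""
    n_per = round(acq.fs * cfg.epoch_seconds)
    n_epochs = len(acq.samples) // n_per
    if n_epochs == 0:
        log.warning(
            "acquisition %s shorter than one epoch (%d < %d samples)",
            acq.entity_id, len(acq.samples), n_per,
        )
        return []
    return [
        Epoch(
            samples=acq.samples[i * n_per : (i + 1) * n_per],
            entity_id=acq.entity_id,
            class_label=acq.class_label,
            index=i,
        )
        for i in range(n_epochs)
    ]


def reject_artifacts(
    epochs: Sequence[Epoch],
    cfg: PreprocessConfig = PreprocessConfig(),
    *,
    reference_mean: float | None = None,
    reference_sd: float | None = None,
) -> list[Epoch]:
    """Flag epochs whose z-scores exceed the threshold.

    With the default acquisition-level reference, z is computed per sample
    against the mean/SD of the parent acquisition's filtered samples (passed
    as ``reference_mean``/``reference_sd``, or computed from the concatenated
    epochs when absent); an epoch is rejected iff its aggregated |z| (max by
    default) exceeds the threshold.  A zero-variance reference defines z = 0
    everywhere (all epochs accepted, logged).
    """
    if len(epochs) == 0:
        raise ValueError("at least one epoch required")
    out: list[Epoch] = []
    if cfg.zscore_reference == "acquisition":
        if reference_mean is None or reference_sd is None:
            pooled = np.concatenate([e.samples for e in epochs])
            reference_mean = float(np.mean(pooled))
            reference_sd = float(np.std(pooled))
    for e in epochs:
        if cfg.zscore_reference == "epoch":
            mu, sd = float(np.mean(e.samples)), float(np.std(e.samples))
        else:
            mu, sd = reference_mean, reference_sd
        if sd == 0:
            log.warning("zero-variance reference for %s: z defined as 0", e.entity_id)
            z = np.zeros_like(e.samples)
        else:
            z = np.abs((e.samples - mu) / sd)
        stat = float(np.max(z)) if cfg.zscore_aggregation == "max" else float(np.mean(z))
        out.append(replace_epoch(e, accepted=stat <= cfg.zscore_threshold, stat_abs_z=stat))
    return out


def replace_epoch(e: Epoch, **kw) -> Epoch:
    d = dict(
        samples=e.samples, entity_id=e.entity_id, class_label=e.class_label,
        index=e.index, accepted=e.accepted, stat_abs_z=e.stat_abs_z,
    )
    d.update(kw)
    return Epoch(**d)


def preprocess(acq: Acquisition, cfg: PreprocessConfig = PreprocessConfig()) -> list[Epoch]:
    """Full chain: high-pass -> epoch split -> artifact rejection.

    The z-score reference statistics are taken from the entire filtered
    acquisition (including any trailing remainder the epoching discards).
    """
    filtered = highpass(acq, cfg)
    epochs = epoch_split(filtered, cfg)
    if not epochs:
        return []
    return reject_artifacts(
        epochs,
        cfg,
        reference_mean=float(np.mean(filtered.samples)),
        reference_sd=float(np.std(filtered.samples)),
    )
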