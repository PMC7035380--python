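"""Synthetic back-scatter acquisitions and restoring trajectories.

The generator emulates the statistical structure of photodetector recordings
from a particle held in a harmonic optical trap: the particle position follows
an Ornstein--Uhlenbeck (OU) process whose variance grows as

    sigma^2(t) = (K_B T / k_trap) * (1 - exp(-2 k_trap D t / (K_B T))),

i.e. Brownian motion confined by a spring of stiffness ``k_trap``.  The
photodetector voltage couples (linearly and quadratically) to that position,
rides on a 1 kHz amplitude-modulated laser carrier, and is contaminated by
50 Hz grid interference and white sensor noise.  A "no particle trapped"
class emits carrier + noise only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

K_B = 1.380649e-23
"""Boltzmann constant (J/K)."""

CLASS_ORDER = ("no_particle", "mock", "hst6", "ps")
"""Canonical class order used for confusion matrices and vote tie-breaks."""


@dataclass(frozen=True)
class TrapModel:
    """Harmonic trap + thermal bath parameters (SI units).

    Parameters
    ----------
    k_trap : float
        Trap stiffness (N/m).
    temperature : float
        Absolute temperature (K).
    diffusion : float
        Particle diffusion coefficient in the suspension medium (m^2/s).
    x0 : float
        Initial particle position relative to the trap centre (m).
    """

    k_trap: float
    temperature: float = 310.15
    diffusion: float = 3.0e-14
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.k_trap <= 0:
            raise ValueError("k_trap must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.diffusion <= 0:
            raise ValueError("diffusion must be positive")

    @property
    def gamma(self) -> float:
        """Drag coefficient gamma = K_B*T/D (N s/m), from Einstein's relation."""
        return K_B * self.temperature / self.diffusion

    @property
    def tau(self) -> float:
        """Trap relaxation time gamma/k_trap (s)."""
        return self.gamma / self.k_trap

    @property
    def stationary_variance(self) -> float:
        """Equipartition position variance K_B*T/k_trap (m^2)."""
        return K_B * self.temperature / self.k_trap

    def variance(self, t) -> np.ndarray:
        """Closed-form position variance at time ``t`` for a particle released
        at a deterministic position (the OU transient)."""
        t = np.asarray(t, dtype=float)
        return self.stationary_variance * (
            1.0 - np.exp(-2.0 * self.k_trap * self.diffusion * t / (K_B * self.temperature))
        )


@dataclass(frozen=True)
class ScatterModel:
    """Position-to-voltage transduction and additive interference (volts)."""

    baseline: float = 1.0
    coupling_linear: float = 5.0e6
    coupling_quad: float = 0.0
    carrier_freq: float = 1000.0
    carrier_depth: float = 0.5
    grid_freq: float = 50.0
    grid_amp: float = 0.05
    noise_sd: float = 0.02
    fs: float = 5000.0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.carrier_freq:
            raise ValueError("fs must exceed twice the carrier frequency")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.carrier_depth <= 1.0:
            raise ValueError("carrier_depth must lie in [0, 1]")


@dataclass(frozen=True)
class ClassSpec:
    """One class of the four-way trapping problem.

    ``no_particle`` must carry no trap; the particle classes must carry one.
    ``entity_jitter`` is the relative SD of the lognormal per-entity draw
    applied to the trap stiffness, diffusion and scatter couplings so that
    entities within a class differ (making entity-level leave-one-out
    meaningful).
    """

    label: str
    scatter: ScatterModel
    trap: Optional[TrapModel] = None
    n_entities: int = 1
    entity_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"label must be one of {CLASS_ORDER}, got {self.label!r}")
        if self.label == "no_particle" and self.trap is not None:
            raise ValueError("no_particle class cannot carry a trap")
        if self.label != "no_particle" and self.trap is None:
            raise ValueError(f"particle class {self.label!r} requires a trap")
        if self.n_entities < 1:
            raise ValueError("n_entities must be >= 1")
        if self.entity_jitter < 0:
            raise ValueError("entity_jitter must be non-negative")


@dataclass(frozen=True)
class Acquisition:
    """One entity's photodetector recording."""

    samples: np.ndarray
    fs: float
    duration: float
    entity_id: str
    class_label: str

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if len(samples) != round(self.fs * self.duration):
            raise ValueError(
                f"sample count {len(samples)} != round(fs*duration)="
                f"{round(self.fs * self.duration)}"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("acquisition contains non-finite samples")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_positions(trap: TrapModel, fs: float, duration: float, seed) -> np.ndarray:
    """Exact-discretization OU path of the trapped particle position.

    Returns ``round(fs*duration)`` samples at times ``i/fs`` (i = 0..n-1) with
    ``x[0] = trap.x0``.  The update is the exact OU transition

        x_{i+1} = x_i e^{-dt/tau} + xi_i sqrt(sigma_inf^2 (1 - e^{-2 dt/tau})),

    with ``sigma_inf^2 = K_B T / k_trap``, so the transient variance matches
    the closed form at any step size (no Euler bias).
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("fs and duration must be positive")
    n = round(fs * duration)
    dt = 1.0 / fs
    a = math.exp(-dt / trap.tau)
    innov_sd = math.sqrt(trap.stationary_variance * (1.0 - a * a))
    rng = _rng(seed)
    xi = rng.standard_normal(n)
    # x[i] = a*x[i-1] + innov_sd*xi[i]; run the AR(1) recursion through lfilter.
    xi[0] = 0.0
    drive = innov_sd * xi
    drive[0] = trap.x0
    x = _signal.lfilter([1.0], [1.0, -a], drive)
    return x


def _jitter(value: float, rel_sd: float, rng: np.random.Generator) -> float:
    """Lognormal multiplicative jitter with relative SD ``rel_sd``."""
    if rel_sd == 0 or value == 0:
        return value
    sigma = math.sqrt(math.log1p(rel_sd * rel_sd))
    return value * math.exp(rng.normal(-0.5 * sigma * sigma, sigma))


def realize_entity(spec: ClassSpec, rng: np.random.Generator) -> tuple[Optional[TrapModel], ScatterModel]:
    """Draw one entity's concrete (trap, scatter) parameters from the class spec."""
    j = spec.entity_jitter
    trap = spec.trap
    if trap is not None:
        trap = replace(
            trap,
            k_trap=_jitter(trap.k_trap, j, rng),
            diffusion=_jitter(trap.diffusion, j, rng),
        )
    sc = spec.scatter
    scatter = replace(
        sc,
        baseline=_jitter(sc.baseline, j, rng),
        coupling_linear=_jitter(sc.coupling_linear, j, rng),
        coupling_quad=_jitter(sc.coupling_quad, j, rng),
        noise_sd=_jitter(sc.noise_sd, j, rng),
    )
    return trap, scatter


def synthesize_acquisition(
    spec: ClassSpec,
    entity_id: str,
    duration: float,
    seed,
    *,
    jitter: bool = False,
) -> Acquisition:
    """Synthesize one entity's photodetector voltage trace.

    samples = (baseline + c1*x + c2*x^2) * (1 + depth*sin(2 pi f_c t))
              + grid_amp*sin(2 pi f_g t) + N(0, noise_sd),

    with the x(t) terms omitted for the no-particle class.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    if jitter:
        trap, sc = realize_entity(spec, rng)
    else:
        trap, sc = spec.trap, spec.scatter
    n = round(sc.fs * duration)
    t = np.arange(n) / sc.fs
    level = np.full(n, sc.baseline)
    if trap is not None:
        x = simulate_positions(trap, sc.fs, duration, rng)
        level = level + sc.coupling_linear * x + sc.coupling_quad * x * x
    samples = level * (1.0 + sc.carrier_depth * np.sin(2 * np.pi * sc.carrier_freq * t))
    if sc.grid_amp != 0.0:
        samples = samples + sc.grid_amp * np.sin(2 * np.pi * sc.grid_freq * t)
    if sc.noise_sd > 0:
        samples = samples + rng.normal(0.0, sc.noise_sd, n)
    return Acquisition(samples, sc.fs, duration, entity_id, spec.label)


def generate_cohort(specs: Sequence[ClassSpec], duration: float, seed) -> list[Acquisition]:
    """One jittered acquisition per entity across the four classes.

    Entity ids are ``<label>_<k>``; each entity's randomness is derived from
    ``(seed, class index, entity index)`` so cohorts are reproducible and
    entities are independent.
    """
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels in cohort spec")
    if set(labels) != set(CLASS_ORDER):
        raise ValueError(f"cohort must cover all classes {CLASS_ORDER}")
    by_label = {s.label: s for s in specs}
    acqs: list[Acquisition] = []
    for ci, label in enumerate(CLASS_ORDER):
        spec = by_label[label]
        for ei in range(spec.n_entities):
            ss = np.random.SeedSequence([int(seed), ci, ei])
            acqs.append(
                synthesize_acquisition(
                    spec, f"{label}_{ei:02d}", duration, np.random.default_rng(ss), jitter=True
                )
            )
    return acqs


# ---------------------------------------------------------------------------
# Presets: the study conditions for the four-class problem.
# ---------------------------------------------------------------------------

DEFAULT_COHORT_COUNTS = {"no_particle": 13, "mock": 15, "hst6": 15, "ps": 10}
"""Entity counts of the full study (13 x 15 x 15 x 10 = 29,250 LOO runs)."""

DEFAULT_DURATION = 80.0
"""Acquisition length in seconds (40 epochs of 2 s at 5 kHz)."""


def separated_class_specs(
    counts: Optional[dict] = None,
    *,
    fs: float = 5000.0,
    entity_jitter: float = 0.1,
) -> list[ClassSpec]:
    """Four-class cohort with distinct trap/scatter parameters per class.

    Stiffnesses are pN/um-scale order-of-magnitude choices (the physical
    magnitudes are not measurable from the recordings themselves) with the
    polystyrene control stiffest.  The carrier-modulation amplitude each
    particle imprints (coupling x position SD) steps by roughly 2.7x between
    classes -- distinct optical polarizabilities -- so classes differ in
    fluctuation structure well beyond the 10% per-entity jitter.
    """
    counts = dict(DEFAULT_COHORT_COUNTS if counts is None else counts)

    def sc(**kw):
        # carrier/grid track fs so reduced-rate cohorts keep the same
        # spectral layout (1 kHz / 50 Hz at the canonical 5 kHz rate)
        return ScatterModel(fs=fs, carrier_freq=fs / 5.0, grid_freq=fs / 100.0, **kw)

    return [
        ClassSpec("no_particle", sc(), None, counts["no_particle"], entity_jitter),
        ClassSpec(
            "mock",
            sc(coupling_linear=2.0e6, coupling_quad=0.0),
            TrapModel(k_trap=1.5e-6, diffusion=3.0e-14),
            counts["mock"],
            entity_jitter,
        ),
        ClassSpec(
            "hst6",
            sc(coupling_linear=8.0e6, coupling_quad=5.0e12),
            TrapModel(k_trap=3.0e-6, diffusion=2.7e-14),
            counts["hst6"],
            entity_jitter,
        ),
        ClassSpec(
            "ps",
            sc(coupling_linear=3.0e7, coupling_quad=2.0e13),
            TrapModel(k_trap=6.0e-6, diffusion=5.7e-14),
            counts["ps"],
            entity_jitter,
        ),
    ]


def identical_class_specs(
    counts: Optional[dict] = None,
    *,
    fs: float = 5000.0,
    entity_jitter: float = 0.0,
) -> list[ClassSpec]:
    """Chance-level control cohort: all four classes emit identically
    distributed signals.

    The particle classes keep (identical) traps, but every scatter coupling is
    zero, so the position process never reaches the detector and each class
    records baseline + carrier + grid + noise only.  Any classifier should sit
    at 25% accuracy on this cohort.  Entity jitter defaults to zero here so
    every epoch is an independent draw of the same process: with jitter, a
    small cohort's handful of entity signatures dominates the run-to-run mean
    and chance-level behaviour is only reached asymptotically in cohort size.
    """
    counts = dict(DEFAULT_COHORT_COUNTS if counts is None else counts)
    sc = ScatterModel(fs=fs, carrier_freq=fs / 5.0, grid_freq=fs / 100.0,
                      coupling_linear=0.0, coupling_quad=0.0)
    trap = TrapModel(k_trap=2.0e-6)
    return [
        ClassSpec("no_particle", sc, None, counts["no_particle"], entity_jitter),
        ClassSpec("mock", sc, trap, counts["mock"], entity_jitter),
        ClassSpec("hst6", sc, trap, counts["hst6"], entity_jitter),
        ClassSpec("ps", sc, trap, counts["ps"], entity_jitter),
    ]


def simulate_restoring_trajectory(
    trap: TrapModel,
    drag,
    s0: float,
    frame_rate: float = 4.0,
    duration: float = 5.0,
    noise_sd: float = 0.0,
    seed=None,
):
    """Relaxation of a released particle toward the trap centre, sampled by a
    camera at ``frame_rate`` (default 4 Hz).

    Positions follow s(t) = s0 * exp(-t * k_trap / gamma) + noise, with gamma
    the Stokes drag 6 pi xi eta r of ``drag``.
    """
    from .force import Trajectory  # local import to avoid cycle

    if frame_rate <= 0 or duration <= 0:
        raise ValueError("frame_rate and duration must be positive")
    times = np.arange(0.0, duration, 1.0 / frame_rate)
    tau = drag.gamma / trap.k_trap
    positions = s0 * np.exp(-times / tau)
    if noise_sd > 0:
        positions = positions + _rng(seed).normal(0.0, noise_sd, len(times))
    return Trajectory(times=times, positions=positions)
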