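"""Optical trapping force from tracked restoring trajectories (Drag Force
method).

A released particle relaxes toward the trap centre; in the low-Reynolds
regime the total trapping force reduces to the wall-corrected Stokes drag

    F_T = 6 pi xi eta r * ds/dt,

with xi = 3.08 the boundary-proximity correction and eta the medium
viscosity.  The trajectory s(t), tracked at ~4 Hz, is fitted to the Langevin
relaxation s(t) = s_eq + (s0 - s_eq) exp(-t/tau); the velocity used in the
force profile is the analytic derivative of that fit (finite differences of
4 Hz positions are noise-dominated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class DragModel:
    """Stokes drag parameters: xi wall correction, eta viscosity (Pa s),
    r particle radius (m), m optional mass (kg)."""

    r: float
    xi: float = 3.08
    eta: float = 1.0e-3
    m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.xi <= 0 or self.eta <= 0 or self.r <= 0:
            raise ValueError("xi, eta and r must be positive")

    @property
    def gamma(self) -> float:
        """Drag coefficient 6 pi xi eta r (N s/m)."""
        return 6.0 * math.pi * self.xi * self.eta * self.r


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray
    positions: np.ndarray
    direction: str = "+x"
    repetition: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        if len(t) != len(p):
            raise ValueError("times and positions must have equal length")
        if len(t) < 3:
            raise ValueError("trajectory needs at least 3 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")


class FitError(RuntimeError):
    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = residuals


@dataclass(frozen=True)
class RelaxationFit:
    s_eq: float
    s0: float
    tau: float
    residuals: np.ndarray

    @property
    def amplitude(self) -> float:
        return self.s0 - self.s_eq


def fit_relaxation(traj: Trajectory) -> RelaxationFit:
    """Least-squares fit of s(t) = s_eq + (s0 - s_eq) exp(-t/tau), tau > 0."""
    t = traj.times - traj.times[0]
    p = traj.positions
    if len(t) < 4:
        raise ValueError("need >= 4 points for the relaxation fit")
    if np.ptp(p) == 0:
        raise FitError("constant positions: relaxation fit is degenerate")

    def model(tt, s_eq, s0, tau):
        return s_eq + (s0 - s_eq) * np.exp(-tt / tau)

    span = t[-1] - t[0]
    p0 = (p[-1], p[0], max(span / 3.0, 1e-6))
    # positions (m) and tau (s) differ by orders of magnitude: scale the
    # parameters so the optimizer's stopping tolerances bite on all three
    pos_scale = max(np.ptp(p), abs(np.mean(p)), 1e-12)
    try:
        popt, _ = curve_fit(
            model, t, p, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            x_scale=[pos_scale, pos_scale, max(span / 3.0, 1e-6)],
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
            maxfev=20000,
        )
    except RuntimeError as err:
        raise FitError(f"relaxation fit did not converge: {err}",
                       residuals=p - model(t, *p0)) from err
    res = p - model(t, *popt)
    return RelaxationFit(s_eq=float(popt[0]), s0=float(popt[1]), tau=float(popt[2]),
                         residuals=res)


def drag_force(v, drag: DragModel):
    """Wall-corrected Stokes drag force F = 6 pi xi eta r v (N)."""
    return drag.gamma * np.asarray(v, dtype=float)


def inertial_check(traj: Trajectory, drag: DragModel) -> Optional[float]:
    """Peak |F_inertial| / |F_drag| along the fitted relaxation.

    For the exponential model the ratio is constant, m / (6 pi xi eta r tau);
    it must be << 1 for the drag-only force estimate to hold.  Returns None
    when no mass is provided.
    """
    if drag.m is None:
        return None
    if drag.m == 0:
        return 0.0
    fit = fit_relaxation(traj)
    return float(drag.m / (drag.gamma * fit.tau))


@dataclass(frozen=True)
class ForceProfile:
    displacements: np.ndarray  # position relative to the trapping point (m)
    forces: np.ndarray         # trapping force magnitudes (N)
    max_force: float
    tau: float
    fit: RelaxationFit
    direction: str = "+x"
    repetition: int = 0


def force_profile(traj: Trajectory, drag: DragModel) -> ForceProfile:
    """Trapping force vs position from the fitted relaxation.

    Velocity is the analytic derivative of the fit at the frame times,
    v(t) = -(s0 - s_eq)/tau * exp(-t/tau); force magnitude peaks at the
    largest displacement, |F|_max = 6 pi xi eta r |s0 - s_eq| / tau, and
    decays to 0 at the equilibrium position.
    """
    fit = fit_relaxation(traj)
    t = traj.times - traj.times[0]
    disp = fit.amplitude * np.exp(-t / fit.tau)
    v = -disp / fit.tau
    forces = np.abs(drag_force(v, drag))
    return ForceProfile(
        displacements=disp,
        forces=forces,
        max_force=float(drag.gamma * abs(fit.amplitude) / fit.tau),
        tau=fit.tau,
        fit=fit,
        direction=traj.direction,
        repetition=traj.repetition,
    )
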