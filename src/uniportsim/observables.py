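"""Experimentalist-facing observables derived from trajectories.

The quantities a release assay reports: the release curve (fraction of the
encapsulated anion free in the EV solution vs time, as an ion-selective
electrode would see it), the initial rate ``k_ini`` (release at the first
dwell divided by the dwell time), the release at the 270 s readout, and the
EC50 -- the carrier dose, in %mol relative to total lipid, at which the
release at 270 s crosses 50%.  Release is mole-based: free guest in the EV
solution divided by the system-wide total guest; complexed guest is not
counted as released (the electrode senses the free anion only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .engine import SimConfig, Trajectory, simulate
from .equilibria import CarrierSpec
from .errors import BracketError, ConfigError
from .geometry import DispersionSpec, MembraneSpec

__all__ = [
    "ReleaseCurve",
    "TransportMetrics",
    "release_curve",
    "value_at",
    "initial_rate",
    "metrics",
    "find_dose_crossing",
    "ec50",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReleaseCurve:
    """Release fraction (0-1) on a strictly increasing time grid starting at 0."""

    times: np.ndarray
    release: np.ndarray
    dose_molpct: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.release, dtype=float)
        if t.ndim != 1 or t.shape != r.shape or t.size == 0:
            raise ConfigError("times and release must be matching 1-D arrays")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ConfigError("times must be strictly increasing and start at 0")
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise ConfigError("release must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "release", r)


@dataclass(frozen=True)
class TransportMetrics:
    """Summary metrics of one carrier/system combination."""

    k_ini: float  # fraction s^-1
    release_270: float  # fraction
    ec50_molpct: float | None = None


def release_curve(traj: Trajectory) -> ReleaseCurve:
    """Extract the release curve from a trajectory (already mole-based)."""
    return ReleaseCurve(times=traj.times.copy(), release=traj.release.copy(), dose_molpct=traj.dose_molpct)


def value_at(curve: ReleaseCurve, t: float) -> float:
    """Release at a time that must lie on the sampling grid."""
    idx = np.nonzero(np.isclose(curve.times, t, rtol=0, atol=1e-9 * max(t, 1.0)))[0]
    if idx.size == 0:
        raise ConfigError(f"t={t} s is not on the sampling grid (dwell multiples)")
    return float(curve.release[idx[0]])


def initial_rate(curve: ReleaseCurve, dwell: float) -> float:
    """Initial release rate ``k_ini = release(dwell) / dwell``, fraction s^-1."""
    return value_at(curve, dwell) / dwell


def metrics(traj: Trajectory, t_read: float = 270.0) -> TransportMetrics:
    """k_ini and the release at the ``t_read`` readout for one trajectory."""
    curve = release_curve(traj)
    return TransportMetrics(
        k_ini=initial_rate(curve, traj.dwell),
        release_270=value_at(curve, t_read),
    )


def find_dose_crossing(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    level: float = 0.5,
    tol: float = 0.005,
    n_scan: int = 6,
) -> tuple[float, int]:
    """Dose at which monotone ``f`` crosses ``level``: geometric scan + bisection.

    Returns ``(dose, n_evaluations)``.  Raises :class:`BracketError` (with the
    achieved extrema attached) when the level is not bracketed in
    ``[lo, hi]``, and :class:`ConfigError` if the coarse scan shows ``f``
    decreasing, violating the monotonicity premise.
    """
    if not 0 < lo < hi:
        raise ConfigError("need 0 < lo < hi")
    doses = np.geomspace(lo, hi, n_scan)
    n_eval = 0
    scanned: list[tuple[float, float]] = []
    for d in doses:
        y = f(d)
        n_eval += 1
        scanned.append((d, y))
        if y >= level:
            break
    vals = [y for _, y in scanned]
    if any(b < a - 1e-6 for a, b in zip(vals, vals[1:])):
        raise ConfigError(f"response is not nondecreasing over the scan: {scanned}")
    if vals[0] >= level:
        raise BracketError(
            f"level {level} already reached at the lowest dose {lo} (f={vals[0]:.4g})",
            extrema=(vals[0], vals[-1]),
        )
    if vals[-1] < level:
        raise BracketError(
            f"level {level} not reached by dose {scanned[-1][0]:.4g} (f={vals[-1]:.4g})",
            extrema=(vals[0], vals[-1]),
        )
    d_lo = scanned[-2][0]
    d_hi = scanned[-1][0]
    while d_hi - d_lo > tol:
        mid = 0.5 * (d_lo + d_hi)
        y = f(mid)
        n_eval += 1
        if y >= level:
            d_hi = mid
        else:
            d_lo = mid
    return 0.5 * (d_lo + d_hi), n_eval


def ec50(
    carrier: CarrierSpec,
    membrane: MembraneSpec,
    dispersion: DispersionSpec,
    guest_in: float,
    cfg: SimConfig = SimConfig(),
    lo: float = 0.05,
    hi: float = 5.0,
    tol: float = 0.005,
    t_read: float = 270.0,
    full_output: bool = False,
):
    """Carrier dose (%mol to lipid) giving 50% release at the readout time.

    Obtained directly by scanning the dose and checking the release at
    ``t_read`` (coarse geometric scan bracketing the crossing, then bisection
    to the dose tolerance ``tol``).  With ``full_output=True`` returns
    ``(dose, n_simulations)``.
    """
    if cfg.t_total < t_read:
        raise ConfigError(f"cfg.t_total={cfg.t_total} s is shorter than the readout t={t_read} s")

    def release_at_read(dose: float) -> float:
        traj = simulate(carrier, membrane, dispersion, dose, guest_in, cfg)
        return value_at(release_curve(traj), t_read)

    dose, n_eval = find_dose_crossing(release_at_read, lo, hi, level=0.5, tol=tol)
    log.info("EC50 = %.4g %%mol (%d simulations)", dose, n_eval)
    return (dose, n_eval) if full_output else dose
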