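"""Least-squares fitting of membrane diffusion coefficients to release data.

The two diffusion coefficients (free carrier D, complex Dc) are usually the
only unknowns of the transport model, every other constant being measurable.
They are recovered from experimental release curves by

1. a grid pre-screen: simulate every vertex of a (log-spaced by default)
   parameter grid and keep the lowest sum of squared differences (SSE), and
2. a greedy Monte Carlo refinement: repeatedly pick one parameter at random,
   perturb it multiplicatively by a uniform factor in ``[1-var, 1+var]``
   (var = 10% by default) and keep the move only if the SSE strictly
   decreases, stopping after ``max_iter`` iterations or ``patience``
   consecutive rejections.

Datasets recorded at different carrier doses are fitted independently.  The
machinery is parameter-name agnostic: any numeric field of the carrier spec
(P, Kfm, ...) can be added to the fitted set.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import SimConfig, simulate
from .equilibria import CarrierSpec
from .errors import ConfigError, NumericalError
from .geometry import DispersionSpec, MembraneSpec
from .observables import ReleaseCurve, release_curve

__all__ = [
    "ReleaseDataset",
    "FitConfig",
    "FitResult",
    "sse",
    "make_simulator",
    "grid_screen",
    "mc_fit",
    "fit_release_data",
]

log = logging.getLogger(__name__)

#: A simulator maps (parameter overrides, dose in %mol) to a release curve.
Simulator = Callable[[Mapping[str, float], float], ReleaseCurve]


@dataclass
class ReleaseDataset:
    """Release records: one row per (dose, time) observation.

    ``frame`` columns: ``dose_molpct`` (%mol), ``time_s`` (s), ``release``
    (fraction; small negative experimental noise down to -0.05 is tolerated
    on input and clipped to [0, 1] when fitting).
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"dose_molpct", "time_s", "release"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigError(f"ReleaseDataset frame missing columns: {sorted(missing)}")
        if (self.frame["time_s"] < 0).any():
            raise ConfigError("ReleaseDataset times must be >= 0")
        r = self.frame["release"]
        if (r < -0.05).any() or (r > 1.05).any():
            raise ConfigError("ReleaseDataset release must lie in [-0.05, 1.05]")

    def doses(self) -> list[float]:
        return sorted(self.frame["dose_molpct"].unique())

    def slice(self, dose: float) -> tuple[np.ndarray, np.ndarray]:
        """(times, release) arrays of one dose, time-sorted."""
        sub = self.frame[np.isclose(self.frame["dose_molpct"], dose)].sort_values("time_s")
        if sub.empty:
            raise ConfigError(f"no records at dose {dose} %mol")
        return sub["time_s"].to_numpy(float), sub["release"].to_numpy(float)


@dataclass(frozen=True)
class FitConfig:
    """Monte Carlo minimisation controls.

    ``seed=None`` selects clock seeding (the non-reproducible mode); the seed
    actually used is always recorded in the result.
    """

    parameters: tuple[str, ...] = ("D", "Dc")
    var_pct: float = 10.0
    max_iter: int = 2000
    patience: int = 500
    seed: int | None = 0
    bounds: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.var_pct < 100:
            raise ConfigError("FitConfig.var_pct must be in (0, 100)")
        if self.max_iter <= 0 or self.patience <= 0:
            raise ConfigError("FitConfig.max_iter and patience must be > 0")
        if not self.parameters:
            raise ConfigError("FitConfig.parameters must be nonempty")


@dataclass
class FitResult:
    """Outcome of one per-dose fit."""

    params: dict[str, float]
    sse: float
    sse_trace: np.ndarray  # initial SSE followed by each accepted SSE
    accepted: int
    n_iter: int
    seed: int
    dose_molpct: float
    start: dict[str, float]
    start_provenance: str


def sse(sim: ReleaseCurve, times: np.ndarray, observed: np.ndarray) -> float:
    """Sum of squared differences, simulation interpolated onto data times.

    Observed values are clipped to [0, 1] before comparison.  Raises if any
    data time falls beyond the simulated range.
    """
    times = np.asarray(times, dtype=float)
    observed = np.clip(np.asarray(observed, dtype=float), 0.0, 1.0)
    t_max = sim.times[-1]
    if times.size and times.max() > t_max * (1 + 1e-9):
        raise ConfigError(
            f"data extend to t={times.max()} s but the simulation stops at {t_max} s"
        )
    pred = np.interp(times, sim.times, sim.release)
    return float(np.sum((pred - observed) ** 2))


def make_simulator(
    carrier: CarrierSpec,
    membrane: MembraneSpec,
    dispersion: DispersionSpec,
    guest_in: float,
    cfg: SimConfig = SimConfig(),
) -> Simulator:
    """Bind the system so that fits only vary carrier parameters and dose."""

    def run(params: Mapping[str, float], dose: float) -> ReleaseCurve:
        return release_curve(simulate(replace(carrier, **params), membrane, dispersion, dose, guest_in, cfg))

    return run


def grid_screen(
    times: np.ndarray,
    observed: np.ndarray,
    dose: float,
    simulator: Simulator,
    bounds: Mapping[str, tuple[float, float]],
    counts: Mapping[str, int],
    log_spaced: bool = True,
) -> tuple[dict[str, float], float, int]:
    """Exhaustive SSE comparison over a parameter grid.

    Returns ``(best_params, best_sse, n_simulations)``; the number of
    simulations is the product of the per-parameter counts.
    """
    names = list(bounds)
    axes = []
    for name in names:
        lo, hi = bounds[name]
        n = counts[name]
        if n < 1:
            raise ConfigError(f"counts[{name!r}] must be >= 1")
        if n == 1:
            axes.append(np.array([np.sqrt(lo * hi) if log_spaced else 0.5 * (lo + hi)]))
        elif log_spaced:
            if not 0 < lo < hi:
                raise ConfigError(f"log-spaced grid needs 0 < lo < hi for {name!r}")
            axes.append(np.geomspace(lo, hi, n))
        else:
            axes.append(np.linspace(lo, hi, n))
    best: dict[str, float] | None = None
    best_sse = np.inf
    n_sims = 0
    for combo in itertools.product(*axes):
        params = dict(zip(names, (float(v) for v in combo)))
        n_sims += 1
        try:
            s = sse(simulator(params, dose), times, observed)
        except NumericalError as exc:  # unstable vertex: skip, keep screening
            log.debug("grid vertex %s failed: %s", params, exc)
            continue
        if s < best_sse:
            best, best_sse = params, s
    if best is None:
        raise NumericalError("every grid vertex failed to simulate")
    return best, float(best_sse), n_sims


def mc_fit(
    times: np.ndarray,
    observed: np.ndarray,
    dose: float,
    simulator: Simulator,
    start: Mapping[str, float],
    cfg: FitConfig = FitConfig(),
) -> FitResult:
    """Greedy Monte Carlo SSE minimisation from ``start``.

    Per iteration one fitted parameter is chosen uniformly at random and
    multiplied by a factor uniform in ``[1-var, 1+var]``; out-of-bounds
    proposals and simulation failures are rejected, and a move is accepted
    only if it strictly decreases the SSE.  Deterministic under a fixed seed.
    """
    seed = cfg.seed if cfg.seed is not None else int(time.time_ns() % 2**31)
    rng = np.random.default_rng(seed)
    names = list(cfg.parameters)
    bounds = dict(cfg.bounds) if cfg.bounds else {}
    current = {k: float(v) for k, v in start.items()}
    for name in names:
        if name not in current:
            raise ConfigError(f"start is missing fitted parameter {name!r}")
        lo, hi = bounds.get(name, (0.0, np.inf))
        if not lo <= current[name] <= hi:
            raise ConfigError(f"start[{name!r}]={current[name]} outside bounds {lo, hi}")

    best_sse = sse(simulator(current, dose), times, observed)
    trace = [best_sse]
    var = cfg.var_pct / 100.0
    accepted = 0
    rejections_in_a_row = 0
    n_iter = 0
    for _ in range(cfg.max_iter):
        n_iter += 1
        name = names[rng.integers(len(names))]
        factor = 1.0 + var * (2.0 * rng.random() - 1.0)
        proposal = dict(current)
        proposal[name] = current[name] * factor
        lo, hi = bounds.get(name, (0.0, np.inf))
        ok = lo <= proposal[name] <= hi and proposal[name] > 0
        if ok:
            try:
                s = sse(simulator(proposal, dose), times, observed)
            except NumericalError as exc:
                log.debug("proposal %s failed: %s", proposal, exc)
                ok = False
        if ok and s < best_sse:
            current = proposal
            best_sse = s
            trace.append(s)
            accepted += 1
            rejections_in_a_row = 0
        else:
            rejections_in_a_row += 1
            if rejections_in_a_row >= cfg.patience:
                break
    return FitResult(
        params=current,
        sse=float(best_sse),
        sse_trace=np.asarray(trace),
        accepted=accepted,
        n_iter=n_iter,
        seed=seed,
        dose_molpct=dose,
        start=dict(start),
        start_provenance="user",
    )


def fit_release_data(
    dataset: ReleaseDataset,
    carrier: CarrierSpec,
    membrane: MembraneSpec,
    dispersion: DispersionSpec,
    guest_in: float,
    sim_cfg: SimConfig = SimConfig(),
    fit_cfg: FitConfig = FitConfig(),
    grid_bounds: Mapping[str, tuple[float, float]] | None = None,
    grid_counts: Mapping[str, int] | None = None,
    simulator: Simulator | None = None,
) -> dict[float, FitResult]:
    """Grid screen + Monte Carlo fit, independently for every dose.

    Per-dose random streams are derived from ``fit_cfg.seed`` keyed by the
    position of the dose in the sorted dose list, so results do not depend on
    dataset row order and no state leaks between doses.  ``simulator``
    overrides the forward model (mainly for testing).  Returns
    ``{dose: FitResult}``.
    """
    if grid_bounds is None:
        grid_bounds = {name: (getattr(carrier, name) / 10, getattr(carrier, name) * 10)
                       for name in fit_cfg.parameters}
    if grid_counts is None:
        grid_counts = {name: 4 for name in fit_cfg.parameters}
    if simulator is None:
        simulator = make_simulator(carrier, membrane, dispersion, guest_in, sim_cfg)
    results: dict[float, FitResult] = {}
    for i, dose in enumerate(dataset.doses()):
        times, observed = dataset.slice(dose)
        start, start_sse, n_grid = grid_screen(
            times, observed, dose, simulator, grid_bounds, grid_counts
        )
        base_seed = fit_cfg.seed if fit_cfg.seed is not None else int(time.time_ns() % 2**31)
        dose_seed = int(np.random.SeedSequence(base_seed, spawn_key=(i,)).generate_state(1)[0] % 2**31)
        res = mc_fit(times, observed, dose, simulator, start, replace(fit_cfg, seed=dose_seed))
        res.start_provenance = f"grid minimum (sse={start_sse:.4g}, {n_grid} simulations)"
        log.info(
            "dose %.4g %%mol: start %s (sse=%.4g) -> fit %s (sse=%.4g, %d accepted / %d iter)",
            dose, start, start_sse, res.params, res.sse, res.accepted, res.n_iter,
        )
        results[dose] = res
    return results
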