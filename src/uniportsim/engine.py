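"""Two-compartment transport engine.

The vesicle dispersion is reduced to two well-mixed aqueous compartments --
extravesicular (EV) and intravesicular (IV) -- separated by the lipid
bilayer.  Chemical equilibria are assumed much faster than permeation, so
each explicit (forward-Euler) step

1. re-establishes the six-species equilibrium in both compartments,
2. evaluates the Fick flux densities of the two membrane-crossing species,
   the free carrier (diffusivity D) and the complex (Dc), from the gradient
   of their membrane-bound concentrations,
3. moves ``J * A * ts`` moles from the donor to the acceptor compartment
   (the complex carries one carrier and one guest mole per mole).

The step size is either fixed or adapted on the sampling (dwell) boundaries
so that no donor membrane pool loses more than a set fraction (default 10%)
of its content per step.  Total carrier and guest moles are conserved by
construction and monitored every dwell, as is the vesicle surface coverage
when molecular footprint areas are supplied.

By default the flux-to-moles conversion uses the total membrane area counting
both leaflets (``Av_out + Av_in``); this is the calibration that reproduces
the benchmark release kinetics (see docs/methods.md).  The single-leaflet
alternative, in which the donor leaflet's own area multiplies the flux, is
available via ``SimConfig.flux_area = "leaflet"`` and yields exactly half the
transport rate in the equal-leaflet geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .constants import AVOGADRO, M3_TO_L
from .equilibria import CarrierSpec, CompartmentTotals, SpeciesState, solve_equilibrium
from .errors import ConfigError, InstabilityError
from .geometry import DispersionSpec, MembraneSpec, VesicleGeometry, build_geometry

__all__ = [
    "SimConfig",
    "SystemState",
    "Trajectory",
    "SPECIES",
    "flux_density",
    "advance",
    "adapt_timestep",
    "simulate",
    "initial_state",
    "surface_coverage",
    "coverage_fraction",
]

log = logging.getLogger(__name__)

#: Species column order used in all trajectory arrays.
SPECIES = ("Hs", "HGs", "Hm", "HGm", "Hz", "G")

_FLUX_AREA_MODES = ("bilayer", "leaflet")


@dataclass(frozen=True)
class SimConfig:
    """Time-stepping and monitoring controls.

    ``t_total`` total simulated time (s); ``ts_init`` the initial (and, with
    ``adaptive=False``, permanent) step (s); ``ts_max`` the cap applied when
    the step is adapted; ``dwell`` the sampling interval (s), matching the
    experimental electrode dwell time; ``depletion_cap`` the maximum fraction
    of a donor membrane pool a single step may move; ``coverage_warn`` the
    occupied-area fraction above which a warning is logged.
    """

    t_total: float = 300.0
    ts_init: float = 1e-6
    ts_max: float = 1e-3
    dwell: float = 5.0
    adaptive: bool = True
    depletion_cap: float = 0.10
    coverage_warn: float = 1.0
    flux_area: str = "bilayer"

    def __post_init__(self) -> None:
        if not 0 < self.ts_init <= self.ts_max <= self.dwell:
            raise ConfigError("SimConfig requires 0 < ts_init <= ts_max <= dwell")
        if not 0 < self.depletion_cap < 1:
            raise ConfigError("SimConfig.depletion_cap must be in (0, 1)")
        if not self.t_total > 0:
            raise ConfigError("SimConfig.t_total must be > 0")
        if self.flux_area not in _FLUX_AREA_MODES:
            raise ConfigError(f"SimConfig.flux_area must be one of {_FLUX_AREA_MODES}")


@dataclass
class SystemState:
    """Full instantaneous state of the two-compartment system.

    Pools are total moles per compartment (all chemical forms); ``ev``/``iv``
    hold the equilibrated species concentrations referenced to ``Vout`` and
    ``Vin`` respectively.
    """

    t: float
    nH_out: float
    nG_out: float
    nH_in: float
    nG_in: float
    ev: SpeciesState
    iv: SpeciesState
    geometry: VesicleGeometry
    carrier: CarrierSpec
    membrane: MembraneSpec
    L_global: float

    @property
    def total_H_moles(self) -> float:
        return self.nH_out + self.nH_in

    @property
    def total_G_moles(self) -> float:
        return self.nG_out + self.nG_in


def flux_density(c_out: float, c_in: float, Dx: float, w: float) -> float:
    """Fick flux density ``J = -(Dx/w) * (c_out - c_in) * 1000``.

    Concentrations in mol L^-1 (the factor 1000 converts to mol m^-3), ``w``
    the membrane hydrophobic thickness in m.  The result is in
    mol m^-2 s^-1; a negative sign means net movement toward the IV side.
    """
    if not w > 0:
        raise ConfigError("membrane thickness w must be > 0")
    if Dx < 0:
        raise ConfigError("diffusion coefficient must be >= 0")
    return -(Dx / w) * (c_out - c_in) * M3_TO_L


def _flux_areas(geometry: VesicleGeometry, mode: str) -> tuple[float, float]:
    """(area used when EV is the donor, area used when IV is the donor)."""
    if mode == "bilayer":
        a = geometry.total_area
        return a, a
    return geometry.Av_out, geometry.Av_in


def _equilibrate(state: SystemState) -> SystemState:
    g = state.geometry
    ev = solve_equilibrium(
        CompartmentTotals(state.nH_out / g.Vout, state.nG_out / g.Vout, g.Vout, state.L_global),
        state.carrier,
        state.membrane.gammaL,
    )
    iv = solve_equilibrium(
        CompartmentTotals(state.nH_in / g.Vin, state.nG_in / g.Vin, g.Vin, state.L_global),
        state.carrier,
        state.membrane.gammaL,
    )
    return replace(state, ev=ev, iv=iv)


def initial_state(
    carrier: CarrierSpec,
    membrane: MembraneSpec,
    dispersion: DispersionSpec,
    dose_molpct: float,
    guest_in: float,
) -> SystemState:
    """Build and equilibrate the t = 0 state.

    The guest is placed entirely in the IV solution at concentration
    ``guest_in`` (M); the carrier dose, given as %mol relative to total
    lipid, is converted to moles and placed in the EV compartment.
    """
    if dose_molpct < 0:
        raise ConfigError("dose_molpct must be >= 0")
    if guest_in < 0:
        raise ConfigError("guest_in must be >= 0")
    geometry = build_geometry(membrane, dispersion)
    nH_out = dose_molpct / 100.0 * dispersion.lipid_conc * dispersion.Vtot
    nG_in = guest_in * geometry.Vin
    zero = SpeciesState(0, 0, 0, 0, 0, 0)
    state = SystemState(
        t=0.0,
        nH_out=nH_out,
        nG_out=0.0,
        nH_in=0.0,
        nG_in=nG_in,
        ev=zero,
        iv=zero,
        geometry=geometry,
        carrier=carrier,
        membrane=membrane,
        L_global=dispersion.lipid_conc,
    )
    return _equilibrate(state)


def _run_interval(state: SystemState, ts: float, span: float, mode: str) -> SystemState:
    """Advance ``span`` seconds in steps of ``ts`` (last step truncated)."""
    g = state.geometry
    c = state.carrier
    pf = c.P * state.membrane.gammaL * state.L_global
    A_out, A_in = _flux_areas(g, mode)
    n_steps = int(span / ts + 1e-9)
    rem = span - n_steps * ts
    if rem < ts * 1e-9:
        rem = 0.0
    status, nH_o, nG_o, nH_i, nG_i, _, _, done = _kernel.run_interval(
        state.nH_out, state.nG_out, state.nH_in, state.nG_in,
        g.Vout, g.Vin,
        pf, c.Kfm, c.Kfs, c.Kag, c.z,
        c.D / state.membrane.w * M3_TO_L, c.Dc / state.membrane.w * M3_TO_L,
        A_out, A_in,
        ts, n_steps, rem,
        state.ev.Hs if state.ev.Hs > 0 else state.nH_out / g.Vout,
        state.iv.Hs if state.iv.Hs > 0 else state.nH_in / g.Vin,
    )
    if status != 0:
        raise InstabilityError(
            f"step of {ts} s at t ~= {state.t + done * ts:.6g} s would have driven the "
            f"{_kernel.STATUS_MESSAGES[status]} pool negative; last valid state at t = {state.t} s"
            if status != 5
            else f"equilibrium solver failed at t ~= {state.t + done * ts:.6g} s"
        )
    new = replace(state, t=state.t + span, nH_out=nH_o, nG_out=nG_o, nH_in=nH_i, nG_in=nG_i)
    return _equilibrate(new)


def advance(state: SystemState, ts: float, flux_area: str = "bilayer") -> SystemState:
    """One explicit Euler step of size ``ts`` (s); returns the new state.

    Both fluxes are evaluated on the pre-step equilibrated state and applied
    simultaneously; the compartments are then re-equilibrated instantly.
    """
    if not ts > 0:
        raise ConfigError("ts must be > 0")
    return _run_interval(state, ts, ts, flux_area)


def _species_fluxes(state: SystemState) -> tuple[float, float]:
    """Signed flux densities (J_carrier, J_complex), mol m^-2 s^-1."""
    w = state.membrane.w
    J = flux_density(state.ev.Hm, state.iv.Hm, state.carrier.D, w)
    Jc = flux_density(state.ev.HGm, state.iv.HGm, state.carrier.Dc, w)
    return J, Jc


def adapt_timestep(state: SystemState, cfg: SimConfig, ts_current: float) -> float:
    """Largest step keeping every donor membrane pool's loss below the cap.

    For each membrane-crossing species the donor pool is the membrane-bound
    amount on the higher-concentration side; the admissible step is
    ``cap * n_pool / (|J| * A)``.  The minimum over species is clamped to
    ``[ts_init, ts_max]``; with no driving gradients the cap ``ts_max`` is
    returned.
    """
    g = state.geometry
    A_out, A_in = _flux_areas(g, cfg.flux_area)
    J, Jc = _species_fluxes(state)
    bound = math.inf
    for flux, out_conc, in_conc in (
        (J, state.ev.Hm, state.iv.Hm),
        (Jc, state.ev.HGm, state.iv.HGm),
    ):
        if flux == 0.0:
            continue
        ev_is_donor = out_conc > in_conc
        n_pool = out_conc * g.Vout if ev_is_donor else in_conc * g.Vin
        area = A_out if ev_is_donor else A_in
        bound = min(bound, cfg.depletion_cap * n_pool / (abs(flux) * area))
    if math.isinf(bound):
        return cfg.ts_max
    return min(max(bound, cfg.ts_init), cfg.ts_max)


def coverage_fraction(
    n_Hm: float, n_HGm: float, area_H: float, area_HG: float, leaflet_area: float
) -> float:
    """Occupied-area fraction of one leaflet.

    ``n_Hm``/``n_HGm`` are moles of membrane-bound carrier/complex on that
    leaflet, ``area_H``/``area_HG`` molecular footprints in m^2 and
    ``leaflet_area`` the total leaflet area in m^2.
    """
    return (n_Hm * area_H + n_HGm * area_HG) * AVOGADRO / leaflet_area


def surface_coverage(state: SystemState) -> tuple[float, float]:
    """Per-leaflet (outer, inner) occupied-area fractions.

    Requires ``area_H`` and ``area_HG`` on the carrier spec.
    """
    c = state.carrier
    if c.area_H is None or c.area_HG is None:
        raise ConfigError("surface coverage requires CarrierSpec.area_H and area_HG")
    g = state.geometry
    out = coverage_fraction(state.ev.Hm * g.Vout, state.ev.HGm * g.Vout, c.area_H, c.area_HG, g.Av_out)
    inner = coverage_fraction(state.iv.Hm * g.Vin, state.iv.HGm * g.Vin, c.area_H, c.area_HG, g.Av_in)
    return out, inner


@dataclass
class Trajectory:
    """Dwell-sampled time series of a simulation.

    ``ev``/``iv`` are ``(n_samples, 6)`` concentration arrays in the
    :data:`SPECIES` column order; ``release`` is the fraction of total guest
    moles free in the EV solution; ``cons_H``/``cons_G`` are relative
    conservation residuals; coverage columns are NaN when monitoring is off.
    ``ts_applied`` is the step in force during the interval ending at each
    sample (0 at t = 0).
    """

    times: np.ndarray
    ts_applied: np.ndarray
    ev: np.ndarray
    iv: np.ndarray
    release: np.ndarray
    cons_H: np.ndarray
    cons_G: np.ndarray
    coverage_out: np.ndarray
    coverage_in: np.ndarray
    max_flux: np.ndarray
    dose_molpct: float
    guest_moles: float
    dwell: float
    geometry: VesicleGeometry
    carrier: CarrierSpec | None = field(repr=False, default=None)
    membrane: MembraneSpec | None = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Flat per-dwell table (one row per sample) for delimited-text export."""
        data = {"t_s": self.times, "ts_s": self.ts_applied}
        for j, name in enumerate(SPECIES):
            data[f"ev_{name}"] = self.ev[:, j]
        for j, name in enumerate(SPECIES):
            data[f"iv_{name}"] = self.iv[:, j]
        data["release"] = self.release
        data["cons_res_H"] = self.cons_H
        data["cons_res_G"] = self.cons_G
        data["coverage_out"] = self.coverage_out
        data["coverage_in"] = self.coverage_in
        data["max_flux"] = self.max_flux
        return pd.DataFrame(data)


def simulate(
    carrier: CarrierSpec,
    membrane: MembraneSpec,
    dispersion: DispersionSpec,
    dose_molpct: float,
    guest_in: float,
    cfg: SimConfig = SimConfig(),
) -> Trajectory:
    """Run a full release experiment and return the dwell-sampled trajectory.

    At t = 0 all guest is intravesicular and all carrier extravesicular; the
    system is then advanced to ``cfg.t_total`` with the (possibly adaptive)
    explicit scheme, sampling at every multiple of ``cfg.dwell``.
    """
    state = initial_state(carrier, membrane, dispersion, dose_molpct, guest_in)
    g = state.geometry
    log.info(
        "geometry: n_v=%.4g, lipids/vesicle=%.4g, Av_out=%.4g m^2, Av_in=%.4g m^2, "
        "Vin=%.4g L, Vout=%.4g L (Vout/Vin=%.4g)",
        g.n_v, g.lipids_per_vesicle, g.Av_out, g.Av_in, g.Vin, g.Vout, g.Vout / g.Vin,
    )

    H0 = state.total_H_moles
    G0 = state.total_G_moles
    monitor_coverage = carrier.area_H is not None and carrier.area_HG is not None
    if not monitor_coverage:
        log.info("surface-coverage monitoring disabled (no footprint areas given)")

    n_full = int(cfg.t_total / cfg.dwell + 1e-9)
    grid = [i * cfg.dwell for i in range(n_full + 1)]
    if grid[-1] < cfg.t_total - 1e-9 * cfg.dwell:
        grid.append(cfg.t_total)

    rows_t, rows_ts = [0.0], [0.0]
    ev_rows, iv_rows = [state.ev.as_tuple()], [state.iv.as_tuple()]
    rel_rows, consH_rows, consG_rows = [], [], []
    cov_out_rows, cov_in_rows, flux_rows = [], [], []
    warned_coverage = False

    def record_derived(st: SystemState) -> None:
        nonlocal warned_coverage
        rel = st.ev.G * g.Vout / G0 if G0 > 0 else 0.0
        rel_rows.append(rel)
        consH_rows.append((st.total_H_moles - H0) / H0 if H0 > 0 else 0.0)
        consG_rows.append((st.total_G_moles - G0) / G0 if G0 > 0 else 0.0)
        J, Jc = _species_fluxes(st)
        flux_rows.append(max(abs(J), abs(Jc)))
        if monitor_coverage:
            cov = surface_coverage(st)
            cov_out_rows.append(cov[0])
            cov_in_rows.append(cov[1])
            if not warned_coverage and max(cov) > cfg.coverage_warn:
                log.warning("surface coverage %.3g exceeds %.3g at t=%.6g s", max(cov), cfg.coverage_warn, st.t)
                warned_coverage = True
        else:
            cov_out_rows.append(math.nan)
            cov_in_rows.append(math.nan)

    record_derived(state)

    ts = cfg.ts_init
    for t0, t1 in zip(grid[:-1], grid[1:]):
        # The step bound is evaluated on dwell boundaries, but gradients can
        # grow within a dwell; on an overshoot (a donor pool would go
        # negative) the dwell is retried from its boundary with half the step.
        for _ in range(60):
            try:
                state = _run_interval(state, ts, t1 - t0, cfg.flux_area)
                break
            except InstabilityError:
                if not cfg.adaptive:  # a pinned step is the caller's choice
                    raise
                ts /= 2.0
                log.debug("dwell at t=%.6g s retried with ts=%.3g s", t0, ts)
        else:
            raise InstabilityError(
                f"dwell starting at t={t0} s remained unstable after 60 step halvings"
            )
        rows_t.append(t1)
        rows_ts.append(ts)
        ev_rows.append(state.ev.as_tuple())
        iv_rows.append(state.iv.as_tuple())
        record_derived(state)
        if abs(consH_rows[-1]) > 1e-9 or abs(consG_rows[-1]) > 1e-9:
            log.warning(
                "conservation drift at t=%.6g s: H %.3g, G %.3g",
                t1, consH_rows[-1], consG_rows[-1],
            )
        log.debug(
            "t=%.6g s ts=%.3g s max|J|=%.3g release=%.6g consH=%.2g consG=%.2g",
            t1, ts, flux_rows[-1], rel_rows[-1], consH_rows[-1], consG_rows[-1],
        )
        if cfg.adaptive:
            ts = adapt_timestep(state, cfg, ts)

    return Trajectory(
        times=np.asarray(rows_t),
        ts_applied=np.asarray(rows_ts),
        ev=np.asarray(ev_rows),
        iv=np.asarray(iv_rows),
        release=np.asarray(rel_rows),
        cons_H=np.asarray(consH_rows),
        cons_G=np.asarray(consG_rows),
        coverage_out=np.asarray(cov_out_rows),
        coverage_in=np.asarray(cov_in_rows),
        max_flux=np.asarray(flux_rows),
        dose_molpct=dose_molpct,
        guest_moles=G0,
        dwell=cfg.dwell,
        geometry=g,
        carrier=carrier,
        membrane=membrane,
    )
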