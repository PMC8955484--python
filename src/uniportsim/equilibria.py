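"""Per-compartment chemical equilibria.

Six species are resolved in each aqueous compartment of the vesicle
dispersion: free carrier in solution (Hs), carrier-anion complex in solution
(HGs), membrane-bound carrier (Hm), membrane-bound complex (HGm), solution
aggregate (Hz) and free anion (G).  All concentrations are mol L^-1
referenced to the compartment's water volume; the water/lipid partition term
uses a single global lipid concentration ``[L] = total lipid / Vtot`` on both
sides of the membrane (only with an identical partition factor on both sides
can the transmembrane fluxes vanish when the solution concentrations
equalize).

The coupled equilibria are::

    Hm + G  <-> HGm      Kfm = [HG]m / ([H]m [G])      (membrane binding)
    Hs + G  <-> HGs      Kfs = [HG]s / ([H]s [G])      (solution binding)
    Hs      <-> Hm       [H]m = P*gammaL*[L]*[H]s      (partition)
    z Hs    <-> Hz       Kag = [Hz] / [H]s^z           (solution aggregation)

Eliminating everything in favour of ``x = [H]_s`` turns the carrier mass
balance into a quadratic (no aggregation, closed form) or a (z+1)-th-order
nonlinear equation (aggregation, safeguarded Newton); see ``_kernel``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import _kernel
from .errors import ConfigError, SolverError

__all__ = [
    "CarrierSpec",
    "CompartmentTotals",
    "SpeciesState",
    "kf_water",
    "partition_factor",
    "complex_partition",
    "solve_equilibrium",
    "equilibrium_residuals",
]


@dataclass(frozen=True)
class CarrierSpec:
    """Physico-chemical constants of one carrier (anionophore).

    Parameters
    ----------
    P : float
        Water/lipid partition coefficient of the free carrier, dimensionless.
    Kfm, Kfs : float
        Complex formation constants in the membrane and in solution, M^-1.
    D, Dc : float
        Membrane diffusion coefficients of the free carrier and of the
        complex, m^2 s^-1.
    Kag : float
        Solution aggregation constant, M^(1-z); 0 disables aggregation.
    z : float
        Aggregation number (monomers per aggregate); a real > 1, may be
        non-integer when used as an effective parameter.
    area_H, area_HG : float or None
        Molecular footprint areas, m^2, for surface-coverage monitoring
        (``None`` disables the monitor).
    """

    P: float
    Kfm: float
    Kfs: float
    D: float
    Dc: float
    Kag: float = 0.0
    z: float = 5.0
    area_H: float | None = None
    area_HG: float | None = None

    def __post_init__(self) -> None:
        for name in ("P", "Kfm", "Kfs", "D", "Dc", "Kag"):
            if getattr(self, name) < 0:
                raise ConfigError(f"CarrierSpec.{name} must be >= 0")
        if self.Kag > 0 and not self.z > 1:
            raise ConfigError("CarrierSpec.z must be > 1 when Kag > 0")
        for name in ("area_H", "area_HG"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ConfigError(f"CarrierSpec.{name} must be > 0 when given")


@dataclass(frozen=True)
class CompartmentTotals:
    """Conserved totals of one compartment.

    ``Htot``/``Gtot`` are total carrier/guest concentrations (all forms, M,
    referenced to the compartment water ``volume`` in litres).  ``L_global``
    is the partition-term lipid concentration, total lipid / Vtot, shared by
    both compartments.
    """

    Htot: float
    Gtot: float
    volume: float
    L_global: float

    def __post_init__(self) -> None:
        if self.Htot < 0 or self.Gtot < 0:
            raise ConfigError("CompartmentTotals.Htot/Gtot must be >= 0")
        if not self.volume > 0:
            raise ConfigError("CompartmentTotals.volume must be > 0")
        if self.L_global < 0:
            raise ConfigError("CompartmentTotals.L_global must be >= 0")


@dataclass(frozen=True)
class SpeciesState:
    """Resolved equilibrium concentrations of the six species, M."""

    Hs: float
    HGs: float
    Hm: float
    HGm: float
    Hz: float
    G: float

    def carrier_total(self, z: float) -> float:
        return self.Hs + self.HGs + self.Hm + self.HGm + z * self.Hz

    @property
    def guest_total(self) -> float:
        return self.G + self.HGs + self.HGm

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.Hs, self.HGs, self.Hm, self.HGm, self.Hz, self.G)


def kf_water(w_pct: float, a: float, b: float) -> float:
    """Binding constant vs water content: ``Kf = a * exp(-b * w%)``.

    Titration series of host-guest binding constants measured at increasing
    water volume-percent are well described by this exponential; evaluating
    the fit at ``w% = 0`` gives the membrane constant Kfm and at ``w% = 100``
    the solution constant Kfs.

    Parameters: ``w_pct`` water content in volume percent (0-100), ``a`` the
    fitted amplitude in M^-1 (> 0), ``b`` the fitted decay per percent.
    """
    if not 0 <= w_pct <= 100:
        raise ConfigError("w_pct must be within [0, 100]")
    if not a > 0:
        raise ConfigError("a must be > 0")
    return a * math.exp(-b * w_pct)


def partition_factor(P: float, gammaL: float, L_global: float) -> float:
    """Ratio [H]_m/[H]_s implied by the partition equilibrium: ``P*gammaL*[L]``."""
    if P < 0 or gammaL < 0 or L_global < 0:
        raise ConfigError("partition_factor arguments must be >= 0")
    return P * gammaL * L_global


def complex_partition(P: float, gammaL: float, gammaW: float, Kfm: float, Kfs: float) -> float:
    """Diagnostic complex partition constant ``K'p = Kp * Kfm / Kfs``.

    ``Kp = P*gammaL/gammaW`` is the thermodynamic partition constant of the
    free carrier.  K'p is fixed by the other three constants and never enters
    the simulation; it is exposed for reporting only.  Returns ``nan``
    (undefined) when ``Kfs = 0``.
    """
    if Kfs == 0:
        return math.nan
    return P * gammaL / gammaW * Kfm / Kfs


def _species_from_hs(x: float, totals: CompartmentTotals, carrier: CarrierSpec, pf: float) -> SpeciesState:
    c = pf * carrier.Kfm + carrier.Kfs
    G = totals.Gtot / (1.0 + c * x)
    Hm = pf * x
    HGm = carrier.Kfm * Hm * G
    HGs = carrier.Kfs * x * G
    Hz = carrier.Kag * x**carrier.z if carrier.Kag > 0 else 0.0
    return SpeciesState(Hs=x, HGs=HGs, Hm=Hm, HGm=HGm, Hz=Hz, G=G)


def solve_equilibrium(
    totals: CompartmentTotals,
    carrier: CarrierSpec,
    gammaL: float,
    method: str = "auto",
) -> SpeciesState:
    """Resolve the six species concentrations of one compartment.

    ``method`` selects the [H]_s root search: ``"analytic"`` (closed-form
    quadratic, requires ``Kag == 0``), ``"newton"`` (safeguarded
    Newton-Raphson started at Htot, works for any ``Kag``), or ``"auto"``
    (analytic when possible).  Both paths agree to machine precision when
    aggregation is off.
    """
    pf = partition_factor(carrier.P, gammaL, totals.L_global)
    if method == "auto":
        method = "analytic" if carrier.Kag == 0 else "newton"
    if method == "analytic":
        if carrier.Kag != 0:
            raise ConfigError("analytic path requires Kag == 0")
        x = _kernel.solve_hs_closed(totals.Htot, totals.Gtot, pf, carrier.Kfm, carrier.Kfs)
    elif method == "newton":
        x, status = _kernel.solve_hs_numeric(
            totals.Htot, totals.Gtot, pf, carrier.Kfm, carrier.Kfs,
            carrier.Kag, carrier.z, totals.Htot,
        )
        if status != 0:
            raise SolverError(
                f"Newton-Raphson did not converge for Htot={totals.Htot}, "
                f"Gtot={totals.Gtot}, pf={pf}, Kag={carrier.Kag}, z={carrier.z}"
            )
    else:
        raise ConfigError(f"unknown method {method!r}")
    if not 0.0 <= x <= totals.Htot * (1 + 1e-12):
        raise SolverError(f"no physical root in (0, Htot]: got [H]s={x}, Htot={totals.Htot}")
    return _species_from_hs(x, totals, carrier, pf)


def equilibrium_residuals(
    state: SpeciesState,
    totals: CompartmentTotals,
    carrier: CarrierSpec,
    gammaL: float,
) -> dict[str, float]:
    """Relative residuals of every equilibrium definition and mass balance.

    A correct solution drives each entry below ~1e-10; useful as a
    certificate that the returned state satisfies the model equations.
    """
    pf = partition_factor(carrier.P, gammaL, totals.L_global)

    def rel(lhs: float, rhs: float) -> float:
        scale = max(abs(lhs), abs(rhs))
        return 0.0 if scale == 0.0 else abs(lhs - rhs) / scale

    out = {
        "partition": rel(state.Hm, pf * state.Hs),
        "binding_membrane": rel(state.HGm, carrier.Kfm * state.Hm * state.G),
        "binding_solution": rel(state.HGs, carrier.Kfs * state.Hs * state.G),
        "aggregation": rel(state.Hz, carrier.Kag * state.Hs**carrier.z if carrier.Kag > 0 else 0.0),
        "carrier_balance": rel(state.carrier_total(carrier.z), totals.Htot),
        "guest_balance": rel(state.guest_total, totals.Gtot),
    }
    return out
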