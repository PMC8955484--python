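"""Vesicle-dispersion geometry.

Converts the macroscopic parameters of a unilamellar-vesicle dispersion
(total lipid concentration, vesicle diameter, lipid surface density, sample
volume) into the quantities the transport engine needs: vesicle count, total
leaflet areas and the intra-/extra-vesicular water volumes.

Two variants are provided.  The *equal-leaflet* model neglects the difference
between the outer and inner monolayer of the bilayer: the number of lipids
per vesicle is ``8*pi*(d/2)^2 * sigmaL`` (both leaflets at the outer radius)
and a single total area serves both sides.  The *curvature-corrected* model
keeps ``d/2`` as the outer radius and uses ``d/2 - w`` as the inner one, so
the two leaflets carry different lipid counts and areas and the internal
volume shrinks accordingly.  All lengths are SI (m); volumes are litres at
the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import AVOGADRO, M3_TO_L, WATER_MOLAR_VOLUME
from .errors import ConfigError

__all__ = ["MembraneSpec", "DispersionSpec", "VesicleGeometry", "build_geometry"]


@dataclass(frozen=True)
class MembraneSpec:
    """Lipid bilayer and vesicle-size parameters.

    Parameters
    ----------
    d : float
        Vesicle outer diameter, m.
    w : float
        Hydrophobic bilayer thickness, m (also the Fick diffusion length).
    sigmaL : float
        Lipid surface density of one monolayer, m^-2.
    gammaL : float
        Lipid molar volume, L mol^-1.
    gammaW : float
        Water molar volume, L mol^-1.
    curvature_corrected : bool
        Distinguish the outer and inner leaflet radii when building geometry.
    """

    d: float
    w: float
    sigmaL: float
    gammaL: float
    gammaW: float = WATER_MOLAR_VOLUME
    curvature_corrected: bool = False

    def __post_init__(self) -> None:
        for name in ("d", "w", "sigmaL", "gammaL", "gammaW"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"MembraneSpec.{name} must be > 0")
        if self.w >= self.d / 2:
            raise ConfigError(
                f"MembraneSpec.w ({self.w}) must be < d/2 ({self.d / 2}): "
                "the inner radius would be nonpositive"
            )


@dataclass(frozen=True)
class DispersionSpec:
    """Sample-level parameters.

    ``lipid_conc`` is the total lipid molar concentration (mol L^-1,
    referenced to the total sample volume ``Vtot`` in litres).
    """

    lipid_conc: float
    Vtot: float = 1.0

    def __post_init__(self) -> None:
        if not self.lipid_conc > 0:
            raise ConfigError("DispersionSpec.lipid_conc must be > 0")
        if not self.Vtot > 0:
            raise ConfigError("DispersionSpec.Vtot must be > 0")


@dataclass(frozen=True)
class VesicleGeometry:
    """Derived dispersion geometry.

    ``Av_out``/``Av_in`` are the *total* (all vesicles) outer/inner leaflet
    areas in m^2; ``Vin``/``Vout`` the total intra-/extra-vesicular water
    volumes in litres.  In the equal-leaflet model ``Av_out == Av_in``.
    """

    n_v: float
    lipids_per_vesicle: float
    Av_out: float
    Av_in: float
    Vin: float
    Vout: float

    @property
    def total_area(self) -> float:
        """Total membrane area counting both leaflets, m^2."""
        return self.Av_out + self.Av_in


def build_geometry(membrane: MembraneSpec, dispersion: DispersionSpec) -> VesicleGeometry:
    """Derive vesicle counts, leaflet areas and compartment volumes.

    Equal-leaflet mode: lipids per vesicle ``8*pi*(d/2)^2*sigmaL``; the single
    total area ``[L]*Vtot*NA/(2*sigmaL)`` is used for both leaflets and the
    internal volume is ``n_v*(4/3)*pi*(d/2)^3`` (converted to litres).
    Curvature mode: the outer radius stays ``d/2``, the inner radius is
    ``d/2 - w``; lipid count, per-leaflet areas and the internal volume follow
    from the two radii.  ``Vout = Vtot - Vin`` in both modes.
    """
    r_out = membrane.d / 2
    r_in = r_out - membrane.w if membrane.curvature_corrected else r_out

    lipid_moles = dispersion.lipid_conc * dispersion.Vtot
    lipids_per_vesicle = 4 * math.pi * (r_out**2 + r_in**2) * membrane.sigmaL
    n_v = lipid_moles * AVOGADRO / lipids_per_vesicle
    Av_out = n_v * 4 * math.pi * r_out**2
    Av_in = n_v * 4 * math.pi * r_in**2
    Vin = n_v * (4.0 / 3.0) * math.pi * r_in**3 * M3_TO_L
    Vout = dispersion.Vtot - Vin
    if Vout <= 0:
        raise ConfigError(
            f"internal volume ({Vin} L) exceeds the sample volume "
            f"({dispersion.Vtot} L); lipid concentration too high for this model"
        )
    return VesicleGeometry(
        n_v=n_v,
        lipids_per_vesicle=lipids_per_vesicle,
        Av_out=Av_out,
        Av_in=Av_in,
        Vin=Vin,
        Vout=Vout,
    )
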