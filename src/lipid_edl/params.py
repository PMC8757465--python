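"""Validated parameter containers and derived physical quantities.

The system is a planar lipid monolayer at x = 0 in contact with an aqueous
half-space x > 0.  A fraction ``beta`` of the lipids is "non-structured": its
head group is a single point charge lying in the plane.  The remaining fraction
``1 - beta`` carries a structured head group: an anchored charge q0 in the
plane plus one or two mobile charges (q1, q2) on rigid segments that protrude
into the solution.  All in-plane charge (q0 of every lipid plus the full charge
of the non-structured lipids) is smeared into a uniform surface charge density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    MOLAR_TO_NM3,
    NM,
    VACUUM_PERMITTIVITY,
)

COUNTERIONS_ONLY = "counterions_only"
SALT_1_1 = "salt_1_1"

RIGID_ROTOR = "rigid_rotor"
FLEXIBLE = "flexible"
TRIANGULAR = "triangular"
ZWITTERIONIC = "zwitterionic"

VARIANTS = (RIGID_ROTOR, FLEXIBLE, TRIANGULAR, ZWITTERIONIC)


class ParameterError(ValueError):
    """Raised for physically inadmissible model parameters."""


def bjerrum_length(temperature: float, dielectric_constant: float) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps_w eps_0 k_B T) in nm.

    The separation at which two elementary charges in the medium interact with
    thermal energy k_B*T; 0.70 nm in water (eps_w = 80) at 298 K.
    """
    if temperature <= 0:
        raise ParameterError(f"temperature must be positive, got {temperature}")
    if dielectric_constant < 1:
        raise ParameterError(
            f"dielectric constant must be >= 1, got {dielectric_constant}"
        )
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0
        * math.pi
        * dielectric_constant
        * VACUUM_PERMITTIVITY
        * BOLTZMANN
        * temperature
    )
    return lb_m / NM


def surface_charge_density(area_per_lipid: float, q_eff: float) -> float:
    """Surface charge density sigma = q_eff * e / a in C/m^2.

    ``area_per_lipid`` is in nm^2, ``q_eff`` is a charge number (signed).
    """
    if area_per_lipid <= 0:
        raise ParameterError(
            f"area per lipid must be positive, got {area_per_lipid}"
        )
    return q_eff * ELEMENTARY_CHARGE / (area_per_lipid * NM**2)


def debye_length(
    bulk_concentration: float,
    temperature: float = 298.0,
    dielectric_constant: float = 80.0,
) -> float:
    """Debye screening length of a 1:1 electrolyte in nm.

    l_D = sqrt(eps_0 eps_w k_B T / (2 n_0 e^2)) with n_0 the bulk number
    density of each monovalent species; ~1 nm at 0.1 mol/dm^3 in water.
    """
    if bulk_concentration <= 0:
        raise ParameterError(
            f"bulk concentration must be positive, got {bulk_concentration}"
        )
    n0_m3 = bulk_concentration * 1000.0 * AVOGADRO
    ld_m = math.sqrt(
        VACUUM_PERMITTIVITY
        * dielectric_constant
        * BOLTZMANN
        * temperature
        / (2.0 * n0_m3 * ELEMENTARY_CHARGE**2)
    )
    return ld_m / NM


@dataclass(frozen=True)
class SystemParams:
    """Physical and compositional parameters of the monolayer/electrolyte system.

    Parameters
    ----------
    area_per_lipid : float
        Surface area per lipid molecule a, nm^2.
    beta : float
        Mole fraction of non-structured (point-charge-only) lipids in [0, 1].
        The structured fraction is 1 - beta.
    electrolyte_mode : str
        ``"counterions_only"`` or ``"salt_1_1"``.
    bulk_concentration : float, optional
        Bulk 1:1 salt concentration c in mol/dm^3; required in salt mode.
    temperature : float
        Absolute temperature in K.
    dielectric_constant : float
        Relative permittivity of the aqueous phase eps_w.
    nonstructured_charge : float
        Charge number of the point-like lipid component (default -1).
    de_broglie : float
        Gauge constant v of the counterions-only ideal-gas entropy; shifts the
        normalization multiplier lambda but no observable profile.
    """

    area_per_lipid: float
    beta: float = 0.5
    electrolyte_mode: str = COUNTERIONS_ONLY
    bulk_concentration: Optional[float] = None
    temperature: float = 298.0
    dielectric_constant: float = 80.0
    nonstructured_charge: float = -1.0
    de_broglie: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.dielectric_constant < 1:
            raise ParameterError("dielectric constant must be >= 1")
        if self.area_per_lipid <= 0:
            raise ParameterError("area per lipid must be positive")
        if not 0.0 <= self.beta <= 1.0:
            raise ParameterError(f"beta must be in [0, 1], got {self.beta}")
        if self.electrolyte_mode not in (COUNTERIONS_ONLY, SALT_1_1):
            raise ParameterError(
                f"unknown electrolyte mode {self.electrolyte_mode!r}"
            )
        if self.electrolyte_mode == SALT_1_1:
            if self.bulk_concentration is None or self.bulk_concentration <= 0:
                raise ParameterError(
                    "salt_1_1 mode requires a positive bulk_concentration"
                )

    @property
    def bjerrum_length(self) -> float:
        """l_B in nm."""
        return bjerrum_length(self.temperature, self.dielectric_constant)

    @property
    def debye_length(self) -> Optional[float]:
        """l_D in nm (salt mode only, else None)."""
        if self.electrolyte_mode != SALT_1_1:
            return None
        return debye_length(
            self.bulk_concentration, self.temperature, self.dielectric_constant
        )

    @property
    def bulk_density(self) -> Optional[float]:
        """Bulk number density n_0 of each ion species in nm^-3 (salt mode)."""
        if self.electrolyte_mode != SALT_1_1:
            return None
        return self.bulk_concentration * MOLAR_TO_NM3

    @property
    def thermal_voltage(self) -> float:
        """k_B T / e in volts."""
        return BOLTZMANN * self.temperature / ELEMENTARY_CHARGE


@dataclass(frozen=True)
class HeadGroupSpec:
    """Geometry and discrete charges of the structured head-group variant.

    Charge q0 is anchored in the plane x = 0 for every variant.  For the rigid
    rotor and the flexible head group, q1 sits at the end of the first segment
    (length l1) and q2 at the end of the second (length l2).  For the
    triangular head group the two arms (length l1 = l2 = l) carry q1 and q2 at
    their tips with fixed apex angle alpha between them.  The zwitterionic
    variant is a single segment (l2 = 0) with terminal charge q1.
    """

    variant: str
    l1: float
    l2: float = 0.0
    q0: float = -1.0
    q1: float = 1.0
    q2: float = -1.0
    alpha: float = 0.0  # degrees, triangular only

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown head-group variant {self.variant!r}")
        if self.l1 <= 0:
            raise ParameterError("l1 must be positive")
        if self.variant == ZWITTERIONIC:
            if self.l2 != 0.0:
                raise ParameterError("zwitterionic head group has l2 = 0")
        else:
            if self.l2 <= 0:
                raise ParameterError("l2 must be positive")
        if self.variant == TRIANGULAR:
            if not 0.0 < self.alpha < 180.0:
                raise ParameterError(
                    f"apex angle must lie in (0, 180) degrees, got {self.alpha}"
                )

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha)

    @property
    def mobile_charge(self) -> float:
        """Total mobile charge number per structured head group."""
        if self.variant == ZWITTERIONIC:
            return self.q1
        return self.q1 + self.q2


class HeadGroupExtent:
    """Extent of a head group along the surface normal, nm.

    ``extent`` is the maximal projection of the outermost mobile charge
    (rotor/flexible: l1 + l2; triangular: l*cos(alpha/2) for the centre of
    mass of the charge pair).  ``exclusion`` is the triangular lower support
    bound l*sin(alpha/2) below which the centre-of-mass projection has zero
    probability; 0 for the other variants.
    """

    __slots__ = ("extent", "exclusion")

    def __init__(self, extent: float, exclusion: float = 0.0):
        self.extent = extent
        self.exclusion = exclusion

    def __iter__(self):
        return iter((self.extent, self.exclusion))

    def __repr__(self) -> str:  # pragma: no cover
        return f"HeadGroupExtent(extent={self.extent}, exclusion={self.exclusion})"


def headgroup_extent(spec: HeadGroupSpec) -> HeadGroupExtent:
    """Extent (and, for the triangular variant, exclusion bound) of ``spec``."""
    if spec.variant == TRIANGULAR:
        if spec.l1 != spec.l2:
            raise ParameterError(
                "triangular head group extent is defined for equal arms"
            )
        half = 0.5 * spec.alpha_rad
        return HeadGroupExtent(
            spec.l1 * math.cos(half), spec.l1 * math.sin(half)
        )
    return HeadGroupExtent(spec.l1 + spec.l2)


def plane_charge_density(params: SystemParams, spec: HeadGroupSpec) -> float:
    """Smeared in-plane charge at x = 0, in e/nm^2 (signed).

    Carries q0 of all structured lipids plus the full charge of the
    non-structured component.
    """
    return (
        (1.0 - params.beta) * spec.q0
        + params.beta * params.nonstructured_charge
    ) / params.area_per_lipid


def counterion_valence(params: SystemParams, spec: HeadGroupSpec) -> int:
    """Charge number of the neutralizing counterion in counterions-only mode."""
    total = plane_charge_density(params, spec) + (
        1.0 - params.beta
    ) * spec.mobile_charge / params.area_per_lipid
    if total == 0.0:
        return 1
    return 1 if total < 0 else -1


@dataclass(frozen=True)
class PhysicalContext:
    """Derived physical quantities in laboratory units."""

    bjerrum_length: float  # nm
    surface_charge_density: float  # C/m^2, sign of the in-plane charge
    thermal_voltage: float  # V
    debye_length: Optional[float] = None  # nm, salt mode only

    @classmethod
    def from_params(
        cls, params: SystemParams, spec: HeadGroupSpec
    ) -> "PhysicalContext":
        sigma_e = plane_charge_density(params, spec)  # e/nm^2
        return cls(
            bjerrum_length=params.bjerrum_length,
            surface_charge_density=sigma_e
            * ELEMENTARY_CHARGE
            / NM**2
            * 1.0,
            thermal_voltage=params.thermal_voltage,
            debye_length=params.debye_length,
        )
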