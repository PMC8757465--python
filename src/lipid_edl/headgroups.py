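"""Head-group orientation states, supports, and volume-charge assembly.

Each structured head-group variant defines an orientation coordinate (the
projection of its mobile charges on the surface normal), an admissible support,
and a probability density W over that support.  The entropy -int W ln W is
taken with respect to the uniform measure in the projected coordinate(s); for a
rigid segment pivoting isotropically this is exactly the Archimedes projection
of the uniform hemisphere measure.  At stationarity W is the Boltzmann weight
of the segment electrostatic energies, normalized by a Lagrange multiplier.

Charge assembly deposits quadrature-weighted orientation masses onto the
solver grid with a mass-conserving cloud-in-cell rule, so that the integrated
head charge per lipid is exact (no quadrature leak into electroneutrality) and
jumps of the density at region boundaries are represented by their half-cell
averages automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .grid import Grid
from .params import (
    FLEXIBLE,
    HeadGroupSpec,
    ParameterError,
    RIGID_ROTOR,
    SystemParams,
    TRIANGULAR,
    ZWITTERIONIC,
)

_EXP_CLIP = 200.0


class ContractError(ValueError):
    """Raised when a density handed to an operation violates its contract."""


# ---------------------------------------------------------------------------
# Supports


def support_rigid(spec: HeadGroupSpec) -> tuple[float, float]:
    """Interval [0, l1] of the middle-charge projection of a rigid rotor.

    The rotor is a straight two-segment rod pivoting about its anchor in the
    half-space, so the middle charge projects onto [0, l1] and the terminal
    charge is slaved to s = x (l1 + l2)/l1 by collinearity.
    """
    if spec.variant not in (RIGID_ROTOR, ZWITTERIONIC):
        raise ParameterError("support_rigid requires a rigid rotor variant")
    return (0.0, spec.l1)


@dataclass(frozen=True)
class FlexibleSupport:
    """Admissible (x, s) region Omega of the flexible head group.

    x in [0, l1] is the middle-charge projection; given x the terminal charge
    (bond length l2, free joint) projects onto s in [max(0, x - l2), x + l2]:
    the Archimedes shell around the middle charge clipped by the wall.
    """

    l1: float
    l2: float

    @property
    def x_range(self) -> tuple[float, float]:
        return (0.0, self.l1)

    def s_range(self, x: float) -> tuple[float, float]:
        return (max(0.0, x - self.l2), x + self.l2)

    def contains(self, x: float, s: float, atol: float = 1e-12) -> bool:
        if not -atol <= x <= self.l1 + atol:
            return False
        lo, hi = self.s_range(x)
        return lo - atol <= s <= hi + atol


def support_flexible(spec: HeadGroupSpec) -> FlexibleSupport:
    if spec.variant != FLEXIBLE:
        raise ParameterError("support_flexible requires the flexible variant")
    return FlexibleSupport(l1=spec.l1, l2=spec.l2)


def support_triangular(spec: HeadGroupSpec) -> tuple[float, float]:
    """Support [l sin(alpha/2), l cos(alpha/2)] of the centre-of-mass projection.

    The triangle (anchor plus two arms of length l at apex angle alpha)
    rotates within a plane normal to the surface; wall non-penetration of both
    apex charges restricts the projection x of the charge pair's centre of
    mass to this interval.
    """
    if spec.variant != TRIANGULAR:
        raise ParameterError("support_triangular requires the triangular variant")
    if spec.l1 != spec.l2:
        raise ParameterError("triangular support is defined for equal arms")
    half = 0.5 * spec.alpha_rad
    return (spec.l1 * math.sin(half), spec.l1 * math.cos(half))


def triangle_charge_heights(
    spec: HeadGroupSpec, x_com: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Heights of the two apex charges for centre-of-mass projection x_com.

    The bisector elevation is theta = arcsin(x_com / (l cos(alpha/2))); the
    charges sit at l sin(theta -+ alpha/2).  Vectorized; values are clipped
    to the admissible sine range.
    """
    half = 0.5 * spec.alpha_rad
    l = spec.l1
    arg = np.clip(np.asarray(x_com, dtype=float) / (l * math.cos(half)), -1.0, 1.0)
    theta = np.arcsin(arg)
    h1 = l * np.sin(theta - half)
    h2 = l * np.sin(theta + half)
    return np.clip(h1, 0.0, None), h2


# ---------------------------------------------------------------------------
# Density containers


@dataclass
class OrientationDensity:
    """Normalized orientation probability density of a head-group variant.

    ``x``/``W`` hold the one-dimensional density on its support grid (for the
    flexible variant, the marginal W_x).  Flexible runs additionally carry the
    (x, s) grid, the full density ``W2d`` with its quadrature measure, and the
    terminal marginal ``W_s`` on ``s``.  ``charge_profiles`` are the deposited
    number densities (unit integral each) of the mobile charges on the solver
    grid, used for volume-charge assembly.
    """

    variant: str
    x: np.ndarray
    W: np.ndarray
    area_per_lipid: float
    structured_fraction: float
    charge_profiles: Dict[str, np.ndarray] = field(default_factory=dict)
    grid_x: Optional[np.ndarray] = None
    s: Optional[np.ndarray] = None
    W_s: Optional[np.ndarray] = None
    W2d: Optional[np.ndarray] = None
    measure2d: Optional[np.ndarray] = None

    def integral(self) -> float:
        return float(np.trapezoid(self.W, self.x))

    def integral_s(self) -> Optional[float]:
        if self.W_s is None:
            return None
        return float(np.trapezoid(self.W_s, self.s))


@dataclass
class ChargeDensityField:
    """Volume charge density rho(x)/e in e/nm^3 on the solver grid."""

    x: np.ndarray
    rho: np.ndarray
    rho_ions: np.ndarray
    rho_head: np.ndarray


def assemble_charge_density(
    W: OrientationDensity,
    n_plus: np.ndarray,
    n_minus: np.ndarray,
    params: SystemParams,
    spec: HeadGroupSpec,
) -> ChargeDensityField:
    """rho/e = (n+ - n-) + (1-beta)/a * [q1, q2 contributions placed by W]."""
    if abs(W.integral() - 1.0) > 1e-6:
        raise ContractError(
            f"orientation density is not normalized: integral={W.integral()}"
        )
    f = W.structured_fraction / W.area_per_lipid
    rho_head = np.zeros_like(np.asarray(n_plus, dtype=float))
    charge_of = {"q1": spec.q1, "q2": spec.q2}
    for key, profile in W.charge_profiles.items():
        rho_head = rho_head + f * charge_of[key] * profile
    rho_ions = np.asarray(n_plus, dtype=float) - np.asarray(n_minus, dtype=float)
    return ChargeDensityField(
        x=W.grid_x if W.grid_x is not None else W.x,
        rho=rho_ions + rho_head,
        rho_ions=rho_ions,
        rho_head=rho_head,
    )


# ---------------------------------------------------------------------------
# Deposition


class _Depositor:
    """Mass-conserving linear (cloud-in-cell) deposition onto grid nodes.

    Node values are cell masses divided by the trapezoid weights, so that
    trapezoidal integration of the deposited density returns the total mass
    exactly.
    """

    def __init__(self, grid: Grid, positions: np.ndarray):
        h = grid.h
        n = grid.n_nodes
        p = np.clip(np.asarray(positions, dtype=float), 0.0, grid.x_max)
        idx = np.minimum((p / h).astype(int), n - 2)
        frac = p / h - idx
        # snap float jitter at nodes
        frac[frac > 1.0 - 1e-12] = 1.0
        frac[frac < 1e-12] = 0.0
        self.idx = idx
        self.frac = frac
        self.n = n
        self.w = grid.trapz_weights

    def __call__(self, masses: np.ndarray) -> np.ndarray:
        acc = np.zeros(self.n)
        np.add.at(acc, self.idx, masses * (1.0 - self.frac))
        np.add.at(acc, self.idx + 1, masses * self.frac)
        return acc / self.w


def _interp_coeffs(grid: Grid, positions: np.ndarray):
    """(idx, frac) for linear interpolation of node arrays at ``positions``."""
    h = grid.h
    p = np.clip(np.asarray(positions, dtype=float), 0.0, grid.x_max)
    idx = np.minimum((p / h).astype(int), grid.n_nodes - 2)
    frac = p / h - idx
    return idx, np.clip(frac, 0.0, 1.0)


def _bexp(arg: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(arg, -_EXP_CLIP, _EXP_CLIP))


# ---------------------------------------------------------------------------
# Variant models


class HeadModel:
    """Maps a reduced-potential node array to head-group charge density.

    ``rho_head(psi)`` returns (1-beta)/a-weighted charge number density on the
    solver grid; ``orientation(psi)`` builds the full OrientationDensity.
    """

    def __init__(self, params: SystemParams, spec: HeadGroupSpec, grid: Grid):
        self.params = params
        self.spec = spec
        self.grid = grid
        self.f = (1.0 - params.beta) / params.area_per_lipid

    def rho_head(self, psi: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def orientation(self, psi: np.ndarray) -> OrientationDensity:
        raise NotImplementedError

    def log_partition(self, psi: np.ndarray) -> float:
        """ln Z of the orientation Boltzmann weight (for the multiplier)."""
        raise NotImplementedError


class _NoHead(HeadModel):
    """beta = 1: no structured lipids; head charge vanishes identically."""

    def rho_head(self, psi):
        return np.zeros(self.grid.n_nodes)

    def orientation(self, psi):
        x = self.grid.x[: self.grid.i_d1 + 1]
        W = np.full(len(x), 1.0 / self.grid.d1)
        return OrientationDensity(
            variant=self.spec.variant,
            x=x,
            W=W,
            area_per_lipid=self.params.area_per_lipid,
            structured_fraction=0.0,
            charge_profiles={},
            grid_x=self.grid.x,
        )

    def log_partition(self, psi):
        return 0.0


class RotorHead(HeadModel):
    """Rigid rotor: collinear segments l1, l2; W(x) on [0, l1].

    The middle charge q1 projects to x; the terminal charge q2 is slaved to
    s = x (l1+l2)/l1 and contributes with the projection Jacobian l1/(l1+l2)
    (handled implicitly by mass deposition).
    """

    def __init__(self, params, spec, grid):
        super().__init__(params, spec, grid)
        m = grid.i_d2 if grid.i_d2 is not None else grid.i_d1
        self.y = grid.x[: m + 1]
        self.wy = np.full(m + 1, grid.h)
        self.wy[0] = self.wy[-1] = 0.5 * grid.h
        self.zwitterionic = spec.variant == ZWITTERIONIC
        if self.zwitterionic:
            self.s_term = None
        else:
            ratio = (spec.l1 + spec.l2) / spec.l1
            self.s_term = self.y * ratio
            self._term_interp = _interp_coeffs(grid, self.s_term)
            self._dep_term = _Depositor(grid, self.s_term)
        self._dep_mid = _Depositor(grid, self.y)

    def _boltzmann(self, psi: np.ndarray) -> np.ndarray:
        m = len(self.y) - 1
        u = self.spec.q1 * psi[: m + 1]
        if not self.zwitterionic:
            idx, frac = self._term_interp
            psi_term = psi[idx] * (1.0 - frac) + psi[idx + 1] * frac
            u = u + self.spec.q2 * psi_term
        return _bexp(-u)

    def _normalized(self, psi):
        B = self._boltzmann(psi)
        Z = float(self.wy @ B)
        return B / Z, Z

    def rho_head(self, psi):
        W, _ = self._normalized(psi)
        masses = self.wy * W
        rho = self.spec.q1 * self._dep_mid(masses)
        if not self.zwitterionic:
            rho = rho + self.spec.q2 * self._dep_term(masses)
        return self.f * rho

    def orientation(self, psi):
        W, _ = self._normalized(psi)
        masses = self.wy * W
        profiles = {"q1": self._dep_mid(masses)}
        if not self.zwitterionic:
            profiles["q2"] = self._dep_term(masses)
        return OrientationDensity(
            variant=self.spec.variant,
            x=self.y.copy(),
            W=W,
            area_per_lipid=self.params.area_per_lipid,
            structured_fraction=1.0 - self.params.beta,
            charge_profiles=profiles,
            grid_x=self.grid.x,
        )

    def log_partition(self, psi):
        B = self._boltzmann(psi)
        return math.log(float(self.wy @ B))


class FlexibleHead(HeadModel):
    """Flexible head group: W(x, s) on Omega, tensor grid masked to Omega."""

    def __init__(self, params, spec, grid):
        super().__init__(params, spec, grid)
        if grid.i_d2 is None:
            raise ParameterError("flexible head group requires l2 > 0")
        h = grid.h
        self.nx = grid.i_d2
        self.ns = grid.i_d1
        self.xg = grid.x[: self.nx + 1]
        self.sg = grid.x[: self.ns + 1]
        n2 = round(spec.l2 / h)
        # row s-index limits: s in [max(0, x_i - l2), x_i + l2], exact nodes
        self.j_lo = np.maximum(np.arange(self.nx + 1) - n2, 0)
        self.j_hi = np.arange(self.nx + 1) + n2
        wx = np.full(self.nx + 1, h)
        wx[0] = wx[-1] = 0.5 * h
        self.wx = wx
        ws_full = np.full(self.ns + 1, h)
        ws_full[0] = ws_full[-1] = 0.5 * h
        self.ws_full = ws_full
        # 2D quadrature measure V_ij = wx_i * ws_j(row i), zero outside Omega
        V = np.zeros((self.nx + 1, self.ns + 1))
        cols = np.arange(self.ns + 1)
        for i in range(self.nx + 1):
            lo, hi = self.j_lo[i], self.j_hi[i]
            row = np.where((cols >= lo) & (cols <= hi), h, 0.0)
            row[lo] = 0.5 * h
            row[hi] = 0.5 * h
            V[i] = wx[i] * row
        self.V = V

    def _weights(self, psi):
        bx = _bexp(-self.spec.q1 * psi[: self.nx + 1])
        bs = _bexp(-self.spec.q2 * psi[: self.ns + 1])
        M = self.V * np.outer(bx, bs)
        Z = float(M.sum())
        return M, Z, bx, bs

    def rho_head(self, psi):
        M, Z, _, _ = self._weights(psi)
        rho = np.zeros(self.grid.n_nodes)
        mass_x = M.sum(axis=1) / Z
        mass_s = M.sum(axis=0) / Z
        rho[: self.nx + 1] += self.spec.q1 * mass_x / self.grid.trapz_weights[: self.nx + 1]
        rho[: self.ns + 1] += self.spec.q2 * mass_s / self.grid.trapz_weights[: self.ns + 1]
        return self.f * rho

    def orientation(self, psi):
        M, Z, bx, bs = self._weights(psi)
        mass_x = M.sum(axis=1) / Z
        mass_s = M.sum(axis=0) / Z
        W_x = mass_x / self.wx
        W_s = mass_s / self.ws_full
        W2d = np.outer(bx, bs) / Z
        W2d[self.V == 0.0] = 0.0
        wfull = self.grid.trapz_weights
        profiles = {
            "q1": np.concatenate(
                [mass_x / wfull[: self.nx + 1], np.zeros(self.grid.n_nodes - self.nx - 1)]
            ),
            "q2": np.concatenate(
                [mass_s / wfull[: self.ns + 1], np.zeros(self.grid.n_nodes - self.ns - 1)]
            ),
        }
        return OrientationDensity(
            variant=FLEXIBLE,
            x=self.xg.copy(),
            W=W_x,
            area_per_lipid=self.params.area_per_lipid,
            structured_fraction=1.0 - self.params.beta,
            charge_profiles=profiles,
            grid_x=self.grid.x,
            s=self.sg.copy(),
            W_s=W_s,
            W2d=W2d,
            measure2d=self.V,
        )

    def log_partition(self, psi):
        _, Z, _, _ = self._weights(psi)
        return math.log(Z)


class TriangularHead(HeadModel):
    """Triangular head group rotating in a plane normal to the surface.

    The orientation coordinate is the centre-of-mass projection x of the two
    apex charges, uniform reference measure on [l sin(a/2), l cos(a/2)].  Each
    value of x corresponds to two mirror orientations (bisector elevation
    theta and pi - theta) that swap the charge heights; both carry half
    weight.  Charges are deposited from a fine sub-grid in x, which absorbs
    the integrable Jacobian singularity of the upper charge at full arm
    extension without special-casing.
    """

    SUBSAMPLE = 6

    def __init__(self, params, spec, grid):
        super().__init__(params, spec, grid)
        if spec.l1 != spec.l2:
            raise NotImplementedError(
                "triangular head groups are implemented for equal arms only"
            )
        lo, hi = support_triangular(spec)
        self.x_lo, self.x_hi = lo, hi
        n_sup = max(20, round((hi - lo) / grid.h))
        self.xs = np.linspace(lo, hi, n_sup + 1)
        # fine deposition sub-grid
        nf = self.SUBSAMPLE * (n_sup + 1)
        self.xf = np.linspace(lo, hi, nf)
        self.wf = np.full(nf, (hi - lo) / (nf - 1))
        self.wf[0] *= 0.5
        self.wf[-1] *= 0.5
        h1, h2 = triangle_charge_heights(spec, self.xf)
        self.h1f, self.h2f = h1, h2
        self._i1 = _interp_coeffs(grid, h1)
        self._i2 = _interp_coeffs(grid, h2)
        self._dep1 = _Depositor(grid, h1)
        self._dep2 = _Depositor(grid, h2)
        hs1, hs2 = triangle_charge_heights(spec, self.xs)
        self._is1 = _interp_coeffs(grid, hs1)
        self._is2 = _interp_coeffs(grid, hs2)

    @staticmethod
    def _interp(psi, coeffs):
        idx, frac = coeffs
        return psi[idx] * (1.0 - frac) + psi[idx + 1] * frac

    def _branch_weights(self, psi):
        """Boltzmann weights of the two mirror branches on the fine sub-grid."""
        p1 = self._interp(psi, self._i1)
        p2 = self._interp(psi, self._i2)
        bA = _bexp(-(self.spec.q1 * p1 + self.spec.q2 * p2))
        bB = _bexp(-(self.spec.q1 * p2 + self.spec.q2 * p1))
        Z = float(self.wf @ (0.5 * (bA + bB)))
        return bA, bB, Z

    def rho_head(self, psi):
        bA, bB, Z = self._branch_weights(psi)
        m_lower = self.wf * 0.5 * (self.spec.q1 * bA + self.spec.q2 * bB) / Z
        m_upper = self.wf * 0.5 * (self.spec.q2 * bA + self.spec.q1 * bB) / Z
        return self.f * (self._dep1(m_lower) + self._dep2(m_upper))

    def orientation(self, psi):
        bA, bB, Z = self._branch_weights(psi)
        # reported density on the support grid
        p1 = self._interp(psi, self._is1)
        p2 = self._interp(psi, self._is2)
        wA = _bexp(-(self.spec.q1 * p1 + self.spec.q2 * p2))
        wB = _bexp(-(self.spec.q1 * p2 + self.spec.q2 * p1))
        W = 0.5 * (wA + wB)
        W = W / np.trapezoid(W, self.xs)
        profiles = {
            "q1": 0.5 * (self._dep1(self.wf * bA / Z) + self._dep2(self.wf * bB / Z)),
            "q2": 0.5 * (self._dep2(self.wf * bA / Z) + self._dep1(self.wf * bB / Z)),
        }
        return OrientationDensity(
            variant=TRIANGULAR,
            x=self.xs.copy(),
            W=W,
            area_per_lipid=self.params.area_per_lipid,
            structured_fraction=1.0 - self.params.beta,
            charge_profiles=profiles,
            grid_x=self.grid.x,
        )

    def log_partition(self, psi):
        _, _, Z = self._branch_weights(psi)
        return math.log(Z)


def build_head_model(
    params: SystemParams, spec: HeadGroupSpec, grid: Grid
) -> HeadModel:
    if params.beta >= 1.0:
        return _NoHead(params, spec, grid)
    if spec.variant in (RIGID_ROTOR, ZWITTERIONIC):
        return RotorHead(params, spec, grid)
    if spec.variant == FLEXIBLE:
        return FlexibleHead(params, spec, grid)
    if spec.variant == TRIANGULAR:
        return TriangularHead(params, spec, grid)
    raise ParameterError(f"unknown variant {spec.variant!r}")
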