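"""Finite-difference solver for the coupled Euler-Lagrange equations.

The stationarity conditions of the free energy F = F_el + F_head + F_ion under
Gauss's law and the W-normalization constraint are:

* ions take Boltzmann form: n+- = n0 exp(-+psi) in 1:1 salt, or
  n = A exp(-z psi) with a single prefactor A in counterions-only mode;
* the orientation density is the normalized Boltzmann weight of the segment
  electrostatic energies, W ~ exp(-q1 psi(x) - q2 psi(s(x)));
* the reduced potential satisfies psi'' = -4 pi l_B rho/e with rho assembled
  from ions and head-group segments, psi'(0) set by the smeared surface
  charge, and decay into the bulk.

Ion densities and W are eliminated analytically, leaving a nonlinear system in
the node values of psi alone, solved by damped Newton iteration.  The
discretization is a conservative flux-balance form of a second-order finite
difference scheme: half-cell flux equations at x = 0 and at d1, central flux
differences in between, and the half-cell average of the (possibly
discontinuous) charge density at the region boundary d2.  Summing the
discrete equations telescopes exactly onto the trapezoidal quadrature, so a
converged solution is electroneutral to solver tolerance, and the single-valued
flux makes psi C1 across d2 and d1 by construction.  Beyond d1 the solution is
the closed-form Poisson-Boltzmann tail matched through its first integral.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import baselines
from .constants import FOUR_PI, NM3_TO_MOLAR
from .grid import CLOSED, Grid, GridError, TAIL, discretize
from .headgroups import OrientationDensity, _bexp, build_head_model
from .params import (
    COUNTERIONS_ONLY,
    FLEXIBLE,
    HeadGroupSpec,
    SALT_1_1,
    SystemParams,
    counterion_valence,
    plane_charge_density,
)

logger = logging.getLogger(__name__)

#: gauge prefactor used during the counterions-only solve (nm^-3); the
#: physical profiles are invariant under (A, psi) -> (A e^c, psi + c), and the
#: converged solution is re-gauged to psi(d1) = 0 afterwards.
_A_GAUGE = 1.0


class SolverError(RuntimeError):
    """Raised when the nonlinear solve fails irrecoverably."""


# ---------------------------------------------------------------------------
# Finite-difference operators


def fd_derivatives(psi_nodes: np.ndarray, h: float):
    """Second-order first and second derivatives on a uniform grid.

    Central stencils at interior nodes; one-sided second-order stencils at the
    edges.  Between grid points the potential is understood as linearly
    interpolated.
    """
    f = np.asarray(psi_nodes, dtype=float)
    n = len(f)
    if n < 3:
        raise GridError("fd_derivatives needs at least 3 nodes")
    d1 = np.empty(n)
    d2 = np.empty(n)
    d1[1:-1] = (f[2:] - f[:-2]) / (2.0 * h)
    d2[1:-1] = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / h**2
    d1[0] = (-3.0 * f[0] + 4.0 * f[1] - f[2]) / (2.0 * h)
    d1[-1] = (3.0 * f[-1] - 4.0 * f[-2] + f[-3]) / (2.0 * h)
    if n >= 4:
        d2[0] = (2.0 * f[0] - 5.0 * f[1] + 4.0 * f[2] - f[3]) / h**2
        d2[-1] = (2.0 * f[-1] - 5.0 * f[-2] + 4.0 * f[-3] - f[-4]) / h**2
    else:
        d2[0] = d2[-1] = d2[1]
    return d1, d2


def argmax_parabolic(x: np.ndarray, y: np.ndarray) -> float:
    """Position of the maximum of y(x), refined by parabolic interpolation.

    Fits a parabola through the three nodes around the discrete maximum; at a
    support edge the node position is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= -1e-300:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[i + 1] - x[i]))


# ---------------------------------------------------------------------------
# Analytic tail (region R3)


@dataclass(frozen=True)
class TailModel:
    """Closed-form Poisson-Boltzmann solution on R3 = [d1, inf).

    Salt mode: the nonlinear Gouy-Chapman decay matched at d1 through the
    first integral psi'^2 = 2 kappa^2 (cosh psi - 1).  Counterions-only mode:
    the algebraic Gouy profile n = n(d1)/(1 + (x-d1)/x0)^2 with
    psi'(d1)^2 = 8 pi l_B n(d1).
    """

    mode: str
    d1: float
    psi_d1: float
    slope_d1: float  # psi'(d1)
    kappa: float = 0.0  # salt mode
    n_d1: float = 0.0  # counterion density at d1
    valence: int = 1
    lb: float = 0.7

    def psi_at(self, x):
        x = np.asarray(x, dtype=float)
        if self.mode == SALT_1_1:
            t = math.tanh(0.25 * self.psi_d1)
            return 4.0 * np.arctanh(t * np.exp(-self.kappa * (x - self.d1)))
        if abs(self.slope_d1) < 1e-300:
            return np.full_like(x, self.psi_d1)
        x0 = 2.0 / (self.valence * self.slope_d1)
        return self.psi_d1 + (2.0 / self.valence) * np.log1p((x - self.d1) / x0)

    def n_at(self, x):
        """Counterion density on the tail (nm^-3)."""
        x = np.asarray(x, dtype=float)
        if self.mode == SALT_1_1:
            raise ValueError("use psi_at and Boltzmann weights in salt mode")
        if abs(self.slope_d1) < 1e-300:
            return np.full_like(x, self.n_d1)
        x0 = 2.0 / (self.valence * self.slope_d1)
        return self.n_d1 / (1.0 + (x - self.d1) / x0) ** 2


def analytic_tail(
    psi_d1: float,
    mode: str,
    params: SystemParams,
    n_d1: float = 0.0,
    valence: int = 1,
    d1: float = 0.0,
) -> TailModel:
    """Build the matched analytic tail for a boundary value psi(d1).

    In salt mode the decaying branch slope follows from psi(d1) alone; in
    counterions-only mode the local counterion density n(d1) sets the slope
    through the first integral (which simultaneously enforces global
    electroneutrality).
    """
    lb = params.bjerrum_length
    if mode == SALT_1_1:
        kappa = 1.0 / params.debye_length
        slope = -2.0 * kappa * math.sinh(0.5 * psi_d1)
        return TailModel(
            mode=mode, d1=d1, psi_d1=psi_d1, slope_d1=slope, kappa=kappa, lb=lb
        )
    slope = valence * math.sqrt(8.0 * math.pi * lb * max(n_d1, 0.0))
    return TailModel(
        mode=mode,
        d1=d1,
        psi_d1=psi_d1,
        slope_d1=slope,
        n_d1=n_d1,
        valence=valence,
        lb=lb,
    )


# ---------------------------------------------------------------------------
# Solution container


@dataclass
class EDLSolution:
    """Converged electric-double-layer profiles."""

    params: SystemParams
    spec: HeadGroupSpec
    grid: Grid
    psi: np.ndarray
    converged: bool
    iterations: int
    residual_norm: float
    W: OrientationDensity
    lambda_norm: float
    A: Optional[float] = None  # counterion prefactor n = A exp(-z psi)
    valence: int = 1
    tail: Optional[TailModel] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    @property
    def mode(self) -> str:
        return self.params.electrolyte_mode

    def n_plus(self) -> np.ndarray:
        """Counterion (cation) density at the nodes, nm^-3."""
        if self.mode == SALT_1_1:
            return self.params.bulk_density * _bexp(-self.psi)
        n = self.A * _bexp(-self.valence * self.psi)
        return n if self.valence > 0 else np.zeros_like(n)

    def n_minus(self) -> np.ndarray:
        """Co-ion (anion) density at the nodes, nm^-3."""
        if self.mode == SALT_1_1:
            return self.params.bulk_density * _bexp(self.psi)
        n = self.A * _bexp(-self.valence * self.psi)
        return n if self.valence < 0 else np.zeros_like(n)

    def rho(self) -> np.ndarray:
        """Total volume charge density rho/e at the nodes (e/nm^3)."""
        head = build_head_model(self.params, self.spec, self.grid)
        return self.n_plus() - self.n_minus() + head.rho_head(self.psi)

    def field(self) -> np.ndarray:
        """Reduced field E = -dpsi/dx at the nodes (region-split stencils)."""
        E = np.empty_like(self.psi)
        cuts = [0]
        if self.grid.i_d2 is not None:
            cuts.append(self.grid.i_d2)
        if self.grid.i_d1 not in cuts and self.grid.i_d1 < len(self.psi) - 1:
            cuts.append(self.grid.i_d1)
        cuts.append(len(self.psi) - 1)
        counts = np.zeros_like(self.psi)
        acc = np.zeros_like(self.psi)
        for a, b in zip(cuts[:-1], cuts[1:]):
            d1_, _ = fd_derivatives(self.psi[a : b + 1], self.grid.h)
            acc[a : b + 1] += -d1_
            counts[a : b + 1] += 1.0
        E[:] = acc / counts
        return E

    def psi_at(self, x) -> np.ndarray:
        """Reduced potential at arbitrary positions (linear interp + tail)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.interp(x, self.grid.x, self.psi)
        if self.tail is not None:
            beyond = x > self.grid.d1
            if np.any(beyond):
                out[beyond] = self.tail.psi_at(x[beyond])
        return out

    def electroneutrality_residual(self) -> float:
        """sigma/e + int rho/e dx (+ tail charge), relative to |sigma/e|."""
        sigma_e = plane_charge_density(self.params, self.spec)
        total = sigma_e + float(np.trapezoid(self.rho(), self.grid.x))
        if self.tail is not None:
            # integrated Gauss law over the tail: charge = slope(d1)/(4 pi lB)
            total += self.tail.slope_d1 / (FOUR_PI * self.params.bjerrum_length)
        scale = max(abs(sigma_e), 1e-30)
        return total / scale

    def c1_jump(self) -> float:
        """|psi'(d2-) - psi'(d2+)| from one-sided second-order stencils."""
        m = self.grid.i_d2
        if m is None:
            return 0.0
        h = self.grid.h
        f = self.psi
        left = (3.0 * f[m] - 4.0 * f[m - 1] + f[m - 2]) / (2.0 * h)
        right = (-3.0 * f[m] + 4.0 * f[m + 1] - f[m + 2]) / (2.0 * h)
        return abs(left - right)

    def n_plus_molar(self) -> np.ndarray:
        return self.n_plus() * NM3_TO_MOLAR

    def n_minus_molar(self) -> np.ndarray:
        return self.n_minus() * NM3_TO_MOLAR


def marginals(W: OrientationDensity):
    """Marginals (x, W_x), (s, W_s) of a flexible orientation density."""
    if W.variant != FLEXIBLE or W.W_s is None:
        raise ValueError("marginals are defined for the flexible variant")
    return (W.x, W.W), (W.s, W.W_s)


def orientation_statistics(x: np.ndarray, W: np.ndarray) -> dict:
    """Mode (parabolic-refined argmax) and mean of a 1D orientation density."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    return {
        "mode": argmax_parabolic(x, W),
        "mean": float(np.trapezoid(x * W, x) / np.trapezoid(W, x)),
    }


# ---------------------------------------------------------------------------
# Nonlinear system


class _System:
    """Residual assembly for the discrete Euler-Lagrange equations."""

    def __init__(
        self,
        params: SystemParams,
        spec: HeadGroupSpec,
        grid: Grid,
        charge_scale: float = 1.0,
    ):
        self.params = params
        self.spec = spec
        self.grid = grid
        self.lb = params.bjerrum_length
        self.c4 = FOUR_PI * self.lb
        self.sigma_e = plane_charge_density(params, spec) * charge_scale
        self.charge_scale = charge_scale
        self.head = build_head_model(params, spec, grid)
        self.mode = params.electrolyte_mode
        if self.mode == SALT_1_1:
            self.n0 = params.bulk_density
            self.valence = 1
        else:
            self.n0 = None
            self.valence = counterion_valence(params, spec)

    def rho_ions(self, psi: np.ndarray) -> np.ndarray:
        if self.mode == SALT_1_1:
            return self.n0 * (_bexp(-psi) - _bexp(psi))
        z = self.valence
        return z * _A_GAUGE * _bexp(-z * psi)

    def rho(self, psi: np.ndarray) -> np.ndarray:
        return self.rho_ions(psi) + self.charge_scale * self.head.rho_head(psi)

    def tail_slope(self, psi_end: float) -> float:
        if self.grid.boundary == CLOSED:
            return 0.0
        if self.mode == SALT_1_1:
            kappa = 1.0 / self.params.debye_length
            return -2.0 * kappa * math.sinh(0.5 * psi_end)
        z = self.valence
        n_end = _A_GAUGE * float(_bexp(-z * psi_end))
        return z * math.sqrt(8.0 * math.pi * self.lb * n_end)

    def residual(self, psi: np.ndarray) -> np.ndarray:
        h = self.grid.h
        rho = self.rho(psi)
        flux = np.diff(psi) / h
        R = np.empty_like(psi)
        R[0] = flux[0] + self.c4 * (self.sigma_e + 0.5 * h * rho[0])
        R[1:-1] = np.diff(flux) + self.c4 * h * rho[1:-1]
        R[-1] = self.tail_slope(float(psi[-1])) - flux[-1] + self.c4 * 0.5 * h * rho[-1]
        return R

    def initial_guess(self) -> np.ndarray:
        x = self.grid.x
        sigma = self.sigma_e
        if abs(sigma) < 1e-14:
            return np.zeros_like(x)
        if self.mode == SALT_1_1:
            gc = baselines.gouy_chapman_salt(
                sigma, self.params.bulk_concentration, self.params
            )
            return gc.psi_at(x)
        z = self.valence
        b = 1.0 / (2.0 * math.pi * self.lb * abs(sigma))
        n_gc = 1.0 / (2.0 * math.pi * self.lb * (x + b) ** 2)
        return -np.log(n_gc / _A_GAUGE) / z


def _numerical_jacobian(fun: Callable, x: np.ndarray, f0: np.ndarray) -> np.ndarray:
    n = len(x)
    J = np.empty((n, n))
    for k in range(n):
        eps = 1e-7 * (1.0 + abs(x[k]))
        xk = x.copy()
        xk[k] += eps
        J[:, k] = (fun(xk) - f0) / eps
    return J


def _newton(
    fun: Callable,
    x0: np.ndarray,
    tol: float,
    max_iter: int,
):
    x = np.asarray(x0, dtype=float).copy()
    F = fun(x)
    norm = float(np.max(np.abs(F)))
    for it in range(1, max_iter + 1):
        if norm < tol:
            return x, True, it - 1, norm
        J = _numerical_jacobian(fun, x, F)
        try:
            dx = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            dx = np.linalg.lstsq(J, -F, rcond=None)[0]
        lam = 1.0
        improved = False
        while lam >= 1.0 / 1024.0:
            xn = x + lam * dx
            Fn = fun(xn)
            norm_n = float(np.max(np.abs(Fn)))
            if norm_n < norm or not np.isfinite(norm):
                x, F, norm = xn, Fn, norm_n
                improved = True
                break
            lam *= 0.5
        if not improved:
            return x, False, it, norm
    return x, norm < tol, max_iter, norm


# ---------------------------------------------------------------------------
# Public solve


def solve(
    params: SystemParams,
    spec: HeadGroupSpec,
    grid: Optional[Grid] = None,
    h: float = 0.005,
    tol: float = 1e-8,
    max_iter: int = 200,
    boundary: str = TAIL,
    x_max: Optional[float] = None,
    initial: Optional[np.ndarray] = None,
) -> EDLSolution:
    """Solve the Euler-Lagrange system and return converged EDL profiles.

    Parameters mirror the model definition; ``h`` (nm) is the target grid
    step (default 0.005, fine enough for support boundaries as small as
    ~0.18 nm), ``tol`` the max-norm residual tolerance.  On non-convergence
    the best iterate is returned with ``converged=False`` and the residual
    norm in ``residual_norm``; no exception is raised.
    """
    if grid is None:
        grid = discretize(spec, h, boundary=boundary, x_max=x_max)
    system = _System(params, spec, grid)
    psi0 = np.asarray(initial, dtype=float) if initial is not None else system.initial_guess()
    psi, ok, iters, norm = _newton(system.residual, psi0, tol, max_iter)
    if not ok:
        # homotopy in the interface charge: solve a weakly charged system
        # first and follow the solution branch up to full charge
        logger.info("direct solve failed (residual %.3g); using charge continuation", norm)
        psi_c = None
        total_iters = iters
        for scale in (0.25, 0.5, 0.75, 1.0):
            sys_c = _System(params, spec, grid, charge_scale=scale)
            guess = psi_c if psi_c is not None else sys_c.initial_guess()
            psi_c, ok, it_c, norm = _newton(sys_c.residual, guess, tol, max_iter)
            total_iters += it_c
            if not ok:
                break
        psi, iters = psi_c, total_iters
    return _finalize(system, psi, ok, iters, norm)


def _finalize(
    system: _System, psi: np.ndarray, ok: bool, iters: int, norm: float
) -> EDLSolution:
    params, spec, grid = system.params, system.spec, system.grid
    A = None
    valence = system.valence
    if system.mode == COUNTERIONS_ONLY:
        # re-gauge: psi = 0 at the last node, fold the shift into A
        shift = float(psi[-1])
        psi = psi - shift
        A = _A_GAUGE * math.exp(-valence * shift)
    tail = None
    if grid.boundary == TAIL:
        if system.mode == SALT_1_1:
            tail = analytic_tail(float(psi[-1]), SALT_1_1, params, d1=grid.d1)
        else:
            n_d1 = A * float(_bexp(-valence * psi[-1]))
            tail = analytic_tail(
                float(psi[-1]),
                COUNTERIONS_ONLY,
                params,
                n_d1=n_d1,
                valence=valence,
                d1=grid.d1,
            )
    W = system.head.orientation(psi)
    f = (1.0 - params.beta) / params.area_per_lipid
    lam = f * (1.0 - system.head.log_partition(psi)) if params.beta < 1.0 else 0.0
    if not ok:
        logger.warning(
            "solver did not converge: residual max-norm %.3g after %d iterations",
            norm,
            iters,
        )
    return EDLSolution(
        params=params,
        spec=spec,
        grid=grid,
        psi=psi,
        converged=bool(ok),
        iterations=iters,
        residual_norm=norm,
        W=W,
        lambda_norm=lam,
        A=A,
        valence=valence,
        tail=tail,
        diagnostics={"charge_scale": system.charge_scale},
    )
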