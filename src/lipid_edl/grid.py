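"""Three-region discretization of the half-space [0, inf).

The domain splits at d2 <= d1 into R1 = [0, d2], R2 = [d2, d1] where head-group
charge lives and a tail R3 = [d1, inf) that is handled analytically (or, in
closed-box mode, a hard wall at finite x_max with zero field).  For the rotor
and flexible variants d2 = l1 and d1 = l1 + l2; for the triangular variant
d2 = min(l1, l2) and d1 = max(l1, l2), so with equal arms R2 collapses and the
grid has a single interior region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np

from .params import HeadGroupSpec, TRIANGULAR, ZWITTERIONIC

logger = logging.getLogger(__name__)

TAIL = "tail"
CLOSED = "closed"


class GridError(ValueError):
    """Raised for inadmissible grid construction."""


def region_boundaries(spec: HeadGroupSpec) -> tuple[float, float]:
    """(d2, d1) region boundaries in nm for a head-group variant."""
    if spec.variant == TRIANGULAR:
        return min(spec.l1, spec.l2), max(spec.l1, spec.l2)
    if spec.variant == ZWITTERIONIC:
        return spec.l1, spec.l1
    return spec.l1, spec.l1 + spec.l2


@dataclass(frozen=True)
class Grid:
    """Uniform-step node set covering [0, d1] (plus closed-box extension).

    Attributes
    ----------
    h : float
        Grid step, nm; divides d2 and d1 - d2 exactly.
    x : numpy.ndarray
        Node positions, x[0] = 0; x[i_d1] = d1; last node is d1 in tail mode
        or x_max in closed mode.
    i_d2, i_d1 : int
        Node indices of the region boundaries; ``i_d2 is None`` when R2
        collapses (d2 = d1).
    boundary : str
        ``"tail"`` (analytic R3) or ``"closed"`` (hard wall, zero field at
        the last node).
    """

    h: float
    d1: float
    d2: float
    x: np.ndarray
    i_d1: int
    i_d2: Optional[int]
    boundary: str = TAIL

    @property
    def n_nodes(self) -> int:
        return len(self.x)

    @property
    def x_max(self) -> float:
        return float(self.x[-1])

    @property
    def trapz_weights(self) -> np.ndarray:
        w = np.full(self.n_nodes, self.h)
        w[0] = w[-1] = 0.5 * self.h
        return w


def _commensurate_step(h: float, d2: float, d1: float) -> float:
    """Largest step <= h dividing both d2 and d1 - d2 (nearly) exactly."""
    r2 = d1 - d2
    n1 = max(1, math.ceil(d2 / h - 1e-9))
    if r2 <= 1e-12:
        return d2 / n1
    # need h' = d2/n1 = r2/n2 -> n2/n1 = r2/d2
    frac = Fraction(r2 / d2).limit_denominator(100)
    if frac.numerator == 0 or abs(frac.numerator / frac.denominator - r2 / d2) > 1e-9:
        raise GridError(
            f"region lengths d2={d2} and d1-d2={r2} are incommensurate; "
            "choose rationally related segment lengths"
        )
    p, q = frac.numerator, frac.denominator  # r2/d2 = p/q
    # h' = d2/(k*q) for integer k; smallest k with h' <= h
    k = max(1, math.ceil(d2 / (q * h) - 1e-9))
    return d2 / (k * q)


def discretize(
    spec: HeadGroupSpec,
    h: float,
    boundary: str = TAIL,
    x_max: Optional[float] = None,
) -> Grid:
    """Build the grid for a head-group variant with target step ``h``.

    ``h`` is adjusted downward to the nearest value commensurate with the
    region boundaries (and logged when it changes).  In closed mode the node
    set extends to ``x_max`` (rounded up to a node).
    """
    if h <= 0:
        raise GridError("step h must be positive")
    d2, d1 = region_boundaries(spec)
    if h > d2 / 4.0 + 1e-12:
        raise GridError(f"step h={h} too coarse; need h <= d2/4 = {d2 / 4.0}")
    if boundary not in (TAIL, CLOSED):
        raise GridError(f"unknown boundary mode {boundary!r}")
    h_eff = _commensurate_step(h, d2, d1)
    if abs(h_eff - h) > 1e-12:
        logger.info("grid step adjusted from %g to %g nm", h, h_eff)
    n1 = round(d2 / h_eff)
    n2 = round((d1 - d2) / h_eff)
    i_d2: Optional[int] = n1 if n2 > 0 else None
    i_d1 = n1 + n2
    if boundary == CLOSED:
        if x_max is None or x_max <= d1:
            raise GridError("closed mode requires x_max > d1")
        n3 = math.ceil((x_max - d1) / h_eff - 1e-9)
        n_tot = i_d1 + n3
    else:
        n_tot = i_d1
    x = h_eff * np.arange(n_tot + 1)
    # pin boundary nodes exactly
    x[i_d1] = d1
    if i_d2 is not None:
        x[i_d2] = d2
    if n1 < 3:
        raise GridError("fewer than 3 nodes in region R1; decrease h")
    return Grid(h=h_eff, d1=d1, d2=d2, x=x, i_d1=i_d1, i_d2=i_d2, boundary=boundary)
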