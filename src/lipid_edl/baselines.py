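"""Closed-form Poisson-Boltzmann references (Gouy-Chapman family).

Used for solver initialization, for validation in the beta = 1 limit (no
structured head groups), and for the comparison of structured-head-group
profiles against the classical flat-interface picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import NM3_TO_MOLAR
from .params import COUNTERIONS_ONLY, SALT_1_1, SystemParams


@dataclass(frozen=True)
class GCSolution:
    """Closed-form diffuse-layer solution for a uniformly charged plane.

    ``sigma_e`` is the surface charge density in e/nm^2 (signed).  Salt mode
    is the standard nonlinear Gouy-Chapman profile; counterions-only mode is
    the algebraic Gouy profile, whose potential has a logarithmically
    divergent reference and is therefore reported relative to ``x_ref``
    (fields and densities are gauge-free).
    """

    mode: str
    sigma_e: float
    lb: float
    psi0: float = 0.0
    kappa: float = 0.0  # 1/l_D, salt mode
    n0: float = 0.0  # bulk density, nm^-3, salt mode
    b: float = math.inf  # Gouy length, counterions-only
    valence: int = 1
    x_ref: float = 0.0

    # -- potential ---------------------------------------------------------
    def psi_at(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mode == SALT_1_1:
            t = math.tanh(0.25 * self.psi0)
            return 4.0 * np.arctanh(t * np.exp(-self.kappa * x))
        if not math.isfinite(self.b):
            return np.zeros_like(x)
        return (2.0 / self.valence) * np.log((x + self.b) / (self.x_ref + self.b))

    def field_at(self, x) -> np.ndarray:
        """Reduced field E = -dpsi/dx."""
        x = np.asarray(x, dtype=float)
        if self.mode == SALT_1_1:
            return 2.0 * self.kappa * np.sinh(0.5 * self.psi_at(x))
        if not math.isfinite(self.b):
            return np.zeros_like(x)
        return -(2.0 / self.valence) / (x + self.b)

    # -- densities ---------------------------------------------------------
    def n_plus_at(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mode == SALT_1_1:
            return self.n0 * np.exp(-self.psi_at(x))
        if self.valence < 0 or not math.isfinite(self.b):
            return np.zeros_like(x)
        return 1.0 / (2.0 * math.pi * self.lb * (x + self.b) ** 2)

    def n_minus_at(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.mode == SALT_1_1:
            return self.n0 * np.exp(self.psi_at(x))
        if self.valence > 0 or not math.isfinite(self.b):
            return np.zeros_like(x)
        return 1.0 / (2.0 * math.pi * self.lb * (x + self.b) ** 2)


def grahame_psi0(sigma_e: float, kappa: float, lb: float) -> float:
    """Surface potential from the Grahame relation for a 1:1 electrolyte.

    sigma_e = kappa sinh(psi0/2) / (2 pi l_B), all in nm/e units.
    """
    return 2.0 * math.asinh(2.0 * math.pi * lb * sigma_e / kappa)


def grahame_sigma(psi0: float, kappa: float, lb: float) -> float:
    """Inverse of :func:`grahame_psi0`."""
    return kappa * math.sinh(0.5 * psi0) / (2.0 * math.pi * lb)


def gouy_chapman_salt(
    sigma_e: float, concentration: float, params: SystemParams
) -> GCSolution:
    """Gouy-Chapman solution for a plane with charge sigma_e (e/nm^2) in 1:1 salt.

    psi(x) = 4 artanh(tanh(psi0/4) exp(-kappa x)) with psi0 from the Grahame
    relation.
    """
    if concentration <= 0:
        raise ValueError("salt concentration must be positive")
    lb = params.bjerrum_length
    n0 = concentration * (1.0 / NM3_TO_MOLAR)
    kappa = math.sqrt(8.0 * math.pi * lb * n0)
    psi0 = grahame_psi0(sigma_e, kappa, lb)
    return GCSolution(
        mode=SALT_1_1, sigma_e=sigma_e, lb=lb, psi0=psi0, kappa=kappa, n0=n0
    )


def gouy_chapman_counterions(
    sigma_e: float, params: SystemParams, x_ref: float = 0.0
) -> GCSolution:
    """Algebraic Gouy profile for counterions only.

    n(x) = 1/(2 pi l_B (x + b)^2) with Gouy length b = 1/(2 pi l_B |sigma_e|);
    the counterions integrate exactly to |sigma_e| and the contact density
    obeys n(0) = 2 pi l_B sigma_e^2.  For sigma_e = 0 the flat vacuum solution
    is returned.
    """
    lb = params.bjerrum_length
    if sigma_e == 0.0:
        return GCSolution(mode=COUNTERIONS_ONLY, sigma_e=0.0, lb=lb)
    b = 1.0 / (2.0 * math.pi * lb * abs(sigma_e))
    valence = 1 if sigma_e < 0 else -1
    return GCSolution(
        mode=COUNTERIONS_ONLY,
        sigma_e=sigma_e,
        lb=lb,
        b=b,
        valence=valence,
        x_ref=x_ref,
    )
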