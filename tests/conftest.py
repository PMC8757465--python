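"""Shared solver runs (session-scoped: each converged profile is reused)."""

import pytest

from lipid_edl import HeadGroupSpec, SystemParams, solve
from lipid_edl.mc import MCConfig, run_mc

ROTOR_05 = HeadGroupSpec(variant="rigid_rotor", l1=0.5, l2=0.5)
ROTOR_1 = HeadGroupSpec(variant="rigid_rotor", l1=1.0, l2=1.0)
FLEX_05 = HeadGroupSpec(variant="flexible", l1=0.5, l2=0.5)
TRI = HeadGroupSpec(
    variant="triangular", l1=0.68, l2=0.68, alpha=30.0, q1=-1.0, q2=-1.0
)


def _salt(a=0.6, c=0.1, beta=0.5):
    return SystemParams(
        area_per_lipid=a, beta=beta, electrolyte_mode="salt_1_1", bulk_concentration=c
    )


def _ct(a=0.6, beta=0.5):
    return SystemParams(area_per_lipid=a, beta=beta)


@pytest.fixture(scope="session")
def rotor_salt_l1():
    """Rigid rotor, 0.1 M salt, a=0.6, beta=0.5, l1=l2=1 nm."""
    return solve(_salt(), ROTOR_1, h=0.005)


@pytest.fixture(scope="session")
def rotor_salt_l05():
    return solve(_salt(), ROTOR_05, h=0.005)


@pytest.fixture(scope="session")
def rotor_ct_l1():
    return solve(_ct(), ROTOR_1, h=0.005)


@pytest.fixture(scope="session")
def flexible_ct():
    return solve(_ct(), FLEX_05, h=0.005)


@pytest.fixture(scope="session")
def flexible_salt():
    return solve(_salt(), FLEX_05, h=0.005)


@pytest.fixture(scope="session")
def rotor_c001():
    return solve(_salt(c=0.01), ROTOR_05, h=0.005)


@pytest.fixture(scope="session")
def flexible_c001():
    return solve(_salt(c=0.01), FLEX_05, h=0.005)


@pytest.fixture(scope="session")
def triangular_ct():
    return solve(_ct(), TRI, h=0.005)


@pytest.fixture(scope="session")
def mc_fd_pair():
    """Scaled-down slab MC (50 lipids, a=6, rigid rotor, counterions only)
    next to the matching closed-box finite-difference solution."""
    params = _ct(a=6.0)
    cfg = MCConfig(
        n_lipids=50,
        moves_equilibration=2000,
        moves_production=10000,
        seed=11,
        bin_width=0.1,
    )
    res = run_mc(params, ROTOR_1, cfg)
    sol = solve(params, ROTOR_1, h=0.01, boundary="closed", x_max=cfg.box_z)
    return res, sol
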