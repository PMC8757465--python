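"""Regression fixture generation: coarse-grid runs with stored invariants.

All four head-group variants x two charge regimes x both electrolyte modes,
plus the beta = 1 Gouy-Chapman equivalence pair, at a coarse step so the set
regenerates in seconds.  The summary JSON stores, per run, the surface
potential, the electroneutrality residual, and the orientation-density mode,
which later runs must reproduce.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as edlio
from .params import (
    COUNTERIONS_ONLY,
    FLEXIBLE,
    HeadGroupSpec,
    RIGID_ROTOR,
    SALT_1_1,
    SystemParams,
    TRIANGULAR,
    ZWITTERIONIC,
)
from .solver import argmax_parabolic, solve

DEFAULT_SPECS = {
    RIGID_ROTOR: HeadGroupSpec(variant=RIGID_ROTOR, l1=0.5, l2=0.5),
    FLEXIBLE: HeadGroupSpec(variant=FLEXIBLE, l1=0.5, l2=0.5),
    TRIANGULAR: HeadGroupSpec(
        variant=TRIANGULAR, l1=0.68, l2=0.68, alpha=30.0, q1=-1.0, q2=-1.0
    ),
    ZWITTERIONIC: HeadGroupSpec(variant=ZWITTERIONIC, l1=1.0, q1=1.0),
}


def fixture_matrix(
    variants=None, areas=(0.6, 6.0), modes=(COUNTERIONS_ONLY, SALT_1_1)
):
    """(name, params, spec) combinations of the regression set."""
    variants = variants or list(DEFAULT_SPECS)
    combos = []
    for v in variants:
        for a in areas:
            for mode in modes:
                kw = {"bulk_concentration": 0.1} if mode == SALT_1_1 else {}
                name = f"{v}_a{a:g}_{'salt' if mode == SALT_1_1 else 'ct'}"
                combos.append(
                    (
                        name,
                        SystemParams(
                            area_per_lipid=a, beta=0.5, electrolyte_mode=mode, **kw
                        ),
                        DEFAULT_SPECS[v],
                    )
                )
    return combos


def run_summary(params, spec, h=0.025) -> dict:
    sol = solve(params, spec, h=h)
    return {
        "converged": bool(sol.converged),
        "psi0": float(sol.psi[0]),
        "electroneutrality": float(sol.electroneutrality_residual()),
        "W_argmax": float(argmax_parabolic(sol.W.x, sol.W.W)),
        "W_integral": float(sol.W.integral()),
    }, sol


def make_fixtures(
    outdir, h: float = 0.025, variants=None, write_profiles: bool = True
) -> dict:
    """Generate the regression fixture set under ``outdir``.

    Returns the summary mapping (also written to ``fixtures.json``).
    Includes the beta = 1 Gouy-Chapman equivalence pair.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, params, spec in fixture_matrix(variants=variants):
        info, sol = run_summary(params, spec, h=h)
        summary[name] = info
        if write_profiles:
            df = edlio.solution_frame(sol, n_tail=20)
            edlio.write_profile(
                outdir / f"{name}.tsv", df, params, spec, fixture=name
            )
    # beta = 1 pair: solver vs closed-form Gouy-Chapman
    from . import baselines
    from .params import plane_charge_density

    p1 = SystemParams(
        area_per_lipid=0.6,
        beta=1.0,
        electrolyte_mode=SALT_1_1,
        bulk_concentration=0.1,
    )
    s1 = DEFAULT_SPECS[RIGID_ROTOR]
    sol1 = solve(p1, s1, h=h)
    gc = baselines.gouy_chapman_salt(plane_charge_density(p1, s1), 0.1, p1)
    dev = float(
        np.max(np.abs(sol1.psi - gc.psi_at(sol1.x))) / np.max(np.abs(sol1.psi))
    )
    summary["beta1_gc_pair"] = {
        "converged": bool(sol1.converged),
        "psi0": float(sol1.psi[0]),
        "gc_psi0": float(gc.psi0),
        "max_rel_dev": dev,
    }
    (outdir / "fixtures.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
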