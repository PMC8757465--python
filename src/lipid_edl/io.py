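"""Profile tables, run manifests, and configuration handling.

Profiles are plain tab-separated tables with a '#'-prefixed metadata header so
they diff cleanly and load directly into plotting tools; manifests are JSON
documents from which every output file can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import HeadGroupSpec, SALT_1_1, SystemParams
from .solver import EDLSolution

PROFILE_COLUMNS = [
    "x_nm",
    "psi_reduced",
    "psi_volts",
    "E_reduced",
    "n_plus_M",
    "n_minus_M",
    "W",
]
FLEX_COLUMNS = PROFILE_COLUMNS + ["W_x", "W_s"]


class ProfileFormatError(ValueError):
    """Raised when a profile table violates the strict schema."""


def _metadata(params: SystemParams, spec: HeadGroupSpec, extra: dict) -> dict:
    meta = {"model": "edl_solver", "version": __version__}
    meta.update(dataclasses.asdict(params))
    meta.update({f"hg_{k}": v for k, v in dataclasses.asdict(spec).items()})
    meta.update(extra)
    return {k: v for k, v in meta.items() if v is not None}


def solution_frame(sol: EDLSolution, n_tail: int = 60) -> pd.DataFrame:
    """Tabulate a solution on its nodes plus sampled analytic-tail points."""
    x = sol.x
    psi = sol.psi
    E = sol.field()
    npl = sol.n_plus_molar()
    nmi = sol.n_minus_molar()
    # W on the main grid: interpolate the support density, zero outside
    W_main = np.interp(x, sol.W.x, sol.W.W, left=0.0, right=0.0)
    W_main[x > sol.W.x[-1] + 1e-12] = 0.0
    W_main[x < sol.W.x[0] - 1e-12] = 0.0
    cols = {
        "x_nm": x,
        "psi_reduced": psi,
        "psi_volts": psi * sol.params.thermal_voltage,
        "E_reduced": E,
        "n_plus_M": npl,
        "n_minus_M": nmi,
        "W": W_main,
    }
    flexible = sol.W.W_s is not None
    if flexible:
        cols["W_x"] = np.interp(x, sol.W.x, sol.W.W, left=0.0, right=0.0)
        cols["W_s"] = np.interp(x, sol.W.s, sol.W.W_s, left=0.0, right=0.0)
    df = pd.DataFrame(cols)
    if sol.tail is not None and n_tail > 0:
        if sol.mode == SALT_1_1:
            span = 6.0 * sol.params.debye_length
        else:
            x0 = 2.0 / max(abs(sol.tail.slope_d1), 1e-3)
            span = min(10.0 * x0, 50.0)
        xt = sol.grid.d1 + np.linspace(0, span, n_tail + 1)[1:]
        psit = sol.tail.psi_at(xt)
        if sol.mode == SALT_1_1:
            n0 = sol.params.bulk_density
            npt = n0 * np.exp(-psit)
            nmt = n0 * np.exp(psit)
        else:
            npt = sol.tail.n_at(xt) if sol.valence > 0 else np.zeros_like(xt)
            nmt = sol.tail.n_at(xt) if sol.valence < 0 else np.zeros_like(xt)
        from .constants import NM3_TO_MOLAR

        rows = {
            "x_nm": xt,
            "psi_reduced": psit,
            "psi_volts": psit * sol.params.thermal_voltage,
            "E_reduced": -np.gradient(psit, xt),
            "n_plus_M": npt * NM3_TO_MOLAR,
            "n_minus_M": nmt * NM3_TO_MOLAR,
            "W": np.zeros_like(xt),
        }
        if flexible:
            rows["W_x"] = np.zeros_like(xt)
            rows["W_s"] = np.zeros_like(xt)
        df = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    return df


def write_profile(
    path, df: pd.DataFrame, params: SystemParams, spec: HeadGroupSpec, **extra
) -> None:
    """Write a TSV profile with '#'-prefixed metadata header lines."""
    path = Path(path)
    meta = _metadata(params, spec, extra)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_profile(path):
    """Strict reader: returns (metadata, DataFrame); validates the schema."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            data_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[data_start:])), sep="\t")
    expected = set(PROFILE_COLUMNS)
    if not expected.issubset(df.columns):
        raise ProfileFormatError(
            f"missing columns: {sorted(expected - set(df.columns))}"
        )
    x = df["x_nm"].to_numpy()
    if np.any(np.diff(x) <= 0):
        raise ProfileFormatError("x_nm must be strictly increasing")
    return meta, df


# ---------------------------------------------------------------------------
# Run manifest


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's output files."""

    command: str
    params: dict
    headgroup: dict
    options: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    version: str = __version__
    config_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls.from_json(Path(path).read_text())


def config_hash(d: dict) -> str:
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def make_manifest(
    command: str,
    params: SystemParams,
    spec: Optional[HeadGroupSpec],
    options: dict,
    outputs: list,
) -> RunManifest:
    p = dataclasses.asdict(params)
    h = dataclasses.asdict(spec) if spec is not None else {}
    return RunManifest(
        command=command,
        params=p,
        headgroup=h,
        options=options,
        outputs=[str(o) for o in outputs],
        config_hash=config_hash({"params": p, "headgroup": h, "options": options}),
    )


# ---------------------------------------------------------------------------
# Config files


def load_config(path) -> dict:
    """Flat key-value YAML config mapping to parameter fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data


def merge_config(config: dict, flags: dict) -> dict:
    """Explicit CLI flags win over config-file values; None flags are unset."""
    merged = dict(config)
    for k, v in flags.items():
        if v is not None:
            merged[k] = v
    return merged
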