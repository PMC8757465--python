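"""Canonical Metropolis Monte Carlo of the monolayer EDL in a periodic slab.

The same head-group models as the theory, sampled in the restricted primitive
model: a rectangular box periodic in the two lateral directions, a hard wall
at x = 0 carrying the smeared surface charge sigma (q0 of every lipid plus the
full charge of the non-structured component) and a hard wall at x = box_z.
Mobile species are the neutralizing counterions (charged hard spheres) and the
discrete q1/q2 segment charges anchored at grafting sites.

Electrostatics uses the charged-sheet method: each pair interacts through the
lateral minimum-image Coulomb term plus an analytic far-field correction that
replaces all further periodic images of the partner by a uniform infinite
sheet minus its central square at the partner's height.  The smeared surface
charge acts through the exact infinite-plane field.  Intramolecular
segment-segment pairs are rigid (constant separation) and are excluded from
the energy.  Every charged species carries a hard core of radius
``ion_radius`` (unlike the point-charge theory, the primitive model is not
defined without one: opposite point charges would fuse); bonded partners are
exempt.  The beta = 1 limit against the closed-form Gouy profile is the
accuracy arbiter for this scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .params import (
    COUNTERIONS_ONLY,
    FLEXIBLE,
    HeadGroupSpec,
    ParameterError,
    RIGID_ROTOR,
    SystemParams,
    TRIANGULAR,
    ZWITTERIONIC,
    counterion_valence,
)


@dataclass(frozen=True)
class MCConfig:
    """Simulation controls.

    ``box_xy`` is derived as sqrt(n_lipids * a); ``moves_*`` are attempted
    moves per particle.  Displacement parameters are tuned toward ~50%
    acceptance during equilibration only.
    """

    n_lipids: int = 400
    box_z: float = 8.0
    ion_radius: float = 0.2
    moves_equilibration: int = 20000
    moves_production: int = 100000
    bin_width: float = 0.05
    seed: int = 0
    n_blocks: int = 10
    displacement_ion: float = 0.4
    displacement_lipid: float = 0.4
    rotation_delta: float = 0.6
    tune_interval: int = 50
    energy_check_interval: int = 100

    def __post_init__(self):
        if self.n_lipids < 1:
            raise ParameterError("n_lipids must be positive")
        if not 0.02 - 1e-12 <= self.bin_width <= 0.1 + 1e-12:
            raise ParameterError("bin_width outside the supported 0.02-0.1 nm range")
        if self.box_z <= 0:
            raise ParameterError("box_z must be positive")


def box_side(n_lipids: int, area_per_lipid: float) -> float:
    """Lateral box side L = sqrt(n_lipids * a) in nm."""
    return math.sqrt(n_lipids * area_per_lipid)


def square_sheet_potential(z: np.ndarray, side: float) -> np.ndarray:
    """Integral of 1/r over a uniform square sheet of given side at height z.

    Potential (in units of charge/length) on the axis of a square
    [-side/2, side/2]^2 carrying unit charge density, at perpendicular
    distance z.  Closed form; behaves as side^2/z for z >> side and tends to
    4*side*asinh(1) at z = 0.
    """
    b = 0.5 * side
    z = np.abs(np.asarray(z, dtype=float))
    rb = np.sqrt(b * b + z * z)
    term1 = 8.0 * b * np.arcsinh(b / rb)
    with np.errstate(divide="ignore", invalid="ignore"):
        term2 = np.where(
            z > 0.0,
            4.0 * z * np.arctan(b * b / (z * np.sqrt(2 * b * b + z * z))),
            0.0,
        )
    return term1 - term2


@dataclass
class MCState:
    """Particle coordinates, grafting sites, and bookkeeping.

    Axis 0 of every position array is the surface normal x; axes 1-2 are the
    periodic lateral coordinates.
    """

    params: SystemParams
    spec: HeadGroupSpec
    config: MCConfig
    rng: np.random.Generator
    box_xy: float
    sigma_e: float  # smeared plane charge, e/nm^2
    valence: int
    ion_pos: np.ndarray  # (n_ion, 3)
    anchors: np.ndarray  # (n_struct, 2) lateral grafting sites
    orient: Dict[str, np.ndarray]  # variant-specific unit vectors
    seg_pos: np.ndarray  # (n_seg, 3)
    seg_q: np.ndarray  # (n_seg,)
    seg_lipid: np.ndarray  # lipid index per segment charge
    energy: float = 0.0
    displacement_ion: float = 0.4
    displacement_lipid: float = 0.4
    rotation_delta: float = 0.6
    accept: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_ion(self) -> int:
        return len(self.ion_pos)

    @property
    def n_struct(self) -> int:
        return len(self.anchors)

    def all_charges(self):
        """(positions, charge numbers) of every mobile charge."""
        if len(self.seg_pos):
            P = np.vstack([self.ion_pos, self.seg_pos])
            Q = np.concatenate(
                [np.full(self.n_ion, float(self.valence)), self.seg_q]
            )
        else:
            P = self.ion_pos.copy()
            Q = np.full(self.n_ion, float(self.valence))
        return P, Q

    def total_charge(self) -> float:
        _, Q = self.all_charges()
        return float(Q.sum() + self.sigma_e * self.box_xy**2)


def _segment_geometry(spec: HeadGroupSpec, anchors, orient):
    """Mobile charge positions and charge numbers from orientation vectors."""
    ns = len(anchors)
    a3 = np.zeros((ns, 3))
    a3[:, 1:] = anchors
    if spec.variant in (RIGID_ROTOR, ZWITTERIONIC):
        u = orient["u"]
        if spec.variant == ZWITTERIONIC:
            pos = a3 + spec.l1 * u
            return pos, np.full(ns, spec.q1), np.arange(ns)
        p1 = a3 + spec.l1 * u
        p2 = a3 + (spec.l1 + spec.l2) * u
        pos = np.concatenate([p1, p2])
        q = np.concatenate([np.full(ns, spec.q1), np.full(ns, spec.q2)])
        return pos, q, np.concatenate([np.arange(ns), np.arange(ns)])
    if spec.variant == FLEXIBLE:
        u1, u2 = orient["u1"], orient["u2"]
        p1 = a3 + spec.l1 * u1
        p2 = p1 + spec.l2 * u2
        pos = np.concatenate([p1, p2])
        q = np.concatenate([np.full(ns, spec.q1), np.full(ns, spec.q2)])
        return pos, q, np.concatenate([np.arange(ns), np.arange(ns)])
    if spec.variant == TRIANGULAR:
        eb, ep = orient["eb"], orient["ep"]
        half = 0.5 * spec.alpha_rad
        l = spec.l1
        p1 = a3 + l * (math.cos(half) * eb - math.sin(half) * ep)
        p2 = a3 + l * (math.cos(half) * eb + math.sin(half) * ep)
        pos = np.concatenate([p1, p2])
        q = np.concatenate([np.full(ns, spec.q1), np.full(ns, spec.q2)])
        return pos, q, np.concatenate([np.arange(ns), np.arange(ns)])
    raise ParameterError(f"unknown variant {spec.variant!r}")


def init_state(
    params: SystemParams, spec: HeadGroupSpec, config: MCConfig
) -> MCState:
    """Electroneutral initial configuration.

    Grafting sites are uniform random in-plane; head groups start
    perpendicular to the surface; counterions are inserted uniformly at
    random without hard-core overlap.
    """
    if params.electrolyte_mode != COUNTERIONS_ONLY:
        raise ParameterError(
            "the MC validator samples the counterions-only ensemble"
        )
    rng = np.random.default_rng(config.seed)
    n_lip = config.n_lipids
    n_struct_f = (1.0 - params.beta) * n_lip
    n_struct = round(n_struct_f)
    if abs(n_struct_f - n_struct) > 1e-9:
        raise ParameterError(
            f"beta={params.beta} gives a non-integer structured-lipid count "
            f"{n_struct_f}; nearest admissible beta = {1.0 - n_struct / n_lip}"
        )
    q_plane = n_struct * spec.q0 + (n_lip - n_struct) * params.nonstructured_charge
    q_head = n_struct * spec.mobile_charge
    valence = counterion_valence(params, spec)
    n_ion_f = -(q_plane + q_head) / valence
    n_ion = round(n_ion_f)
    if abs(n_ion_f - n_ion) > 1e-9 or n_ion < 0:
        raise ParameterError(
            f"composition is not electroneutral in integers: "
            f"{n_ion_f} counterions of valence {valence} required"
        )
    L = box_side(n_lip, params.area_per_lipid)
    # grafting sites with a minimal lateral spacing so that the initial
    # (perpendicular) head groups do not overlap
    anchors = np.empty((n_struct, 2))
    spacing2 = (2.0 * config.ion_radius) ** 2
    k = 0
    attempts = 0
    while k < n_struct:
        attempts += 1
        if attempts > 2000 * max(n_struct, 1):
            raise ParameterError("could not place grafting sites without overlap")
        cand = rng.uniform(0.0, L, size=2)
        if k:
            d = anchors[:k] - cand
            d -= L * np.round(d / L)
            if np.min(np.einsum("ij,ij->i", d, d)) < spacing2:
                continue
        anchors[k] = cand
        k += 1
    xhat = np.tile(np.array([1.0, 0.0, 0.0]), (n_struct, 1))
    yhat = np.tile(np.array([0.0, 1.0, 0.0]), (n_struct, 1))
    if spec.variant in (RIGID_ROTOR, ZWITTERIONIC):
        orient = {"u": xhat.copy()}
    elif spec.variant == FLEXIBLE:
        orient = {"u1": xhat.copy(), "u2": xhat.copy()}
    else:
        orient = {"eb": xhat.copy(), "ep": yhat.copy()}
    seg_pos, seg_q, seg_lipid = _segment_geometry(spec, anchors, orient)
    # non-overlapping random ion insertion (cores against ions and segments)
    ion_pos = np.empty((n_ion, 3))
    d2min = (2.0 * config.ion_radius) ** 2
    k = 0
    attempts = 0
    while k < n_ion:
        attempts += 1
        if attempts > 1000 * max(n_ion, 1):
            raise ParameterError("could not insert ions without overlap")
        cand = np.array(
            [rng.uniform(0.0, config.box_z), rng.uniform(0.0, L), rng.uniform(0.0, L)]
        )
        placed = np.vstack([ion_pos[:k], seg_pos]) if len(seg_pos) else ion_pos[:k]
        if len(placed):
            d = placed - cand
            d[:, 1:] -= L * np.round(d[:, 1:] / L)
            if np.min(np.einsum("ij,ij->i", d, d)) < d2min:
                continue
        ion_pos[k] = cand
        k += 1
    sigma_e = q_plane / L**2
    state = MCState(
        params=params,
        spec=spec,
        config=config,
        rng=rng,
        box_xy=L,
        sigma_e=sigma_e,
        valence=valence,
        ion_pos=ion_pos,
        anchors=anchors,
        orient=orient,
        seg_pos=seg_pos,
        seg_q=seg_q,
        seg_lipid=seg_lipid,
        displacement_ion=config.displacement_ion,
        displacement_lipid=config.displacement_lipid,
        rotation_delta=config.rotation_delta,
        accept={
            k: np.zeros(2) for k in ("ion", "lipid_translate", "lipid_rotate")
        },
    )
    state.energy = total_energy(state)
    return state


# ---------------------------------------------------------------------------
# Energies


def _pair_potential(dpos: np.ndarray, L: float) -> np.ndarray:
    """Geometric pair factor 1/r_mi + far-field sheet correction.

    ``dpos`` is an (n, 3) array of separations (axis 0 = normal); lateral
    components are minimum-imaged.
    """
    d = dpos.copy()
    d[:, 1:] -= L * np.round(d[:, 1:] / L)
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    dz = np.abs(d[:, 0])
    far = (-2.0 * math.pi * dz - square_sheet_potential(dz, L)) / (L * L)
    with np.errstate(divide="ignore"):
        inv = np.where(r > 0.0, 1.0 / np.maximum(r, 1e-300), 0.0)
    return inv + far


def _wall_energy(state: MCState, x: np.ndarray, q: np.ndarray) -> float:
    """Interaction of charges with the smeared plane at x = 0.

    The infinite uniformly charged plane gives the exact reduced potential
    phi(x) = -2 pi l_B sigma_e x.
    """
    lb = state.params.bjerrum_length
    return float(-2.0 * math.pi * lb * state.sigma_e * np.dot(q, x))


def _cross_energy(
    state: MCState,
    P_other: np.ndarray,
    Q_other: np.ndarray,
    P_set: np.ndarray,
    Q_set: np.ndarray,
) -> float:
    lb = state.params.bjerrum_length
    e = 0.0
    for p, q in zip(P_set, Q_set):
        phi = _pair_potential(P_other - p, state.box_xy)
        e += q * float(Q_other @ phi)
    return lb * e


def total_energy(state: MCState) -> float:
    """Full configurational energy in k_B T (excluding constants)."""
    P, Q = state.all_charges()
    lb = state.params.bjerrum_length
    n = len(P)
    e = 0.0
    n_ion = state.n_ion
    for i in range(n - 1):
        dp = P[i + 1 :] - P[i]
        phi = _pair_potential(dp, state.box_xy)
        qq = Q[i] * Q[i + 1 :]
        if i >= n_ion:  # mask intramolecular partner
            li = state.seg_lipid[i - n_ion]
            partner = state.seg_lipid[i + 1 - n_ion :] == li
            qq = np.where(partner, 0.0, qq)
        e += float(qq @ phi)
    return lb * e + _wall_energy(state, P[:, 0], Q)


def _entity_rows(state: MCState, kind: str, idx: int):
    """Charge-row indices of an entity in the stacked charge arrays."""
    if kind == "ion":
        return np.array([idx])
    rows = np.nonzero(state.seg_lipid == idx)[0] + state.n_ion
    return rows


def _hard_core_overlap(
    state: MCState, new_positions: np.ndarray, rows: np.ndarray, P: np.ndarray
) -> bool:
    """True if any new position violates the hard core against non-excluded
    charges (bonded partners are in ``rows`` and exempt)."""
    d2min = (2.0 * state.config.ion_radius) ** 2
    mask = np.ones(len(P), dtype=bool)
    mask[rows] = False
    others = P[mask]
    if not len(others):
        return False
    L = state.box_xy
    for p in np.atleast_2d(new_positions):
        d = others - p
        d[:, 1:] -= L * np.round(d[:, 1:] / L)
        if np.min(np.einsum("ij,ij->i", d, d)) < d2min:
            return True
    return False


def _entity_energy(state: MCState, rows: np.ndarray, P, Q) -> float:
    mask = np.ones(len(P), dtype=bool)
    mask[rows] = False
    return _cross_energy(state, P[mask], Q[mask], P[rows], Q[rows]) + _wall_energy(
        state, P[rows, 0], Q[rows]
    )


def _random_rotation(rng: np.random.Generator, delta: float) -> np.ndarray:
    """Rodrigues rotation matrix for a random rotation vector ~ delta*N(0,1)."""
    w = delta * rng.standard_normal(3)
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        return np.eye(3)
    k = w / theta
    K = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
    )
    return np.eye(3) + math.sin(theta) * K + (1 - math.cos(theta)) * (K @ K)


def mc_sweep(state: MCState, tune: bool = False) -> MCState:
    """One attempted move per particle (ions and structured lipids), in place.

    Symmetric proposals (uniform displacements, random-rotation-vector
    rotations) with Metropolis acceptance on the full energy difference.
    Hard constraints (walls, ion cores, half-space for segments) reject.
    """
    rng = state.rng
    n_ent = state.n_ion + state.n_struct
    order = rng.permutation(n_ent)
    P, Q = state.all_charges()
    L = state.box_xy
    for ent in order:
        if ent < state.n_ion:
            i = int(ent)
            old = state.ion_pos[i].copy()
            new = old + state.displacement_ion * rng.uniform(-1, 1, 3)
            new[1:] %= L
            key = "ion"
            state.accept[key][1] += 1
            if not 0.0 <= new[0] <= state.config.box_z:
                continue
            rows = np.array([i])
            if _hard_core_overlap(state, new, rows, P):
                continue
            e_old = _entity_energy(state, rows, P, Q)
            P_new = P.copy()
            P_new[i] = new
            e_new = _entity_energy(state, rows, P_new, Q)
            dE = e_new - e_old
            if dE <= 0 or rng.random() < math.exp(-min(dE, 700.0)):
                state.ion_pos[i] = new
                P[i] = new
                state.energy += dE
                state.accept[key][0] += 1
        else:
            j = int(ent - state.n_ion)
            rotate = rng.random() < 0.5
            key = "lipid_rotate" if rotate else "lipid_translate"
            state.accept[key][1] += 1
            new_orient = {k: v.copy() for k, v in state.orient.items()}
            new_anchor = state.anchors[j].copy()
            if rotate:
                R = _random_rotation(rng, state.rotation_delta)
                if state.spec.variant == FLEXIBLE and rng.random() < 0.5:
                    new_orient["u2"][j] = R @ state.orient["u2"][j]
                elif state.spec.variant == FLEXIBLE:
                    new_orient["u1"][j] = R @ state.orient["u1"][j]
                elif state.spec.variant == TRIANGULAR:
                    new_orient["eb"][j] = R @ state.orient["eb"][j]
                    new_orient["ep"][j] = R @ state.orient["ep"][j]
                else:
                    new_orient["u"][j] = R @ state.orient["u"][j]
            else:
                new_anchor = (
                    new_anchor + state.displacement_lipid * rng.uniform(-1, 1, 2)
                ) % L
            anchors_new = state.anchors.copy()
            anchors_new[j] = new_anchor
            seg_pos_new, _, _ = _segment_geometry(
                state.spec, anchors_new, new_orient
            )
            rows = _entity_rows(state, "lipid", j)
            xs = seg_pos_new[rows - state.n_ion, 0]
            if np.any(xs < 0.0) or np.any(xs > state.config.box_z):
                continue
            if _hard_core_overlap(
                state, seg_pos_new[rows - state.n_ion], rows, P
            ):
                continue
            e_old = _entity_energy(state, rows, P, Q)
            P_new = P.copy()
            P_new[rows] = seg_pos_new[rows - state.n_ion]
            e_new = _entity_energy(state, rows, P_new, Q)
            dE = e_new - e_old
            if dE <= 0 or rng.random() < math.exp(-min(dE, 700.0)):
                state.anchors[j] = new_anchor
                for k in state.orient:
                    state.orient[k][j] = new_orient[k][j]
                state.seg_pos[rows - state.n_ion] = seg_pos_new[rows - state.n_ion]
                P[rows] = seg_pos_new[rows - state.n_ion]
                state.energy += dE
                state.accept[key][0] += 1
    if tune:
        _tune_displacements(state)
    return state


def _tune_displacements(state: MCState) -> None:
    for key, attr in (
        ("ion", "displacement_ion"),
        ("lipid_translate", "displacement_lipid"),
        ("lipid_rotate", "rotation_delta"),
    ):
        acc, att = state.accept[key]
        if att < 10:
            continue
        rate = acc / att
        val = getattr(state, attr)
        if rate > 0.55:
            val *= 1.1
        elif rate < 0.45:
            val /= 1.1
        setattr(state, attr, min(val, state.box_xy))
        state.accept[key][:] = 0.0


# ---------------------------------------------------------------------------
# Profiles


def _segment_heights(state: MCState) -> Dict[str, np.ndarray]:
    """Heights to histogram for the orientation densities."""
    spec = state.spec
    ns = state.n_struct
    if ns == 0:
        return {}
    if spec.variant in (RIGID_ROTOR, ZWITTERIONIC):
        u = state.orient["u"][:, 0]
        out = {"W": spec.l1 * u}
        if spec.variant == RIGID_ROTOR:
            out["W_terminal"] = (spec.l1 + spec.l2) * u
        return out
    if spec.variant == FLEXIBLE:
        x1 = spec.l1 * state.orient["u1"][:, 0]
        return {"W_x": x1, "W_s": x1 + spec.l2 * state.orient["u2"][:, 0]}
    h = state.seg_pos[:, 0]
    return {"W": 0.5 * (h[:ns] + h[ns:]), "W_lower": np.minimum(h[:ns], h[ns:])}


def accumulate_profiles(state: MCState, bin_width: float, box_z: float, hist_range: float):
    """Single-sample histograms: ion counts and segment-height counts."""
    edges_ion = np.arange(0.0, box_z + bin_width, bin_width)
    counts = {"ion": np.histogram(state.ion_pos[:, 0], bins=edges_ion)[0]}
    edges_w = np.arange(0.0, hist_range + bin_width, bin_width)
    for key, h in _segment_heights(state).items():
        counts[key] = np.histogram(h, bins=edges_w)[0]
    return counts, edges_ion, edges_w


@dataclass
class MCResult:
    """Block-averaged profiles and run report."""

    x_ion: np.ndarray
    n_ion: np.ndarray  # nm^-3
    se_ion: np.ndarray
    x_w: np.ndarray
    W: Dict[str, np.ndarray]
    W_se: Dict[str, np.ndarray]
    acceptance: Dict[str, float]
    energy_drift: float
    equilibration_warning: bool
    seed: int
    config: MCConfig
    box_xy: float
    valence: int

    def report(self) -> dict:
        return {
            "seed": self.seed,
            "box_xy_nm": self.box_xy,
            "acceptance": self.acceptance,
            "energy_drift": self.energy_drift,
            "equilibration_warning": self.equilibration_warning,
            "n_blocks": self.config.n_blocks,
        }


def run_mc(
    params: SystemParams, spec: HeadGroupSpec, config: MCConfig
) -> MCResult:
    """Equilibrate, sample, and block-average the slab simulation.

    Deterministic for a fixed seed.  Energy bookkeeping is verified against
    full recomputation every ``energy_check_interval`` sweeps; the worst
    relative drift is reported.
    """
    state = init_state(params, spec, config)
    assert abs(state.total_charge()) < 1e-9, "configuration must be electroneutral"
    drift = 0.0
    for sweep in range(config.moves_equilibration):
        mc_sweep(state, tune=(sweep + 1) % config.tune_interval == 0)
        if (sweep + 1) % config.energy_check_interval == 0:
            e_full = total_energy(state)
            drift = max(
                drift, abs(e_full - state.energy) / max(abs(e_full), 1.0)
            )
            state.energy = e_full
    for key in state.accept:
        state.accept[key][:] = 0.0
    hist_range = spec.l1 + spec.l2  # segment heights live below full extension
    n_blocks = config.n_blocks
    sweeps_per_block = max(1, config.moves_production // n_blocks)
    block_ion = []
    block_w: Dict[str, list] = {}
    edges_ion = edges_w = None
    for b in range(n_blocks):
        acc_ion = None
        acc_w: Dict[str, np.ndarray] = {}
        for _ in range(sweeps_per_block):
            mc_sweep(state)
            counts, edges_ion, edges_w = accumulate_profiles(
                state, config.bin_width, config.box_z, hist_range
            )
            if acc_ion is None:
                acc_ion = counts["ion"].astype(float)
            else:
                acc_ion += counts["ion"]
            for k, v in counts.items():
                if k == "ion":
                    continue
                acc_w[k] = acc_w.get(k, 0.0) + v.astype(float)
        area = state.box_xy**2
        block_ion.append(acc_ion / (sweeps_per_block * area * config.bin_width))
        for k, v in acc_w.items():
            total = v.sum()
            dens = v / (total * config.bin_width) if total > 0 else v
            block_w.setdefault(k, []).append(dens)
        e_full = total_energy(state)
        drift = max(drift, abs(e_full - state.energy) / max(abs(e_full), 1.0))
        state.energy = e_full
    ion_blocks = np.array(block_ion)
    n_ion_prof = ion_blocks.mean(axis=0)
    se_ion = ion_blocks.std(axis=0, ddof=1) / math.sqrt(n_blocks)
    W = {}
    W_se = {}
    for k, blocks in block_w.items():
        arr = np.array(blocks)
        W[k] = arr.mean(axis=0)
        W_se[k] = arr.std(axis=0, ddof=1) / math.sqrt(n_blocks)
    # crude drift detection: first vs second half of production blocks
    half = n_blocks // 2
    warn = False
    if half >= 2:
        m1 = ion_blocks[:half].mean(axis=0)
        m2 = ion_blocks[half:].mean(axis=0)
        pooled = ion_blocks.std(axis=0, ddof=1) / math.sqrt(half)
        mask = pooled > 0
        if mask.any():
            zmax = np.max(np.abs(m1[mask] - m2[mask]) / pooled[mask])
            warn = bool(zmax > 5.0)
    acceptance = {
        k: (float(v[0] / v[1]) if v[1] else float("nan"))
        for k, v in state.accept.items()
    }
    return MCResult(
        x_ion=0.5 * (edges_ion[:-1] + edges_ion[1:]),
        n_ion=n_ion_prof,
        se_ion=se_ion,
        x_w=0.5 * (edges_w[:-1] + edges_w[1:]),
        W=W,
        W_se=W_se,
        acceptance=acceptance,
        energy_drift=drift,
        equilibration_warning=warn,
        seed=config.seed,
        config=config,
        box_xy=state.box_xy,
        valence=state.valence,
    )
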