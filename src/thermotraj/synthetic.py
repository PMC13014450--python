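"""Deterministic toy structures and trajectories with known ground truth.

Builders return one-frame :class:`Trajectory` objects (topology plus a
reference conformation); trajectory factories derive multi-frame
trajectories with engineered statistical properties (zero-RMSD rigid
motion, prescribed per-residue noise, monotone expansion, prescribed
salt-bridge presence fractions, engineered protein-water hydrogen
bonds).  Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .io_structures import (
    ACIDIC_SIDECHAIN_O,
    BASIC_SIDECHAIN_N,
    AtomRecord,
    Topology,
    Trajectory,
    _mass_for,
)

__all__ = [
    "GeneratorSpec",
    "ToyProteinSpec",
    "ChargePair",
    "build_ideal_helix",
    "build_beta_hairpin",
    "build_extended_strand",
    "build_toy_protein",
    "make_rigid_trajectory",
    "make_fluctuation_trajectory",
    "make_unfolding_trajectory",
    "make_contact_trajectory",
    "add_water_shell",
]

# ideal backbone geometry (Å, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_N_H = 1.01
B_CA_CB = 1.53
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_C_N_H = 119.5

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0

WATER_OH = 0.9572
WATER_HOH = 104.52

CLASH_DISTANCE = 0.8  # Å


@dataclasses.dataclass
class GeneratorSpec:
    """Parameters shared by the trajectory factories."""

    seed: int = 0
    n_frames: int = 100
    noise_sigma: Sequence[float] | float = 0.0  # per-residue Å
    expansion_schedule: Sequence[float] | None = None
    contact_plan: list[tuple] = dataclasses.field(default_factory=list)
    water_plan: list[dict] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expansion_schedule is not None:
            s = np.asarray(self.expansion_schedule, dtype=float)
            if np.any(s < 1.0):
                raise ValueError("expansion factors must be >= 1")
        for entry in self.contact_plan:
            p = entry[-1]
            if not (0.0 <= p <= 1.0):
                raise ValueError("contact presence fraction must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class ChargePair:
    """A basic/acidic residue pair to engineer into a toy protein."""

    basic_pos: int  # 0-based residue position
    basic_name: str  # LYS or ARG
    acidic_pos: int
    acidic_name: str  # ASP or GLU
    distance: float  # Å between the charged terminal atoms


@dataclasses.dataclass
class ToyProteinSpec:
    n_helix: int = 12
    n_per_strand: int = 5
    charge_pairs: list[ChargePair] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# Internal-coordinate chain building
# ---------------------------------------------------------------------------

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position atom D from internal coordinates relative to A-B-C
    (bond C-D, angle B-C-D, dihedral A-B-C-D)."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(dih), bond * np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(
    phis: np.ndarray, psis: np.ndarray, omegas: np.ndarray
) -> dict[str, np.ndarray]:
    """Backbone N/CA/C/O/H positions for a chain with given dihedrals.

    phis[0] is unused (no preceding carbonyl); H is absent for residue 0.
    """
    n_res = len(phis)
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = np.radians(A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psis[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, omegas[i])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C, phis[i + 1])
    O = np.empty((n_res, 3))
    for i in range(n_res):
        psi = psis[i] if i < n_res - 1 else psis[-1]
        O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi + 180.0)
    H = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        H[i] = place_atom(O[i - 1], C[i - 1], N[i], B_N_H, A_C_N_H, 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    u1 = n - ca
    u1 /= np.linalg.norm(u1)
    u2 = c - ca
    u2 /= np.linalg.norm(u2)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    ang = np.radians(54.0)
    return ca + B_CA_CB * (np.cos(ang) * bis + np.sin(ang) * perp)


def _assemble(
    bb: dict[str, np.ndarray],
    residue_names: Sequence[str],
    start_seq: int = 1,
    chain_id: str = "A",
    extra_atoms: dict[int, list[tuple[str, np.ndarray]]] | None = None,
    with_cb: bool = True,
) -> Trajectory:
    """Turn backbone arrays (plus optional per-residue extra atoms) into a
    one-frame trajectory."""
    extra_atoms = extra_atoms or {}
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 1

    def add(name: str, element: str, resname: str, seq: int, pos: np.ndarray) -> None:
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial, name=name, element=element, residue_name=resname,
                residue_seq=seq, chain_id=chain_id, mass=_mass_for(element),
            )
        )
        coords.append(np.asarray(pos, dtype=float))
        serial += 1

    n_res = len(residue_names)
    for i in range(n_res):
        resname = residue_names[i]
        seq = start_seq + i
        add("N", "N", resname, seq, bb["N"][i])
        add("CA", "C", resname, seq, bb["CA"][i])
        add("C", "C", resname, seq, bb["C"][i])
        add("O", "O", resname, seq, bb["O"][i])
        if not np.isnan(bb["H"][i]).any():
            add("H", "H", resname, seq, bb["H"][i])
        if with_cb and resname != "GLY":
            add("CB", "C", resname, seq, _cb_position(bb["N"][i], bb["CA"][i], bb["C"][i]))
        for name, pos in extra_atoms.get(i, []):
            add(name, name[0], resname, seq, pos)

    frame = np.stack(coords)
    _check_clashes(frame)
    return Trajectory(Topology(atoms), frame[None, :, :])


def _check_clashes(frame: np.ndarray) -> None:
    d = np.sqrt(np.sum((frame[:, None, :] - frame[None, :, :]) ** 2, axis=2))
    np.fill_diagonal(d, np.inf)
    if d.min() < CLASH_DISTANCE:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(f"overlapping atoms {i} and {j} ({d.min():.2f} Å apart)")


# ---------------------------------------------------------------------------
# Structure builders
# ---------------------------------------------------------------------------

def build_ideal_helix(n_residues: int, sequence: str | None = None) -> Trajectory:
    """Ideal poly-Ala (or given-sequence) alpha helix, amide H included."""
    if n_residues < 4:
        raise ValueError("helix needs at least 4 residues")
    phis = np.full(n_residues, HELIX_PHI)
    psis = np.full(n_residues, HELIX_PSI)
    omegas = np.full(n_residues, 180.0)
    bb = _build_backbone(phis, psis, omegas)
    names = _residue_names(n_residues, sequence)
    return _assemble(bb, names)


def build_extended_strand(n_residues: int, sequence: str | None = None) -> Trajectory:
    """Single fully extended strand; every amide N-H and carbonyl is
    solvent-exposed, which makes it the fixture of choice for engineered
    protein-water hydrogen bonds."""
    if n_residues < 2:
        raise ValueError("strand needs at least 2 residues")
    phis = np.full(n_residues, STRAND_PHI)
    psis = np.full(n_residues, STRAND_PSI)
    omegas = np.full(n_residues, 180.0)
    bb = _build_backbone(phis, psis, omegas)
    return _assemble(bb, _residue_names(n_residues, sequence))


def _residue_names(n: int, sequence: str | None) -> list[str]:
    from .io_structures import THREE_TO_ONE

    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    if sequence is None:
        return ["ALA"] * n
    if len(sequence) != n:
        raise ValueError("sequence length must equal residue count")
    return [one_to_three[c] for c in sequence.upper()]


def _hairpin_registry(n: int) -> list[tuple[int, int]]:
    """Mutually hydrogen-bonded (i, j) pairs, 0-based within 2n residues."""
    pairs = []
    for i in range(n - 2, -1, -2):
        pairs.append((i, 2 * n - 1 - i))
    return pairs


_HAIRPIN_CACHE: dict[tuple, "Trajectory"] = {}


def build_beta_hairpin(n_per_strand: int, sequence: str | None = None) -> Trajectory:
    """Two antiparallel ideal strands with proper inter-strand hydrogen-bond
    registry (residue i pairs with 2n-1-i; alternating mutual N-H...O=C
    bonds at ~2.9 Å N...O).

    The two strands form one chain with a gap (no connecting turn); the
    second strand's rigid placement is found by a deterministic
    least-squares fit to the designed registry.
    """
    n = n_per_strand
    if n < 3:
        raise ValueError("strands need at least 3 residues each")
    cache_key = (n, sequence)
    if cache_key in _HAIRPIN_CACHE:
        cached = _HAIRPIN_CACHE[cache_key]
        return Trajectory(cached.topology, cached.frames.copy())
    phis = np.full(n, STRAND_PHI)
    psis = np.full(n, STRAND_PSI)
    omegas = np.full(n, 180.0)
    bb1 = _build_backbone(phis, psis, omegas)
    bb2 = _build_backbone(phis, psis, omegas)

    pairs = [(i, j - n) for i, j in _hairpin_registry(n)]  # j index within strand 2
    # strand 2 runs antiparallel: residue j (within-strand index) sits
    # opposite residue i, so reverse its internal index when pairing
    targets = []  # (atom set 1, atom set 2, target distance)
    for i, j2 in pairs:
        targets.append((bb1["N"][i], "O", j2, 2.9))
        targets.append((bb1["O"][i], "N", j2, 2.9))
        if i > 0:
            targets.append((bb1["H"][i], "O", j2, 1.9))
        if j2 > 0:
            targets.append((bb1["O"][i], "H", j2, 1.9))

    p1_arr = np.array([t[0] for t in targets])
    s2_arr = np.array([bb2[t[1]][t[2]] for t in targets])
    tgt_arr = np.array([t[3] for t in targets])
    base2 = np.concatenate([bb2[k] for k in ("N", "CA", "C", "O")])
    all1 = np.concatenate([bb1[k] for k in ("N", "CA", "C", "O")])

    def transform(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(params[:3])
        return rot.apply(pts) + params[3:]

    def objective(params: np.ndarray) -> float:
        moved_targets = transform(params, s2_arr)
        d = np.linalg.norm(p1_arr - moved_targets, axis=1)
        cost = float(np.sum((d - tgt_arr) ** 2))
        # soft clash penalty between strand backbones
        moved = transform(params, base2)
        dd = np.sqrt(np.sum((all1[:, None, :] - moved[None, :, :]) ** 2, axis=2))
        cost += float(np.sum(np.clip(3.2 - dd, 0.0, None) ** 2))
        return cost

    axis = bb1["CA"][-1] - bb1["CA"][0]
    axis /= np.linalg.norm(axis)
    rng = np.random.default_rng(20240101)
    # deterministic multi-start: flips about in-plane axes + lateral offsets
    seeds = []
    center = bb1["CA"].mean(axis=0)
    for _ in range(4):
        v = rng.normal(size=3)
        v -= axis * (v @ axis)
        v /= np.linalg.norm(v)
        rotvec = v * np.pi
        rot = Rotation.from_rotvec(rotvec)
        for off in (4.6, -4.6):
            for lateral in (np.cross(axis, v), v):
                shift = center + off * lateral - rot.apply(bb2["CA"].mean(axis=0))
                seeds.append(np.concatenate([rotvec, shift]))
    coarse = [
        minimize(objective, x0, method="Nelder-Mead",
                 options={"maxiter": 600, "xatol": 1e-4, "fatol": 1e-6})
        for x0 in seeds
    ]
    coarse.sort(key=lambda r: r.fun)
    best = None
    for r in coarse[:3]:
        res = minimize(objective, r.x, method="Nelder-Mead",
                       options={"maxiter": 3000, "xatol": 1e-7, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    params = best.x

    bb2t = {k: transform(params, v) if k != "H" else v for k, v in bb2.items()}
    bb2t["H"] = np.full_like(bb2["H"], np.nan)
    valid = ~np.isnan(bb2["H"][:, 0])
    bb2t["H"][valid] = transform(params, bb2["H"][valid])

    merged = {k: np.concatenate([bb1[k], bb2t[k]]) for k in bb1}
    names = _residue_names(2 * n, sequence)
    result = _assemble(merged, names)
    _HAIRPIN_CACHE[cache_key] = result
    return Trajectory(result.topology, result.frames.copy())


def build_toy_protein(spec: ToyProteinSpec) -> Trajectory:
    """Mini alpha/beta fold: helix + hairpin side by side (one chain, a
    flagged gap between segments) with charged side-chain terminal atoms
    placed at configured pair distances."""
    helix = build_ideal_helix(spec.n_helix)
    hairpin = build_beta_hairpin(spec.n_per_strand)

    h_top, h_frame = helix.topology, helix.frames[0]
    p_top, p_frame = hairpin.topology, hairpin.frames[0]
    # place the hairpin clear of the helix
    offset = h_frame.max(axis=0) - p_frame.min(axis=0) + np.array([0.0, 12.0, 0.0])
    offset[0] = 0.0
    offset[2] = 0.0
    p_frame = p_frame + offset

    n_res_total = spec.n_helix + 2 * spec.n_per_strand
    names = ["ALA"] * n_res_total
    for cp in spec.charge_pairs:
        for pos, resname in ((cp.basic_pos, cp.basic_name), (cp.acidic_pos, cp.acidic_name)):
            if not (0 <= pos < n_res_total):
                raise ValueError(f"charge-pair position {pos} out of range")
            if names[pos] != "ALA" and names[pos] != resname:
                raise ValueError(f"conflicting residue assignments at position {pos}")
            names[pos] = resname
        if cp.basic_name not in BASIC_SIDECHAIN_N or cp.acidic_name not in ACIDIC_SIDECHAIN_O:
            raise ValueError("charge pair must be Lys/Arg vs Asp/Glu")

    # gather per-residue backbone coords across both segments
    def seg_coords(top: Topology, frame: np.ndarray, key: str) -> list[np.ndarray]:
        out = []
        for ri in range(top.n_residues):
            idx = top.residue_atoms(ri, [key])
            out.append(frame[idx[0]] if idx else np.full(3, np.nan))
        return out

    bb = {
        k: np.array(
            seg_coords(h_top, h_frame, k) + seg_coords(p_top, p_frame, k)
        )
        for k in ("N", "CA", "C", "O", "H")
    }

    extra: dict[int, list[tuple[str, np.ndarray]]] = {}
    for cp in spec.charge_pairs:
        ca_b = bb["CA"][cp.basic_pos]
        ca_a = bb["CA"][cp.acidic_pos]
        u = ca_a - ca_b
        gap = np.linalg.norm(u)
        u = u / gap
        mid = 0.5 * (ca_b + ca_a)
        basic_atom = BASIC_SIDECHAIN_N[cp.basic_name][0]
        acidic_atom = ACIDIC_SIDECHAIN_O[cp.acidic_name][0]
        extra.setdefault(cp.basic_pos, []).append(
            (basic_atom, mid - 0.5 * cp.distance * u)
        )
        extra.setdefault(cp.acidic_pos, []).append(
            (acidic_atom, mid + 0.5 * cp.distance * u)
        )
    return _assemble(bb, names, extra_atoms=extra)


# ---------------------------------------------------------------------------
# Trajectory factories
# ---------------------------------------------------------------------------

def _base(structure: Trajectory) -> tuple[Topology, np.ndarray]:
    return structure.topology, structure.frames[0]


def make_rigid_trajectory(structure: Trajectory, n_frames: int, seed: int = 0) -> Trajectory:
    """Random proper rotation + translation per frame; internal geometry
    is preserved exactly (zero-RMSD control)."""
    top, x0 = _base(structure)
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, top.n_atoms, 3))
    for f in range(n_frames):
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-20.0, 20.0, size=3)
        frames[f] = rot.apply(x0) + shift
    return Trajectory(top, frames)


def make_fluctuation_trajectory(
    structure: Trajectory,
    sigma_profile: Sequence[float] | float,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """IID Gaussian displacement per coordinate about fixed mean positions;
    ``sigma_profile`` gives the per-residue sigma in Å (scalar = uniform)."""
    top, x0 = _base(structure)
    sigma = np.asarray(sigma_profile, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(top.n_residues, float(sigma))
    if len(sigma) != top.n_residues:
        raise ValueError("sigma profile must have one value per residue")
    per_atom = sigma[top.atom_residue]
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n_frames, top.n_atoms, 3)) * per_atom[None, :, None]
    return Trajectory(top, x0[None, :, :] + noise)


def make_unfolding_trajectory(
    structure: Trajectory,
    expansion_schedule: Sequence[float],
    seed: int = 0,
    jitter: float = 0.0,
) -> Trajectory:
    """Frame t scales all deviations from the center of mass by
    ``expansion_schedule[t]`` (plus optional small seeded jitter)."""
    top, x0 = _base(structure)
    s = np.asarray(expansion_schedule, dtype=float)
    if np.any(s < 1.0):
        raise ValueError("expansion factors must be >= 1")
    w = top.masses / top.masses.sum()
    com = w @ x0
    rng = np.random.default_rng(seed)
    frames = com + s[:, None, None] * (x0 - com)[None, :, :]
    if jitter > 0:
        frames = frames + rng.normal(scale=jitter, size=frames.shape)
    return Trajectory(top, frames)


def make_contact_trajectory(
    structure: Trajectory,
    pair: tuple[int, int],
    p: float,
    n_frames: int,
    seed: int = 0,
    on_distance: float = 3.5,
    off_distance: float = 6.0,
) -> Trajectory:
    """The charged pair's terminal atoms sit within 4 Å in exactly
    ``round(p * n_frames)`` frames and beyond 5 Å otherwise.

    ``pair`` gives 0-based residue indices (basic, acidic); the basic
    side-chain terminal atom is moved along the line to the acidic
    oxygen.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("presence fraction must lie in [0, 1]")
    top, x0 = _base(structure)
    bi, ai = pair
    b_res = top.residues[bi]
    a_res = top.residues[ai]
    b_atoms = top.residue_atoms(bi, BASIC_SIDECHAIN_N.get(b_res.residue_name, ()))
    a_atoms = top.residue_atoms(ai, ACIDIC_SIDECHAIN_O.get(a_res.residue_name, ()))
    if not b_atoms or not a_atoms:
        raise ValueError("pair residues lack charged terminal atoms")
    b_idx, a_idx = b_atoms[0], a_atoms[0]

    k_on = round(p * n_frames)
    rng = np.random.default_rng(seed)
    on_frames = set(rng.permutation(n_frames)[:k_on].tolist())

    frames = np.repeat(x0[None, :, :], n_frames, axis=0)
    a_pos = x0[a_idx]
    u = x0[b_idx] - a_pos
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise ValueError("pair atoms coincide")
    u = u / norm
    for f in range(n_frames):
        d = on_distance if f in on_frames else off_distance
        frames[f, b_idx] = a_pos + d * u
    return Trajectory(top, frames)


def add_water_shell(
    structure: Trajectory,
    water_plan: Sequence[dict],
    seed: int = 0,
    n_random: int = 0,
    random_min_distance: float = 6.0,
) -> Trajectory:
    """Append 3-site waters at engineered hydrogen-bond geometries.

    Plan entries are dicts with keys ``residue_seq``, ``atom`` (protein
    atom name), ``kind`` ("protein_donor": the water accepts from that
    atom's attached H; "water_donor": the water donates to that acceptor
    atom), optional ``distance`` (heavy-atom separation, default 2.9 Å).
    ``n_random`` extra waters are scattered beyond ``random_min_distance``
    of every protein atom.  Raises on overlapping placement.
    """
    top, x0 = _base(structure)
    rng = np.random.default_rng(seed)
    atoms = list(top.atoms)
    coords = [x0[i] for i in range(top.n_atoms)]
    serial = max(a.serial for a in atoms)
    wat_seq = max(a.residue_seq for a in atoms)

    def protein_atom_index(residue_seq: int, name: str) -> int:
        for i, a in enumerate(top.atoms):
            if a.residue_seq == residue_seq and a.name == name:
                return i
        raise ValueError(f"no atom {name} in residue {residue_seq}")

    def add_water(o_pos: np.ndarray, h1: np.ndarray, h2: np.ndarray) -> None:
        nonlocal serial, wat_seq
        wat_seq += 1
        for name, el, pos in (("OW", "O", o_pos), ("HW1", "H", h1), ("HW2", "H", h2)):
            serial += 1
            atoms.append(
                AtomRecord(serial=serial, name=name, element=el, residue_name="SOL",
                           residue_seq=wat_seq, chain_id="W", mass=_mass_for(el))
            )
            coords.append(np.asarray(pos, dtype=float))

    def water_hydrogens(o_pos: np.ndarray, toward: np.ndarray | None) -> tuple:
        """H positions; if ``toward`` is given the first H points at it."""
        if toward is None:
            away = o_pos - x0.mean(axis=0)
            away /= np.linalg.norm(away)
            axis1 = away
        else:
            axis1 = toward - o_pos
            axis1 /= np.linalg.norm(axis1)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(axis1 @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = np.cross(axis1, ref)
        perp /= np.linalg.norm(perp)
        ang = np.radians(WATER_HOH)
        h1 = o_pos + WATER_OH * axis1
        h2 = o_pos + WATER_OH * (np.cos(ang) * axis1 + np.sin(ang) * perp)
        return h1, h2

    for entry in water_plan:
        d_target = float(entry.get("distance", 2.9))
        idx = protein_atom_index(entry["residue_seq"], entry["atom"])
        kind = entry["kind"]
        if kind == "protein_donor":
            # find the attached hydrogen
            h_idx = None
            for i, a in enumerate(top.atoms):
                if a.element == "H" and np.linalg.norm(x0[i] - x0[idx]) <= 1.25:
                    h_idx = i
                    break
            if h_idx is None:
                raise ValueError(
                    f"protein donor {entry['atom']}/{entry['residue_seq']} has no hydrogen"
                )
            u = x0[h_idx] - x0[idx]
            u /= np.linalg.norm(u)
            o_pos = x0[idx] + d_target * u
            h1, h2 = water_hydrogens(o_pos, toward=None)
        elif kind == "water_donor":
            away = x0[idx] - x0.mean(axis=0)
            if np.linalg.norm(away) < 1e-9:
                away = np.array([1.0, 0.0, 0.0])
            away /= np.linalg.norm(away)
            o_pos = x0[idx] + d_target * away
            h1, h2 = water_hydrogens(o_pos, toward=x0[idx])
        else:
            raise ValueError(f"unknown water-plan kind {kind!r}")
        add_water(o_pos, h1, h2)

    # random far waters
    bbox_lo = x0.min(axis=0) - 15.0
    bbox_hi = x0.max(axis=0) + 15.0
    placed = 0
    attempts = 0
    while placed < n_random:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place random waters")
        o_pos = rng.uniform(bbox_lo, bbox_hi)
        d = np.sqrt(np.sum((x0 - o_pos) ** 2, axis=1))
        if d.min() < random_min_distance:
            continue
        h1, h2 = water_hydrogens(o_pos, toward=None)
        add_water(o_pos, h1, h2)
        placed += 1

    frame = np.stack(coords)
    _check_clashes(frame)
    return Trajectory(Topology(atoms), frame[None, :, :])
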