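"""Self-contained secondary-structure assignment and derived statistics.

Assignment follows the classic hydrogen-bond-pattern approach: backbone
amide hydrogens are reconstructed when absent, per-pair electrostatic
energies decide hydrogen bonds (E < -0.5 kcal/mol), n-turns and bridge
patterns yield the codes {H, G, I, E, B, T, C}, and a three-class
collapse maps {H, G, I} -> alpha, {E} -> beta, everything else -> coil.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .io_structures import Topology, Trajectory

__all__ = [
    "SSAssignment",
    "SSContentSeries",
    "SSElementDefinition",
    "CLASS_OF_CODE",
    "reconstruct_amide_hydrogen",
    "backbone_hbond_energy",
    "assign_dssp_lite",
    "assign_trajectory",
    "ss_content_series",
    "content_percentages",
    "element_persistence",
    "ilv_composition",
    "load_ss_elements",
]

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
ENERGY_PREFACTOR = 0.084 * 332.0  # kcal/mol * Å (q1*q2*f)
CHAIN_BREAK_CN = 2.5  # Å
NH_BOND_LENGTH = 1.01  # Å

CLASS_OF_CODE = {
    "H": "alpha", "G": "alpha", "I": "alpha",
    "E": "beta",
    "B": "coil", "T": "coil", "C": "coil",
}

ILV_LETTERS = frozenset("ILV")


@dataclasses.dataclass
class SSAssignment:
    """Per-residue, per-frame secondary-structure codes."""

    residue_ids: list[tuple[str, int]]
    codes: np.ndarray  # (F, R) of single characters

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.ndim == 1:
            self.codes = self.codes[None, :]
        if self.codes.shape[1] != len(self.residue_ids):
            raise ValueError("codes width must equal residue count")

    @property
    def classes(self) -> np.ndarray:
        out = np.empty(self.codes.shape, dtype="<U5")
        for code, cls in CLASS_OF_CODE.items():
            out[self.codes == code] = cls
        return out


@dataclasses.dataclass
class SSContentSeries:
    """Per-frame three-class percentages (each row sums to 100)."""

    times: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    coil: np.ndarray


@dataclasses.dataclass(frozen=True)
class SSElementDefinition:
    """A named secondary-structure element over an inclusive residue range."""

    name: str
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"element {self.name}: end < start")

    @property
    def expected_class(self) -> str:
        key = self.name.lower()
        if key.startswith(("a", "α", "h", "3")):
            return "alpha"
        if key.startswith(("b", "β", "e")):
            return "beta"
        return "coil"

    def residue_seqs(self) -> range:
        return range(self.start, self.end + 1)


# ---------------------------------------------------------------------------
# Backbone extraction and amide-H reconstruction
# ---------------------------------------------------------------------------

class _Backbone:
    """Indices of backbone atoms (N, CA, C, O, H) per protein residue."""

    def __init__(self, topology: Topology):
        self.res_indices: list[int] = []
        self.chain: list[str] = []
        names = ("N", "CA", "C", "O", "H")
        idx: dict[str, list[int]] = {n: [] for n in names}
        for ri, res in enumerate(topology.residues):
            if res.residue_name not in ("HOH", "SOL", "WAT") and any(
                topology.atoms[a].is_protein
                for a in range(res.atom_start, res.atom_stop)
            ):
                found = {}
                for a in range(res.atom_start, res.atom_stop):
                    nm = topology.atoms[a].name
                    if nm in names and nm not in found:
                        found[nm] = a
                    elif nm in ("HN", "H1") and "H" not in found:
                        found["H"] = a
                if not all(n in found for n in ("N", "CA", "C", "O")):
                    continue
                self.res_indices.append(ri)
                self.chain.append(res.chain_id)
                for n in names:
                    idx[n].append(found.get(n, -1))
        self.index = {n: np.array(idx[n], dtype=np.intp) for n in names}
        self.n = len(self.res_indices)

    def coords(self, frame: np.ndarray, name: str) -> np.ndarray:
        i = self.index[name]
        out = np.full((self.n, 3), np.nan)
        has = i >= 0
        out[has] = frame[i[has]]
        return out


def reconstruct_amide_hydrogen(
    topology: Topology, frame: np.ndarray
) -> dict[int, np.ndarray]:
    """Geometric backbone amide-H positions for residues lacking one.

    H is placed 1.01 Å from N along the (outward) bisector of the
    C(prev)-N-CA angle, i.e. anti to the previous carbonyl in a planar
    peptide.  The first residue of a chain and residues after a chain
    break (C-N distance > 2.5 Å) get no hydrogen.  Keys are residue
    indices into ``topology.residues``.
    """
    bb = _Backbone(topology)
    n_pos = bb.coords(frame, "N")
    ca_pos = bb.coords(frame, "CA")
    c_pos = bb.coords(frame, "C")
    out: dict[int, np.ndarray] = {}
    for k in range(1, bb.n):
        if bb.chain[k] != bb.chain[k - 1]:
            continue
        c_prev = c_pos[k - 1]
        if np.linalg.norm(n_pos[k] - c_prev) > CHAIN_BREAK_CN:
            continue
        u1 = n_pos[k] - c_prev
        u1 /= np.linalg.norm(u1)
        u2 = n_pos[k] - ca_pos[k]
        u2 /= np.linalg.norm(u2)
        d = u1 + u2
        d /= np.linalg.norm(d)
        out[bb.res_indices[k]] = n_pos[k] + NH_BOND_LENGTH * d
    return out


def backbone_hbond_energy(
    c: np.ndarray, o: np.ndarray, n: np.ndarray, h: np.ndarray
) -> float:
    """Electrostatic hydrogen-bond energy (kcal/mol) of a C=O ... H-N pair.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN); the pair is
    bonded when E < -0.5 kcal/mol.
    """
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-9:
        raise ValueError("coincident atoms in hydrogen-bond energy evaluation")
    return float(ENERGY_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def _hbond_matrix(bb: _Backbone, topology: Topology, frame: np.ndarray) -> np.ndarray:
    """hb[d, a] True when NH of residue d donates to C=O of residue a."""
    n_pos = bb.coords(frame, "N")
    c_pos = bb.coords(frame, "C")
    o_pos = bb.coords(frame, "O")
    h_pos = bb.coords(frame, "H")
    if np.any(bb.index["H"] < 0):
        rebuilt = reconstruct_amide_hydrogen(topology, frame)
        for k in range(bb.n):
            if bb.index["H"][k] < 0 and bb.res_indices[k] in rebuilt:
                h_pos[k] = rebuilt[bb.res_indices[k]]

    hb = np.zeros((bb.n, bb.n), dtype=bool)
    has_h = ~np.isnan(h_pos[:, 0])
    # distance prefilter: O-N beyond 5.2 Å cannot reach the energy cutoff
    d_on = np.sqrt(
        np.sum((o_pos[None, :, :] - n_pos[:, None, :]) ** 2, axis=2)
    )
    for d in range(bb.n):
        if not has_h[d]:
            continue
        for a in range(bb.n):
            if a == d or d_on[d, a] > 5.2:
                continue
            e = backbone_hbond_energy(c_pos[a], o_pos[a], n_pos[d], h_pos[d])
            if e < HBOND_ENERGY_CUTOFF:
                hb[d, a] = True
    return hb


def _chain_break_mask(bb: _Backbone, frame: np.ndarray) -> np.ndarray:
    """break[k] True when residues k and k+1 are not peptide-bonded."""
    n_pos = bb.coords(frame, "N")
    c_pos = bb.coords(frame, "C")
    brk = np.zeros(max(bb.n - 1, 0), dtype=bool)
    for k in range(bb.n - 1):
        if bb.chain[k] != bb.chain[k + 1]:
            brk[k] = True
        elif np.linalg.norm(n_pos[k + 1] - c_pos[k]) > CHAIN_BREAK_CN:
            brk[k] = True
    return brk


def _contiguous(brk: np.ndarray, i: int, j: int) -> bool:
    """No chain break between residues i and j (i <= j)."""
    if i > j:
        i, j = j, i
    return not brk[i:j].any()


def _assign_codes(hb: np.ndarray, brk: np.ndarray) -> np.ndarray:
    r = hb.shape[0]
    codes = np.full(r, "", dtype="<U1")
    if r < 3:
        codes[:] = "C"
        return codes

    # n-turns: CO(i) ... HN(i+n)
    turn = {n: np.zeros(r, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(r - n):
            if hb[i + n, i] and _contiguous(brk, i, i + n):
                turn[n][i] = True

    # helices; priority H (4) > G (3) > I (5)
    helix_code = {4: "H", 3: "G", 5: "I"}
    for n in (4, 3, 5):
        for i in range(1, r - n):
            if turn[n][i - 1] and turn[n][i]:
                for k in range(i, i + n):
                    if codes[k] == "":
                        codes[k] = helix_code[n]

    # bridges (Kabsch-Sander patterns); hb[d, a] = NH(d) -> CO(a)
    def par(i: int, j: int) -> bool:
        return (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])

    def anti(i: int, j: int) -> bool:
        return (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])

    bridges: list[tuple[int, int, str]] = []
    for i in range(1, r - 1):
        for j in range(i + 3, r - 1):
            if par(i, j):
                bridges.append((i, j, "P"))
            elif anti(i, j):
                bridges.append((i, j, "A"))

    # merge bridges into ladders; ladders of length >= 2 become E
    bridge_set = set(bridges)
    in_ladder: set[int] = set()
    in_bridge: set[int] = set()
    for (i, j, t) in bridges:
        in_bridge.update((i, j))
        nxt = (i + 1, j + 1, "P") if t == "P" else (i + 1, j - 1, "A")
        if nxt in bridge_set:
            in_ladder.update((i, j, nxt[0], nxt[1]))
    for k in sorted(in_bridge):
        if codes[k] == "":
            codes[k] = "E" if k in in_ladder else "B"

    # turns: interior residues of any n-turn
    for n in (3, 4, 5):
        for i in range(r - n):
            if turn[n][i]:
                for k in range(i + 1, i + n):
                    if codes[k] == "":
                        codes[k] = "T"

    codes[codes == ""] = "C"
    return codes


def assign_dssp_lite(frame: np.ndarray, topology: Topology) -> SSAssignment:
    """Assign secondary-structure codes for one frame."""
    bb = _Backbone(topology)
    residue_ids = [
        (topology.residues[ri].chain_id, topology.residues[ri].residue_seq)
        for ri in bb.res_indices
    ]
    if bb.n == 0:
        return SSAssignment(residue_ids=[], codes=np.empty((1, 0), dtype="<U1"))
    hb = _hbond_matrix(bb, topology, frame)
    brk = _chain_break_mask(bb, frame)
    codes = _assign_codes(hb, brk)
    return SSAssignment(residue_ids=residue_ids, codes=codes[None, :])


def assign_trajectory(traj: Trajectory) -> SSAssignment:
    """Per-frame assignment over a trajectory."""
    bb = _Backbone(traj.topology)
    residue_ids = [
        (traj.topology.residues[ri].chain_id, traj.topology.residues[ri].residue_seq)
        for ri in bb.res_indices
    ]
    all_codes = np.empty((traj.n_frames, bb.n), dtype="<U1")
    for f in range(traj.n_frames):
        hb = _hbond_matrix(bb, traj.topology, traj.frames[f])
        brk = _chain_break_mask(bb, traj.frames[f])
        all_codes[f] = _assign_codes(hb, brk)
    return SSAssignment(residue_ids=residue_ids, codes=all_codes)


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------

def ss_content_series(
    traj: Trajectory, assignment: SSAssignment | None = None
) -> SSContentSeries:
    """Per-frame three-class percentages over all protein residues."""
    if assignment is None:
        assignment = assign_trajectory(traj)
    classes = assignment.classes
    r = classes.shape[1]
    if r == 0:
        raise ValueError("no protein residues with a complete backbone")
    alpha = 100.0 * np.sum(classes == "alpha", axis=1) / r
    beta = 100.0 * np.sum(classes == "beta", axis=1) / r
    coil = 100.0 * np.sum(classes == "coil", axis=1) / r
    return SSContentSeries(times=traj.times, alpha=alpha, beta=beta, coil=coil)


def content_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of the total residue count in each category.

    Accepts any category -> count mapping (e.g. crystal-structure counts)
    and divides by the sum of all counts.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total residue count must be positive")
    return {k: 100.0 * v / total for k, v in counts.items()}


def element_persistence(
    assignment: SSAssignment,
    elements: Sequence[SSElementDefinition],
    min_fraction: float = 0.5,
) -> dict[str, float]:
    """Fraction of frames in which each element holds its class.

    An element "holds" in a frame when at least ``min_fraction`` of its
    residues carry the element's expected three-state class.
    """
    pos = {rid: k for k, rid in enumerate(assignment.residue_ids)}
    classes = assignment.classes
    out: dict[str, float] = {}
    for el in elements:
        cols = [pos[(el.chain, s)] for s in el.residue_seqs() if (el.chain, s) in pos]
        if not cols:
            raise ValueError(f"element {el.name} covers no assigned residues")
        frac_per_frame = np.mean(classes[:, cols] == el.expected_class, axis=1)
        out[el.name] = float(np.mean(frac_per_frame >= min_fraction))
    return out


def ilv_composition(
    sequence: str, classes: Sequence[str]
) -> dict[str, dict[str, float]]:
    """Ile/Leu/Val counts and percentages per three-state class.

    ``sequence`` is the 1-letter sequence; ``classes`` the per-residue
    class labels ("alpha"/"beta"/"coil"), same length.
    """
    if len(sequence) != len(classes):
        raise ValueError("sequence and class assignment lengths differ")
    out: dict[str, dict[str, float]] = {}
    for cls in ("alpha", "beta", "coil"):
        members = [aa for aa, c in zip(sequence, classes) if c == cls]
        total = len(members)
        ilv = sum(1 for aa in members if aa in ILV_LETTERS)
        out[cls] = {
            "ilv_count": ilv,
            "total": total,
            "percent": (100.0 * ilv / total) if total else 0.0,
        }
    return out


def load_ss_elements(protein: str) -> list[SSElementDefinition]:
    """Load the bundled element definitions for a named protein (e.g.
    "TmY", "EcY"); ranges use PDB residue numbering."""
    text = (
        resources.files("thermotraj").joinpath("data/ss_elements.tsv").read_text()
    )
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        prot, name, chain, start, end = line.split("\t")
        if prot.lower() == protein.lower():
            out.append(SSElementDefinition(name, chain, int(start), int(end)))
    return out
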