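"""Structures, trajectories and atom selections.

The reference on-disk dialect is PDB: single structures as plain
ATOM/HETATM records and trajectories as multi-model PDB files
(MODEL/ENDMDL blocks).  Coordinates are stored internally in Å;
reporting layers convert to nm where appropriate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "ReplicaSet",
    "PDBParseError",
    "EmptyStructureError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select",
    "STANDARD_RESIDUES",
    "WATER_RESIDUES",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_RESIDUES = frozenset({"HOH", "SOL", "WAT", "TIP3"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# standard atomic masses, amu
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "ZN": 65.38, "FE": 55.845, "MN": 54.938,
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})
BASIC_SIDECHAIN_N = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
ACIDIC_SIDECHAIN_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


class PDBParseError(ValueError):
    """Raised when a coordinate record cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a file yields no atoms."""


class SelectionError(ValueError):
    """Raised for unknown selector tokens."""


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """A single atom: identity and metadata (coordinates live in frames)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    mass: float
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_RESIDUES

    @property
    def is_protein(self) -> bool:
        return self.residue_name in STANDARD_RESIDUES and not self.is_hetero


@dataclasses.dataclass(frozen=True)
class Residue:
    chain_id: str
    residue_seq: int
    residue_name: str
    atom_start: int  # [start, stop) span into the atom list
    atom_stop: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_seq)


class Topology:
    """Ordered atom list with a derived residue table.

    Atoms belonging to one residue must be contiguous; residues are keyed
    by ``(chain_id, residue_seq)`` which must be unique.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        if not self.atoms:
            raise EmptyStructureError("topology has no atoms")
        residues: list[Residue] = []
        seen: set[tuple[str, int]] = set()
        start = 0
        for i in range(1, len(self.atoms) + 1):
            if i == len(self.atoms) or (
                (self.atoms[i].chain_id, self.atoms[i].residue_seq)
                != (self.atoms[start].chain_id, self.atoms[start].residue_seq)
            ):
                a = self.atoms[start]
                key = (a.chain_id, a.residue_seq)
                if key in seen:
                    raise ValueError(f"residue {key} appears in non-contiguous blocks")
                seen.add(key)
                residues.append(Residue(a.chain_id, a.residue_seq, a.residue_name, start, i))
                start = i
        self.residues: tuple[Residue, ...] = tuple(residues)
        self._residue_index = {r.key: idx for idx, r in enumerate(self.residues)}
        # per-atom residue index
        self.atom_residue = np.empty(len(self.atoms), dtype=np.intp)
        for idx, r in enumerate(self.residues):
            self.atom_residue[r.atom_start: r.atom_stop] = idx

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def residue_index(self, chain_id: str, residue_seq: int) -> int:
        return self._residue_index[(chain_id, residue_seq)]

    def residue_atoms(self, res_index: int, names: Iterable[str] | None = None) -> list[int]:
        r = self.residues[res_index]
        idx = range(r.atom_start, r.atom_stop)
        if names is None:
            return list(idx)
        wanted = set(names)
        return [i for i in idx if self.atoms[i].name in wanted]

    def sequences(self) -> dict[str, str]:
        """Per-chain 1-letter sequence over protein residues."""
        out: dict[str, list[str]] = {}
        for r in self.residues:
            if r.residue_name in STANDARD_RESIDUES:
                out.setdefault(r.chain_id, []).append(THREE_TO_ONE[r.residue_name])
        return {c: "".join(s) for c, s in out.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms

    def __repr__(self) -> str:
        return f"<Topology {self.n_atoms} atoms, {self.n_residues} residues>"


class Trajectory:
    """Frames over a fixed topology.

    frames: (F, N, 3) float array in Å; times: (F,) ps, strictly increasing.
    """

    def __init__(
        self,
        topology: Topology,
        frames: np.ndarray,
        times: np.ndarray | None = None,
        box: np.ndarray | None = None,
    ):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {frames.shape[1]} != topology atom count {topology.n_atoms}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValueError("coordinates must be finite")
        if times is None:
            times = np.arange(frames.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (frames.shape[0],):
            raise ValueError("times length must equal frame count")
        if frames.shape[0] > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        self.topology = topology
        self.frames = frames
        self.times = times
        self.box = box

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __repr__(self) -> str:
        return f"<Trajectory {self.n_frames} frames, {self.n_atoms} atoms>"


@dataclasses.dataclass
class ReplicaSet:
    """Replicated trajectories of one system at one temperature."""

    temperature: float
    replicas: list[Trajectory]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("replica list must be non-empty")
        top0 = self.replicas[0].topology
        for i, t in enumerate(self.replicas[1:], start=2):
            if t.topology != top0:
                raise ValueError(f"replica {i} topology differs from replica 1")

    @property
    def topology(self) -> Topology:
        return self.replicas[0].topology


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if residue_name in WATER_RESIDUES:
        return "O" if name.startswith("O") else "H"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    first = name[0].upper()
    if first in "HCNOSP":
        return first
    if name[:2].upper() in ATOMIC_MASSES:
        return name[:2].upper()
    return first


def _mass_for(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 12.011)


def _parse_coordinate_line(path: Path, lineno: int, line: str) -> tuple:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21] if line[21].strip() else "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"{path}:{lineno}: malformed coordinate record: {line.rstrip()}"
        ) from exc
    element_field = line[76:78].strip() if len(line) >= 78 else ""
    hetero = line[:6] == "HETATM"
    return (serial, name, altloc, resname, chain, resseq,
            np.array([x, y, z]), occupancy, element_field, hetero)


def read_pdb(path: str | Path) -> Trajectory:
    """Parse a (possibly multi-model) PDB file.

    One frame per MODEL block; a file without MODEL records yields a
    single frame.  Alternate locations are resolved to the highest
    occupancy (ties go to the first listed), consistently across models.
    Returns a :class:`Trajectory` whose ``topology`` covers ATOM and
    HETATM records (waters flagged by residue name).
    """
    path = Path(path)
    models: list[list[tuple]] = []
    current: list[tuple] = []
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if saw_model and current:
                    models.append(current)
                    current = []
                saw_model = True
                continue
            if rec in ("ATOM  ", "HETATM"):
                current.append(_parse_coordinate_line(path, lineno, line))
    if current:
        models.append(current)
    if not models:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")

    # resolve altlocs on the first model: winner per site by occupancy
    chosen_altloc: dict[tuple, str] = {}
    best_occ: dict[tuple, float] = {}
    for (serial, name, altloc, resname, chain, resseq,
         pos, occ, element_field, hetero) in models[0]:
        if not altloc:
            continue
        site = (chain, resseq, resname, name)
        if site not in chosen_altloc or occ > best_occ[site]:
            chosen_altloc[site] = altloc
            best_occ[site] = occ

    def keep(rec: tuple) -> bool:
        _, name, altloc, resname, chain, resseq, *_ = rec
        if not altloc:
            return True
        return chosen_altloc.get((chain, resseq, resname, name)) == altloc

    atoms: list[AtomRecord] = []
    for rec in models[0]:
        if not keep(rec):
            continue
        (serial, name, altloc, resname, chain, resseq,
         pos, occ, element_field, hetero) = rec
        element = element_field or _guess_element(name, resname)
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_seq=resseq,
                chain_id=chain,
                mass=_mass_for(element),
                is_hetero=(hetero and resname not in WATER_RESIDUES),
            )
        )
    topology = Topology(atoms)
    n = topology.n_atoms

    frames = []
    for i, model in enumerate(models):
        kept = [rec[6] for rec in model if keep(rec)]
        if len(kept) != n:
            raise PDBParseError(
                f"{path}: MODEL {i + 1} has {len(kept)} atoms, expected {n}"
            )
        frames.append(np.stack(kept))
    return Trajectory(topology, np.stack(frames))


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a (multi-model) PDB file.

    Single-frame trajectories are written without MODEL/ENDMDL records.
    """
    if trajectory.n_frames < 1:  # pragma: no cover - Trajectory forbids this
        raise ValueError("cannot write a trajectory with zero frames")
    if not np.all(np.isfinite(trajectory.frames)):
        raise ValueError("coordinates must be finite")
    top = trajectory.topology
    multi = trajectory.n_frames > 1
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        if multi:
            lines.append(f"MODEL {f + 1:>8d}")
        coords = trajectory.frames[f]
        for i, a in enumerate(top.atoms):
            rec = "HETATM" if (a.is_hetero or a.is_water) else "ATOM  "
            # PDB atom-name column convention: 1-letter elements start in col 14
            if len(a.name) < 4 and len(a.element) == 1:
                name_field = f" {a.name:<3s}"
            else:
                name_field = f"{a.name:<4s}"
            x, y, z = coords[i]
            lines.append(
                f"{rec}{a.serial % 100000:>5d} {name_field} {a.residue_name:>3s} "
                f"{a.chain_id}{a.residue_seq:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_NAMED_SETS = (
    "ca",
    "backbone",
    "heavy",
    "protein",
    "water",
    "basic_sidechain_N",
    "acidic_sidechain_O",
    "all",
)


def _named_set_mask(topology: Topology, token: str) -> np.ndarray:
    atoms = topology.atoms
    if token == "all":
        return np.ones(len(atoms), dtype=bool)
    if token == "ca":
        return np.array([a.is_protein and a.name == "CA" for a in atoms])
    if token == "backbone":
        return np.array([a.is_protein and a.name in BACKBONE_NAMES for a in atoms])
    if token == "heavy":
        return np.array([a.is_protein and a.element != "H" for a in atoms])
    if token == "protein":
        return np.array([a.is_protein for a in atoms])
    if token == "water":
        return np.array([a.is_water for a in atoms])
    if token == "basic_sidechain_N":
        return np.array(
            [a.name in BASIC_SIDECHAIN_N.get(a.residue_name, ()) for a in atoms]
        )
    if token == "acidic_sidechain_O":
        return np.array(
            [a.name in ACIDIC_SIDECHAIN_O.get(a.residue_name, ()) for a in atoms]
        )
    raise SelectionError(
        f"unknown selector token {token!r}; valid named sets: {', '.join(_NAMED_SETS)}"
    )


def select(topology: Topology, selector: str) -> np.ndarray:
    """Resolve a selection expression to sorted atom indices.

    Grammar: ``<named_set> [resid A-B[,C-D,...]]`` where ``named_set`` is one
    of ``ca backbone heavy protein water basic_sidechain_N acidic_sidechain_O
    all``.  The optional ``resid`` clause keeps atoms whose residue_seq falls
    in any listed (inclusive) range; single numbers are allowed.
    """
    tokens = selector.split()
    if not tokens:
        raise SelectionError("empty selector")
    mask = _named_set_mask(topology, tokens[0])
    rest = tokens[1:]
    if rest and rest[0] == "and":
        rest = rest[1:]
    if rest:
        if rest[0] != "resid" or len(rest) != 2:
            raise SelectionError(
                f"unknown selector clause {' '.join(rest)!r}; expected 'resid A-B[,C-D]'"
            )
        ranges = []
        for part in rest[1].split(","):
            if "-" in part[1:]:
                lo, hi = part.rsplit("-", 1) if not part.startswith("-") else (part, part)
                lo_i, hi_i = int(lo), int(hi)
            else:
                lo_i = hi_i = int(part)
            ranges.append((lo_i, hi_i))
        seqs = np.array([a.residue_seq for a in topology.atoms])
        resid_mask = np.zeros(topology.n_atoms, dtype=bool)
        for lo_i, hi_i in ranges:
            resid_mask |= (seqs >= lo_i) & (seqs <= hi_i)
        mask &= resid_mask
    return np.flatnonzero(mask)
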