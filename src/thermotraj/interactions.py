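"""Hydrogen bonds and salt bridges.

Hydrogen bonds use a geometric criterion: donor-acceptor distance
<= r_max and the angle at the donor between D->H and D->A <= theta_max
(a flag switches to the at-hydrogen convention, 180 deg - angle(D-H-A)).
Salt bridges are residue-level contacts between basic side-chain
nitrogens (Lys NZ; Arg NE/NH1/NH2) and acidic side-chain oxygens
(Asp OD1/OD2; Glu OE1/OE2) within r_max; per-replica presence fractions
are averaged arithmetically across replicas.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io_structures import (
    ACIDIC_SIDECHAIN_O,
    BASIC_SIDECHAIN_N,
    ReplicaSet,
    Topology,
    Trajectory,
)

__all__ = [
    "HBondCriteria",
    "HBondCount",
    "SaltBridgeObservation",
    "StabilityClass",
    "SaltBridgeNetwork",
    "ResidueRef",
    "find_donors",
    "find_acceptors",
    "detect_hbonds_frame",
    "hbond_series",
    "detect_salt_bridges_frame",
    "salt_bridge_frequencies",
    "classify_stability",
    "formed_pairs",
    "build_networks",
    "classify_locality",
    "detect_nonnative_bridges",
]

H_COVALENT_CUTOFF = 1.25  # Å: H within this distance of N/O is treated as bonded


@dataclasses.dataclass(frozen=True)
class HBondCriteria:
    r_max: float = 3.5  # Å, donor-acceptor
    theta_max: float = 30.0  # degrees
    angle_at_hydrogen: bool = False

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not (0 < self.theta_max < 90):
            raise ValueError("theta_max must lie in (0, 90) degrees")


@dataclasses.dataclass
class HBondCount:
    mode: str  # "pp" or "ps"
    counts: np.ndarray  # per-frame integers
    times: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclasses.dataclass(frozen=True, order=True)
class ResidueRef:
    """Identifies a residue by chain, sequence number and 3-letter name."""

    chain: str
    seq: int
    name: str

    def __str__(self) -> str:
        return f"{self.name}{self.seq}"


class StabilityClass(enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"
    NEGLIGIBLE = "negligible"


@dataclasses.dataclass
class SaltBridgeObservation:
    """Per-pair presence statistics across replicas."""

    basic_residue: ResidueRef
    acidic_residue: ResidueRef
    r_max: float
    presence: list[np.ndarray]  # per replica, per-frame booleans
    f_per_replica: np.ndarray
    f_mean: float

    @property
    def pair(self) -> tuple[ResidueRef, ResidueRef]:
        return (self.basic_residue, self.acidic_residue)

    @property
    def stability(self) -> StabilityClass:
        return classify_stability(self.f_mean)


@dataclasses.dataclass
class SaltBridgeNetwork:
    members: frozenset[ResidueRef]
    edges: tuple[tuple[ResidueRef, ResidueRef], ...]

    @property
    def motif(self) -> str:
        n = len(self.members)
        return {2: "dyad", 3: "triad", 4: "tetrad"}.get(n, "extended network")


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def find_donors(
    topology: Topology, frame: np.ndarray, candidates: Iterable[int] | None = None
) -> list[tuple[int, int]]:
    """(heavy, hydrogen) donor pairs: N/O atoms with a covalently bound H.

    Attachment is decided geometrically (H within 1.25 Å in ``frame``).
    """
    atoms = topology.atoms
    if candidates is None:
        candidates = [i for i, a in enumerate(atoms) if a.element in ("N", "O")]
    h_idx = np.array([i for i, a in enumerate(atoms) if a.element == "H"], dtype=np.intp)
    pairs: list[tuple[int, int]] = []
    if len(h_idx) == 0:
        return pairs
    h_pos = frame[h_idx]
    for d in candidates:
        dist = np.sqrt(np.sum((h_pos - frame[d]) ** 2, axis=1))
        for h in h_idx[dist <= H_COVALENT_CUTOFF]:
            pairs.append((int(d), int(h)))
    return pairs


def find_acceptors(topology: Topology, candidates: Iterable[int] | None = None) -> list[int]:
    """Acceptor candidates: all N/O atoms."""
    if candidates is not None:
        return [i for i in candidates if topology.atoms[i].element in ("N", "O")]
    return [i for i, a in enumerate(topology.atoms) if a.element in ("N", "O")]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds_frame(
    frame: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    donor_pairs: Sequence[tuple[int, int]] | None = None,
    acceptor_indices: Sequence[int] | None = None,
    exclude_same_residue: bool = True,
) -> list[tuple[int, int, int]]:
    """Detect hydrogen bonds in one frame.

    Returns (donor, hydrogen, acceptor) atom-index triples satisfying
    d(D, A) <= r_max and the angular criterion.  Donors without an
    attached hydrogen are skipped with a warning.  Same-residue
    donor/acceptor pairs are excluded by default.
    """
    if donor_pairs is None:
        donor_pairs = find_donors(topology, frame)
    if acceptor_indices is None:
        acceptor_indices = find_acceptors(topology)
    acceptor_indices = np.asarray(list(acceptor_indices), dtype=np.intp)
    if len(acceptor_indices) == 0:
        return []
    res_of = topology.atom_residue
    acc_pos = frame[acceptor_indices]
    bonds: list[tuple[int, int, int]] = []
    for d, h in donor_pairs:
        if h < 0:
            warnings.warn(f"donor atom {d} has no attached hydrogen; skipped")
            continue
        dvec = acc_pos - frame[d]
        dist = np.sqrt(np.sum(dvec**2, axis=1))
        near = np.flatnonzero(dist <= criteria.r_max)
        for k in near:
            a = int(acceptor_indices[k])
            if a == d or a == h:
                continue
            if exclude_same_residue and res_of[a] == res_of[d]:
                continue
            if criteria.angle_at_hydrogen:
                theta = 180.0 - _angle_deg(frame[d] - frame[h], frame[a] - frame[h])
            else:
                theta = _angle_deg(frame[h] - frame[d], frame[a] - frame[d])
            if theta <= criteria.theta_max:
                bonds.append((d, h, a))
    return bonds


def hbond_series(
    traj: Trajectory,
    mode: str = "pp",
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondCount:
    """Per-frame hydrogen-bond counts.

    mode "pp": both donor heavy atom and acceptor belong to the protein.
    mode "ps": one side protein, the other water (either direction).
    """
    if mode not in ("pp", "ps"):
        raise ValueError("mode must be 'pp' or 'ps'")
    top = traj.topology
    is_protein = np.array([a.is_protein for a in top.atoms])
    is_water = np.array([a.is_water for a in top.atoms])
    if mode == "ps" and not is_water.any():
        raise ValueError("mode 'ps' requires water in the topology")

    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        donors = find_donors(top, frame)
        acceptors = find_acceptors(top)
        bonds = detect_hbonds_frame(frame, top, criteria, donors, acceptors)
        n = 0
        for d, h, a in bonds:
            if mode == "pp":
                if is_protein[d] and is_protein[a]:
                    n += 1
            else:
                if (is_protein[d] and is_water[a]) or (is_water[d] and is_protein[a]):
                    n += 1
        counts[f] = n
    return HBondCount(mode=mode, counts=counts, times=traj.times)


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

def _charged_atom_table(topology: Topology):
    """Map residue index -> atom indices of charged side-chain termini."""
    basic: dict[int, list[int]] = {}
    acidic: dict[int, list[int]] = {}
    for ri, res in enumerate(topology.residues):
        if res.residue_name in BASIC_SIDECHAIN_N:
            idx = topology.residue_atoms(ri, BASIC_SIDECHAIN_N[res.residue_name])
            if idx:
                basic[ri] = idx
        elif res.residue_name in ACIDIC_SIDECHAIN_O:
            idx = topology.residue_atoms(ri, ACIDIC_SIDECHAIN_O[res.residue_name])
            if idx:
                acidic[ri] = idx
    return basic, acidic


def _residue_ref(topology: Topology, res_index: int) -> ResidueRef:
    r = topology.residues[res_index]
    return ResidueRef(r.chain_id, r.residue_seq, r.residue_name)


def detect_salt_bridges_frame(
    frame: np.ndarray,
    topology: Topology,
    r_max: float = 4.0,
) -> set[tuple[ResidueRef, ResidueRef]]:
    """Residue pairs whose minimum basic-N/acidic-O distance is <= r_max."""
    basic, acidic = _charged_atom_table(topology)
    present: set[tuple[ResidueRef, ResidueRef]] = set()
    for bi, b_atoms in basic.items():
        b_pos = frame[b_atoms]
        for ai, a_atoms in acidic.items():
            a_pos = frame[a_atoms]
            d = np.sqrt(
                np.sum((b_pos[:, None, :] - a_pos[None, :, :]) ** 2, axis=2)
            )
            if d.min() <= r_max:
                present.add((_residue_ref(topology, bi), _residue_ref(topology, ai)))
    return present


def salt_bridge_frequencies(
    replica_set: ReplicaSet,
    r_max: float = 4.0,
) -> list[SaltBridgeObservation]:
    """Presence fraction of every observed basic-acidic pair, per replica
    and averaged over replicas.

    A pair enters the output if it is present in at least one frame of
    any replica; pairs never within ``r_max`` are omitted.
    """
    top = replica_set.topology
    basic, acidic = _charged_atom_table(top)
    pair_keys = [(bi, ai) for bi in sorted(basic) for ai in sorted(acidic)]
    if not pair_keys:
        return []
    presence: dict[tuple[int, int], list[np.ndarray]] = {k: [] for k in pair_keys}
    for traj in replica_set.replicas:
        flags = {k: np.zeros(traj.n_frames, dtype=bool) for k in pair_keys}
        for f in range(traj.n_frames):
            frame = traj.frames[f]
            for (bi, ai) in pair_keys:
                b_pos = frame[basic[bi]]
                a_pos = frame[acidic[ai]]
                d = np.sqrt(
                    np.sum((b_pos[:, None, :] - a_pos[None, :, :]) ** 2, axis=2)
                )
                flags[(bi, ai)][f] = d.min() <= r_max
        for k in pair_keys:
            presence[k].append(flags[k])

    out: list[SaltBridgeObservation] = []
    for (bi, ai) in pair_keys:
        per_rep = presence[(bi, ai)]
        if not any(p.any() for p in per_rep):
            continue
        f_rep = np.array([p.mean() for p in per_rep])
        out.append(
            SaltBridgeObservation(
                basic_residue=_residue_ref(top, bi),
                acidic_residue=_residue_ref(top, ai),
                r_max=r_max,
                presence=per_rep,
                f_per_replica=f_rep,
                f_mean=float(f_rep.mean()),
            )
        )
    return out


def classify_stability(f_mean: float) -> StabilityClass:
    """Map a mean presence fraction to a stability class.

    high: f >= 0.75; moderate: 0.50 <= f < 0.75; low: 0.30 <= f < 0.50;
    negligible: f < 0.30.  Boundaries are inclusive on the lower edge.
    """
    if not (0.0 <= f_mean <= 1.0):
        raise ValueError(f"frequency {f_mean} outside [0, 1]")
    if f_mean >= 0.75:
        return StabilityClass.HIGH
    if f_mean >= 0.50:
        return StabilityClass.MODERATE
    if f_mean >= 0.30:
        return StabilityClass.LOW
    return StabilityClass.NEGLIGIBLE


def formed_pairs(
    observations: Sequence[SaltBridgeObservation],
    threshold: float = 0.30,
) -> list[SaltBridgeObservation]:
    """Observations whose replica-mean frequency meets the formation
    threshold, ordered by descending f_mean (ties by residue numbering).

    The threshold applies to the replica mean only; individual replicas
    below it never disqualify a pair.
    """
    kept = [o for o in observations if o.f_mean >= threshold]
    kept.sort(key=lambda o: (-o.f_mean, o.basic_residue.seq, o.acidic_residue.seq))
    return kept


def build_networks(
    pairs: Sequence[SaltBridgeObservation] | Sequence[tuple[ResidueRef, ResidueRef]],
) -> list[SaltBridgeNetwork]:
    """Connected components of the formed-pair residue graph."""
    g: nx.Graph = nx.Graph()
    for p in pairs:
        if isinstance(p, SaltBridgeObservation):
            u, v = p.basic_residue, p.acidic_residue
        else:
            u, v = p
        g.add_edge(u, v)
    nets = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nets.append(
            SaltBridgeNetwork(
                members=frozenset(comp),
                edges=tuple(sorted(tuple(sorted(e)) for e in sub.edges)),
            )
        )
    nets.sort(key=lambda n: (-len(n.members), min(n.members)))
    return nets


def classify_locality(
    pair: tuple[ResidueRef, ResidueRef],
    ss_element_map: dict[tuple[str, int], str],
) -> str:
    """"intra" if both residues sit in the same named secondary-structure
    element, "inter" if in different ones, "unassigned" if either residue
    is unmapped."""
    a = ss_element_map.get((pair[0].chain, pair[0].seq))
    b = ss_element_map.get((pair[1].chain, pair[1].seq))
    if a is None or b is None:
        return "unassigned"
    return "intra" if a == b else "inter"


def detect_nonnative_bridges(
    observations_by_temperature: dict[float, Sequence[SaltBridgeObservation]],
    reference_temperature: float,
    threshold: float = 0.30,
) -> list[dict]:
    """Pairs below the formation threshold at the reference temperature
    that reach it at one or more higher temperatures.

    Returns one record per emerging pair with the temperatures (and
    frequencies) at which it is formed.
    """
    if reference_temperature not in observations_by_temperature:
        raise ValueError(f"reference temperature {reference_temperature} not present")
    ref_f: dict[tuple[ResidueRef, ResidueRef], float] = {
        o.pair: o.f_mean for o in observations_by_temperature[reference_temperature]
    }
    emerged: dict[tuple[ResidueRef, ResidueRef], list[tuple[float, float]]] = {}
    for temp in sorted(observations_by_temperature):
        if temp <= reference_temperature:
            continue
        for o in observations_by_temperature[temp]:
            if o.f_mean >= threshold and ref_f.get(o.pair, 0.0) < threshold:
                emerged.setdefault(o.pair, []).append((temp, o.f_mean))
    return [
        {
            "pair": pair,
            "reference_frequency": ref_f.get(pair, 0.0),
            "formed_at": formed,
        }
        for pair, formed in sorted(
            emerged.items(), key=lambda kv: (kv[0][0].seq, kv[0][1].seq)
        )
    ]
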