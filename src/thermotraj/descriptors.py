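"""Global structural descriptors: superposition/RMSD, Rg, RMSF and the
smooth-switching fraction of native contacts.

All coordinates are Å internally; RMSD/Rg/RMSF series are reported in nm,
the fraction of native contacts is dimensionless.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .io_structures import Topology, Trajectory, select

__all__ = [
    "SuperpositionResult",
    "DescriptorSeries",
    "RMSFProfile",
    "NativeContactSet",
    "kabsch",
    "rmsd_series",
    "radius_of_gyration_series",
    "rmsf_profile",
    "native_contacts",
    "q_series",
]

ANGSTROM_PER_NM = 10.0


class DegenerateGeometryError(ValueError):
    """Raised when superposition is attempted on collinear points."""


@dataclasses.dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition of a mobile onto a reference point set."""

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # Å
    rmsd: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclasses.dataclass
class DescriptorSeries:
    """Per-frame scalar descriptor (RMSD, Rg or Q)."""

    name: str
    values: np.ndarray
    times: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class RMSFProfile:
    """Per-residue root-mean-square fluctuation, nm."""

    residue_ids: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_ids) != len(self.values):
            raise ValueError("one value per residue required")


@dataclasses.dataclass
class NativeContactSet:
    """Reference contact pairs with smooth-switching parameters.

    ``beta`` (Å^-1) and ``lam`` parameterize the per-pair sigmoid
    1 / (1 + exp(beta * (r - lam * r0))).
    """

    pairs: np.ndarray  # (P, 2) atom indices, i < j
    r0: np.ndarray  # (P,) Å
    beta: float = 5.0
    lam: float = 1.8
    cutoff: float = 4.5
    min_seq_sep: int = 3

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted optimal rigid-body superposition (proper rotation only).

    Returns rotation R and translation t such that ``mobile @ R.T + t``
    minimizes the weighted RMSD to ``reference``.  A reflection solution
    (det = -1) is corrected by flipping the sign of the singular vector
    belonging to the smallest singular value.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("at least 3 points required")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = weights / weights.sum()

    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference

    # collinearity check on the weighted point cloud
    cov_m = (mob_c * w[:, None]).T @ mob_c
    if np.linalg.matrix_rank(cov_m, tol=1e-10) < 2:
        raise DegenerateGeometryError("all points are collinear; rotation is not unique")

    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = (w @ reference) - rotation @ (w @ mobile)
    diff = mob_c @ rotation.T - ref_c
    rmsd = float(np.sqrt(np.sum(w * np.sum(diff**2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _resolve_selection(topology: Topology, selection) -> np.ndarray:
    if isinstance(selection, str):
        idx = select(topology, selection)
    else:
        idx = np.asarray(selection, dtype=np.intp)
    if len(idx) == 0:
        raise ValueError("selection is empty")
    return idx


def rmsd_series(
    traj: Trajectory,
    selection="ca",
    ref_frame_index: int = 0,
) -> DescriptorSeries:
    """Per-frame RMSD (nm) to a reference frame after optimal superposition."""
    idx = _resolve_selection(traj.topology, selection)
    if not (0 <= ref_frame_index < traj.n_frames):
        raise IndexError(f"reference frame {ref_frame_index} out of range")
    ref = traj.frames[ref_frame_index][idx]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if f == ref_frame_index:
            values[f] = 0.0
            continue
        values[f] = kabsch(traj.frames[f][idx], ref).rmsd
    return DescriptorSeries("RMSD", values / ANGSTROM_PER_NM, traj.times, "nm")


def radius_of_gyration_series(
    traj: Trajectory,
    selection="protein",
    mass_weighted: bool = True,
) -> DescriptorSeries:
    """Per-frame radius of gyration (nm) of the selected atoms."""
    idx = _resolve_selection(traj.topology, selection)
    masses = traj.topology.masses[idx] if mass_weighted else np.ones(len(idx))
    w = masses / masses.sum()
    coords = traj.frames[:, idx, :]
    com = np.einsum("i,fij->fj", w, coords)
    sq = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(np.einsum("i,fi->f", w, sq))
    return DescriptorSeries("Rg", rg / ANGSTROM_PER_NM, traj.times, "nm")


def rmsf_profile(
    traj: Trajectory,
    selection="ca",
    ref_frame_index: int = 0,
) -> RMSFProfile:
    """Per-residue RMSF (nm) about the time-averaged position.

    Every frame is first superposed to the reference frame on the
    selection; fluctuations are then measured about the per-atom mean
    over frames, averaged (as mean-square) over the selected atoms of
    each residue.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for a single-frame trajectory")
    idx = _resolve_selection(traj.topology, selection)
    ref = traj.frames[ref_frame_index][idx]
    aligned = np.empty((traj.n_frames, len(idx), 3))
    for f in range(traj.n_frames):
        sup = kabsch(traj.frames[f][idx], ref)
        aligned[f] = sup.apply(traj.frames[f][idx])
    mean_pos = aligned.mean(axis=0)
    msf_atom = np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0)

    res_of = traj.topology.atom_residue[idx]
    residue_ids: list[tuple[str, int]] = []
    values: list[float] = []
    for r in np.unique(res_of):
        res = traj.topology.residues[r]
        residue_ids.append((res.chain_id, res.residue_seq))
        values.append(float(np.sqrt(msf_atom[res_of == r].mean())))
    return RMSFProfile(residue_ids, np.array(values) / ANGSTROM_PER_NM)


def native_contacts(
    traj_or_frame,
    topology: Topology | None = None,
    ref_frame_index: int = 0,
    cutoff: float = 4.5,
    min_seq_sep: int = 3,
    selection: str = "heavy",
) -> NativeContactSet:
    """Build the native contact set from a reference conformation.

    Pairs of selected heavy atoms whose residues are separated by more
    than ``min_seq_sep`` positions and whose reference distance is at
    most ``cutoff`` Å.
    """
    if isinstance(traj_or_frame, Trajectory):
        topology = traj_or_frame.topology
        frame = traj_or_frame.frames[ref_frame_index]
    else:
        frame = np.asarray(traj_or_frame, dtype=float)
        if topology is None:
            raise ValueError("topology required when passing a raw frame")
    idx = _resolve_selection(topology, selection)
    coords = frame[idx]
    res_of = topology.atom_residue[idx]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    sep = np.abs(res_of[:, None] - res_of[None, :])
    ii, jj = np.where(np.triu(sep > min_seq_sep) & (dist <= cutoff))
    pairs = np.stack([idx[ii], idx[jj]], axis=1)
    r0 = dist[ii, jj]
    return NativeContactSet(
        pairs=pairs, r0=r0, cutoff=cutoff, min_seq_sep=min_seq_sep
    )


def q_series(
    traj: Trajectory,
    contacts: NativeContactSet,
    normalize: bool = False,
    ref_frame_index: int = 0,
) -> DescriptorSeries:
    """Per-frame fraction of native contacts.

    Q(frame) = mean over pairs of 1 / (1 + exp(beta * (r - lam * r0))).
    With ``normalize=True`` values are divided by Q at the reference
    frame (the raw value at the native conformation sits slightly
    below 1 because the switching function is smooth).
    """
    if contacts.n_pairs == 0:
        raise ValueError("contact set is empty")
    i = contacts.pairs[:, 0]
    j = contacts.pairs[:, 1]
    d = traj.frames[:, i, :] - traj.frames[:, j, :]
    r = np.sqrt(np.sum(d**2, axis=2))  # (F, P)
    expo = np.clip(contacts.beta * (r - contacts.lam * contacts.r0), -700.0, 700.0)
    q = np.mean(1.0 / (1.0 + np.exp(expo)), axis=1)
    if normalize:
        qref = q[ref_frame_index]
        if qref <= 0:
            warnings.warn("reference Q is zero; normalization skipped")
        else:
            q = q / qref
    return DescriptorSeries("Q", q, traj.times, "dimensionless")
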