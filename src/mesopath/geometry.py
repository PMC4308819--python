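"""Superposition and RMSD machinery for conformational trajectories.

The binding analyses in this package monitor ligand geometry relative to a
reference (crystal-like) pose: frames are first superposed on an *alignment*
atom set (typically backbone atoms of the binding site) and the deviation is
then measured on a *measurement* set (typically the ligand heavy atoms).
This module provides the Kabsch least-squares superposition, selection-aware
RMSD, all-pairs RMSD matrices (the clustering metric), the RMSD-vs-reference
time series and the final-ensemble classifier.

Coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Frame",
    "Trajectory",
    "SelectionPair",
    "DistanceMatrix",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "rmsd",
    "pairwise_rmsd_matrix",
    "rmsd_to_reference_series",
    "classify_binding_ensemble",
    "ENSEMBLE_THRESHOLDS",
]


class DegenerateGeometryError(ValueError):
    """Raised when an alignment set is collinear or otherwise degenerate."""


@dataclass
class Frame:
    """A single conformation: atom coordinates plus light-weight metadata.

    Parameters
    ----------
    coords : (n_atoms, 3) float array, Angstrom.
    atom_names, residue_names, chain_ids : per-atom labels (optional).
    residue_ids : per-atom integer residue numbers (optional).
    elements : per-atom element symbols; used for heavy-atom selection.
    """

    coords: np.ndarray
    atom_names: list[str] | None = None
    residue_names: list[str] | None = None
    residue_ids: np.ndarray | None = None
    chain_ids: list[str] | None = None
    elements: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n_atoms, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def heavy_atom_indices(self) -> np.ndarray:
        """Indices of non-hydrogen atoms (requires element metadata)."""
        if self.elements is None:
            raise ValueError("frame carries no element metadata")
        return np.array(
            [i for i, e in enumerate(self.elements) if e.strip().upper() not in ("H", "D")],
            dtype=int,
        )

    def with_coords(self, coords: np.ndarray) -> "Frame":
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology.

    ``coords`` has shape (n_frames, n_atoms, 3); metadata is shared across
    frames (atom identity does not change along a trajectory).
    """

    coords: np.ndarray
    atom_names: list[str] | None = None
    residue_names: list[str] | None = None
    residue_ids: np.ndarray | None = None
    chain_ids: list[str] | None = None
    elements: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(
            coords=self.coords[i],
            atom_names=self.atom_names,
            residue_names=self.residue_names,
            residue_ids=self.residue_ids,
            chain_ids=self.chain_ids,
            elements=self.elements,
        )

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


@dataclass
class SelectionPair:
    """Alignment and measurement atom selections.

    ``align_set`` drives the superposition (e.g. backbone binding-site
    atoms); ``measure_set`` is where the deviation is measured (e.g. ligand
    heavy atoms). Both are integer index arrays into the frame's atoms.
    """

    align_set: np.ndarray
    measure_set: np.ndarray

    def __post_init__(self) -> None:
        self.align_set = np.asarray(self.align_set, dtype=int)
        self.measure_set = np.asarray(self.measure_set, dtype=int)
        if self.align_set.size < 3:
            raise ValueError("align_set needs at least 3 atoms")
        if self.measure_set.size < 1:
            raise ValueError("measure_set must not be empty")

    def validate(self, n_atoms: int) -> None:
        for name, sel in (("align_set", self.align_set), ("measure_set", self.measure_set)):
            if sel.min() < 0 or sel.max() >= n_atoms:
                raise ValueError(f"{name} indexes outside [0, {n_atoms})")


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs frame dissimilarities with metric provenance."""

    values: np.ndarray
    metric: str = "RMSD"  # "RMSD" (Angstrom) or "MSD" (Angstrom^2)
    selection: SelectionPair | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        D = self.values
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(D < 0):
            raise ValueError("distances must be non-negative")
        if np.max(np.abs(np.diagonal(D))) > 1e-10:
            raise ValueError("distance matrix diagonal must be zero")
        if np.max(np.abs(D - D.T)) > 1e-10:
            raise ValueError("distance matrix must be symmetric")
        # symmetrize exactly so downstream arithmetic is order-free
        self.values = 0.5 * (D + D.T)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_align_nondegenerate(centered: np.ndarray) -> None:
    # collinear (or coincident) alignment atoms leave the rotation
    # undetermined about the common axis
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size < 2 or s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("alignment atoms are collinear or coincident")


def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||P @ R.T - Q|| for centered P, Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _batched_kabsch_rotations(H: np.ndarray) -> np.ndarray:
    """Proper rotations for a stack of 3x3 cross-covariance matrices."""
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nij,nkj->nik", Vt, U, optimize=False))
    V = np.swapaxes(Vt, 1, 2)
    V = V.copy()
    V[:, :, 2] *= np.sign(det)[:, None]
    return np.einsum("nij,nkj->nik", V, U)


def kabsch_superpose(
    mobile: Frame, target: Frame, align_set: np.ndarray
) -> tuple[np.ndarray, np.ndarray, Frame]:
    """Least-squares superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, aligned)`` where
    ``aligned.coords = mobile.coords @ rotation.T + translation`` minimizes
    the RMSD over ``align_set`` and ``rotation`` is proper (det = +1).
    """
    align_set = np.asarray(align_set, dtype=int)
    if align_set.size < 3:
        raise ValueError("align_set needs at least 3 atoms")
    if align_set.max() >= mobile.n_atoms or align_set.max() >= target.n_atoms:
        raise ValueError("align_set indexes outside frame bounds")
    P = mobile.coords[align_set]
    Q = target.coords[align_set]
    if P.shape != Q.shape:
        raise ValueError("alignment sets differ in atom count")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    _check_align_nondegenerate(Pc)
    R = _kabsch_rotation(Pc, Qc)
    t = cq - cp @ R.T
    aligned = mobile.with_coords(mobile.coords @ R.T + t)
    return R, t, aligned


def rmsd(a: Frame, b: Frame, selection: SelectionPair) -> float:
    """RMSD over ``measure_set`` after superposing on ``align_set`` (Angstrom)."""
    selection.validate(min(a.n_atoms, b.n_atoms))
    _, _, a_on_b = kabsch_superpose(a, b, selection.align_set)
    diff = a_on_b.coords[selection.measure_set] - b.coords[selection.measure_set]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def _centered_selections(
    coords: np.ndarray, selection: SelectionPair
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame align/measure coordinates relative to the align centroid."""
    A = coords[:, selection.align_set, :]
    centroids = A.mean(axis=1, keepdims=True)
    return A - centroids, coords[:, selection.measure_set, :] - centroids


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: SelectionPair, metric: str = "RMSD"
) -> DistanceMatrix:
    """All-pairs frame dissimilarity under the align/measure protocol.

    Every unordered frame pair is superposed on ``align_set`` and the RMSD
    (or MSD, Angstrom^2) over ``measure_set`` is recorded, so that no frame
    is privileged as a common reference. Vectorized row-wise with batched
    3x3 SVDs; O(n^2) pairs overall.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if metric not in ("RMSD", "MSD"):
        raise ValueError(f"unknown metric {metric!r}")
    selection.validate(traj.n_atoms)
    A, M = _centered_selections(traj.coords, selection)
    for i in range(traj.n_frames):
        _check_align_nondegenerate(A[i])
    n = traj.n_frames
    D = np.zeros((n, n))
    for i in range(n - 1):
        # rotate frame i onto every later frame j: H_j = A_i^T A_j
        H = np.einsum("ak,jal->jkl", A[i], A[i + 1 :], optimize=True)
        R = _batched_kabsch_rotations(H)
        moved = np.einsum("jkl,al->jak", R, M[i], optimize=True)
        diff = moved - M[i + 1 :]
        msd = np.mean(np.sum(diff * diff, axis=2), axis=1)
        row = msd if metric == "MSD" else np.sqrt(msd)
        D[i, i + 1 :] = row
        D[i + 1 :, i] = row
    return DistanceMatrix(values=D, metric=metric, selection=selection)


def rmsd_to_reference_series(
    traj: Trajectory, reference: Frame, selection: SelectionPair
) -> np.ndarray:
    """Per-frame RMSD to a reference pose, in frame order (Angstrom)."""
    selection.validate(min(traj.n_atoms, reference.n_atoms))
    A, M = _centered_selections(traj.coords, selection)
    Aref, Mref = _centered_selections(reference.coords[None, :, :], selection)
    _check_align_nondegenerate(Aref[0])
    H = np.einsum("jak,al->jkl", A, Aref[0], optimize=True)
    R = _batched_kabsch_rotations(H)
    moved = np.einsum("jkl,jal->jak", R, M, optimize=True)
    diff = moved - Mref[0]
    return np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))


#: Ligand-RMSD class boundaries (Angstrom): A < 1.25 <= intermediate < 2
#: <= B < 3 <= C < 4 <= unbound.
ENSEMBLE_THRESHOLDS = (1.25, 2.0, 3.0, 4.0)


def classify_binding_ensemble(series: np.ndarray, tail_fraction: float = 0.1) -> str:
    """Classify a run's final state from its ligand-RMSD time series.

    The mean over the final ``tail_fraction`` of the series is mapped to
    ``"A"`` (crystal-like, < 1.25 A), ``"B"`` (2-3 A), ``"C"`` (3-4 A),
    ``"unbound"`` (>= 4 A) or ``"intermediate"`` (the unlabelled 1.25-2 A
    gap).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if np.any(series < 0):
        raise ValueError("RMSD series must be non-negative")
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    n_tail = max(1, int(np.ceil(tail_fraction * series.size)))
    m = float(series[-n_tail:].mean())
    a, gap, b, c = ENSEMBLE_THRESHOLDS
    if m < a:
        return "A"
    if m < gap:
        return "intermediate"
    if m < b:
        return "B"
    if m < c:
        return "C"
    return "unbound"
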