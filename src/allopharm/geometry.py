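"""Trajectory geometry metrics: superposition RMSD, RMSF, distances and
side-chain dihedral angles.

Conventions: coordinates are in angstroms throughout; dihedrals follow the
standard signed atan2 torsion convention and are reported in degrees in
(-180, 180]. For a tryptophan chi2 angle the atom quadruple is
CA-CB-CG-CD1. Superposition uses the Kabsch algorithm (proper rotations
only; the reflection branch is corrected), allowing a ligand-RMSD-after-
receptor-fit by separating the fitting and measuring selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


from .exceptions import DegenerateGeometryError, DomainError, ShapeError

__all__ = [
    "Trajectory",
    "AtomSelection",
    "superpose_kabsch",
    "rmsd_series",
    "rmsf",
    "dihedral_series",
    "distance_series",
    "read_xyz",
    "write_xyz",
    "read_traj_csv",
    "write_traj_csv",
]


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (frames x atoms x 3, angstrom)."""

    coords: np.ndarray
    atom_labels: list = field(default_factory=list)
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ShapeError("coords must be (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ShapeError("need at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise DomainError("coordinates must be finite")
        if not self.atom_labels:
            self.atom_labels = [f"A{i}" for i in range(self.coords.shape[1])]
        if len(self.atom_labels) != self.coords.shape[1]:
            raise ShapeError("one label per atom required")
        if len(set(self.atom_labels)) != len(self.atom_labels):
            raise ShapeError("atom labels must be unique")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class AtomSelection:
    """Validated atom indices with a role tag (fit set vs measure set)."""

    indices: tuple
    role: str = "measure"

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise DomainError("selection indices must be unique")
        if any(i < 0 for i in idx):
            raise DomainError("selection indices must be >= 0")
        object.__setattr__(self, "indices", idx)


def _indices(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        idx = np.arange(n_atoms)
    elif isinstance(selection, AtomSelection):
        idx = np.asarray(selection.indices, dtype=int)
    else:
        idx = np.asarray(list(selection), dtype=int)
    if idx.size == 0:
        raise DomainError("empty selection")
    if idx.max() >= n_atoms:
        raise DomainError("selection index out of range")
    return idx


def superpose_kabsch(reference: np.ndarray, mobile: np.ndarray,
                     selection=None) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD over the
    selection. The rotation is proper (det = +1).
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if reference.shape != mobile.shape or reference.ndim != 2:
        raise ShapeError("reference and mobile must be equal (atoms, 3) arrays")
    idx = _indices(selection, reference.shape[0])
    a = reference[idx]
    b = mobile[idx]
    if a.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 selected atoms")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if (np.linalg.matrix_rank(ac, tol=1e-9) < 2
            or np.linalg.matrix_rank(bc, tol=1e-9) < 2):
        raise DegenerateGeometryError("selected atoms are collinear")
    # Kabsch: SVD of the covariance, reflection branch corrected by a sign
    # flip on the smallest singular direction
    H = bc.T @ ac
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = a.mean(axis=0) - R @ b.mean(axis=0)
    moved = bc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ac) ** 2, axis=1))))
    return R, t, rmsd


def _raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                fit_selection=None, measure_selection=None,
                fit: bool = True) -> np.ndarray:
    """Per-frame RMSD over ``measure_selection`` after superposing each
    frame on ``reference`` over ``fit_selection`` (``fit=False`` skips the
    superposition and reports the raw RMSD)."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != traj.coords.shape[1:]:
        raise ShapeError("reference frame must match trajectory atoms")
    m_idx = _indices(measure_selection, traj.n_atoms)
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        if fit:
            R, t, _ = superpose_kabsch(reference, frame, fit_selection)
            moved = frame @ R.T + t
        else:
            moved = frame
        out[i] = _raw_rmsd(moved[m_idx], reference[m_idx])
    return out


def rmsf(traj: Trajectory, selection=None, fit_selection=None,
         n_iterations: int = 2) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    Frames are aligned to the running mean structure (iterated
    ``n_iterations`` times) over ``fit_selection`` (default: all atoms);
    fluctuations are then reported for ``selection``.
    """
    if traj.n_frames < 2:
        raise DegenerateGeometryError("RMSF is undefined for a single frame")
    idx = _indices(selection, traj.n_atoms)
    frames = traj.coords.copy()
    mean = frames.mean(axis=0)
    for _ in range(max(1, n_iterations)):
        for i in range(frames.shape[0]):
            R, t, _ = superpose_kabsch(mean, frames[i], fit_selection)
            frames[i] = frames[i] @ R.T + t
        mean = frames.mean(axis=0)
    dev = frames[:, idx, :] - mean[idx]
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


def _dihedral(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if (np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10
            or nb2 < 1e-10):
        raise DegenerateGeometryError(
            "dihedral undefined for collinear atoms or zero-length bonds")
    m1 = np.cross(n1, b2 / nb2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def dihedral_series(traj: Trajectory, atom_quadruple: Sequence[int]
                    ) -> np.ndarray:
    """Signed torsion angle (degrees, (-180, 180]) of four atoms per frame.

    For a tryptophan chi2 angle pass the CA, CB, CG, CD1 indices.
    """
    quad = [int(i) for i in atom_quadruple]
    if len(quad) != 4 or len(set(quad)) != 4:
        raise DomainError("need 4 distinct atom indices")
    _indices(quad, traj.n_atoms)
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        out[i] = _dihedral(*(frame[j] for j in quad))
    return out


def distance_series(traj: Trajectory, selection_a, selection_b,
                    mode: str = "atom") -> np.ndarray:
    """Per-frame Euclidean distance between two selections.

    ``mode='atom'`` requires single-atom selections; ``mode='centroid'``
    measures between the selection centroids (covers ring-to-group
    distances).
    """
    ia = _indices(selection_a, traj.n_atoms)
    ib = _indices(selection_b, traj.n_atoms)
    if mode == "atom":
        if ia.size != 1 or ib.size != 1:
            raise DomainError("mode='atom' requires single-atom selections")
        pa = traj.coords[:, ia[0], :]
        pb = traj.coords[:, ib[0], :]
    elif mode == "centroid":
        pa = traj.coords[:, ia, :].mean(axis=1)
        pb = traj.coords[:, ib, :].mean(axis=1)
    else:
        raise DomainError("mode must be 'atom' or 'centroid'")
    return np.linalg.norm(pa - pb, axis=1)


# ---------------------------------------------------------------------------
# simple text I/O (multi-frame XYZ and a long-form CSV dialect)


def write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for f, frame in enumerate(traj.coords):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for label, (x, y, z) in zip(traj.atom_labels, frame):
                fh.write(f"{label} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> Trajectory:
    frames = []
    labels: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2:i + 2 + n]
        frame = []
        frame_labels = []
        for ln in block:
            parts = ln.split()
            frame_labels.append(parts[0])
            frame.append([float(p) for p in parts[1:4]])
        if not labels:
            labels = frame_labels
        frames.append(frame)
        i += 2 + n
    # XYZ element symbols repeat; make labels unique for the container
    if len(set(labels)) != len(labels):
        labels = [f"{lab}{k}" for k, lab in enumerate(labels)]
    return Trajectory(coords=np.array(frames), atom_labels=labels)


def write_traj_csv(traj: Trajectory, path) -> None:
    rows = []
    for f, frame in enumerate(traj.coords):
        for a, (x, y, z) in enumerate(frame):
            rows.append((f, traj.atom_labels[a], x, y, z))
    pd.DataFrame(rows, columns=["frame", "atom", "x", "y", "z"]).to_csv(
        path, index=False)


def read_traj_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    need = {"frame", "atom", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise ShapeError(f"trajectory CSV requires columns {sorted(need)}")
    labels = list(df[df["frame"] == df["frame"].min()]["atom"].astype(str))
    frames = []
    for _, grp in df.groupby("frame", sort=True):
        frames.append(grp[["x", "y", "z"]].to_numpy())
    return Trajectory(coords=np.array(frames), atom_labels=labels)
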