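"""Per-frame geometric descriptors: Rg, end-to-end distance, pair
distances, Kabsch-superposed RMSD, and rolling averages.

All descriptors are invariant under global rotation and translation of a
frame; distances are plain Euclidean (ensembles are assumed whole, no
periodic-image handling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import Trajectory

__all__ = [
    "FrameSeries",
    "radius_of_gyration",
    "end_to_end",
    "pair_distance",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rolling_mean",
    "ATOMIC_MASSES",
]

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "CL": 35.45, "NA": 22.990,
}


@dataclass
class FrameSeries:
    """A scalar observable per frame, with units."""

    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FrameSeries values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FrameSeries values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        return float(self.values.mean())


def _masses(traj: Trajectory) -> np.ndarray:
    return np.array(
        [ATOMIC_MASSES.get(e.upper(), 12.011) for e in traj.atoms["element"]]
    )


def radius_of_gyration(traj: Trajectory, *, mass_weighted: bool = True) -> FrameSeries:
    """Radius of gyration per frame (nm).

    Rg = sqrt( sum_i m_i |r_i - rbar|^2 / sum_i m_i ), with rbar the
    (mass-weighted) centroid; unweighted uses unit masses.
    """
    w = _masses(traj) if mass_weighted else np.ones(traj.n_atoms)
    w = w / w.sum()
    center = np.einsum("a,fax->fx", w, traj.coords)
    d2 = ((traj.coords - center[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt(np.einsum("a,fa->f", w, d2))
    return FrameSeries(rg, label="R_G", units="nm")


def end_to_end(
    traj: Trajectory, *, end_atom: str = "CA"
) -> FrameSeries:
    """End-to-end distance per frame (nm): first vs last residue's
    ``end_atom`` (Calpha by default)."""
    resids = traj.residue_numbers
    i = traj.atom_index(int(resids[0]), end_atom)
    j = traj.atom_index(int(resids[-1]), end_atom)
    d = np.linalg.norm(traj.coords[:, j] - traj.coords[:, i], axis=1)
    return FrameSeries(d, label="EE_DIST", units="nm")


def pair_distance(
    traj: Trajectory, res_i: int, res_j: int, atom: str = "CA"
) -> FrameSeries:
    """Distance between a named atom of two residues, per frame (nm)."""
    i = traj.atom_index(res_i, atom)
    j = traj.atom_index(res_j, atom)
    d = np.linalg.norm(traj.coords[:, j] - traj.coords[:, i], axis=1)
    return FrameSeries(d, label=f"d({res_i}:{atom}-{res_j}:{atom})", units="nm")


def kabsch_rotation(
    a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids superposing b onto a.

    Standard 3x3 covariance SVD with a reflection guard (determinant sign
    correction) so R is a proper rotation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate arrays must have equal shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    w = np.ones(len(a)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    ca = w @ a
    cb = w @ b
    A = a - ca
    B = b - cb
    H = (B * w[:, None]).T @ A
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (collinear) coordinates: rotation ill-defined")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, ca, cb


def kabsch_rmsd(
    a: np.ndarray,
    b: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    superpose: bool = True,
) -> float:
    """Minimal RMSD (nm) between two frames over rigid superposition.

    ``superpose=False`` skips the alignment and returns the plain RMSD of
    the coordinates as given (identity alignment)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    w = np.ones(len(a)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    if superpose:
        R, ca, cb = kabsch_rotation(a, b, weights)
        b = (b - cb) @ R.T + ca
    elif a.shape != b.shape:
        raise ValueError("coordinate arrays must have equal shape")
    d2 = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt(w @ d2))


def rolling_mean(series: FrameSeries | np.ndarray, window: int) -> FrameSeries:
    """Centered-origin rolling average over ``window`` frames (valid mode:
    output has len - window + 1 points). window=1 is the identity."""
    values = series.values if isinstance(series, FrameSeries) else np.asarray(series, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(values):
        raise ValueError("window longer than series")
    kernel = np.full(window, 1.0 / window)
    out = np.convolve(values, kernel, mode="valid")
    label = series.label if isinstance(series, FrameSeries) else ""
    units = series.units if isinstance(series, FrameSeries) else ""
    return FrameSeries(out, label=f"{label} (rolling {window})".strip(), units=units)
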