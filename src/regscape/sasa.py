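"""Shrake-Rupley solvent-accessible surface area.

A probe sphere (default water radius 0.14 nm) is rolled over the van der
Waals surface by point sampling: each atom's expanded sphere of radius
r_i + r_probe carries a quasi-uniform point set (golden spiral), and the
exposed fraction -- points not buried inside any neighbour's expanded
sphere -- times the expanded-sphere area gives the atomic SASA.

Two ensemble accountings are provided: the plain per-frame total, and a
total over a residue subset (e.g. excluding phosphosites, so that the
bulky phosphate's own surface does not mask the burial response of the
unmodified residues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import FrameSeries
from .trajectory_io import Trajectory

__all__ = [
    "SasaMatrix",
    "sphere_points",
    "shrake_rupley",
    "residue_sasa_series",
    "total_sasa",
    "sasa_difference",
]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden
    spiral / Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class SasaMatrix:
    """Per-frame, per-residue SASA (nm^2)."""

    values: np.ndarray  # (frames, residues)
    resids: np.ndarray  # author residue numbers, chain order
    probe: float
    n_points: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.resids = np.asarray(self.resids, int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.resids):
            raise ValueError("values must be (frames, residues)")
        if np.any(self.values < -1e-12):
            raise ValueError("SASA values must be non-negative")

    def per_residue_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def per_residue_variance(self) -> np.ndarray:
        return self.values.var(axis=0)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, columns=self.resids).to_csv(path, index=False)


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 0.14,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (nm^2) for a single frame.

    ``coords`` (atoms, 3) and ``radii`` (atoms,) in nm. Atoms with NaN
    radius raise; the exposed-point fraction is multiplied by
    4 pi (r + probe)^2.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if coords.ndim != 2 or coords.shape[0] != radii.shape[0]:
        raise ValueError("coords and radii must match")
    bad = np.flatnonzero(~np.isfinite(radii))
    if bad.size:
        raise ValueError(f"missing van der Waals radius for atom index {bad[0]}")
    n = coords.shape[0]
    unit = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = tree.query_ball_point(coords[i], expanded[i] + expanded.max())
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > expanded[j] ** 2
            if not exposed.any():
                break
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas


def residue_sasa_series(
    traj: Trajectory, probe: float = 0.14, n_points: int = 960
) -> SasaMatrix:
    """Residue-level SASA over an ensemble: atomic areas summed by author
    residue number, one row per frame."""
    radii = traj.atoms["radius"].to_numpy(float)
    resids = traj.residue_numbers
    index = {r: k for k, r in enumerate(resids)}
    atom_res = np.array([index[r] for r in traj.atoms["resid"]])
    values = np.zeros((traj.n_frames, len(resids)))
    for f in range(traj.n_frames):
        atom_areas = shrake_rupley(traj.coords[f], radii, probe, n_points)
        np.add.at(values[f], atom_res, atom_areas)
    return SasaMatrix(values=values, resids=resids, probe=probe, n_points=n_points)


def total_sasa(
    matrix: SasaMatrix, exclude_sites: set[int] | frozenset[int] = frozenset()
) -> FrameSeries:
    """Per-frame total SASA, optionally excluding residues by author number
    (the phosphosite-controlled accounting)."""
    keep = ~np.isin(matrix.resids, list(exclude_sites))
    label = "SASA" if not exclude_sites else "SASA (excl. sites)"
    return FrameSeries(matrix.values[:, keep].sum(axis=1), label=label, units="nm^2")


def sasa_difference(
    matrix_condition: SasaMatrix, matrix_control: SasaMatrix
) -> np.ndarray:
    """Mean per-residue SASA change, condition minus control.

    Residues are aligned positionally by author number (a phosphosite is
    compared against its unmodified counterpart at the same number).
    """
    if not np.array_equal(matrix_condition.resids, matrix_control.resids):
        raise ValueError("residue axes differ: align by author number first")
    return matrix_condition.per_residue_mean() - matrix_control.per_residue_mean()
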