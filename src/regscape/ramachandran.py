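"""Backbone dihedrals and Ramachandran-region population analysis.

The (phi, psi) plane is partitioned into named basins associated with
secondary-structure propensity: P (polyproline-II), beta (beta-sheet),
alpha (right-handed helix), delta (deformed helix), L (left-handed
helix), gamma (remaining phi > 0) and "other". Populations integrated
over an ensemble, and their differences between conditions, quantify
how a perturbation (e.g. phosphorylation) redistributes backbone
conformers among basins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import Trajectory

__all__ = [
    "torsion",
    "wrap_angle",
    "RegionTable",
    "DEFAULT_REGIONS",
    "compute_dihedrals",
    "classify",
    "classify_array",
    "region_populations",
    "population_difference",
]


def torsion(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle (degrees, in [-180, 180)) of four points.

    Accepts arrays broadcastable to (..., 3); IUPAC sign convention
    (right-handed rotation of p3 about the p1->p2 axis, viewed from p1).
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def wrap_angle(a):
    """Wrap angles (degrees) into [-180, 180)."""
    return (np.asarray(a, float) + 180.0) % 360.0 - 180.0


Interval = tuple[float, float]


@dataclass(frozen=True)
class RegionTable:
    """Priority-ordered Ramachandran regions.

    Each entry is (label, phi intervals, psi intervals); intervals are
    half-open [lo, hi) on the wrapped domain [-180, 180). Evaluation in
    order returns the first matching label, so the table is total and
    single-valued provided the last entry covers the remainder.
    """

    entries: tuple[tuple[str, tuple[Interval, ...], tuple[Interval, ...]], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)


# Numeric bounds are a configuration choice: the field's basin labels are
# conventional but their exact borders are not standardised.
DEFAULT_REGIONS = RegionTable(
    entries=(
        ("P", ((-110.0, -40.0),), ((100.0, 180.0),)),
        ("beta", ((-180.0, -110.0),), ((90.0, 180.0), (-180.0, -160.0))),
        ("alpha", ((-120.0, -20.0),), ((-80.0, 30.0),)),
        ("delta", ((-180.0, -120.0),), ((-90.0, 60.0),)),
        ("L", ((0.0, 90.0),), ((-30.0, 90.0),)),
        ("gamma", ((0.0, 180.0),), ((-180.0, 180.0),)),
        ("other", ((-180.0, 180.0),), ((-180.0, 180.0),)),
    )
)


def _in_intervals(x: np.ndarray, intervals: tuple[Interval, ...]) -> np.ndarray:
    m = np.zeros(np.shape(x), dtype=bool)
    for lo, hi in intervals:
        m |= (x >= lo) & (x < hi)
    return m


def classify(phi: float, psi: float, table: RegionTable = DEFAULT_REGIONS) -> str:
    """Region label for one (phi, psi) pair (degrees, any wrap)."""
    return classify_array([phi], [psi], table)[0]


def classify_array(
    phi, psi, table: RegionTable = DEFAULT_REGIONS
) -> np.ndarray:
    """Vectorised region classification; NaN angles label as ''."""
    phi = wrap_angle(phi)
    psi = wrap_angle(psi)
    out = np.full(phi.shape, "", dtype=object)
    undecided = ~(np.isnan(phi) | np.isnan(psi))
    for label, phi_iv, psi_iv in table.entries:
        hit = undecided & _in_intervals(phi, phi_iv) & _in_intervals(psi, psi_iv)
        out[hit] = label
        undecided &= ~hit
    return out.astype(str)


def _backbone_indices(traj: Trajectory) -> dict[str, np.ndarray]:
    resids = traj.residue_numbers
    idx = {}
    for name in ("N", "CA", "C"):
        idx[name] = np.array([traj.atom_index(int(r), name) for r in resids])
    return idx


def compute_dihedrals(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Backbone (phi, psi) per frame and residue, degrees.

    Returns two (n_frames, n_residues) arrays; the first residue's phi and
    the last residue's psi are NaN (undefined at chain termini).
    """
    bb = _backbone_indices(traj)
    X = traj.coords
    n_f = traj.n_frames
    n_r = len(bb["N"])
    phi = np.full((n_f, n_r), np.nan)
    psi = np.full((n_f, n_r), np.nan)
    N, CA, C = bb["N"], bb["CA"], bb["C"]
    if n_r >= 2:
        # phi_i: C(i-1) N(i) CA(i) C(i) for i >= 1
        phi[:, 1:] = torsion(
            X[:, C[:-1]], X[:, N[1:]], X[:, CA[1:]], X[:, C[1:]]
        )
        # psi_i: N(i) CA(i) C(i) N(i+1) for i <= n-2
        psi[:, :-1] = torsion(
            X[:, N[:-1]], X[:, CA[:-1]], X[:, C[:-1]], X[:, N[1:]]
        )
    return phi, psi


def region_populations(
    traj_or_angles,
    table: RegionTable = DEFAULT_REGIONS,
) -> dict[str, float]:
    """Fraction of defined (phi, psi) observations in each region.

    Accepts a Trajectory (dihedrals computed on the fly) or a (phi, psi)
    array pair. Fractions sum to 1 over the table's labels.
    """
    if isinstance(traj_or_angles, Trajectory):
        phi, psi = compute_dihedrals(traj_or_angles)
    else:
        phi, psi = traj_or_angles
    phi = np.asarray(phi, float).ravel()
    psi = np.asarray(psi, float).ravel()
    ok = ~(np.isnan(phi) | np.isnan(psi))
    labels = classify_array(phi[ok], psi[ok], table)
    n = labels.size
    if n == 0:
        raise ValueError("no defined dihedral pairs")
    return {lab: float(np.count_nonzero(labels == lab)) / n for lab in table.labels}


def population_difference(
    cond: dict[str, float], control: dict[str, float]
) -> dict[str, float]:
    """Signed per-region population change, condition minus control."""
    keys = set(cond) | set(control)
    return {k: cond.get(k, 0.0) - control.get(k, 0.0) for k in sorted(keys)}
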