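"""Salt-bridge and hydrogen-bond occupancy analysis.

A contact between two charged groups is scored per frame from the
minimum distance over the groups' atom pairs (centroid distance is
available as an option). Two distance criteria coexist because both are
in common use: 0.35 nm for salt-bridge statistics between oppositely
charged species, and a stricter 0.30 nm for H-bond-style heatmaps over
all group pairs. No angular criterion is applied.

Occupancy is the fraction of frames below the cutoff; matrices are
indexed by charged-group label (author residue numbering) and are
symmetric in pair order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .chem_topology import ChargedGroup, Topology, charged_groups
from .trajectory_io import Trajectory

__all__ = [
    "ContactOccupancy",
    "min_group_distance",
    "group_distance_series",
    "saltbridge_occupancy",
    "hbond_occupancy",
    "occupancy_difference",
    "contact_mask",
]

SALTBRIDGE_CUTOFF = 0.35  # nm
HBOND_CUTOFF = 0.30  # nm


@dataclass
class ContactOccupancy:
    """Occupancy fractions for charged-group pairs."""

    matrix: pd.DataFrame  # square, labels x labels, NaN diagonal
    cutoff: float
    criterion: str  # "saltbridge" | "hbond"

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(float)
        off = ~np.eye(len(m), dtype=bool)
        vals = m[off]
        vals = vals[~np.isnan(vals)]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("occupancies must lie in [0, 1]")

    def pair(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])

    def mean_occupancy(self, *, observed_only: bool = False) -> float:
        """Mean occupancy over scored pairs; ``observed_only`` averages
        only pairs seen bonded at least once."""
        m = self.matrix.to_numpy(float)
        iu = np.triu_indices(len(m), k=1)
        vals = m[iu]
        vals = vals[~np.isnan(vals)]
        if observed_only:
            vals = vals[vals > 0]
        return float(vals.mean()) if vals.size else 0.0

    def top_pairs(self, k: int = 10) -> list[tuple[str, str, float]]:
        m = self.matrix
        out = []
        labels = list(m.index)
        for i, j in combinations(range(len(labels)), 2):
            v = m.iloc[i, j]
            if not np.isnan(v):
                out.append((labels[i], labels[j], float(v)))
        out.sort(key=lambda t: -abs(t[2]))
        return out[:k]


def _group_atom_indices(traj: Trajectory, group: ChargedGroup) -> np.ndarray:
    """Atom indices for a charged group, falling back to CB then CA when
    the side-chain atoms are not present (coarse synthetic chains)."""
    resid_match = (traj.atoms["resid"] == group.author_number).to_numpy()
    for names in (sorted(group.atoms), ["CB"], ["CA"]):
        mask = resid_match & traj.atoms["name"].isin(names).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size:
            return idx
    raise KeyError(f"no atoms found for charged group {group.label}")


def min_group_distance(
    frame: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> float:
    """Minimum distance (nm) over all atom pairs of two groups in one
    frame of coordinates."""
    a = frame[np.asarray(idx_a)]
    b = frame[np.asarray(idx_b)]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())


def group_distance_series(
    traj: Trajectory,
    group_a: ChargedGroup,
    group_b: ChargedGroup,
    *,
    mode: str = "min",
) -> np.ndarray:
    """Per-frame group-group distance (nm); ``mode`` is "min" (closest
    atom pair) or "centroid"."""
    ia = _group_atom_indices(traj, group_a)
    ib = _group_atom_indices(traj, group_b)
    A = traj.coords[:, ia]
    B = traj.coords[:, ib]
    if mode == "centroid":
        return np.linalg.norm(A.mean(axis=1) - B.mean(axis=1), axis=1)
    if mode != "min":
        raise ValueError(f"unknown distance mode {mode!r}")
    d = np.linalg.norm(A[:, :, None, :] - B[:, None, :, :], axis=3)
    return d.min(axis=(1, 2))


def _occupancy_matrix(
    traj: Trajectory,
    groups: list[ChargedGroup],
    cutoff: float,
    criterion: str,
    pair_filter,
    mode: str,
) -> ContactOccupancy:
    labels = [g.label for g in groups]
    m = np.full((len(groups), len(groups)), np.nan)
    for i, j in combinations(range(len(groups)), 2):
        if not pair_filter(groups[i], groups[j]):
            continue
        d = group_distance_series(traj, groups[i], groups[j], mode=mode)
        occ = float(np.mean(d < cutoff))
        m[i, j] = m[j, i] = occ
    return ContactOccupancy(
        matrix=pd.DataFrame(m, index=labels, columns=labels),
        cutoff=cutoff,
        criterion=criterion,
    )


def saltbridge_occupancy(
    traj: Trajectory,
    top: Topology,
    cutoff: float = SALTBRIDGE_CUTOFF,
    *,
    mode: str = "min",
    include_termini: bool = False,
) -> ContactOccupancy:
    """Occupancy of salt bridges: pairs of oppositely signed charged
    groups within ``cutoff`` (default 0.35 nm)."""
    groups = charged_groups(top, include_termini=include_termini)
    return _occupancy_matrix(
        traj, groups, cutoff, "saltbridge",
        lambda a, b: a.sign * b.sign < 0, mode,
    )


def hbond_occupancy(
    traj: Trajectory,
    donors: list[ChargedGroup],
    acceptors: list[ChargedGroup],
    cutoff: float = HBOND_CUTOFF,
    *,
    mode: str = "min",
) -> ContactOccupancy:
    """Distance-only H-bond-style occupancy (default 0.30 nm) between two
    group lists (donor/acceptor chemistry is not further restricted)."""
    seen = {}
    for g in [*donors, *acceptors]:
        seen.setdefault(g.label, g)
    groups = list(seen.values())
    donor_labels = {g.label for g in donors}
    acceptor_labels = {g.label for g in acceptors}

    def pair_ok(a: ChargedGroup, b: ChargedGroup) -> bool:
        return (a.label in donor_labels and b.label in acceptor_labels) or (
            b.label in donor_labels and a.label in acceptor_labels
        )

    return _occupancy_matrix(traj, groups, cutoff, "hbond", pair_ok, mode)


def occupancy_difference(
    cond: ContactOccupancy, control: ContactOccupancy
) -> pd.DataFrame:
    """Signed occupancy change, condition minus control, on the union of
    the two label sets (missing pairs treated as unobserved NaN)."""
    labels = sorted(set(cond.matrix.index) | set(control.matrix.index))
    a = cond.matrix.reindex(index=labels, columns=labels)
    b = control.matrix.reindex(index=labels, columns=labels)
    return a - b


def contact_mask(
    traj: Trajectory,
    top: Topology,
    pair: tuple[int, int],
    cutoff: float = SALTBRIDGE_CUTOFF,
    *,
    mode: str = "min",
) -> np.ndarray:
    """Boolean per-frame series: True where the two residues' charged
    groups are within ``cutoff``. Used to condition other observables on
    a bond being formed."""
    groups = {g.author_number: g for g in charged_groups(top)}
    try:
        ga, gb = groups[pair[0]], groups[pair[1]]
    except KeyError as exc:
        raise ValueError(f"residue {exc} carries no charged group") from exc
    d = group_distance_series(traj, ga, gb, mode=mode)
    return d < cutoff
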