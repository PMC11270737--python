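"""Secondary-structure assignment with a polyproline-II class.

The assignment follows the classic hydrogen-bond pattern approach: an
electrostatic model of the backbone N-H...O=C interaction defines the
bonds, n-turn and bridge patterns built from those bonds define helices
(H/G/I for 4/3/5-turns), strands and isolated bridges (E/B), turns (T)
and bends (S). Disordered ensembles spend most of their time outside
those classes, so the assignment is extended with the left-handed
polyproline-II helix (P), detected from backbone dihedral runs, which
the classic alphabet lumps into coil. Phosphorylated residues form their
own class (X): a phosphosite's chemistry differs from the standard
residue, so its structural state is bookkept separately rather than
mixed into the unmodified statistics.

Alphabet: H G I E B T S P ~ X (one code per residue per frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ramachandran import compute_dihedrals, wrap_angle
from .trajectory_io import Trajectory

__all__ = [
    "SSAssignment",
    "kabsch_sander_energy",
    "hbond_energy",
    "assign",
    "composition",
    "per_residue_fraction",
    "SS_CLASSES",
]

HBOND_CUTOFF = -0.5  # kcal/mol
ENERGY_MIN = -9.9
COUPLING = 0.084 * 332.0  # kcal/mol * Angstrom, partial-charge model
PPII_CENTER = (-75.0, 145.0)
PPII_TOL = 29.0
BEND_ANGLE = 70.0

# Table-style aggregation of the per-residue alphabet
SS_CLASSES = {
    "Coils": ("~",),
    "Bridges": ("E", "B"),
    "Helices": ("H", "G", "I"),
    "PPII": ("P",),
    "Bend": ("S",),
    "Turn": ("T",),
    "Phos.": ("X",),
}


def kabsch_sander_energy(r_on, r_ch, r_oh, r_cn) -> float:
    """Electrostatic H-bond energy (kcal/mol) from the four donor/acceptor
    distances N...O, C...H, O...H, C...N in Angstrom."""
    e = COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(np.maximum(e, ENERGY_MIN))


@dataclass
class SSAssignment:
    """Per-frame, per-residue secondary-structure codes."""

    codes: np.ndarray  # (frames, residues), single characters
    resids: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="U1")
        self.resids = np.asarray(self.resids, int)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.resids):
            raise ValueError("codes must be (frames, residues)")

    def frame_strings(self) -> list[str]:
        return ["".join(row) for row in self.codes]

    def write_flat(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# columns: residues %d-%d\n" % (self.resids[0], self.resids[-1]))
            for s in self.frame_strings():
                fh.write(s + "\n")


def _backbone(traj: Trajectory):
    resids = traj.residue_numbers
    n = len(resids)
    idx = {}
    for name in ("N", "CA", "C", "O"):
        idx[name] = np.array([traj.atom_index(int(r), name) for r in resids])
    h_idx = np.full(n, -1)
    for k, r in enumerate(resids):
        try:
            h_idx[k] = traj.atom_index(int(r), "H")
        except KeyError:
            pass
    resnames = np.array(
        [traj.atoms["resname"].iloc[idx["CA"][k]] for k in range(n)]
    )
    return resids, idx, h_idx, resnames


def _amide_h(N, CA, C_prev):
    """Reconstructed amide hydrogen: 1.0 A from N along the bisector of
    the N->(previous C) and N->CA directions, pointing away from both."""
    u1 = N - C_prev
    u1 /= np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = N - CA
    u2 /= np.linalg.norm(u2, axis=-1, keepdims=True)
    d = u1 + u2
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    return N + 0.1 * d  # nm


def _hbond_matrix(X, idx, h_idx, resnames, n) -> np.ndarray:
    """hb[d, a] True when NH of residue d donates to C=O of residue a."""
    Npos = X[idx["N"]]
    CApos = X[idx["CA"]]
    Cpos = X[idx["C"]]
    Opos = X[idx["O"]]
    Hpos = np.full_like(Npos, np.nan)
    for k in range(1, n):
        if resnames[k] == "PRO":
            continue  # proline has no amide hydrogen
        if h_idx[k] >= 0:
            Hpos[k] = X[h_idx[k]]
        else:
            Hpos[k] = _amide_h(Npos[k], CApos[k], Cpos[k - 1])
    hb = np.zeros((n, n), dtype=bool)
    ang = 10.0  # nm -> Angstrom
    for d in range(1, n):
        if np.isnan(Hpos[d, 0]):
            continue
        for a in range(n):
            if abs(d - a) < 2:
                continue
            r_on = np.linalg.norm(Npos[d] - Opos[a]) * ang
            if r_on > 5.2:  # beyond this the energy cannot reach -0.5
                continue
            r_oh = np.linalg.norm(Hpos[d] - Opos[a]) * ang
            r_ch = np.linalg.norm(Hpos[d] - Cpos[a]) * ang
            r_cn = np.linalg.norm(Npos[d] - Cpos[a]) * ang
            if kabsch_sander_energy(r_on, r_ch, r_oh, r_cn) < HBOND_CUTOFF:
                hb[d, a] = True
    return hb


def hbond_energy(
    traj: Trajectory, donor_resid: int, acceptor_resid: int, frame: int = 0
) -> float:
    """Backbone H-bond energy (kcal/mol) of donor NH -> acceptor C=O in
    one frame; the amide H is reconstructed if absent."""
    resids, idx, h_idx, resnames = _backbone(traj)
    pos = {int(r): k for k, r in enumerate(resids)}
    d, a = pos[donor_resid], pos[acceptor_resid]
    if d == 0:
        raise ValueError("N-terminal residue has no amide donor")
    X = traj.coords[frame]
    if h_idx[d] >= 0:
        H = X[h_idx[d]]
    else:
        H = _amide_h(X[idx["N"][d]], X[idx["CA"][d]], X[idx["C"][d - 1]])
    ang = 10.0
    r_on = np.linalg.norm(X[idx["N"][d]] - X[idx["O"][a]]) * ang
    r_oh = np.linalg.norm(H - X[idx["O"][a]]) * ang
    r_ch = np.linalg.norm(H - X[idx["C"][a]]) * ang
    r_cn = np.linalg.norm(X[idx["N"][d]] - X[idx["C"][a]]) * ang
    return kabsch_sander_energy(r_on, r_ch, r_oh, r_cn)


def _assign_frame(X, idx, h_idx, resnames, phi, psi, phospho_mask) -> np.ndarray:
    n = len(resnames)
    codes = np.full(n, "~", dtype="U1")
    if n >= 3:
        hb = _hbond_matrix(X, idx, h_idx, resnames, n)

        def turn(i, t):
            return i + t < n and hb[i + t, i]

        helix = np.zeros(n, dtype=int)  # 0 none, 4/3/5 by priority
        for t, code in ((4, "H"), (3, "G"), (5, "I")):
            starts = [i for i in range(1, n - t) if turn(i - 1, t) and turn(i, t)]
            for i in starts:
                for k in range(i, i + t):
                    if helix[k] == 0:
                        helix[k] = t
        for k in range(n):
            if helix[k] == 4:
                codes[k] = "H"
            elif helix[k] == 3:
                codes[k] = "G"
            elif helix[k] == 5:
                codes[k] = "I"

        bridges = set()
        for i in range(1, n - 1):
            for j in range(i + 3, n - 1):
                par = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
                anti = (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
                if par or anti:
                    bridges.add((i, j))
        in_ladder = set()
        for (i, j) in bridges:
            for di, dj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                if (i + di, j + dj) in bridges or (j + dj, i + di) in bridges:
                    in_ladder.update((i, j))
        for (i, j) in bridges:
            for k in (i, j):
                if codes[k] == "~":
                    codes[k] = "E" if k in in_ladder else "B"

        # PPII runs: >=2 consecutive residues in the basin, coil-like only
        in_basin = (
            (np.abs(wrap_angle(phi - PPII_CENTER[0])) <= PPII_TOL)
            & (np.abs(wrap_angle(psi - PPII_CENTER[1])) <= PPII_TOL)
        )
        in_basin &= np.isin(codes, ("~",))
        for k in range(n):
            if in_basin[k] and (
                (k > 0 and in_basin[k - 1]) or (k + 1 < n and in_basin[k + 1])
            ):
                codes[k] = "P"

        for t in (3, 4, 5):
            for i in range(n - t):
                if turn(i, t):
                    for k in range(i + 1, i + t):
                        if codes[k] == "~":
                            codes[k] = "T"

        CA = X[idx["CA"]]
        for k in range(2, n - 2):
            if codes[k] != "~":
                continue
            u = CA[k] - CA[k - 2]
            v = CA[k + 2] - CA[k]
            c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            if np.degrees(np.arccos(np.clip(c, -1, 1))) > BEND_ANGLE:
                codes[k] = "S"

    codes[phospho_mask] = "X"
    return codes


def assign(
    traj: Trajectory, phosphosites: set[int] | frozenset[int] | None = None
) -> SSAssignment:
    """Assign per-residue secondary structure for every frame.

    ``phosphosites`` (author numbers) default to residues whose name is
    SEP/TPO in the atom table; those residues are reported as class X.
    """
    resids, idx, h_idx, resnames = _backbone(traj)
    n = len(resids)
    if phosphosites is None:
        phospho_mask = np.isin(resnames, ("SEP", "TPO"))
    else:
        phospho_mask = np.isin(resids, list(phosphosites))
    phi, psi = compute_dihedrals(traj)
    codes = np.empty((traj.n_frames, n), dtype="U1")
    for f in range(traj.n_frames):
        codes[f] = _assign_frame(
            traj.coords[f], idx, h_idx, resnames, phi[f], psi[f], phospho_mask
        )
    return SSAssignment(codes=codes, resids=resids)


def composition(assignment: SSAssignment) -> dict[str, float]:
    """Class percentages over residues x frames (sum to 100)."""
    total = assignment.codes.size
    out = {}
    for cls, members in SS_CLASSES.items():
        out[cls] = 100.0 * np.isin(assignment.codes, members).sum() / total
    return out


def per_residue_fraction(assignment: SSAssignment, cls: str) -> np.ndarray:
    """Fraction of frames each residue spends in a class (or single code)."""
    members = SS_CLASSES.get(cls, (cls,))
    return np.isin(assignment.codes, members).mean(axis=0)
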