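"""Synthetic conformational ensembles with known ground truth.

Microsecond explicit-solvent trajectories of a disordered peptide are far
too expensive to regenerate, so every analysis stage in this package is
exercised against generators whose statistics are known in closed form:

* :func:`build_peptide` — a backbone builder that turns a (phi, psi) list
  into coordinates with canonical bond geometry, so dihedral-based stages
  can be tested by construction/inversion.
* :func:`markov_dihedral_walk` — dihedral dynamics governed by a Markov
  process over Ramachandran basins, with exact stationary distribution and
  spectral (autocorrelation) structure.
* :func:`freely_jointed_chain` — ideal-chain ensembles with closed-form
  size statistics (<R^2> = N b^2, <Rg^2> = N b^2 / 6).
* :func:`plant_contact_ensemble` — charged-pair contacts planted at an
  exact occupancy for the salt-bridge/H-bond counters.

All generators are seed-deterministic. They make no claim to physical
realism (no sterics, no solvent): they are measurement standards, not
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_topology import Topology, parse_sequence, charged_groups
from .trajectory_io import (
    BONDI_RADII_NM,
    PHOSPHO_THREE_LETTER,
    THREE_LETTER,
    Trajectory,
)
from .ramachandran import torsion

__all__ = [
    "MarkovDihedralModel",
    "build_peptide",
    "markov_dihedral_walk",
    "dihedral_ensemble",
    "freely_jointed_chain",
    "plant_contact_ensemble",
    "plant_contacts",
]

# Engh-Huber canonical backbone geometry (Angstrom / degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_N_H = 1.000
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
OMEGA = 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: return d with |c-d|=bond, angle(b,c,d)=angle and
    dihedral(a,b,c,d)=torsion."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _normalize_dihedrals(n_res: int, dihedrals) -> np.ndarray:
    arr = np.asarray(dihedrals, dtype=float)
    if arr.shape == (2,):
        arr = np.tile(arr, (n_res, 1))
    if arr.shape == (n_res - 2, 2):
        # one pair per non-terminal residue; pad ends (phi of first and
        # psi of last are undefined anyway)
        arr = np.vstack([arr[:1], arr, arr[-1:]])
    if arr.shape != (n_res, 2):
        raise ValueError(
            f"need a (phi, psi) pair per residue: got shape {arr.shape} "
            f"for {n_res} residues"
        )
    return arr


def build_peptide(
    sequence: str | Topology,
    dihedrals,
    *,
    first_author_number: int = 1,
) -> Trajectory:
    """Build a single-frame backbone trajectory from (phi, psi) angles.

    Atoms per residue: N, H (except the N-terminus), CA, CB (except Gly),
    C, O, at canonical bond lengths/angles with omega fixed at 180 deg.
    ``dihedrals`` may be a single (phi, psi) pair (applied to every
    residue), one pair per residue, or one per non-terminal residue.
    Recomputing dihedrals on the output returns the inputs to well below
    1e-3 degrees.
    """
    if isinstance(sequence, Topology):
        top = sequence
    else:
        top = parse_sequence(sequence, first_author_number)
    n = len(top.residues)
    ang = _normalize_dihedrals(n, dihedrals)
    phi, psi = ang[:, 0], ang[:, 1]

    # backbone trace in Angstrom
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    theta = np.radians(180.0 - ANG_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])
    for i in range(n - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], B_C_N, ANG_CA_C_N, psi[i])
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], B_N_CA, ANG_C_N_CA, OMEGA)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], B_CA_C, ANG_N_CA_C, phi[i + 1])

    rows = []
    coords = []

    def add(resid, resname, name, element, xyz):
        rows.append((name, element, resid, resname))
        coords.append(xyz)

    for i, res in enumerate(top.residues):
        resname = (
            PHOSPHO_THREE_LETTER[res.code]
            if res.is_phosphorylated
            else THREE_LETTER[res.code]
        )
        rid = res.author_number
        add(rid, resname, "N", "N", N[i])
        if i > 0:
            u1 = N[i] - C[i - 1]
            u2 = N[i] - CA[i]
            h_dir = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            h_dir /= np.linalg.norm(h_dir)
            add(rid, resname, "H", "H", N[i] + B_N_H * h_dir)
        add(rid, resname, "CA", "C", CA[i])
        if res.code != "G":
            b1 = CA[i] - N[i]
            b2 = C[i] - CA[i]
            a = np.cross(b1, b2)
            cb = -0.58273431 * a + 0.56802827 * b1 - 0.54067466 * b2 + CA[i]
            add(rid, resname, "CB", "C", cb)
        add(rid, resname, "C", "C", C[i])
        o_psi = psi[i] if i < n - 1 else psi[i]
        if i == n - 1:
            ref = np.nan_to_num(o_psi, nan=180.0)
        else:
            ref = o_psi
        add(rid, resname, "O", "O", _place_atom(N[i], CA[i], C[i], B_C_O,
                                                ANG_CA_C_O, ref + 180.0))

    atoms = pd.DataFrame(rows, columns=["name", "element", "resid", "resname"])
    atoms["radius"] = [BONDI_RADII_NM[e] for e in atoms["element"]]
    xyz = np.asarray(coords)[None] * 0.1  # Angstrom -> nm
    return Trajectory(coords=xyz, atoms=atoms)


@dataclass(frozen=True)
class MarkovDihedralModel:
    """Discrete-state model of backbone dihedral dynamics.

    Each state is a Ramachandran basin center (phi, psi); the per-frame
    state follows a Markov chain with transition matrix ``transition``;
    emitted angles are the center plus isotropic Gaussian jitter of
    standard deviation ``jitter_deg``.
    """

    centers: tuple[tuple[float, float], ...]
    transition: tuple[tuple[float, ...], ...]
    jitter_deg: float = 10.0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, float)
        if T.ndim != 2 or T.shape[0] != T.shape[1] or T.shape[0] != len(self.centers):
            raise ValueError("transition matrix must be square, one row per state")
        if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must be stochastic")
        if self.jitter_deg < 0:
            raise ValueError("jitter must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.centers)

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left Perron eigenvector)."""
        T = np.asarray(self.transition, float)
        vals, vecs = np.linalg.eig(T.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    def slowest_eigenvalue(self) -> float:
        """Second-largest transition eigenvalue magnitude (relaxation rate
        of the slowest mode is -ln lambda_2 per frame)."""
        vals = np.sort(np.abs(np.linalg.eigvals(np.asarray(self.transition, float))))
        return float(vals[-2]) if len(vals) > 1 else 0.0


def markov_dihedral_walk(
    model: MarkovDihedralModel,
    n_frames: int,
    n_residues: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a dihedral time series from the Markov basin model.

    One chain drives all residues (the whole backbone hops between basins
    together); jitter is independent per residue and frame. Returns
    (angles, states): angles with shape (n_frames, n_residues, 2) in
    degrees, states with shape (n_frames,).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    T = np.asarray(model.transition, float)
    cum = np.cumsum(T, axis=1)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.stationary())
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")
    centers = np.asarray(model.centers, float)[states]  # (F, 2)
    angles = centers[:, None, :] + rng.normal(
        0.0, model.jitter_deg, size=(n_frames, n_residues, 2)
    )
    return angles, states


def dihedral_ensemble(
    sequence: str | Topology,
    model: MarkovDihedralModel,
    n_frames: int,
    seed: int = 0,
    *,
    first_author_number: int = 1,
    pin_first: bool = False,
) -> tuple[Trajectory, np.ndarray]:
    """Full-coordinate ensemble driven by a Markov dihedral walk.

    Builds one peptide frame per sampled dihedral vector. ``pin_first``
    keeps the first residue's position fixed across frames, emulating a
    terminally restrained chain. Returns (trajectory, state labels).
    """
    if isinstance(sequence, Topology):
        top = sequence
    else:
        top = parse_sequence(sequence, first_author_number)
    n_res = len(top.residues)
    angles, states = markov_dihedral_walk(model, n_frames, n_res, seed)
    frames = []
    atoms = None
    for f in range(n_frames):
        t = build_peptide(top, angles[f])
        frames.append(t.coords[0])
        if atoms is None:
            atoms = t.atoms
    coords = np.asarray(frames)
    if not pin_first:
        # random global pose per frame so orientation-dependent bugs show up
        rng = np.random.default_rng(seed + 1)
        for f in range(n_frames):
            M = _random_rotation(rng)
            coords[f] = coords[f] @ M.T + rng.normal(0, 1.0, 3)
    traj = Trajectory(coords=coords, atoms=atoms, times=np.arange(n_frames, dtype=float))
    return traj, states


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def freely_jointed_chain(
    n_bonds: int,
    bond_length: float = 0.38,
    n_frames: int = 1000,
    seed: int = 0,
    *,
    pin_first: bool = False,
) -> Trajectory:
    """Ideal freely-jointed chain ensemble of point beads.

    ``n_bonds`` i.i.d. uniformly oriented bonds of fixed length (nm) give
    n_bonds+1 beads per frame; <R_ee^2> = N b^2 and <Rg^2> -> N b^2/6.
    Beads are carried as Calpha pseudo-atoms.
    """
    if n_bonds < 1:
        raise ValueError("need at least one bond")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_frames, n_bonds, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    steps = np.concatenate([np.zeros((n_frames, 1, 3)), v * bond_length], axis=1)
    coords = np.cumsum(steps, axis=1)
    if not pin_first:
        coords = coords + rng.normal(0, 1.0, size=(n_frames, 1, 3))
    n_atoms = n_bonds + 1
    atoms = pd.DataFrame(
        {
            "name": ["CA"] * n_atoms,
            "element": ["C"] * n_atoms,
            "resid": np.arange(1, n_atoms + 1),
            "resname": ["GLY"] * n_atoms,
        }
    )
    atoms["radius"] = BONDI_RADII_NM["C"]
    return Trajectory(coords=coords, atoms=atoms)


def _contact_scaffold(top: Topology, spacing: float) -> tuple[pd.DataFrame, np.ndarray]:
    """Baseline single-frame layout: residues on a line, charged-group
    atoms clustered near their residue site."""
    groups = {g.author_number: g for g in charged_groups(top)}
    rows = []
    xyz = []
    for i, res in enumerate(top.residues):
        resname = (
            PHOSPHO_THREE_LETTER[res.code]
            if res.is_phosphorylated
            else THREE_LETTER[res.code]
        )
        base = np.array([i * spacing, 0.0, 0.0])
        rows.append(("CA", "C", res.author_number, resname))
        xyz.append(base)
        g = groups.get(res.author_number)
        if g is not None:
            for j, aname in enumerate(sorted(g.atoms)):
                elem = aname[0]
                rows.append((aname, elem, res.author_number, resname))
                xyz.append(base + np.array([0.0, 0.15 + 0.03 * j, 0.05]))
    atoms = pd.DataFrame(rows, columns=["name", "element", "resid", "resname"])
    atoms["radius"] = [BONDI_RADII_NM.get(e, 0.17) for e in atoms["element"]]
    return atoms, np.asarray(xyz)


def plant_contacts(
    top: Topology,
    plan: dict[tuple[int, int], float],
    cutoff: float = 0.35,
    n_frames: int = 1000,
) -> Trajectory:
    """Ensemble with several charged pairs bonded at exact occupancies.

    For each pair (author numbers) with target occupancy f, exactly
    round(f * n_frames) frames place the pair's charged groups within
    0.8 * cutoff; in every other frame the pair sits farther than
    2 * cutoff apart. Pairs must involve disjoint residues. Placement is
    deterministic (staggered contiguous blocks), so measured occupancy
    equals the plan exactly.
    """
    involved: set[int] = set()
    groups = {g.author_number: g for g in charged_groups(top)}
    for (a, b), f in plan.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"occupancy {f} outside [0, 1]")
        for r in (a, b):
            if r not in groups:
                raise ValueError(f"residue {r} carries no charged group")
            if r in involved:
                raise ValueError(f"residue {r} appears in more than one planted pair")
            involved.add(r)
    spacing = max(0.8, 2.5 * cutoff)
    atoms, base = _contact_scaffold(top, spacing)
    coords = np.tile(base, (n_frames, 1, 1))
    resid = atoms["resid"].to_numpy()
    names = atoms["name"].to_numpy()
    for k, ((a, b), f) in enumerate(sorted(plan.items())):
        n_on = int(round(f * n_frames))
        start = (k * max(1, n_frames // max(len(plan), 1))) % n_frames
        on = (np.arange(n_frames) - start) % n_frames < n_on
        ga, gb = groups[a], groups[b]
        ia = np.flatnonzero((resid == a) & np.isin(names, sorted(ga.atoms)))
        ib = np.flatnonzero((resid == b) & np.isin(names, sorted(gb.atoms)))
        anchor = base[ia[0]]
        for j, idx in enumerate(ib):
            target = anchor + np.array([0.8 * cutoff, 0.02 * (j + 1), 0.0])
            coords[on, idx] = target
    return Trajectory(coords=coords, atoms=atoms,
                      times=np.arange(n_frames, dtype=float))


def plant_contact_ensemble(
    top: Topology,
    pair: tuple[int, int],
    occupancy: float,
    cutoff: float = 0.35,
    n_frames: int = 1000,
) -> Trajectory:
    """Single planted charged-pair contact; see :func:`plant_contacts`."""
    return plant_contacts(top, {tuple(pair): occupancy}, cutoff, n_frames)
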