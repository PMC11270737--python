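"""Ensemble I/O and atom selection.

A :class:`Trajectory` is the in-memory container every analysis stage
consumes: coordinates in nanometres, frame times in picoseconds, and an
atom table (name, element, author residue number, van der Waals radius).
Multi-model PDB is the canonical on-disk format; binary trajectories
(DCD/XTC with a PDB topology) are supported through the same entry point.
This is the only module that delegates format parsing to external I/O
libraries (biotite for PDB, mdtraj for binary formats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_topology import Topology

__all__ = [
    "Trajectory",
    "read_ensemble",
    "write_ensemble",
    "select",
    "BONDI_RADII_NM",
    "THREE_LETTER",
    "ONE_LETTER",
]

# Bondi van der Waals radii, nm
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "F": 0.147,
    "CL": 0.175,
}
DEFAULT_RADIUS_NM = 0.170

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
# phosphorylated serine/threonine use the standard PDB het codes
PHOSPHO_THREE_LETTER = {"S": "SEP", "T": "TPO"}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}
ONE_LETTER.update({"SEP": "S", "TPO": "T"})


def _infer_element(name: str) -> str:
    name = name.strip()
    if name[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _radius_for(element: str) -> float:
    try:
        return BONDI_RADII_NM[element.upper()]
    except KeyError:
        warnings.warn(
            f"no van der Waals radius for element {element!r}; "
            f"using default {DEFAULT_RADIUS_NM} nm",
            stacklevel=3,
        )
        return DEFAULT_RADIUS_NM


@dataclass
class Trajectory:
    """Conformational ensemble: frames x atoms x 3 coordinates in nm.

    ``atoms`` columns: ``name``, ``element``, ``resid`` (author residue
    number), ``resname``, ``radius`` (nm).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table length does not match coordinates")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times length does not match frame count")
        if "radius" not in self.atoms.columns:
            self.atoms = self.atoms.assign(
                radius=[_radius_for(e) for e in self.atoms["element"]]
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_numbers(self) -> np.ndarray:
        """Unique author residue numbers, in chain order."""
        return pd.unique(self.atoms["resid"].to_numpy())

    def atom_index(self, resid: int, name: str) -> int:
        mask = (self.atoms["resid"] == resid) & (self.atoms["name"] == name)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError(f"no atom {name!r} in residue {resid}")
        return int(idx[0])

    def take_atoms(self, indices: np.ndarray) -> "Trajectory":
        indices = np.asarray(indices)
        if indices.size == 0:
            raise ValueError("empty atom selection")
        return Trajectory(
            coords=self.coords[:, indices],
            atoms=self.atoms.iloc[indices].reset_index(drop=True),
            times=self.times.copy(),
        )

    def take_frames(self, indices) -> "Trajectory":
        return Trajectory(
            coords=self.coords[indices],
            atoms=self.atoms.copy(),
            times=self.times[indices],
        )

    def select(self, **kwargs) -> "Trajectory":
        return select(self, **kwargs)

    def to_csv(self, path: str | Path, series: dict[str, np.ndarray]) -> None:
        """Export per-frame series (one column each) with frame times."""
        df = pd.DataFrame({"time_ps": self.times, **series})
        df.to_csv(path, index=False)


def select(
    traj: Trajectory,
    *,
    name: str | Sequence[str] | None = None,
    resid: Iterable[int] | None = None,
    resid_range: tuple[int, int] | None = None,
    element: str | None = None,
    stride: int | None = None,
    predicate: Callable[[pd.Series], bool] | None = None,
) -> Trajectory:
    """Subset atoms (and optionally frames) preserving order.

    Criteria combine conjunctively, so ``select(select(t, a), b)`` equals
    ``select(t, a, b)``. Raises ``ValueError`` on an empty selection.
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    atoms = traj.atoms
    if name is not None:
        names = [name] if isinstance(name, str) else list(name)
        mask &= atoms["name"].isin(names).to_numpy()
    if resid is not None:
        mask &= atoms["resid"].isin(list(resid)).to_numpy()
    if resid_range is not None:
        lo, hi = resid_range
        r = atoms["resid"].to_numpy()
        mask &= (r >= lo) & (r <= hi)
    if element is not None:
        mask &= (atoms["element"].str.upper() == element.upper()).to_numpy()
    if predicate is not None:
        mask &= atoms.apply(predicate, axis=1).to_numpy()
    out = traj.take_atoms(np.flatnonzero(mask))
    if stride is not None and stride > 1:
        out = out.take_frames(slice(0, None, stride))
    return out


def _atoms_from_topology(topology: Topology | None, resids, resnames):
    """Map three-letter names back to phospho flags when a Topology is given."""
    if topology is None:
        return
    known = {r.author_number for r in topology.residues}
    missing = set(np.unique(resids)) - known
    if missing:
        raise ValueError(
            f"residues {sorted(missing)} in the file are absent from the topology"
        )


def read_ensemble(
    path: str | Path,
    topology: Topology | None = None,
    *,
    top_path: str | Path | None = None,
) -> Trajectory:
    """Read a conformational ensemble.

    Multi-model PDB files are read with biotite (one frame per MODEL).
    ``.dcd``/``.xtc`` require ``top_path`` pointing at a PDB topology and
    are read with mdtraj. Coordinates are normalised to nm, times to ps.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcd", ".xtc"):
        if top_path is None:
            raise ValueError(f"{suffix} input requires a PDB topology file")
        import mdtraj as md

        t = md.load(str(path), top=str(top_path))
        atoms = pd.DataFrame(
            {
                "name": [a.name for a in t.topology.atoms],
                "element": [
                    a.element.symbol.upper() if a.element else "" for a in t.topology.atoms
                ],
                "resid": [a.residue.resSeq for a in t.topology.atoms],
                "resname": [a.residue.name for a in t.topology.atoms],
            }
        )
        atoms["radius"] = [_radius_for(e) for e in atoms["element"]]
        _atoms_from_topology(topology, atoms["resid"].to_numpy(), atoms["resname"])
        return Trajectory(coords=np.asarray(t.xyz, dtype=float), atoms=atoms,
                          times=np.asarray(t.time, dtype=float))

    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    except Exception as exc:  # mismatched models, malformed records
        raise ValueError(f"cannot read {path} as a multi-model ensemble: {exc}") from exc
    elements = [e.upper() if e else _infer_element(n)
                for e, n in zip(stack.element, stack.atom_name)]
    atoms = pd.DataFrame(
        {
            "name": list(stack.atom_name),
            "element": elements,
            "resid": np.asarray(stack.res_id, dtype=int),
            "resname": list(stack.res_name),
        }
    )
    atoms["radius"] = [_radius_for(e) for e in atoms["element"]]
    _atoms_from_topology(topology, atoms["resid"].to_numpy(), atoms["resname"])
    coords = np.asarray(stack.coord, dtype=float) * 0.1  # Angstrom -> nm
    return Trajectory(coords=coords, atoms=atoms)


def write_ensemble(traj: Trajectory, path: str | Path) -> None:
    """Write as a multi-model PDB (one MODEL per frame), nm -> Angstrom."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords * 10.0
    stack.chain_id = np.full(n, "A")
    stack.res_id = traj.atoms["resid"].to_numpy(dtype=int)
    stack.res_name = traj.atoms["resname"].to_numpy(dtype="U5")
    stack.atom_name = traj.atoms["name"].to_numpy(dtype="U6")
    stack.element = traj.atoms["element"].to_numpy(dtype="U2")
    stack.hetero = np.isin(stack.res_name, ("SEP", "TPO"))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
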