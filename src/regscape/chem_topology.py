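"""Sequence parsing, residue chemistry and charged-group bookkeeping.

The analyses downstream (salt bridges, net-charge accounting, counterion
counts, phospho-aware secondary-structure classes) all hinge on a small
amount of chemistry: which side chains carry formal charge, which serines
and threonines are phosphorylated, and how the phosphate group is modelled.
The phosphate is treated as monoanionic by default -- one protic hydrogen
retained on the phosphate, three ionisable oxygens of which one is
protonated -- so each phosphosite contributes -1 to the formal charge.
Histidine is neutral at physiological pH by default, with a protonated
override for constructs whose reported net charge implies charged His.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "Residue",
    "Topology",
    "ChargedGroup",
    "parse_sequence",
    "read_fasta_sequence",
    "topology_from_config",
    "charged_groups",
    "formal_net_charge",
    "counterion_count",
    "AMINO_ACIDS",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Side-chain atoms that carry the formal charge, standard PDB v3 naming.
_POSITIVE_ATOMS = {
    "K": frozenset({"NZ"}),
    "R": frozenset({"NE", "NH1", "NH2"}),
}
_NEGATIVE_ATOMS = {
    "D": frozenset({"OD1", "OD2"}),
    "E": frozenset({"OE1", "OE2"}),
}
_PHOSPHO_ATOMS = {
    "S": frozenset({"O1P", "O2P", "O3P", "OG"}),
    "T": frozenset({"O1P", "O2P", "O3P", "OG1"}),
}
_HIS_ATOMS = frozenset({"ND1", "NE2"})


@dataclass(frozen=True)
class Residue:
    """One residue with author (literature-convention) numbering.

    ``formal_side_charge`` is the side-chain charge only; termini are
    accounted for at the Topology level.
    """

    author_number: int
    code: str
    is_phosphorylated: bool = False
    charged_group: frozenset[str] | None = None
    formal_side_charge: int = 0

    def __post_init__(self) -> None:
        if self.code not in AMINO_ACIDS:
            raise ValueError(f"unknown residue code {self.code!r}")
        if self.is_phosphorylated and self.code not in ("S", "T"):
            raise ValueError(
                f"residue {self.code}{self.author_number} cannot be "
                "phosphorylated: only S/T sites are supported"
            )
        if self.formal_side_charge not in (-2, -1, 0, 1):
            raise ValueError(
                f"formal side charge {self.formal_side_charge} outside {{-2..+1}}"
            )


@dataclass(frozen=True)
class Topology:
    """Ordered residue list plus the charge-model conventions."""

    residues: tuple[Residue, ...]
    termini_model: Literal["zwitterionic", "capped"] = "zwitterionic"
    his_protonation: Literal["neutral", "protonated"] = "neutral"
    phospho_charge: int = -1

    def __post_init__(self) -> None:
        numbers = [r.author_number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("author numbers must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def first_author_number(self) -> int:
        return self.residues[0].author_number

    @property
    def phosphosites(self) -> tuple[int, ...]:
        return tuple(r.author_number for r in self.residues if r.is_phosphorylated)

    def residue(self, author_number: int) -> Residue:
        for r in self.residues:
            if r.author_number == author_number:
                return r
        raise KeyError(f"no residue numbered {author_number}")

    def with_his(self, his_protonation: Literal["neutral", "protonated"]) -> "Topology":
        return replace(self, his_protonation=his_protonation)


@dataclass(frozen=True)
class ChargedGroup:
    """A titratable side-chain (or terminal) group used for contact analysis."""

    author_number: int
    label: str
    atoms: frozenset[str]
    sign: int  # formal charge of the group


def _side_charge(code: str, phosphorylated: bool, phospho_charge: int) -> int:
    if phosphorylated:
        return phospho_charge
    if code in _POSITIVE_ATOMS:
        return 1
    if code in _NEGATIVE_ATOMS:
        return -1
    return 0


def parse_sequence(
    seq: str,
    first_author_number: int = 351,
    phosphosites: Sequence[int] = (),
    *,
    phospho_charge: int = -1,
    his_protonation: Literal["neutral", "protonated"] = "neutral",
    termini_model: Literal["zwitterionic", "capped"] = "zwitterionic",
) -> Topology:
    """Build a Topology from a one-letter sequence with author numbering.

    Parameters
    ----------
    seq
        One-letter amino-acid string (case-insensitive).
    first_author_number
        Author number of the first residue; the construct studied here uses
        351 for the first tetramerization-domain residue.
    phosphosites
        Author numbers of phosphorylated S/T residues.

    Raises
    ------
    ValueError
        If the sequence is empty, contains an unknown code, a phosphosite
        falls outside the numbering range, or names a non-S/T residue.
    """
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    last = first_author_number + len(seq) - 1
    sites = set(phosphosites)
    for site in sites:
        if not first_author_number <= site <= last:
            raise ValueError(
                f"phosphosite {site} outside residue range "
                f"{first_author_number}-{last}"
            )
        code = seq[site - first_author_number]
        if code not in ("S", "T"):
            raise ValueError(
                f"phosphosite {site} is {code}, not a serine or threonine"
            )
    residues = []
    for i, code in enumerate(seq):
        number = first_author_number + i
        phos = number in sites
        charge = _side_charge(code, phos, phospho_charge)
        if phos:
            atoms: frozenset[str] | None = _PHOSPHO_ATOMS[code]
        elif code in _POSITIVE_ATOMS:
            atoms = _POSITIVE_ATOMS[code]
        elif code in _NEGATIVE_ATOMS:
            atoms = _NEGATIVE_ATOMS[code]
        else:
            atoms = None
        residues.append(
            Residue(
                author_number=number,
                code=code,
                is_phosphorylated=phos,
                charged_group=atoms,
                formal_side_charge=charge,
            )
        )
    return Topology(
        residues=tuple(residues),
        termini_model=termini_model,
        his_protonation=his_protonation,
        phospho_charge=phospho_charge,
    )


def read_fasta_sequence(path: str | Path) -> str:
    """Read the first record of a FASTA file as a one-letter sequence."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def topology_from_config(config: dict) -> Topology:
    """Build a Topology from a JSON-style config block.

    Recognised keys: ``sequence`` (or ``fasta`` path), ``first_residue``,
    ``phosphosites``, ``phospho_charge``, ``his_protonation``,
    ``termini_model``.
    """
    if "sequence" in config:
        seq = config["sequence"]
    elif "fasta" in config:
        seq = read_fasta_sequence(config["fasta"])
    else:
        raise ValueError("config needs 'sequence' or 'fasta'")
    return parse_sequence(
        seq,
        first_author_number=int(config.get("first_residue", 1)),
        phosphosites=config.get("phosphosites", ()),
        phospho_charge=int(config.get("phospho_charge", -1)),
        his_protonation=config.get("his_protonation", "neutral"),
        termini_model=config.get("termini_model", "zwitterionic"),
    )


def charged_groups(
    top: Topology, *, include_termini: bool = False
) -> list[ChargedGroup]:
    """Enumerate charged side-chain groups (one per K/R/D/E and phosphosite).

    Histidine contributes a +1 group only under the protonated convention.
    Termini are excluded by default so the group count matches salt-bridge
    bookkeeping over side chains; pass ``include_termini=True`` to append
    the N-terminal amine and C-terminal carboxylate as two extra groups.
    """
    groups: list[ChargedGroup] = []
    for r in top.residues:
        if r.is_phosphorylated:
            groups.append(
                ChargedGroup(r.author_number, f"p{r.code}{r.author_number}",
                             _PHOSPHO_ATOMS[r.code], top.phospho_charge)
            )
        elif r.code in _POSITIVE_ATOMS:
            groups.append(
                ChargedGroup(r.author_number, f"{r.code}{r.author_number}",
                             _POSITIVE_ATOMS[r.code], +1)
            )
        elif r.code in _NEGATIVE_ATOMS:
            groups.append(
                ChargedGroup(r.author_number, f"{r.code}{r.author_number}",
                             _NEGATIVE_ATOMS[r.code], -1)
            )
        elif r.code == "H" and top.his_protonation == "protonated":
            groups.append(
                ChargedGroup(r.author_number, f"H{r.author_number}", _HIS_ATOMS, +1)
            )
    if include_termini and top.termini_model == "zwitterionic":
        first, last = top.residues[0], top.residues[-1]
        groups.insert(
            0, ChargedGroup(first.author_number, "N-term", frozenset({"N"}), +1)
        )
        groups.append(
            ChargedGroup(last.author_number, "C-term", frozenset({"O", "OXT"}), -1)
        )
    return groups


def formal_net_charge(top: Topology) -> int:
    """Formal net charge: side chains + phosphates + His model + termini.

    Zwitterionic termini contribute net zero (NH3+ and COO- cancel);
    capped termini are neutral.
    """
    charge = sum(r.formal_side_charge for r in top.residues)
    if top.his_protonation == "protonated":
        charge += sum(1 for r in top.residues if r.code == "H")
    # both termini models are net-neutral overall
    return charge


def counterion_count(net: int) -> int:
    """Number of monovalent counterions of the opposite sign needed to
    neutralise a solute of formal charge ``net``."""
    return abs(int(net))
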