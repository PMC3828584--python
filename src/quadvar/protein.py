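"""Protein-level interpretation: domain mapping and conservation.

Maps a mutated residue onto named protein-domain intervals (the shipped
default is the myosin XVa architecture — N-terminal extension, motor
domain, IQ light-chain motifs, two MyTH4 domains, two FERM domains and
an SH3 domain) and assesses evolutionary conservation of the residue as
column identity in a protein multiple sequence alignment, with a
separate all-mammals flag over a configurable mammal subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .types import MSA

#: species treated as mammals by default when judging mammalian conservation
DEFAULT_MAMMALS = ("human", "chimpanzee", "macaque", "cow", "dog", "mouse", "rat")


@dataclass(frozen=True)
class DomainTable:
    """Named protein-residue intervals, 1-based inclusive at both ends.

    Entries may abut or overlap (myosin XVa's SH3 domain overlaps the end
    of its first FERM domain); all containing intervals are reported.
    """

    entries: tuple  # of (name, start, end)

    def __post_init__(self):
        entries = tuple((str(n), int(s), int(e)) for n, s, e in self.entries)
        for n, s, e in entries:
            if not (1 <= s <= e):
                raise ValueError(f"bad interval for {n}: [{s}, {e}]")
        object.__setattr__(self, "entries", entries)

    @classmethod
    def from_yaml(cls, path) -> "DomainTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls(tuple((d["name"], d["start"], d["end"])
                         for d in data["domains"]))

    @classmethod
    def from_tsv(cls, path) -> "DomainTable":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, start, end = line.split("\t")[:3]
            entries.append((name, int(start), int(end)))
        return cls(tuple(entries))


def myo15a_domain_table() -> DomainTable:
    """The myosin XVa domain table shipped with the package."""
    ref = resources.files("quadvar").joinpath("data/myo15a_domains.yaml")
    data = yaml.safe_load(ref.read_text())
    return DomainTable(tuple((d["name"], d["start"], d["end"])
                             for d in data["domains"]))


def map_residue_to_domain(residue: int, table: DomainTable
                          ) -> List[Tuple[str, int, int]]:
    """All domain entries whose closed interval contains the residue,
    in table order; empty when the residue falls in a linker."""
    if residue < 1:
        raise ValueError("residue index must be >= 1")
    return [(n, s, e) for n, s, e in table.entries if s <= residue <= e]


@dataclass(frozen=True)
class ConservationResult:
    """Cross-species conservation of one reference residue.

    ``identity_fraction`` is the proportion of non-gap residues in the
    alignment column equal to the reference residue (the reference itself
    included); ``mammal_conserved`` requires every declared mammal to
    match exactly.
    """

    residue_index: int
    reference_residue: str
    column_residues: Dict[str, str]
    identity_fraction: float
    mammal_conserved: bool


def reference_column(msa: MSA, residue_index: int) -> int:
    """Alignment column (1-based) of the reference's residue_index-th
    non-gap character."""
    if residue_index < 1:
        raise ValueError("residue index must be >= 1")
    seen = 0
    for col, ch in enumerate(msa.sequences[msa.reference], start=1):
        if ch != "-":
            seen += 1
            if seen == residue_index:
                return col
    raise ValueError(
        f"reference has only {seen} residues, asked for {residue_index}"
    )


def conservation_at(msa: MSA, residue_index: int,
                    mammal_ids: Sequence[str] = DEFAULT_MAMMALS
                    ) -> ConservationResult:
    """Column identity at a reference residue, plus a mammals-only flag."""
    for sp in mammal_ids:
        if sp not in msa.sequences:
            raise ValueError(f"species {sp!r} absent from the alignment")
    col = reference_column(msa, residue_index)
    column = {sp: seq[col - 1] for sp, seq in msa.sequences.items()}
    ref_res = column[msa.reference]
    non_gap = [r for r in column.values() if r != "-"]
    identity = sum(1 for r in non_gap if r == ref_res) / len(non_gap)
    mammal_ok = all(column[sp] == ref_res for sp in mammal_ids)
    return ConservationResult(
        residue_index=residue_index,
        reference_residue=ref_res,
        column_residues=column,
        identity_fraction=identity,
        mammal_conserved=mammal_ok,
    )
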