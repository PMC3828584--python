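"""Core domain types shared across the pipeline.

A variant is always biallelic here: multi-allelic VCF rows are split on
read, each alternate allele becoming its own :class:`VariantRecord` with
genotypes recoded against that allele. Genotypes are unphased; parental
origin of alleles is inferred from parental genotypes, never from phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class Genotype:
    """Unordered, unphased diploid genotype against a single alt allele.

    Each allele is 0 (ref), 1 (alt) or None (missing). A genotype with any
    missing allele is treated as missing as a whole: segregation logic
    fails closed on it.
    """

    alleles: tuple

    def __post_init__(self):
        if len(self.alleles) != 2:
            raise ValueError("diploid genotypes only")
        for a in self.alleles:
            if a not in (0, 1, None):
                raise ValueError(f"allele must be 0, 1 or None, got {a!r}")
        # canonical order so 1/0 == 0/1
        object.__setattr__(
            self, "alleles",
            tuple(sorted(self.alleles, key=lambda a: (a is None, a)))
        )

    @property
    def is_missing(self) -> bool:
        return None in self.alleles

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles == (0, 0)

    @property
    def is_het(self) -> bool:
        return self.alleles == (0, 1)

    @property
    def is_hom_alt(self) -> bool:
        return self.alleles == (1, 1)

    @property
    def carries_alt(self) -> bool:
        return 1 in self.alleles

    def vcf_string(self) -> str:
        return "/".join("." if a is None else str(a) for a in self.alleles)

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        parts = s.replace("|", "/").split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse genotype {s!r}")
        return cls(tuple(None if p == "." else int(p) for p in parts))


MISSING = Genotype((None, None))
HOM_REF = Genotype((0, 0))
HET = Genotype((0, 1))
HOM_ALT = Genotype((1, 1))


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site with per-sample genotypes.

    ``pos`` is the 1-based genomic coordinate of the first reference base,
    as in VCF. Interval arithmetic elsewhere converts to 0-based half-open.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict  # sample id -> Genotype

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1

    def genotype(self, sample: str) -> Genotype:
        return self.genotypes.get(sample, MISSING)


@dataclass(frozen=True)
class Pedigree:
    """A nuclear family with unaffected parents and affected children.

    Models the quad design (two parents, two affected siblings) but any
    number >= 1 of affected children is accepted.
    """

    family_id: str
    father: str
    mother: str
    affected_children: tuple

    def __post_init__(self):
        object.__setattr__(self, "affected_children",
                           tuple(self.affected_children))
        ids = [self.father, self.mother, *self.affected_children]
        if len(set(ids)) != len(ids):
            raise ValueError("pedigree sample ids must be distinct")
        if not self.affected_children:
            raise ValueError("need at least one affected child")

    @property
    def samples(self) -> tuple:
        return (self.father, self.mother, *self.affected_children)


@dataclass
class SiteSet:
    """A known-variant site database: exact (chrom, pos, ref, alt) membership."""

    name: str
    sites: set = field(default_factory=set)

    def __contains__(self, key) -> bool:
        if isinstance(key, VariantRecord):
            key = key.key
        return tuple(key) in self.sites

    def add(self, chrom, pos, ref, alt):
        self.sites.add((str(chrom), int(pos), str(ref), str(alt)))

    def __len__(self):
        return len(self.sites)


@dataclass(frozen=True)
class GeneList:
    """Case-normalized set of gene symbols (upper-cased on construction)."""

    genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "genes",
                           frozenset(g.upper() for g in self.genes))
        if not self.genes:
            raise ValueError("gene list must be non-empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes

    def __len__(self):
        return len(self.genes)


@dataclass
class MSA:
    """A protein multiple sequence alignment keyed by species id.

    All aligned strings have equal length; one sequence is the reference
    against which ungapped residue indices are interpreted.
    """

    sequences: dict  # species id -> aligned residue string (may contain '-')
    reference: str

    def __post_init__(self):
        if self.reference not in self.sequences:
            raise ValueError(f"reference {self.reference!r} not in alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences have unequal lengths")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def species(self) -> list:
        return list(self.sequences)
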