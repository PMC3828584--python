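"""Shared fixtures and builders for the test suite.

Toy genes are constructed explicitly (exon layout and CDS chosen by the
test), so expected coordinates can be computed by independent arithmetic
rather than by the code under test.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from quadvar.annotation import GeneModel, GeneModelSet
from quadvar.simulate import NONSTOP_CODONS, _random_dna
from quadvar.types import Genotype, Pedigree, VariantRecord

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP[b] for b in reversed(s))


@pytest.fixture
def quad() -> Pedigree:
    return Pedigree(family_id="F1", father="FA", mother="MO",
                    affected_children=("C1", "C2"))


def gt(s: str) -> Genotype:
    return Genotype.from_string(s)


def make_record(chrom, pos, ref, alt, pedigree: Pedigree,
                father="0/0", mother="0/0", children=("0/0", "0/0")
                ) -> VariantRecord:
    gts = {pedigree.father: gt(father), pedigree.mother: gt(mother)}
    for sample, g in zip(pedigree.affected_children, children):
        gts[sample] = gt(g)
    return VariantRecord(chrom, pos, ref, alt, gts)


def make_plus_gene(cds: str, exon_coding_lens: Sequence[int],
                   intron_lens: Sequence[int], chrom="toy", symbol="TOY",
                   pad=10, utr5=4, utr3=5,
                   intron_seqs: Optional[Sequence[str]] = None,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[GeneModel, str]:
    """Explicit plus-strand gene. CDS split into the given exon chunks;
    introns either given literally or drawn from rng."""
    assert sum(exon_coding_lens) == len(cds)
    assert len(intron_lens) == len(exon_coding_lens) - 1
    rng = rng or np.random.default_rng(0)
    if intron_seqs is None:
        intron_seqs = [_random_dna(rng, n) for n in intron_lens]
    chunks, off = [], 0
    for ln in exon_coding_lens:
        chunks.append(cds[off:off + ln])
        off += ln
    utr5_seq = _random_dna(rng, utr5)
    utr3_seq = _random_dna(rng, utr3)
    exon_seqs = list(chunks)
    exon_seqs[0] = utr5_seq + exon_seqs[0]
    exon_seqs[-1] = exon_seqs[-1] + utr3_seq
    parts = [_random_dna(rng, pad)]
    coords = []
    cursor = pad
    for i, ex in enumerate(exon_seqs):
        coords.append((cursor, cursor + len(ex)))
        parts.append(ex)
        cursor += len(ex)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            cursor += len(intron_seqs[i])
    parts.append(_random_dna(rng, pad))
    seq = "".join(parts)
    model = GeneModel(
        gene_symbol=symbol, transcript_id=f"{symbol}.t1", chrom=chrom,
        strand="+", exons=tuple(coords),
        cds_start=coords[0][0] + utr5, cds_end=coords[-1][1] - utr3,
        cds_sequence=cds,
    )
    return model, seq


def mirror_gene(model: GeneModel, chrom_seq: str) -> Tuple[GeneModel, str]:
    """Reverse-complement the whole chromosome: coordinates flip, strand
    flips, the transcript (and its CDS) is unchanged."""
    L = len(chrom_seq)
    exons = tuple(sorted((L - e, L - s) for s, e in model.exons))
    return GeneModel(
        gene_symbol=model.gene_symbol, transcript_id=model.transcript_id,
        chrom=model.chrom, strand="-" if model.strand == "+" else "+",
        exons=exons, cds_start=L - model.cds_end, cds_end=L - model.cds_start,
        cds_sequence=model.cds_sequence,
    ), revcomp(chrom_seq)


def mirror_pos(pos_1based: int, chrom_len: int) -> int:
    return chrom_len - pos_1based + 1


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons - 1)
    return "ATG" + "".join(NONSTOP_CODONS[i] for i in idx)


def random_toy_gene(rng: np.random.Generator, symbol="TOY", chrom="toy"
                    ) -> Tuple[GeneModel, str]:
    """A random small multi-exon gene for property tests."""
    n_exons = int(rng.integers(2, 5))
    lens = [int(rng.integers(9, 45)) for _ in range(n_exons)]
    total = sum(lens)
    lens[-1] += (3 - total % 3) % 3
    cds = random_cds(rng, sum(lens) // 3)
    introns = [int(rng.integers(15, 60)) for _ in range(n_exons - 1)]
    return make_plus_gene(cds, lens, introns, chrom=chrom, symbol=symbol,
                          utr5=int(rng.integers(0, 8)),
                          utr3=int(rng.integers(0, 8)), rng=rng)


def flat_gene(symbol: str, chrom: str, n_codons: int = 100) -> GeneModel:
    """Single-exon gene whose whole exon is CDS; for segregation tests
    where only gene membership matters."""
    rng = np.random.default_rng(sum(ord(c) for c in symbol))
    cds = random_cds(rng, n_codons)
    return GeneModel(
        gene_symbol=symbol, transcript_id=f"{symbol}.t1", chrom=chrom,
        strand="+", exons=((0, len(cds)),), cds_start=0, cds_end=len(cds),
        cds_sequence=cds,
    )


def flat_models(n: int) -> GeneModelSet:
    return GeneModelSet(
        [flat_gene(f"G{i}", f"chr{i}") for i in range(1, n + 1)])


def mendelian_consistent(child: Genotype, father: Genotype,
                         mother: Genotype) -> bool:
    """True iff the child's genotype can arise from one allele of each
    parent (missing alleles treated as wildcards)."""
    def options(g):
        return {a for a in g.alleles} if not g.is_missing else {0, 1}
    if child.is_missing:
        return True
    a, b = child.alleles
    fo, mo = options(father), options(mother)
    return (a in fo and b in mo) or (b in fo and a in mo)
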