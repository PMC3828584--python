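"""Transcript coordinate arithmetic and consequence classification.

A :class:`GeneModel` is one canonical transcript: ordered exons, a CDS
span, and the spliced, strand-corrected coding sequence. Genomic
positions map onto CDS coordinates (1-based within the coding sequence)
or intron-offset coordinates (legacy IVS style: intron number plus a
signed distance, positive from the donor side, negative from the
acceptor side). Coding SNVs are classified by translating the reference
and mutant codon with the standard genetic code; intronic variants
within ``splice_window`` bases of an exon boundary are splice-region
candidates; coding indels are frameshift when the length change is not a
multiple of three.

Coordinates are 0-based half-open internally; variant positions are
1-based as in VCF and converted on entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .types import VariantRecord

log = logging.getLogger(__name__)

#: consequence categories retained by the functional filter
DAMAGING_CATEGORIES = frozenset(
    {"nonsynonymous", "stop_gain", "splice_region", "frameshift_indel"}
)

DEFAULT_SPLICE_WINDOW = 10


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon structure, CDS bounds and coding sequence.

    ``exons`` are genomic (start, end) half-open 0-based intervals sorted
    by genomic start; ``cds_start``/``cds_end`` delimit the coding span in
    genomic coordinates. ``cds_sequence`` is the spliced coding sequence
    in transcript orientation, excluding the terminal stop codon.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValueError("empty exon")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        protein = str(Seq(self.cds_sequence).translate())
        if "*" in protein:
            raise ValueError("internal stop codon in CDS")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def protein(self) -> str:
        return str(Seq(self.cds_sequence).translate())

    def cds_segments(self) -> List[Tuple[int, int]]:
        """Genomic intervals of the coding parts of each exon, ascending."""
        segs = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                segs.append((cs, ce))
        return segs

    def contains(self, pos_1based: int) -> bool:
        p = pos_1based - 1
        return self.tx_start <= p < self.tx_end


@dataclass(frozen=True)
class CdsCoordinate:
    """Position expressed against the coding sequence.

    kind 'coding': ``cds_pos`` is 1-based within the CDS. kind 'intronic':
    ``intron_index`` is the 1-based intron number in transcript order and
    ``offset`` the signed distance from the nearest exon boundary
    (positive from the donor/5' side, negative from the acceptor/3' side;
    never zero).
    """

    kind: str
    cds_pos: Optional[int] = None
    intron_index: Optional[int] = None
    offset: Optional[int] = None

    def __post_init__(self):
        if self.kind == "coding":
            if self.cds_pos is None or self.cds_pos < 1:
                raise ValueError("coding coordinate needs cds_pos >= 1")
        elif self.kind == "intronic":
            if self.offset == 0 or self.offset is None or self.intron_index is None:
                raise ValueError("intronic coordinate needs nonzero offset and intron")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass(frozen=True)
class Consequence:
    """Predicted effect of a variant on one transcript."""

    category: str
    protein_change: Optional[tuple] = None  # (ref_aa, residue_index, alt_aa)

    def __post_init__(self):
        coding_snv = self.category in ("nonsynonymous", "synonymous", "stop_gain")
        if coding_snv != (self.protein_change is not None):
            raise ValueError(
                "protein_change present iff category is a coding SNV class"
            )


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------

def cds_to_codon(cds_pos: int) -> Tuple[int, int]:
    """Map a 1-based CDS nucleotide position to (codon_index, offset 1..3).

    Codon ``k`` covers CDS positions ``3k-2 .. 3k``; e.g. position 8375
    is the second base of codon 2792.
    """
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


def _region(model: GeneModel, pos_1based: int) -> str:
    """Coarse location of one genomic base: coding/intronic/utr/intergenic."""
    p = pos_1based - 1
    if not (model.tx_start <= p < model.tx_end):
        return "intergenic"
    for s, e in model.exons:
        if s <= p < e:
            return "coding" if model.cds_start <= p < model.cds_end else "utr"
    return "intronic"


def genomic_to_cds(variant_or_pos, model: GeneModel) -> Optional[CdsCoordinate]:
    """Map a genomic position onto the transcript's CDS/intron coordinates.

    Returns None (the sentinel consumed by the classifier) for positions
    in UTR exon sequence or outside the transcript.
    """
    if isinstance(variant_or_pos, VariantRecord):
        pos_1based = variant_or_pos.pos
    else:
        pos_1based = int(variant_or_pos)
    p = pos_1based - 1
    region = _region(model, pos_1based)
    if region == "coding":
        acc = 0
        segs = model.cds_segments()
        if model.strand == "+":
            for s, e in segs:
                if s <= p < e:
                    return CdsCoordinate("coding", cds_pos=acc + (p - s) + 1)
                acc += e - s
        else:
            for s, e in reversed(segs):
                if s <= p < e:
                    return CdsCoordinate("coding", cds_pos=acc + (e - 1 - p) + 1)
                acc += e - s
        raise AssertionError("coding position not covered by CDS segments")
    if region != "intronic":
        return None
    for i in range(model.n_introns):
        left_end = model.exons[i][1]
        right_start = model.exons[i + 1][0]
        if left_end <= p < right_start:
            if model.strand == "+":
                intron = i + 1
                donor_off = p - left_end + 1
                acceptor_off = p - right_start  # negative
            else:
                intron = model.n_introns - i
                donor_off = right_start - p
                acceptor_off = -(p - left_end + 1)
            # nearest side wins; exact mid-intron ties go to the donor side
            if donor_off <= abs(acceptor_off):
                return CdsCoordinate("intronic", intron_index=intron, offset=donor_off)
            return CdsCoordinate("intronic", intron_index=intron, offset=acceptor_off)
    raise AssertionError("intronic position not bracketed by exons")


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Inverse of the coding branch of :func:`genomic_to_cds`: 1-based
    genomic position of a 1-based CDS position."""
    if not (1 <= cds_pos <= len(model.cds_sequence)):
        raise ValueError("cds_pos outside the CDS")
    remaining = cds_pos
    segs = model.cds_segments()
    if model.strand == "+":
        for s, e in segs:
            if remaining <= e - s:
                return s + remaining  # 0-based s + (remaining-1), then +1
            remaining -= e - s
    else:
        for s, e in reversed(segs):
            if remaining <= e - s:
                return e - remaining + 1
            remaining -= e - s
    raise AssertionError("unreachable")


def intron_offset_to_genomic(model: GeneModel, intron_index: int,
                             offset: int) -> int:
    """1-based genomic position of an intron-offset coordinate
    (transcript-order intron number, signed offset as in IVS naming)."""
    if not (1 <= intron_index <= model.n_introns) or offset == 0:
        raise ValueError("bad intron coordinate")
    if model.strand == "+":
        i = intron_index - 1
        left_end, right_start = model.exons[i][1], model.exons[i + 1][0]
        p = left_end + offset - 1 if offset > 0 else right_start + offset
    else:
        i = model.n_introns - intron_index
        left_end, right_start = model.exons[i][1], model.exons[i + 1][0]
        p = right_start - offset if offset > 0 else left_end - offset - 1
    if not (left_end <= p < right_start):
        raise ValueError("offset exceeds intron length")
    return p + 1


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

def _cdna_alleles(variant: VariantRecord, model: GeneModel) -> Tuple[str, str]:
    """Variant alleles in transcript (cDNA) orientation."""
    if model.strand == "+":
        return variant.ref, variant.alt
    return _revcomp(variant.ref), _revcomp(variant.alt)


def _classify_snv(variant: VariantRecord, model: GeneModel,
                  splice_window: int) -> Consequence:
    coord = genomic_to_cds(variant.pos, model)
    if coord is None:
        region = _region(model, variant.pos)
        return Consequence("utr" if region == "utr" else "intergenic")
    if coord.kind == "intronic":
        if abs(coord.offset) <= splice_window:
            return Consequence("splice_region")
        return Consequence("intronic")
    ref_c, alt_c = _cdna_alleles(variant, model)
    codon_index, offset = cds_to_codon(coord.cds_pos)
    codon = model.cds_sequence[3 * (codon_index - 1): 3 * codon_index]
    if codon[offset - 1] != ref_c:
        log.warning(
            "reference mismatch at %s:%d (model %s has %s, variant ref %s)",
            variant.chrom, variant.pos, model.transcript_id,
            codon[offset - 1], ref_c,
        )
    alt_codon = codon[: offset - 1] + alt_c + codon[offset:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    change = (ref_aa, codon_index, alt_aa)
    if alt_aa == "*":
        return Consequence("stop_gain", protein_change=change)
    if alt_aa == ref_aa:
        return Consequence("synonymous", protein_change=change)
    return Consequence("nonsynonymous", protein_change=change)


def _classify_indel(variant: VariantRecord, model: GeneModel,
                    splice_window: int) -> Consequence:
    # anchored VCF indels: the shared first base is not part of the change
    anchored = variant.ref[0] == variant.alt[0]
    if len(variant.alt) > len(variant.ref):  # insertion: point between bases
        span = (variant.pos, variant.pos + 1)
    elif anchored:
        span = (variant.pos + 1, variant.end)
    else:
        span = (variant.pos, variant.end)
    regions = {_region(model, p) for p in range(span[0], span[1] + 1)}
    if regions == {"intergenic"}:
        return Consequence("intergenic")
    if "coding" in regions and ("intronic" in regions or "intergenic" in regions):
        # the change disturbs an exon/intron boundary: retained conservatively
        return Consequence("splice_region")
    if regions == {"coding"} or regions == {"coding", "utr"}:
        delta = abs(len(variant.ref) - len(variant.alt))
        return Consequence(
            "frameshift_indel" if delta % 3 != 0 else "inframe_indel"
        )
    if "intronic" in regions:
        offsets = []
        for p in range(span[0], span[1] + 1):
            c = genomic_to_cds(p, model)
            if c is not None and c.kind == "intronic":
                offsets.append(abs(c.offset))
        if offsets and min(offsets) <= splice_window:
            return Consequence("splice_region")
        return Consequence("intronic")
    return Consequence("utr")


def classify_consequence(variant: VariantRecord, model: GeneModel,
                         splice_window: int = DEFAULT_SPLICE_WINDOW) -> Consequence:
    """Predict the effect of one variant on one transcript."""
    if variant.chrom != model.chrom:
        return Consequence("intergenic")
    if variant.is_snv:
        return _classify_snv(variant, model, splice_window)
    return _classify_indel(variant, model, splice_window)


# ---------------------------------------------------------------------------
# gene model collections and the functional filter
# ---------------------------------------------------------------------------

class GeneModelSet:
    """Gene models indexed by chromosome and symbol."""

    def __init__(self, models: Iterable[GeneModel]):
        self.models = list(models)
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        self._by_symbol: Dict[str, GeneModel] = {}
        for m in self.models:
            self._by_chrom.setdefault(m.chrom, []).append(m)
            self._by_symbol[m.gene_symbol] = m
        for lst in self._by_chrom.values():
            lst.sort(key=lambda m: m.tx_start)

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    @property
    def chromosomes(self):
        return set(self._by_chrom)

    def get(self, symbol: str) -> Optional[GeneModel]:
        return self._by_symbol.get(symbol)

    def models_at(self, chrom: str, pos_1based: int) -> List[GeneModel]:
        """All transcripts whose genomic span contains the position."""
        return [m for m in self._by_chrom.get(chrom, ())
                if m.contains(pos_1based)]


def annotate(variant: VariantRecord, models: GeneModelSet,
             splice_window: int = DEFAULT_SPLICE_WINDOW
             ) -> List[Tuple[GeneModel, Consequence]]:
    """Consequences of one variant against every overlapping transcript."""
    hits = models.models_at(variant.chrom, variant.pos)
    return [(m, classify_consequence(variant, m, splice_window)) for m in hits]


def functional_filter(records: Sequence[VariantRecord], models: GeneModelSet,
                      splice_window: int = DEFAULT_SPLICE_WINDOW
                      ) -> List[VariantRecord]:
    """Keep variants whose consequence on any overlapping transcript is
    nonsynonymous, stop-gain, splice-region or frameshift. Order preserved."""
    kept = []
    for rec in records:
        for _, csq in annotate(rec, models, splice_window):
            if csq.category in DAMAGING_CATEGORIES:
                kept.append(rec)
                break
    return kept


# ---------------------------------------------------------------------------
# HGVS / IVS naming
# ---------------------------------------------------------------------------

def hgvs_c_name(coord: CdsCoordinate, ref: str, alt: str) -> str:
    """Coding-DNA substitution name, e.g. ``c.8375T>C``. Alleles are given
    in cDNA orientation."""
    if coord.kind != "coding":
        raise ValueError("hgvs_c_name requires a coding coordinate")
    return f"c.{coord.cds_pos}{ref}>{alt}"


def hgvs_p_name(change: tuple) -> str:
    """Protein substitution name in single-letter code, e.g. ``p.V2792A``."""
    ref_aa, index, alt_aa = change
    return f"p.{ref_aa}{index}{alt_aa}"


def ivs_name(coord: CdsCoordinate, ref: str, alt: str) -> str:
    """Legacy intron-variant name, e.g. ``IVS25+3G>A``. Alleles are given
    in cDNA (sense-strand) orientation."""
    if coord.kind != "intronic":
        raise ValueError("ivs_name requires an intronic coordinate")
    sign = "+" if coord.offset > 0 else "-"
    return f"IVS{coord.intron_index}{sign}{abs(coord.offset)}{ref}>{alt}"


def name_variant(variant: VariantRecord, model: GeneModel) -> str:
    """Render a variant in the notation appropriate to its location:
    HGVS c. for coding positions, legacy IVS for intronic ones."""
    coord = genomic_to_cds(variant.pos, model)
    if coord is None:
        return f"{variant.chrom}:g.{variant.pos}{variant.ref}>{variant.alt}"
    ref_c, alt_c = _cdna_alleles(variant, model)
    if coord.kind == "coding":
        return hgvs_c_name(coord, ref_c, alt_c)
    return ivs_name(coord, ref_c, alt_c)


# ---------------------------------------------------------------------------
# BED12 + genome FASTA input
# ---------------------------------------------------------------------------

def model_from_bed12(line: str, genome) -> GeneModel:
    """Build a GeneModel from one BED12 line and a sequence source.

    The name column is ``SYMBOL`` or ``SYMBOL|TRANSCRIPT``; thickStart and
    thickEnd delimit the CDS. ``genome`` is any mapping of chromosome to
    sliceable sequence (a ``pyfaidx.Fasta`` works).
    """
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"BED12 line needs 12 columns: {line!r}")
    chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
    strand = f[5]
    thick_start, thick_end = int(f[6]), int(f[7])
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError("blockCount inconsistent with blockSizes/blockStarts")
    exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
    if exons[-1][1] != end:
        raise ValueError("last block does not end at chromEnd")
    symbol, _, transcript = name.partition("|")
    transcript = transcript or f"{symbol}.t1"
    segs = []
    for s, e in exons:
        cs, ce = max(s, thick_start), min(e, thick_end)
        if cs < ce:
            segs.append((cs, ce))
    seq = "".join(str(genome[chrom][s:e]) for s, e in segs)
    if strand == "-":
        seq = _revcomp(seq)
    return GeneModel(
        gene_symbol=symbol, transcript_id=transcript, chrom=chrom,
        strand=strand, exons=exons, cds_start=thick_start,
        cds_end=thick_end, cds_sequence=seq.upper(),
    )


def read_gene_models(bed_path, genome_fasta_path) -> GeneModelSet:
    """Read gene models from a BED12 file plus a genome FASTA."""
    import pyfaidx

    genome = pyfaidx.Fasta(str(genome_fasta_path))
    models = []
    for line in Path(bed_path).read_text().splitlines():
        if line.strip() and not line.startswith(("#", "track", "browser")):
            models.append(model_from_bed12(line, genome))
    return GeneModelSet(models)


def bed12_line(model: GeneModel) -> str:
    """Serialise a GeneModel back to one BED12 line."""
    sizes = ",".join(str(e - s) for s, e in model.exons)
    starts = ",".join(str(s - model.tx_start) for s, e in model.exons)
    name = f"{model.gene_symbol}|{model.transcript_id}"
    return "\t".join(str(x) for x in (
        model.chrom, model.tx_start, model.tx_end, name, 0, model.strand,
        model.cds_start, model.cds_end, 0, len(model.exons), sizes, starts,
    ))
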