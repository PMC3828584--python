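"""Synthetic quad-exome datasets with a planted causal recessive gene.

The generator emulates the statistical structure the filtering cascade
assumes: a nuclear family of two unaffected parents and two affected
siblings; a toy genome of multi-exon genes (one chromosome per gene, so
coordinates are trivially valid); background variation drawn under
Mendelian transmission from random parental genotypes, most of it
present in the site databases; near-miss decoy genes (cis-only compound
pairs, homozygous-lookalikes with a homozygous parent, and causal
lookalikes that are catalogued in a database); and one planted causal
gene. In compound-het mode the plant mirrors the family the model was
built around: a maternally transmitted intronic SNV three bases into a
donor site plus a paternally transmitted coding nonsynonymous SNV, both
heterozygous in both children.

Background genotypes are rejection-sampled so that no gene other than
the planted one can satisfy the recessive rule after the functional and
database filters: background variation is, by design, non-causal, which
makes planted-gene recovery a sharp property rather than a seed lottery.

All randomness flows from one ``numpy`` generator seeded by the config,
in a fixed draw order, so identical configs produce byte-identical
datasets. Genotype missingness is driven by per-genotype uniforms that
depend only on the seed and the genotype's position in the dataset, so
the set of missing genotypes at a lower rate is a subset of the set at
any higher rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import io_formats
from .annotation import (
    DAMAGING_CATEGORIES,
    GeneModel,
    GeneModelSet,
    bed12_line,
    cds_to_genomic,
    classify_consequence,
    genomic_to_cds,
    intron_offset_to_genomic,
    name_variant,
)
from .segregation import (
    assign_parental_origin,
    homozygous_qualifies,
)
from .types import HET, HOM_ALT, HOM_REF, MISSING, Genotype, Pedigree, VariantRecord

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                  if a + b + c not in STOPS]


@dataclass
class SimConfig:
    """Knobs of the synthetic quad-exome dataset.

    Defaults describe the standard desk-scale study condition: 200 toy
    genes, 1500 background variants of which 90% are catalogued in the
    site databases (roughly the known fraction in an outbred exome),
    three decoys of each near-miss kind, no missing genotypes, and a
    compound-het plant.
    """

    seed: int = 0
    n_genes: int = 200
    exons_per_gene: Tuple[int, int] = (3, 8)
    exon_coding_length: Tuple[int, int] = (60, 240)
    intron_length: Tuple[int, int] = (40, 120)
    utr_length: Tuple[int, int] = (10, 60)
    n_background_variants: int = 1500
    background_alt_freq: float = 0.3
    background_indel_rate: float = 0.05
    db_membership_rate: float = 0.9
    planted_gene: Optional[str] = None  # None -> chosen by the generator
    planted_mode: str = "compound_het"  # or "homozygous"
    missingness_rate: float = 0.0
    n_decoys_per_kind: int = 3
    n_gene_list_distractors: int = 9
    family_id: str = "F4792"

    def __post_init__(self):
        for p in (self.background_alt_freq, self.db_membership_rate,
                  self.missingness_rate, self.background_indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_mode not in ("compound_het", "homozygous"):
            raise ValueError(f"unknown planted_mode {self.planted_mode!r}")
        needed = 1 + 3 * self.n_decoys_per_kind
        if self.n_background_variants > 0:
            needed += 1  # at least one gene free to host background variation
        if self.n_genes < needed:
            raise ValueError("too few genes for the requested decoys/background")


@dataclass
class TruthSet:
    """Ground truth of one simulated dataset."""

    causal_gene: str
    causal_mode: str
    causal_variants: List[dict]  # chrom/pos/ref/alt/origin/name
    decoys: List[dict]  # gene/reason
    causal_residue: Optional[int] = None  # residue of the coding plant

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        return cls(**json.loads(text))


def default_pedigree(family_id: str = "F4792") -> Pedigree:
    return Pedigree(family_id=family_id, father="I1", mother="I2",
                    affected_children=("II1", "II2"))


# ---------------------------------------------------------------------------
# gene model generation
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons - 1)
    return "ATG" + "".join(NONSTOP_CODONS[i] for i in idx)


def _build_gene(rng: np.random.Generator, symbol: str, chrom: str,
                config: SimConfig) -> Tuple[GeneModel, str]:
    """One random multi-exon gene and its chromosome sequence."""
    lo, hi = config.exons_per_gene
    n_exons = int(rng.integers(lo, hi + 1))
    elo, ehi = config.exon_coding_length
    coding_lens = [int(rng.integers(elo, ehi + 1)) for _ in range(n_exons)]
    total = sum(coding_lens)
    coding_lens[-1] += (3 - total % 3) % 3  # pad to a codon multiple
    total = sum(coding_lens)
    cds = _random_cds(rng, total // 3)
    # split CDS into transcript-order exon chunks
    chunks, off = [], 0
    for ln in coding_lens:
        chunks.append(cds[off:off + ln])
        off += ln
    ulo, uhi = config.utr_length
    utr5 = _random_dna(rng, int(rng.integers(ulo, uhi + 1)))
    utr3 = _random_dna(rng, int(rng.integers(ulo, uhi + 1)))
    strand = "+" if rng.random() < 0.5 else "-"
    # transcript-order exon sequences including UTRs
    tx_exons = list(chunks)
    tx_exons[0] = utr5 + tx_exons[0]
    tx_exons[-1] = tx_exons[-1] + utr3
    if strand == "+":
        genomic_exons = tx_exons
    else:
        from .annotation import _revcomp
        genomic_exons = [_revcomp(s) for s in reversed(tx_exons)]
    ilo, ihi = config.intron_length
    introns = [_random_dna(rng, int(rng.integers(ilo, ihi + 1)))
               for _ in range(n_exons - 1)]
    pad = 100
    seq_parts = [_random_dna(rng, pad)]
    exon_coords = []
    cursor = pad
    for i, ex in enumerate(genomic_exons):
        exon_coords.append((cursor, cursor + len(ex)))
        seq_parts.append(ex)
        cursor += len(ex)
        if i < len(introns):
            seq_parts.append(introns[i])
            cursor += len(introns[i])
    seq_parts.append(_random_dna(rng, pad))
    chrom_seq = "".join(seq_parts)
    if strand == "+":
        cds_start = exon_coords[0][0] + len(utr5)
        cds_end = exon_coords[-1][1] - len(utr3)
    else:
        cds_start = exon_coords[0][0] + len(utr3)
        cds_end = exon_coords[-1][1] - len(utr5)
    model = GeneModel(
        gene_symbol=symbol, transcript_id=f"{symbol}.t1", chrom=chrom,
        strand=strand, exons=tuple(exon_coords),
        cds_start=cds_start, cds_end=cds_end, cds_sequence=cds,
    )
    return model, chrom_seq


def generate_gene_models(config: SimConfig,
                         rng: Optional[np.random.Generator] = None
                         ) -> Tuple[GeneModelSet, Dict[str, str]]:
    """Random toy genes, one per chromosome, with valid CDS structure."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    models, genome = [], {}
    width = max(3, len(str(config.n_genes)))
    for i in range(1, config.n_genes + 1):
        symbol = f"GENE{i:0{width}d}"
        chrom = f"chr{i:0{width}d}"
        model, seq = _build_gene(rng, symbol, chrom, config)
        models.append(model)
        genome[chrom] = seq
    return GeneModelSet(models), genome


# ---------------------------------------------------------------------------
# variant construction helpers
# ---------------------------------------------------------------------------

def _genomic_allele(model: GeneModel, base: str) -> str:
    from .annotation import _revcomp
    return base if model.strand == "+" else _revcomp(base)


def _make_nonsyn_snv(model: GeneModel, rng: np.random.Generator
                     ) -> Tuple[int, str, str, int]:
    """A nonsynonymous (non-stop) coding SNV on the model.

    Returns (genomic 1-based pos, genomic ref, genomic alt, residue index).
    """
    from Bio.Seq import Seq

    n_codons = len(model.cds_sequence) // 3
    while True:
        codon_index = int(rng.integers(2, n_codons + 1))
        offset = int(rng.integers(1, 4))
        codon = model.cds_sequence[3 * (codon_index - 1): 3 * codon_index]
        ref_base = codon[offset - 1]
        alt_base = BASES[int(rng.integers(0, 4))]
        if alt_base == ref_base:
            continue
        alt_codon = codon[:offset - 1] + alt_base + codon[offset:]
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == ref_aa or alt_aa == "*":
            continue
        cds_pos = 3 * (codon_index - 1) + offset
        pos = cds_to_genomic(model, cds_pos)
        return (pos, _genomic_allele(model, ref_base),
                _genomic_allele(model, alt_base), codon_index)


def _make_donor_plus3_snv(model: GeneModel, genome: Dict[str, str],
                          rng: np.random.Generator) -> Tuple[int, str, str, int]:
    """An intronic SNV at donor offset +3 of a random intron.

    Returns (genomic pos, ref, alt, intron index). Mimics a G>A change at
    the third base of the donor site when the reference allows it.
    """
    if model.n_introns == 0:
        raise ValueError(f"{model.gene_symbol} has no intron to mutate")
    intron = int(rng.integers(1, model.n_introns + 1))
    pos = intron_offset_to_genomic(model, intron, +3)
    ref = genome[model.chrom][pos - 1]
    sense_ref = _genomic_allele(model, ref)
    sense_alt = "A" if sense_ref == "G" else ("G" if sense_ref != "G" else "A")
    if sense_alt == sense_ref:
        sense_alt = "C"
    alt = _genomic_allele(model, sense_alt)
    return pos, ref, alt, intron


def _quad_genotypes(pedigree: Pedigree, father: Genotype, mother: Genotype,
                    children: Genotype) -> Dict[str, Genotype]:
    gts = {pedigree.father: father, pedigree.mother: mother}
    for c in pedigree.affected_children:
        gts[c] = children
    return gts


def plant_causal(config: SimConfig, models: GeneModelSet,
                 genome: Dict[str, str], pedigree: Pedigree,
                 rng: np.random.Generator, planted_symbol: str
                 ) -> Tuple[List[VariantRecord], TruthSet]:
    """Plant the causal variants into the chosen gene.

    compound_het mode: a maternal intronic donor+3 SNV and a paternal
    coding nonsynonymous SNV, both het in every affected child, each het
    in exactly one parent. homozygous mode: one coding nonsynonymous SNV,
    hom-alt in the children and het in both parents.
    """
    model = models.get(planted_symbol)
    if model is None:
        raise ValueError(f"planted gene {planted_symbol} not in models")
    records, truth_vars = [], []
    residue = None
    if config.planted_mode == "compound_het":
        ipos, iref, ialt, _ = _make_donor_plus3_snv(model, genome, rng)
        cpos, cref, calt, residue = _make_nonsyn_snv(model, rng)
        while cpos == ipos:  # paranoid: distinct sites
            cpos, cref, calt, residue = _make_nonsyn_snv(model, rng)
        rec_i = VariantRecord(model.chrom, ipos, iref, ialt,
                              _quad_genotypes(pedigree, HOM_REF, HET, HET))
        rec_c = VariantRecord(model.chrom, cpos, cref, calt,
                              _quad_genotypes(pedigree, HET, HOM_REF, HET))
        for rec, origin in ((rec_i, "mother"), (rec_c, "father")):
            records.append(rec)
            truth_vars.append({
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alt, "origin": origin,
                "name": name_variant(rec, model),
            })
    else:
        cpos, cref, calt, residue = _make_nonsyn_snv(model, rng)
        rec = VariantRecord(model.chrom, cpos, cref, calt,
                            _quad_genotypes(pedigree, HET, HET, HOM_ALT))
        records.append(rec)
        truth_vars.append({
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
            "alt": rec.alt, "origin": "both",
            "name": name_variant(rec, model),
        })
    truth = TruthSet(causal_gene=planted_symbol,
                     causal_mode=config.planted_mode,
                     causal_variants=truth_vars, decoys=[],
                     causal_residue=residue)
    return records, truth


def _make_decoys(config: SimConfig, models: GeneModelSet,
                 genome: Dict[str, str], pedigree: Pedigree,
                 rng: np.random.Generator, decoy_symbols: List[str],
                 db_keys: set) -> Tuple[List[VariantRecord], List[dict]]:
    """Near-miss genes: each fails the cascade for one labelled reason."""
    records, decoy_truth = [], []
    kinds = (["cis_pair"] * config.n_decoys_per_kind
             + ["parent_hom_alt"] * config.n_decoys_per_kind
             + ["in_database_pair"] * config.n_decoys_per_kind)
    for symbol, kind in zip(decoy_symbols, kinds):
        model = models.get(symbol)
        if kind == "cis_pair":
            # two damaging variants, both transmitted by the mother: cis
            for _ in range(2):
                pos, ref, alt, _ = _make_nonsyn_snv(model, rng)
                records.append(VariantRecord(
                    model.chrom, pos, ref, alt,
                    _quad_genotypes(pedigree, HOM_REF, HET, HET)))
            reason = "compound pair in cis (single-parent origin)"
        elif kind == "parent_hom_alt":
            # children homozygous but the father is too: not recessive-quad
            pos, ref, alt, _ = _make_nonsyn_snv(model, rng)
            records.append(VariantRecord(
                model.chrom, pos, ref, alt,
                _quad_genotypes(pedigree, HOM_ALT, HET, HOM_ALT)))
            reason = "homozygous lookalike with homozygous unaffected parent"
        else:
            # a genuine trans pair, but catalogued in the site database
            ipos, iref, ialt, _ = _make_donor_plus3_snv(model, genome, rng)
            cpos, cref, calt, _ = _make_nonsyn_snv(model, rng)
            r1 = VariantRecord(model.chrom, ipos, iref, ialt,
                               _quad_genotypes(pedigree, HOM_REF, HET, HET))
            r2 = VariantRecord(model.chrom, cpos, cref, calt,
                               _quad_genotypes(pedigree, HET, HOM_REF, HET))
            records.extend([r1, r2])
            db_keys.add(r1.key)
            db_keys.add(r2.key)
            reason = "causal lookalike present in a site database"
        decoy_truth.append({"gene": symbol, "reason": reason})
    return records, decoy_truth


# ---------------------------------------------------------------------------
# background variation
# ---------------------------------------------------------------------------

def _draw_parent_gt(rng: np.random.Generator, p: float) -> Genotype:
    return Genotype(tuple(sorted(int(rng.random() < p) for _ in range(2))))


def _transmit(rng: np.random.Generator, father: Genotype, mother: Genotype
              ) -> Genotype:
    a = father.alleles[int(rng.integers(0, 2))]
    b = mother.alleles[int(rng.integers(0, 2))]
    return Genotype(tuple(sorted((a, b))))


class _GeneGuard:
    """Tracks damaging, novel variants per gene and vetoes genotype draws
    that would let a background gene satisfy the recessive rule."""

    def __init__(self):
        self.origins: Dict[str, set] = {}

    def dangerous(self, gene: str, rec: VariantRecord, pedigree: Pedigree) -> bool:
        if homozygous_qualifies(rec, pedigree):
            return True
        if not all(rec.genotype(c).is_het for c in pedigree.affected_children):
            return False
        if (rec.genotype(pedigree.father).is_hom_alt
                or rec.genotype(pedigree.mother).is_hom_alt):
            return False
        origin = assign_parental_origin(rec, pedigree)
        if origin not in ("mother", "father"):
            return False
        other = "father" if origin == "mother" else "mother"
        return other in self.origins.get(gene, set())

    def register(self, gene: str, rec: VariantRecord, pedigree: Pedigree):
        if not all(rec.genotype(c).is_het for c in pedigree.affected_children):
            return
        origin = assign_parental_origin(rec, pedigree)
        if origin in ("mother", "father"):
            self.origins.setdefault(gene, set()).add(origin)


def generate_background(config: SimConfig, models: GeneModelSet,
                        genome: Dict[str, str], pedigree: Pedigree,
                        rng: np.random.Generator,
                        excluded_genes: set, db_keys: set,
                        used_keys: set) -> List[VariantRecord]:
    """Background variants under Mendelian transmission.

    Parental genotypes are drawn at the configured alt-allele frequency
    and each child inherits one allele from each parent, so every
    background genotype is Mendelian-consistent by construction. A
    fraction ``db_membership_rate`` of sites is catalogued into the
    databases. Genotype draws that would complete a qualifying recessive
    pattern in a novel, damaging state are redrawn (see module docstring).
    """
    eligible = [m for m in models if m.gene_symbol not in excluded_genes]
    guard = _GeneGuard()
    records = []
    for _ in range(config.n_background_variants):
        model = eligible[int(rng.integers(0, len(eligible)))]
        # site: uniform within the transcript span, redrawn on collision
        for _ in range(50):
            pos = int(rng.integers(model.tx_start + 1, model.tx_end + 1))
            is_indel = rng.random() < config.background_indel_rate
            chrom_seq = genome[model.chrom]
            if is_indel:
                if rng.random() < 0.5 and pos + 3 <= len(chrom_seq):  # deletion
                    dlen = int(rng.integers(1, 4))
                    ref = chrom_seq[pos - 1: pos + dlen]
                    alt = ref[0]
                else:  # insertion
                    ref = chrom_seq[pos - 1]
                    alt = ref + _random_dna(rng, int(rng.integers(1, 4)))
            else:
                ref = chrom_seq[pos - 1]
                alt = BASES[int(rng.integers(0, 4))]
                if alt == ref:
                    alt = BASES[(BASES.index(ref) + 1) % 4]
            if (model.chrom, pos, ref, alt) not in used_keys:
                break
        else:
            continue  # pathological collision streak; drop this draw
        used_keys.add((model.chrom, pos, ref, alt))
        in_db = rng.random() < config.db_membership_rate
        csq = None
        # genotypes: redraw while the pattern would create a false candidate
        for _ in range(100):
            f = _draw_parent_gt(rng, config.background_alt_freq)
            m = _draw_parent_gt(rng, config.background_alt_freq)
            gts = {pedigree.father: f, pedigree.mother: m}
            for c in pedigree.affected_children:
                gts[c] = _transmit(rng, f, m)
            rec = VariantRecord(model.chrom, pos, ref, alt, gts)
            if in_db:
                break
            if csq is None:
                csq = classify_consequence(rec, model)
            if csq.category not in DAMAGING_CATEGORIES:
                break
            if not guard.dangerous(model.gene_symbol, rec, pedigree):
                break
        else:
            # could not find a safe pattern; make the site catalogued
            in_db = True
        if in_db:
            db_keys.add(rec.key)
        elif csq is not None and csq.category in DAMAGING_CATEGORIES:
            guard.register(model.gene_symbol, rec, pedigree)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# missingness and the MSA fixture
# ---------------------------------------------------------------------------

def apply_missingness(records: List[VariantRecord], pedigree: Pedigree,
                      rate: float, seed: int) -> List[VariantRecord]:
    """Blank genotypes with per-genotype uniforms derived only from the
    seed and position, so missing sets are nested across rates."""
    if rate <= 0.0:
        return list(records)
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        gts = {}
        for sample in pedigree.samples:
            u = rng.random()
            gts[sample] = MISSING if u < rate else rec.genotype(sample)
        out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt, gts))
    return out


#: species ids of the synthetic 9-way alignment, mammals first
MSA_SPECIES = ("human", "chimpanzee", "macaque", "cow", "dog", "mouse",
               "rat", "chicken", "zebrafish")


def make_msa_fixture(model: GeneModel, conserved_residue: int,
                     rng: np.random.Generator) -> Dict[str, str]:
    """A synthetic nine-species protein alignment for the planted gene.

    The human row is the gene's translated CDS; other mammals diverge at
    ~4% of positions and distant vertebrates at ~20% (with occasional
    gaps), but every mammal is kept identical to human at the conserved
    residue's column. The distant species may or may not match there.
    """
    ref = model.protein
    n = len(ref)
    seqs = {"human": ref}
    for sp in MSA_SPECIES[1:]:
        mammal = sp not in ("chicken", "zebrafish")
        sub_rate = 0.04 if mammal else 0.20
        gap_rate = 0.0 if mammal else 0.02
        chars = list(ref)
        for i in range(n):
            if i == conserved_residue - 1 and mammal:
                continue
            u = rng.random()
            if u < gap_rate:
                chars[i] = "-"
            elif u < gap_rate + sub_rate:
                chars[i] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
        seqs[sp] = "".join(chars)
    return seqs


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """In-memory view of a simulated dataset plus its file paths."""

    config: SimConfig
    pedigree: Pedigree
    models: GeneModelSet
    genome: Dict[str, str]
    records: List[VariantRecord]
    site_dbs: Dict[str, set]
    gene_list: List[str]
    msa_sequences: Dict[str, str]
    truth: TruthSet


def simulate_dataset(config: SimConfig) -> Dataset:
    """Generate the full dataset in memory (no files written)."""
    rng = np.random.default_rng(config.seed)
    models, genome = generate_gene_models(config, rng)
    pedigree = default_pedigree(config.family_id)
    symbols = [m.gene_symbol for m in models]
    if config.planted_gene is None:
        planted = symbols[int(rng.integers(0, len(symbols)))]
    else:
        planted = config.planted_gene
        if planted not in symbols:
            raise ValueError(f"planted gene {planted} not among generated genes")
    if config.planted_mode == "compound_het":
        planted_model = models.get(planted)
        if planted_model.n_introns == 0:
            raise ValueError("compound_het plant needs an intron")
    others = [s for s in symbols if s != planted]
    decoy_idx = rng.choice(len(others), size=3 * config.n_decoys_per_kind,
                           replace=False)
    decoy_symbols = [others[i] for i in sorted(decoy_idx)]

    db_keys_dbsnp: set = set()
    db_keys_kg: set = set()
    shared_db_keys: set = set()

    causal_records, truth = plant_causal(config, models, genome, pedigree,
                                         rng, planted)
    decoy_records, decoy_truth = _make_decoys(
        config, models, genome, pedigree, rng, decoy_symbols, shared_db_keys)
    truth.decoys = decoy_truth
    used_keys = {r.key for r in causal_records + decoy_records}
    excluded = set(decoy_symbols) | {planted}
    background = generate_background(config, models, genome, pedigree, rng,
                                     excluded, shared_db_keys, used_keys)
    # distribute catalogued sites over the two databases: dbSNP-like gets
    # everything, the 1000G-like list an independent half
    for key in sorted(shared_db_keys):
        db_keys_dbsnp.add(key)
        if rng.random() < 0.5:
            db_keys_kg.add(key)

    records = sorted(causal_records + decoy_records + background,
                     key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    records = apply_missingness(records, pedigree, config.missingness_rate,
                                config.seed + 10_007)

    # distractors for the phenotype gene list: decoys first, then the rest
    pool = decoy_symbols + [s for s in others if s not in set(decoy_symbols)]
    n_distract = min(config.n_gene_list_distractors, len(pool))
    distract_idx = rng.choice(len(pool), size=n_distract, replace=False)
    gene_list = sorted({planted, *(pool[i] for i in distract_idx)})

    planted_model = models.get(planted)
    residue = truth.causal_residue or max(1, len(planted_model.protein) // 2)
    msa = make_msa_fixture(planted_model, residue, rng)

    return Dataset(
        config=config, pedigree=pedigree, models=models, genome=genome,
        records=records,
        site_dbs={"dbsnp_like": db_keys_dbsnp, "thousandg_like": db_keys_kg},
        gene_list=gene_list, msa_sequences=msa, truth=truth,
    )


def write_dataset(config: SimConfig, outdir) -> TruthSet:
    """Generate and write a complete dataset directory.

    Files: genome.fa, genes.bed, quad.vcf, family.ped, two site-database
    TSVs, deafness_genes.txt, msa.fasta (synthetic alignment), truth.json
    and the config as config.yaml. Identical configs give byte-identical
    directories.
    """
    ds = simulate_dataset(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "genome.fa", "w") as fh:
        for chrom in sorted(ds.genome):
            fh.write(f">{chrom}\n")
            seq = ds.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    (out / "genes.bed").write_text(
        "\n".join(bed12_line(m) for m in ds.models) + "\n")
    io_formats.write_vcf(ds.records, ds.pedigree, out / "quad.vcf")
    io_formats.write_ped(ds.pedigree, out / "family.ped")
    for name, keys in ds.site_dbs.items():
        lines = [f"{c}\t{p}\t{r}\t{a}" for c, p, r, a in sorted(keys)]
        (out / f"{name}.sites.tsv").write_text(
            "\n".join(lines) + ("\n" if lines else ""))
    (out / "deafness_genes.txt").write_text("\n".join(ds.gene_list) + "\n")
    with open(out / "msa.fasta", "w") as fh:
        for sp in MSA_SPECIES:
            fh.write(f">{sp}\n{ds.msa_sequences[sp]}\n")
    (out / "truth.json").write_text(ds.truth.to_json() + "\n")
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(ds.config), sort_keys=True))
    return ds.truth
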