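"""The autosomal-recessive segregation core.

Under a fully penetrant recessive model in a nuclear family with
unaffected parents and affected children, a causal gene carries either

* one variant homozygous-alt in every affected child with both parents
  heterozygous (shared homozygous mode), or
* two or more variants heterozygous in every affected child, with at
  least one of unambiguous maternal origin and one of unambiguous
  paternal origin (compound heterozygous in trans).

Parental origin is inferred from parental genotypes alone (genotypes are
unphased): a variant carried by exactly one parent has that parent as
its origin; carried by both parents it is ambiguous; carried by neither
it is inconsistent (possible de novo or genotyping error). Ambiguous
variants never count toward the trans requirement but are reported as
unphased extras. Missing genotypes fail closed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .annotation import GeneModelSet
from .types import GeneList, Pedigree, VariantRecord

log = logging.getLogger(__name__)


@dataclass
class CandidateGene:
    """A gene surviving the recessive scan with its qualifying variants."""

    gene_symbol: str
    mode: str  # 'homozygous' | 'compound_het'
    variants: List[VariantRecord]
    parental_origin: Dict[tuple, str] = field(default_factory=dict)
    dual_mode: bool = False  # both modes applied; homozygous reported

    def sort_key(self):
        v = self.variants[0]
        return (v.chrom, v.pos)


def homozygous_qualifies(record: VariantRecord, pedigree: Pedigree) -> bool:
    """Shared-homozygous test: every affected child hom-alt, both parents het.

    Any missing pedigree genotype fails closed.
    """
    gts = [record.genotype(s) for s in pedigree.samples]
    if any(g.is_missing for g in gts):
        log.debug("missing genotype at %s:%d, fails closed", record.chrom, record.pos)
        return False
    if not record.genotype(pedigree.father).is_het:
        return False
    if not record.genotype(pedigree.mother).is_het:
        return False
    return all(record.genotype(c).is_hom_alt for c in pedigree.affected_children)


def assign_parental_origin(record: VariantRecord, pedigree: Pedigree) -> str:
    """Infer which parent transmitted the alt allele of a child-het variant.

    Returns 'mother', 'father', 'ambiguous' (both parents carry, or a
    parental genotype is missing) or 'inconsistent' (neither carries).
    """
    f = record.genotype(pedigree.father)
    m = record.genotype(pedigree.mother)
    if f.is_missing or m.is_missing:
        return "ambiguous"
    if m.carries_alt and not f.carries_alt:
        return "mother"
    if f.carries_alt and not m.carries_alt:
        return "father"
    if f.carries_alt and m.carries_alt:
        return "ambiguous"
    return "inconsistent"


def _het_in_all_children(record: VariantRecord, pedigree: Pedigree) -> bool:
    gts = [record.genotype(c) for c in pedigree.affected_children]
    if any(g.is_missing for g in gts):
        return False
    return all(g.is_het for g in gts)


def _parent_hom_alt(record: VariantRecord, pedigree: Pedigree) -> bool:
    # an unaffected parent homozygous for the alt contradicts full penetrance
    return (record.genotype(pedigree.father).is_hom_alt
            or record.genotype(pedigree.mother).is_hom_alt)


def compound_het_qualifies(gene_records: Sequence[VariantRecord],
                           pedigree: Pedigree,
                           gene_symbol: Optional[str] = None
                           ) -> Optional[CandidateGene]:
    """Trans compound-het test over the variants of one gene.

    Considers variants heterozygous in every affected child whose
    transmitting parent is unambiguous and which no unaffected parent
    carries homozygously; qualifies iff both a maternal and a paternal
    variant exist. Ambiguous-origin child-het variants ride along as
    unphased extras in the output but do not establish trans.
    """
    maternal, paternal, extras = [], [], []
    for rec in gene_records:
        if not _het_in_all_children(rec, pedigree):
            continue
        if _parent_hom_alt(rec, pedigree):
            continue
        origin = assign_parental_origin(rec, pedigree)
        if origin == "mother":
            maternal.append(rec)
        elif origin == "father":
            paternal.append(rec)
        elif origin == "ambiguous":
            extras.append(rec)
    if not (maternal and paternal):
        return None
    variants = sorted(maternal + paternal + extras, key=lambda r: (r.chrom, r.pos))
    origins = {}
    for rec in maternal:
        origins[rec.key] = "mother"
    for rec in paternal:
        origins[rec.key] = "father"
    for rec in extras:
        origins[rec.key] = "ambiguous"
    return CandidateGene(
        gene_symbol=gene_symbol or "?",
        mode="compound_het",
        variants=variants,
        parental_origin=origins,
    )


def _group_by_gene(records: Sequence[VariantRecord], models: GeneModelSet
                   ) -> Dict[str, List[VariantRecord]]:
    by_gene: Dict[str, List[VariantRecord]] = {}
    for rec in records:
        hits = models.models_at(rec.chrom, rec.pos)
        if not hits:
            log.debug("variant %s:%d in no gene model; skipped", rec.chrom, rec.pos)
            continue
        for m in hits:  # overlapping genes evaluated independently
            by_gene.setdefault(m.gene_symbol, []).append(rec)
    return by_gene


def recessive_scan(records: Sequence[VariantRecord], pedigree: Pedigree,
                   models: GeneModelSet) -> List[CandidateGene]:
    """Scan all genes for recessive candidates.

    A gene qualifying under both modes is emitted once, as homozygous,
    with ``dual_mode`` set. Output sorted by genomic position of the
    first qualifying variant.
    """
    candidates = []
    for symbol, gene_records in _group_by_gene(records, models).items():
        gene_records = sorted({r.key: r for r in gene_records}.values(),
                              key=lambda r: (r.chrom, r.pos))
        hom_hits = [r for r in gene_records if homozygous_qualifies(r, pedigree)]
        ch = compound_het_qualifies(gene_records, pedigree, gene_symbol=symbol)
        if hom_hits:
            candidates.append(CandidateGene(
                gene_symbol=symbol, mode="homozygous",
                variants=hom_hits, dual_mode=ch is not None,
            ))
        elif ch is not None:
            candidates.append(ch)
    candidates.sort(key=lambda c: c.sort_key())
    return candidates


def oracle_recessive(records: Sequence[VariantRecord], pedigree: Pedigree,
                     models: GeneModelSet) -> List[CandidateGene]:
    """Definitional re-implementation for testing: exhaustive enumeration.

    For each gene, tries every single variant against the homozygous rule
    and every subset of size >= 2 against the compound-het rule by
    enumerating all maternal/paternal origin assignments consistent with
    parental genotypes. Only usable on small instances.
    """
    candidates = []
    for symbol, gene_records in _group_by_gene(records, models).items():
        gene_records = sorted({r.key: r for r in gene_records}.values(),
                              key=lambda r: (r.chrom, r.pos))
        hom_hits = []
        for rec in gene_records:
            gts = [rec.genotype(s) for s in pedigree.samples]
            ok = (not any(g.is_missing for g in gts)
                  and rec.genotype(pedigree.father).is_het
                  and rec.genotype(pedigree.mother).is_het
                  and all(rec.genotype(c).is_hom_alt
                          for c in pedigree.affected_children))
            if ok:
                hom_hits.append(rec)
        ch_found = None
        usable = [r for r in gene_records
                  if _het_in_all_children(r, pedigree)
                  and not _parent_hom_alt(r, pedigree)
                  and assign_parental_origin(r, pedigree) in ("mother", "father")]
        for k in range(2, len(usable) + 1):
            for subset in itertools.combinations(usable, k):
                origins = [assign_parental_origin(r, pedigree) for r in subset]
                if "mother" in origins and "father" in origins:
                    ch_found = subset
                    break
            if ch_found:
                break
        if hom_hits:
            candidates.append(CandidateGene(
                gene_symbol=symbol, mode="homozygous", variants=hom_hits,
                dual_mode=ch_found is not None,
            ))
        elif ch_found:
            # report the maximal set: all child-het variants with a known or
            # ambiguous origin and no hom-alt unaffected parent
            reportable = [r for r in gene_records
                          if _het_in_all_children(r, pedigree)
                          and not _parent_hom_alt(r, pedigree)
                          and assign_parental_origin(r, pedigree) != "inconsistent"]
            origins = {r.key: assign_parental_origin(r, pedigree)
                       for r in reportable}
            candidates.append(CandidateGene(
                gene_symbol=symbol, mode="compound_het",
                variants=sorted(reportable, key=lambda r: (r.chrom, r.pos)),
                parental_origin=origins,
            ))
    candidates.sort(key=lambda c: c.sort_key())
    return candidates


def intersect_known_genes(candidates: Sequence[CandidateGene],
                          gene_list: GeneList) -> List[CandidateGene]:
    """Narrow candidates to genes already implicated in the phenotype."""
    return [c for c in candidates if c.gene_symbol in gene_list]
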