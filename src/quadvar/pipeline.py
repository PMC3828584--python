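"""End-to-end orchestration of the prioritization cascade.

Stage order follows the study design the package reproduces: annotate
consequences, keep damaging classes (nonsynonymous, stop-gain,
splice-region within the window, frameshift), drop variants catalogued
in any site database, scan for recessive segregation (shared homozygous
or trans compound-het), then intersect surviving genes with a known
phenotype gene list. The two pre-segregation filters commute; the order
here is the narrative one. Every filtering stage is monotone, so stage
counts never increase.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import io_formats
from .annotation import (
    DEFAULT_SPLICE_WINDOW,
    GeneModelSet,
    cds_to_codon,
    genomic_to_cds,
    hgvs_p_name,
    name_variant,
    read_gene_models,
    classify_consequence,
    functional_filter,
)
from .popfilter import exclude_known
from .protein import (
    DomainTable,
    conservation_at,
    map_residue_to_domain,
    reference_column,
)
from .segregation import (
    CandidateGene,
    intersect_known_genes,
    recessive_scan,
)
from .types import GeneList, Pedigree, SiteSet, VariantRecord

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File inputs and options of one prioritization run."""

    vcf: str
    ped: str
    genes_bed: str
    genome_fasta: str
    site_dbs: List[str] = field(default_factory=list)
    gene_list: Optional[str] = None
    splice_window: int = DEFAULT_SPLICE_WINDOW
    domain_table: Optional[str] = None  # YAML/TSV of protein domains
    msa: Optional[str] = None  # aligned FASTA for conservation
    msa_gene: Optional[str] = None  # gene whose protein the MSA references
    msa_reference: Optional[str] = None  # reference species id
    out_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class StageReport:
    """Counts through one stage of the cascade."""

    stage_name: str
    n_in: int
    n_out: int
    n_genes_out: Optional[int] = None
    notes: str = ""


def _variant_row(candidate: CandidateGene, rec: VariantRecord,
                 models: GeneModelSet,
                 domain_table: Optional[DomainTable],
                 msa, msa_gene: Optional[str]) -> dict:
    model = models.get(candidate.gene_symbol)
    name = name_variant(rec, model)
    coord = genomic_to_cds(rec.pos, model)
    row = {
        "gene": candidate.gene_symbol,
        "mode": candidate.mode,
        "chrom": rec.chrom,
        "pos": rec.pos,
        "ref": rec.ref,
        "alt": rec.alt,
        "name": name,
        "protein_name": "",
        "origin": candidate.parental_origin.get(rec.key, "both"
                                                if candidate.mode == "homozygous"
                                                else "?"),
        "domains": "",
        "conservation": "",
    }
    csq = classify_consequence(rec, model)
    if csq.protein_change is not None:
        row["protein_name"] = hgvs_p_name(csq.protein_change)
    if coord is not None and coord.kind == "coding":
        residue, _ = cds_to_codon(coord.cds_pos)
        if domain_table is not None:
            hits = map_residue_to_domain(residue, domain_table)
            row["domains"] = ";".join(
                f"{n}({s}-{e})" for n, s, e in hits)
        if msa is not None and msa_gene == candidate.gene_symbol:
            try:
                cons = conservation_at(msa, residue)
                row["conservation"] = (
                    f"identity={cons.identity_fraction:.2f},"
                    f"mammal_conserved={cons.mammal_conserved}"
                )
            except ValueError as exc:
                log.warning("conservation lookup failed: %s", exc)
    return row


def run_prioritization(config: PipelineConfig
                       ) -> Tuple[List[CandidateGene], List[StageReport],
                                  pd.DataFrame]:
    """Run the full cascade; returns candidates, stage counts and the
    per-variant report table. Optionally writes TSV/JSON reports."""
    pedigree = io_formats.read_ped(config.ped)
    records = io_formats.read_vcf(config.vcf, pedigree)
    models = read_gene_models(config.genes_bed, config.genome_fasta)
    dbs = [io_formats.read_sites_db(p) for p in config.site_dbs]
    gene_list = (io_formats.read_gene_list(config.gene_list)
                 if config.gene_list else None)
    domain_table = None
    if config.domain_table:
        p = str(config.domain_table)
        domain_table = (DomainTable.from_yaml(p) if p.endswith((".yaml", ".yml"))
                        else DomainTable.from_tsv(p))
    msa = (io_formats.read_msa(config.msa, reference=config.msa_reference)
           if config.msa else None)

    reports: List[StageReport] = []
    n0 = len(records)
    reports.append(StageReport("read_vcf", n0, n0,
                               notes=f"samples={','.join(pedigree.samples)}"))

    functional = functional_filter(records, models, config.splice_window)
    reports.append(StageReport(
        "functional_filter", n0, len(functional),
        notes=f"splice_window={config.splice_window}"))

    novel = exclude_known(functional, dbs)
    reports.append(StageReport(
        "exclude_known", len(functional), len(novel),
        notes=f"databases={','.join(d.name for d in dbs) or 'none'}"))

    candidates = recessive_scan(novel, pedigree, models)
    n_vars = sum(len(c.variants) for c in candidates)
    n_ch = sum(1 for c in candidates if c.mode == "compound_het")
    n_hom = len(candidates) - n_ch
    reports.append(StageReport(
        "recessive_scan", len(novel), n_vars, n_genes_out=len(candidates),
        notes=f"compound_het_genes={n_ch},homozygous_genes={n_hom}"))

    if gene_list is not None:
        final = intersect_known_genes(candidates, gene_list)
        reports.append(StageReport(
            "intersect_known_genes", len(candidates), len(final),
            n_genes_out=len(final),
            notes=f"gene_list_size={len(gene_list)}"))
    else:
        final = candidates

    rows = [
        _variant_row(c, rec, models, domain_table, msa, config.msa_gene)
        for c in final for rec in c.variants
    ]
    table = pd.DataFrame(
        rows, columns=["gene", "mode", "chrom", "pos", "ref", "alt", "name",
                       "protein_name", "origin", "domains", "conservation"])

    for r in reports:
        log.info("stage=%s n_in=%d n_out=%d %s",
                 r.stage_name, r.n_in, r.n_out, r.notes)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "candidates.tsv", sep="\t", index=False)
        payload = {
            "stages": [dataclasses.asdict(r) for r in reports],
            "candidates": [
                {
                    "gene": c.gene_symbol,
                    "mode": c.mode,
                    "dual_mode": c.dual_mode,
                    "variants": [
                        {"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                         "alt": v.alt,
                         "origin": c.parental_origin.get(v.key, "both")}
                        for v in c.variants
                    ],
                }
                for c in final
            ],
        }
        (out / "report.json").write_text(json.dumps(payload, indent=1) + "\n")
    return final, reports, table
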