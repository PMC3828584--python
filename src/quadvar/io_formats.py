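"""Readers and writers for the external formats the pipeline touches.

VCF 4.2 (multi-sample, GT only) is the single variant interchange format;
pysam does the parsing and serialisation, this module maps records onto
the domain model. Multi-allelic rows are split into one biallelic record
per alternate allele, with genotypes recoded against that allele (the
chosen alt becomes 1, reference stays 0, any other alt is recoded 0,
missing stays missing). Phase separators are read but ignored.

Other formats: 6-column PED (one family), site databases as 4-column TSV
(chrom, pos, ref, alt) or sites-only VCF, gene lists as one symbol per
line, and protein MSAs as aligned FASTA.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional

import pysam
from Bio import AlignIO

from .types import MISSING, MSA, GeneList, Genotype, Pedigree, SiteSet, VariantRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _recode_gt(gt_alleles, alt_index: int) -> Genotype:
    """Recode a pysam GT tuple against one alt allele (1-based alt_index)."""
    if gt_alleles is None:
        return MISSING
    alleles = []
    for a in gt_alleles:
        if a is None:
            alleles.append(None)
        elif a == alt_index:
            alleles.append(1)
        else:
            alleles.append(0)
    if len(alleles) == 1:  # haploid call, treat as missing second allele
        alleles.append(None)
    return Genotype(tuple(alleles[:2]))


def read_vcf(path, pedigree: Optional[Pedigree] = None) -> List[VariantRecord]:
    """Read a VCF into sorted biallelic :class:`VariantRecord` objects.

    If a pedigree is given, every pedigree member must appear in the VCF
    header; samples not in the header are fatal, unparseable genotypes
    degrade to missing with a warning.
    """
    path = str(path)
    with pysam.VariantFile(path) as vf:
        header_samples = list(vf.header.samples)
        if pedigree is not None:
            absent = [s for s in pedigree.samples if s not in header_samples]
            if absent:
                raise ValueError(
                    f"pedigree sample(s) {absent} missing from VCF header of {path}"
                )
        wanted = list(pedigree.samples) if pedigree is not None else header_samples
        records = []
        for rec in vf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts, start=1):
                if alt is None or alt in ("*", "<NON_REF>"):
                    continue
                genotypes = {}
                for sample in wanted:
                    try:
                        gt = rec.samples[sample].get("GT")
                        genotypes[sample] = _recode_gt(gt, i)
                    except (ValueError, KeyError) as exc:
                        log.warning(
                            "unparseable genotype for %s at %s:%d (%s); set missing",
                            sample, rec.chrom, rec.pos, exc,
                        )
                        genotypes[sample] = MISSING
                records.append(
                    VariantRecord(rec.chrom, rec.pos, rec.ref, alt, genotypes)
                )
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


def write_vcf(records: Iterable[VariantRecord], pedigree: Pedigree, path) -> None:
    """Write biallelic records as a minimal multi-sample VCF 4.2 file."""
    records = list(records)
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    for c in contigs:
        header.contigs.add(c)
    for s in pedigree.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            for s in pedigree.samples:
                rec.samples[s]["GT"] = r.genotype(s).alleles
                rec.samples[s].phased = False
            out.write(rec)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path) -> Pedigree:
    """Parse a 6-column PED file describing one quad-style family.

    Phenotype column: 2 = affected, anything else = unaffected. The model
    requires two unaffected parents and >= 1 affected child naming both
    parents; affected parents, multiple families, or children missing a
    parent are fatal.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line has fewer than 6 columns: {line!r}")
        rows.append(fields[:6])
    if not rows:
        raise ValueError(f"empty PED file: {path}")
    families = {r[0] for r in rows}
    if len(families) != 1:
        raise ValueError(f"expected one family, found {sorted(families)}")
    family_id = rows[0][0]
    by_id = {r[1]: r for r in rows}
    referenced_parents = {r[2] for r in rows} | {r[3] for r in rows}
    for r in rows:
        if r[5] == "2" and r[1] in referenced_parents:
            raise ValueError(
                f"affected parent {r[1]} violates the recessive quad model")
    affected = [r for r in rows if r[5] == "2"]
    parents_named = set()
    for r in affected:
        if r[2] == "0" or r[3] == "0":
            raise ValueError(f"affected child {r[1]} lacks both parents in PED")
        parents_named.add((r[2], r[3]))
    if not affected:
        raise ValueError("no affected individuals in PED")
    if len(parents_named) != 1:
        raise ValueError("affected children do not share the same two parents")
    father_id, mother_id = next(iter(parents_named))
    for pid, role in ((father_id, "father"), (mother_id, "mother")):
        row = by_id.get(pid)
        if row is None:
            raise ValueError(f"{role} {pid} not present as a PED row")
        if row[5] == "2":
            raise ValueError(f"affected parent {pid} violates the recessive quad model")
    # sanity: sex codes if given (1=male, 2=female)
    if by_id[father_id][4] == "2" or by_id[mother_id][4] == "1":
        raise ValueError("parent sex codes inconsistent with father/mother columns")
    return Pedigree(
        family_id=family_id,
        father=father_id,
        mother=mother_id,
        affected_children=tuple(r[1] for r in affected),
    )


def write_ped(pedigree: Pedigree, path) -> None:
    lines = [
        f"{pedigree.family_id}\t{pedigree.father}\t0\t0\t1\t1",
        f"{pedigree.family_id}\t{pedigree.mother}\t0\t0\t2\t1",
    ]
    for child in pedigree.affected_children:
        lines.append(
            f"{pedigree.family_id}\t{child}\t{pedigree.father}\t{pedigree.mother}\t1\t2"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site databases, gene lists, MSA
# ---------------------------------------------------------------------------

def read_sites_db(path, name: Optional[str] = None) -> SiteSet:
    """Read a known-variant site database.

    Accepts either a sites-only/multi-sample VCF (detected from the
    ``##fileformat`` magic) or a 4-column TSV of chrom, pos, ref, alt.
    Duplicate rows collapse; multi-allelic VCF rows contribute one site
    per alt.
    """
    path = Path(path)
    name = name or path.stem
    db = SiteSet(name=name)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    if alt:
                        db.add(rec.chrom, rec.pos, rec.ref, alt)
        return db
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"site DB line needs 4 columns: {line!r}")
        db.add(fields[0], int(fields[1]), fields[2], fields[3])
    return db


def write_sites_db(db: SiteSet, path) -> None:
    lines = [f"{c}\t{p}\t{r}\t{a}" for c, p, r, a in sorted(db.sites)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_list(path) -> GeneList:
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.add(line)
    return GeneList(frozenset(symbols))


def read_msa(path, reference: Optional[str] = None) -> MSA:
    """Read an aligned FASTA; ragged lengths are fatal (AlignIO enforces).

    The reference defaults to the first sequence in the file.
    """
    aln = AlignIO.read(str(path), "fasta")
    sequences = {rec.id: str(rec.seq).upper() for rec in aln}
    if reference is None:
        reference = aln[0].id
    return MSA(sequences=sequences, reference=reference)
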