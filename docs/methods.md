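# Methods

## The recessive model

The package assumes a fully penetrant autosomal-recessive mode of
inheritance in a nuclear family with unaffected parents and one or more
affected children (the quad — two affected siblings — is the canonical
case). Under that model every affected child must carry two pathogenic
alleles of the causal gene and every unaffected parent at most one, so a
causal gene shows one of two genotype patterns:

* **shared homozygous**: a single variant, homozygous-alternate in every
  affected child, heterozygous in both parents;
* **compound heterozygous in trans**: ≥2 variants, each heterozygous in
  every affected child, with at least one of unambiguous maternal and
  one of unambiguous paternal origin.

Parental origin is inferred from parental genotypes only — genotypes are
treated as unphased throughout, and phase separators in input VCFs are
read but ignored. A variant carried by exactly one parent has that
parent as origin; carried by both it is *ambiguous* and can never
establish the trans configuration (it is still listed on a qualifying
candidate as an unphased extra); carried by neither it is
*inconsistent* (possible de novo call or genotyping error) and is
ignored by the scan. An unaffected parent homozygous for the alternate
allele contradicts full penetrance and disqualifies the variant.

**Missing genotypes fail closed**: a variant with any missing pedigree
genotype cannot qualify, trading sensitivity for reproducibility. This
is why recovery of a planted causal gene degrades as simulated
missingness rises.

## Consequence classification and coordinates

Each gene is represented by one canonical transcript (exon intervals, a
CDS span and the spliced, strand-corrected coding sequence, read from
BED12 plus a genome FASTA). Coordinates are 0-based half-open
internally; variant positions are 1-based as in VCF.

* Coding SNVs are classified by translating the reference and mutant
  codon with the standard genetic code (no selenocysteine or alternative
  codes): synonymous, nonsynonymous, or stop-gain. CDS position *n*
  belongs to codon ⌊(n−1)/3⌋+1 at codon offset ((n−1) mod 3)+1.
* Intronic positions get a transcript-order intron number and a signed
  offset: positive from the donor (5′) side, negative from the acceptor
  (3′) side, whichever is nearer; a position exactly mid-intron is
  reported from the donor side. Offsets with |offset| ≤ the splice
  window (default 10 bases, inclusive at the boundary) are
  splice-region candidates.
* Coding indels are frameshift when |len(ref) − len(alt)| mod 3 ≠ 0,
  in-frame otherwise; an indel whose changed bases straddle an
  exon/intron boundary is conservatively classed splice-region.
* Exonic non-coding positions are UTR; everything outside the transcript
  is intergenic. The functional filter retains {nonsynonymous,
  stop_gain, splice_region, frameshift_indel}; stop-gains are kept as
  nonsynonymous changes in the broad sense.

Intron numbering counts all introns of the transcript in transcript
order, so "IVS25" is the intron following exon 25 — the conventional
reading of legacy IVS nomenclature. Names are rendered as `c.8375T>C`
(coding, cDNA-strand alleles), `p.V2792A` (single-letter protein), and
`IVS25+3G>A` (intronic).

Database exclusion is allele-exact on (chrom, pos, ref, alt): a novel
allele at a catalogued position survives, which is the behaviour needed
for novel pathogenic alleles to pass a presence/absence filter. No
allele-frequency thresholds are applied, and no genotype-quality or
depth filtering is done (the model consumes GT fields only).

## Protein-level interpretation

Domain tables are closed 1-based residue intervals; all intervals
containing a residue are reported, preserving printed overlaps (in the
shipped myosin XVa table the SH3 domain 2865–2959 overlaps the end of
the first FERM domain 2687–2867). The table ships as an editable YAML
config and does not assert a total protein length.

Conservation of a residue is computed on a pre-built protein MSA: the
reference's *k*-th non-gap character fixes the column; identity is the
fraction of non-gap residues in that column equal to the reference
residue; `mammal_conserved` requires exact identity over a declared
mammal subset (default: human, chimpanzee, macaque, cow, dog, mouse,
rat — chicken and zebrafish are excluded). Building the alignment
itself is out of scope; the simulator emits a clearly synthetic one.

## The synthetic-data generator

The generator's defaults define the standard desk-scale study
condition: 200 toy genes (one per chromosome, so coordinates are
trivially valid), 3–8 exons per gene with 60–240 coding bases each and
40–120-base introns, 1500 background variants, 90% database membership
(roughly the catalogued fraction of an outbred exome), background
alternate-allele frequency 0.3, ~5% indels, three decoy genes of each
kind, and no missing genotypes. Tests use smaller gene/variant counts
of the same structure to keep suites fast; the properties checked do
not depend on scale.

Background genotypes are drawn as parental genotypes at the configured
allele frequency with each child inheriting one allele from each parent,
so every background genotype is Mendelian-consistent by construction
(no background de novo events). Sites are independent — the cascade
uses no linkage information, so LD is deliberately not modelled.
Genotype draws that would let a background gene satisfy the recessive
rule in a novel, damaging state are rejection-sampled (redrawn, or the
site is catalogued into a database if no safe pattern is found): the
generator's contract is that background variation is non-causal, which
makes planted-gene recovery a sharp property. Decoy genes provide the
near-misses instead, each labelled with its failure reason in the truth
file: a cis-only compound pair (both variants from the same parent), a
homozygous lookalike with a homozygous-alternate parent, and a genuine
trans pair that is catalogued in a site database.

The compound-het plant mirrors the family configuration the pipeline is
designed around: a maternally transmitted intronic SNV at donor offset
+3 plus a paternally transmitted coding nonsynonymous SNV, both
heterozygous in both children. The homozygous plant is one coding SNV,
homozygous in the children and heterozygous in both parents. Planted
variants are never inserted into the site databases.

All randomness flows from a single seeded generator in a fixed draw
order, so identical configurations produce byte-identical datasets.
Missingness is applied through per-genotype uniforms that depend only on
the seed and the genotype's position, making the missing sets nested
across rates — recovery is therefore monotone non-increasing in the
missingness rate by construction, not merely in expectation.

What passing tests on this generator do **not** show: robustness to
genotyping error (background children are always Mendelian-consistent),
to multi-transcript annotation ambiguity (one canonical transcript per
gene), to population structure or allele-frequency misestimation, or to
real human genome geometry (toy chromosomes carry one gene each).

## Numerical and design choices

* Splice window 10 bases, inclusive (|offset| ≤ 10); the boundary
  inclusivity is this package's choice.
* Multi-allelic VCF rows are split on read into biallelic records, the
  chosen alternate coded 1, other alternates coded 0; splitting
  preserves the multiset of per-sample called alternate alleles.
* A gene qualifying under both recessive modes is reported once, as
  homozygous, with a `dual_mode` flag — it is not double-counted.
* Candidates are ordered by (chrom, pos) of their first variant;
  variants mapping into overlapping genes are evaluated independently
  per gene.
* Exit with an empty candidate list is a valid pipeline outcome, not an
  error.
* The two pre-segregation filters (consequence and database) commute;
  the pipeline fixes the narrative order and a property test documents
  the commutation.

## Known limitations

Single-transcript consequence model; no splice-strength scoring (a
splice-region flag is positional, not predictive); no
pathogenicity predictors; no X-linked, dominant or de novo models; no
penetrance or allele-frequency modelling; PED parsing supports exactly
one family per file.
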