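"""Coordinate arithmetic, consequence classification and naming.

The independent oracles here work positionally: transcript coordinates
are derived by materialising the transcript as an explicit list of
genomic positions, and coding consequences by rebuilding the whole
mutant CDS and translating both proteins.
"""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from quadvar.annotation import (
    CdsCoordinate,
    cds_to_codon,
    cds_to_genomic,
    classify_consequence,
    functional_filter,
    genomic_to_cds,
    GeneModelSet,
    hgvs_c_name,
    hgvs_p_name,
    ivs_name,
    name_variant,
)
from quadvar.types import VariantRecord

from conftest import (
    make_plus_gene,
    make_record,
    mirror_gene,
    mirror_pos,
    random_toy_gene,
    revcomp,
)


# ---------------------------------------------------------------------------
# independent positional oracle
# ---------------------------------------------------------------------------

def naive_coordinates(model):
    """Map every genomic position (1-based) of the transcript span to its
    expected coordinate by explicit position lists."""
    exp = {}
    exon_positions = []  # 0-based, transcript order
    for s, e in model.exons:
        exon_positions.extend(range(s, e))
    if model.strand == "-":
        exon_positions = exon_positions[::-1]
    cds_positions = [p for p in exon_positions
                     if model.cds_start <= p < model.cds_end]
    for i, p in enumerate(cds_positions, start=1):
        exp[p + 1] = ("coding", i)
    for p in exon_positions:
        if p + 1 not in exp:
            exp[p + 1] = ("utr", None)
    # introns: genomic gaps between consecutive exons
    gaps = [(model.exons[i][1], model.exons[i + 1][0])
            for i in range(len(model.exons) - 1)]
    order = range(len(gaps)) if model.strand == "+" else range(len(gaps) - 1, -1, -1)
    for intron_number, gi in enumerate(order, start=1):
        s, e = gaps[gi]
        positions = list(range(s, e))
        if model.strand == "-":
            positions = positions[::-1]
        n = len(positions)
        for idx, p in enumerate(positions):
            donor_off = idx + 1
            acceptor_off = idx - n
            off = donor_off if donor_off <= abs(acceptor_off) else acceptor_off
            exp[p + 1] = ("intronic", (intron_number, off))
    return exp


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("mirrored", [False, True])
def test_genomic_to_cds_agrees_with_positional_oracle(seed, mirrored):
    rng = np.random.default_rng(seed)
    model, seq = random_toy_gene(rng)
    if mirrored:
        model, seq = mirror_gene(model, seq)
    expected = naive_coordinates(model)
    for pos in range(1, len(seq) + 1):
        coord = genomic_to_cds(pos, model)
        if pos not in expected:
            assert coord is None
        else:
            kind, detail = expected[pos]
            if kind == "coding":
                assert coord == CdsCoordinate("coding", cds_pos=detail)
            elif kind == "utr":
                assert coord is None
            else:
                intron, off = detail
                assert coord == CdsCoordinate("intronic", intron_index=intron,
                                              offset=off)


def test_cds_to_genomic_is_inverse_of_coding_mapping():
    for seed in (5, 6):
        rng = np.random.default_rng(seed)
        model, seq = random_toy_gene(rng)
        for m in (model, mirror_gene(model, seq)[0]):
            for cds_pos in range(1, len(m.cds_sequence) + 1):
                g = cds_to_genomic(m, cds_pos)
                assert genomic_to_cds(g, m) == CdsCoordinate("coding",
                                                             cds_pos=cds_pos)


class TestCdsToCodon:
    @pytest.mark.parametrize("cds_pos,expected", [
        (8375, (2792, 2)),  # the worked example: residue 2792, middle base
        (1, (1, 1)),
        (6, (2, 3)),
        (3, (1, 3)),
        (4, (2, 1)),
    ])
    def test_examples(self, cds_pos, expected):
        assert cds_to_codon(cds_pos) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cds_to_codon(0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=1, max_value=100_000))
    def test_inverse_of_codon_expansion(self, k):
        # codon k spans CDS positions 3k-2 .. 3k with offsets 1..3
        for offset in (1, 2, 3):
            assert cds_to_codon(3 * (k - 1) + offset) == (k, offset)


# ---------------------------------------------------------------------------
# a hand-built 3-exon gene with known geometry
# ---------------------------------------------------------------------------

@pytest.fixture
def three_exon_gene():
    # CDS: ATG GTG CTG TAC CTG GTG CCA CTG AAA  (27 nt, 9 codons)
    cds = "ATGGTGCTGTACCTGGTGCCACTGAAA"
    model, seq = make_plus_gene(cds, [9, 12, 6], [30, 40],
                                utr5=4, utr3=5, pad=10)
    return model, seq


def test_first_cds_base_maps_to_coding_1(three_exon_gene):
    model, _ = three_exon_gene
    pos = model.cds_start + 1  # 1-based
    assert genomic_to_cds(pos, model) == CdsCoordinate("coding", cds_pos=1)


def test_donor_plus_three_of_second_intron(three_exon_gene):
    model, _ = three_exon_gene
    # exon 2 ends at model.exons[1][1] (half-open); +3 into intron 2
    pos = model.exons[1][1] + 3  # 1-based: (end-1)+1 + 3
    assert genomic_to_cds(pos, model) == CdsCoordinate(
        "intronic", intron_index=2, offset=3)


def test_acceptor_minus_one_of_first_intron(three_exon_gene):
    model, _ = three_exon_gene
    pos = model.exons[1][0]  # 1-based base just before exon 2
    assert genomic_to_cds(pos, model) == CdsCoordinate(
        "intronic", intron_index=1, offset=-1)


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

def rebuild_oracle(model, cds_pos, alt_sense_base):
    """Expected coding-SNV consequence by rebuilding and translating the
    whole mutant CDS."""
    cds = model.cds_sequence
    mutant = cds[:cds_pos - 1] + alt_sense_base + cds[cds_pos:]
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(mutant).translate())
    if "*" in p_alt:
        return "stop_gain"
    if p_ref == p_alt:
        return "synonymous"
    return "nonsynonymous"


def test_classifier_matches_full_cds_rebuild_oracle_on_random_snvs():
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 1000:
        model, seq = random_toy_gene(rng)
        if rng.random() < 0.5:
            model, seq = mirror_gene(model, seq)
        for _ in range(40):
            cds_pos = int(rng.integers(1, len(model.cds_sequence) + 1))
            ref_sense = model.cds_sequence[cds_pos - 1]
            alt_sense = "ACGT"[int(rng.integers(0, 4))]
            if alt_sense == ref_sense:
                continue
            pos = cds_to_genomic(model, cds_pos)
            if model.strand == "+":
                ref_g, alt_g = ref_sense, alt_sense
            else:
                ref_g, alt_g = revcomp(ref_sense), revcomp(alt_sense)
            rec = VariantRecord(model.chrom, pos, ref_g, alt_g, {})
            csq = classify_consequence(rec, model)
            assert csq.category == rebuild_oracle(model, cds_pos, alt_sense)
            if csq.category in ("nonsynonymous", "synonymous", "stop_gain"):
                codon_index, _ = cds_to_codon(cds_pos)
                assert csq.protein_change[1] == codon_index
            checked += 1


def test_valine_to_alanine_from_middle_base_t_to_c(three_exon_gene):
    model, _ = three_exon_gene
    # codon 2 is GTG (valine); its middle base is CDS position 5
    pos = cds_to_genomic(model, 5)
    rec = VariantRecord(model.chrom, pos, "T", "C", {})
    csq = classify_consequence(rec, model)
    assert csq.category == "nonsynonymous"
    assert csq.protein_change == ("V", 2, "A")


def test_splice_window_boundary(three_exon_gene):
    model, seq = three_exon_gene
    base = model.exons[0][1]  # first intron, donor side (0-based end)
    for offset, expected in [(3, "splice_region"), (10, "splice_region"),
                             (11, "intronic")]:
        pos = base + offset  # 1-based genomic of donor+offset
        ref = seq[pos - 1]
        alt = "A" if ref != "A" else "G"
        rec = VariantRecord(model.chrom, pos, ref, alt, {})
        assert classify_consequence(rec, model).category == expected


def test_indel_classes(three_exon_gene):
    model, seq = three_exon_gene
    # 2-base deletion inside exon 2 CDS -> frameshift
    p = model.exons[1][0] + 3  # 0-based, safely inside exon 2
    rec = VariantRecord(model.chrom, p + 1, seq[p:p + 3], seq[p], {})
    assert classify_consequence(rec, model).category == "frameshift_indel"
    # 3-base deletion -> inframe
    rec = VariantRecord(model.chrom, p + 1, seq[p:p + 4], seq[p], {})
    assert classify_consequence(rec, model).category == "inframe_indel"
    # deletion spanning the exon2/intron2 boundary -> splice_region
    b = model.exons[1][1] - 2  # 0-based, two bases before the donor
    rec = VariantRecord(model.chrom, b + 1, seq[b:b + 5], seq[b], {})
    assert classify_consequence(rec, model).category == "splice_region"


def test_utr_and_intergenic(three_exon_gene):
    model, seq = three_exon_gene
    p5 = model.exons[0][0] + 1  # inside the 5' UTR
    rec = VariantRecord(model.chrom, p5, seq[p5 - 1],
                        "A" if seq[p5 - 1] != "A" else "C", {})
    assert classify_consequence(rec, model).category == "utr"
    rec = VariantRecord(model.chrom, 2, seq[1],
                        "A" if seq[1] != "A" else "C", {})
    assert classify_consequence(rec, model).category == "intergenic"


def test_strand_symmetry_of_consequences():
    """Reverse-complementing the locus leaves every category unchanged."""
    rng = np.random.default_rng(21)
    for seed in range(8):
        model, seq = random_toy_gene(np.random.default_rng(100 + seed))
        mmodel, mseq = mirror_gene(model, seq)
        L = len(seq)
        for _ in range(60):
            pos = int(rng.integers(1, L + 1))
            ref = seq[pos - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            rec = VariantRecord(model.chrom, pos, ref, alt, {})
            mrec = VariantRecord(model.chrom, mirror_pos(pos, L),
                                 revcomp(ref), revcomp(alt), {})
            assert (classify_consequence(rec, model).category
                    == classify_consequence(mrec, mmodel).category)


# ---------------------------------------------------------------------------
# the functional filter
# ---------------------------------------------------------------------------

@pytest.fixture
def filter_fixture(quad):
    """20 variants of known classes on one gene: 5 synonymous, 5
    nonsynonymous, 4 splice-region (offsets +2, +3, -9, -10), 3 deep
    intronic (+11, +30, -100), 3 frameshift. 12 should survive."""
    # codons: ATG then alternating CTG (Leu) and GTG (Val)
    cds = "ATG" + "CTGGTG" * 25  # 153 nt, 51 codons
    model, seq = make_plus_gene(cds, [60, 60, 33], [220, 260], utr5=6, utr3=6)
    models = GeneModelSet([model])
    records = []

    def snv_at_genomic(pos, alt):
        ref = seq[pos - 1]
        assert ref != alt
        return make_record(model.chrom, pos, ref, alt, quad)

    # synonymous: CTG -> CTA (third base of a Leu codon), codons 2,4,...
    for k in (2, 4, 6, 8, 10):
        cds_pos = 3 * k  # third base of codon k
        records.append(snv_at_genomic(cds_to_genomic(model, cds_pos), "A"))
    # nonsynonymous: GTG -> GCG (middle base of a Val codon), codons 3,5,...
    for k in (3, 5, 7, 9, 11):
        cds_pos = 3 * (k - 1) + 2
        records.append(snv_at_genomic(cds_to_genomic(model, cds_pos), "C"))
    # splice-region / deep intronic, via explicit donor/acceptor arithmetic
    donor1, acceptor1 = model.exons[0][1], model.exons[1][0]  # 0-based
    donor2, acceptor2 = model.exons[1][1], model.exons[2][0]
    intron_pos = {
        +2: donor1 + 2, +3: donor1 + 3,       # 1-based donor offsets
        -9: acceptor1 - 8, -10: acceptor1 - 9,
        +11: donor2 + 11, +30: donor2 + 30, -100: acceptor2 - 99,
    }
    for off, pos in intron_pos.items():
        ref = seq[pos - 1]
        alt = "A" if ref != "A" else "G"
        records.append(snv_at_genomic(pos, alt))
    # frameshift: 1-base deletions inside exon 2 CDS
    for shift in (5, 10, 15):
        p = model.exons[1][0] + shift  # 0-based
        records.append(make_record(model.chrom, p + 1, seq[p:p + 2],
                                   seq[p], quad))
    assert len(records) == 20
    return model, models, records


def test_functional_filter_keeps_exactly_the_damaging_twelve(filter_fixture):
    model, models, records = filter_fixture
    kept = functional_filter(records, models)
    assert len(kept) == 12
    categories = [classify_consequence(r, model).category for r in kept]
    assert all(c in ("nonsynonymous", "splice_region", "frameshift_indel",
                     "stop_gain") for c in categories)
    assert categories.count("nonsynonymous") == 5
    assert categories.count("splice_region") == 4
    assert categories.count("frameshift_indel") == 3


def test_functional_filter_is_monotone_and_order_preserving(filter_fixture):
    _, models, records = filter_fixture
    kept = functional_filter(records, models)
    positions = [records.index(r) for r in kept]
    assert positions == sorted(positions)
    # subset property on an arbitrary subsample
    sub = records[::2]
    assert set(r.key for r in functional_filter(sub, models)) <= set(
        r.key for r in kept)


def test_empty_and_all_synonymous_inputs(filter_fixture, quad):
    _, models, _ = filter_fixture
    assert functional_filter([], models) == []
    model = next(iter(models))
    syn = []
    for k in (2, 4, 6):
        pos = cds_to_genomic(model, 3 * k)
        ref = model.cds_sequence[3 * k - 1]
        syn.append(make_record(model.chrom, pos, ref, "A", quad))
    assert functional_filter(syn, models) == []


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

class TestNaming:
    def test_coding_name(self):
        coord = CdsCoordinate("coding", cds_pos=8375)
        assert hgvs_c_name(coord, "T", "C") == "c.8375T>C"

    def test_protein_name(self):
        assert hgvs_p_name(("V", 2792, "A")) == "p.V2792A"

    def test_ivs_name_positive_and_negative(self):
        assert ivs_name(CdsCoordinate("intronic", intron_index=25, offset=3),
                        "G", "A") == "IVS25+3G>A"
        assert ivs_name(CdsCoordinate("intronic", intron_index=7, offset=-2),
                        "A", "G") == "IVS7-2A>G"

    def test_intronic_coordinate_rejected_by_c_name(self):
        coord = CdsCoordinate("intronic", intron_index=1, offset=5)
        with pytest.raises(ValueError):
            hgvs_c_name(coord, "G", "A")

    def test_name_variant_uses_sense_strand_alleles_on_minus_genes(self):
        model, seq = random_toy_gene(np.random.default_rng(40))
        mmodel, mseq = mirror_gene(model, seq)
        cds_pos = 10
        ref_sense = mmodel.cds_sequence[cds_pos - 1]
        alt_sense = "A" if ref_sense != "A" else "C"
        pos = cds_to_genomic(mmodel, cds_pos)
        rec = VariantRecord(mmodel.chrom, pos, revcomp(ref_sense),
                            revcomp(alt_sense), {})
        assert name_variant(rec, mmodel) == f"c.{cds_pos}{ref_sense}>{alt_sense}"
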