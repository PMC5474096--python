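"""Category assignment: worked examples, rule-table oracle, invariants."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from marvd import (
    Category,
    ContigProfile,
    GeneAnnotation,
    TaxonGroup,
    Thresholds,
    assign_category,
    classify_table,
    parse_annotation_table,
    profile_contig,
)

from _oracles import rule_table_category

ARCH = TaxonGroup.ARCHAEAL_VIRUS
PHAGE = TaxonGroup.PHAGE
EUK = TaxonGroup.EUKARYOTIC_VIRUS
CELL = TaxonGroup.CELLULAR


def make_profile(n_total=20, n_arch=0, n_phage=0, n_cell=0, n_euk=0,
                 bit_arch=0.0, bit_phage=0.0, bit_cell=100.0, bit_euk=100.0):
    counts, bits = {}, {}
    for group, n, b in ((ARCH, n_arch, bit_arch), (PHAGE, n_phage, bit_phage),
                        (CELL, n_cell, bit_cell), (EUK, n_euk, bit_euk)):
        if n:
            counts[group] = n
            bits[group] = b
    return ContigProfile(contig_id="c", n_genes_total=n_total, counts=counts,
                         max_bit=bits)


def gene(contig, idx, group, bit):
    lineages = {ARCH: "Sulfolobus spindle-shaped virus 1",
                PHAGE: "Enterobacteria phage T4",
                EUK: "Ostreococcus tauri virus 1",
                CELL: "uncultured marine bacterium",
                TaxonGroup.UNCLASSIFIED: ""}
    return GeneAnnotation(contig_id=contig, gene_id=f"{contig}_{idx}", gene_index=idx,
                          lineage=lineages[group], taxon_group=group, bit_score=bit)


class TestProfileContig:
    def test_two_of_fifty_two_annotated_all_archaeal(self):
        """The long-contig hard case: 2 annotated of 52 genes, both archaeal."""
        annotations = [gene("c", 1, ARCH, 150.0), gene("c", 2, ARCH, 96.0)]
        p = profile_contig(annotations, n_genes_total=52)
        assert p.n_annotated == 2
        assert p.arch_fraction == 1
        assert p.bit(ARCH) == 150.0

    def test_no_annotations_gives_undefined_fraction(self):
        p = profile_contig([], n_genes_total=10)
        assert p.arch_fraction is None
        assert assign_category(p).category is Category.NONE

    def test_eukaryotic_genes_counted_but_excluded_from_fraction(self):
        annotations = [gene("c", 1, ARCH, 90.0), gene("c", 2, ARCH, 120.0),
                       gene("c", 3, PHAGE, 60.0), gene("c", 4, EUK, 200.0)]
        p = profile_contig(annotations, n_genes_total=10)
        assert p.n_annotated == 4
        assert p.arch_fraction == Fraction(2, 3)
        assert p.bit(ARCH) == 120.0 and p.bit(PHAGE) == 60.0

    def test_mixed_contig_ids_rejected(self):
        with pytest.raises(ValueError, match="multiple contigs"):
            profile_contig([gene("a", 1, ARCH, 90.0), gene("b", 1, ARCH, 90.0)], 5)

    def test_cellular_exclusion_flag_changes_denominator(self):
        annotations = [gene("c", 1, ARCH, 90.0), gene("c", 2, CELL, 80.0)]
        assert profile_contig(annotations, 5).arch_fraction == Fraction(1, 2)
        p = profile_contig(annotations, 5, exclude_cellular_from_fraction=True)
        assert p.arch_fraction == 1


class TestAssignCategory:
    def test_few_annotation_clause_long_contig_is_category_1(self):
        p = make_profile(n_total=52, n_arch=2, bit_arch=150.0)
        assert assign_category(p).category is Category.CAT1

    def test_three_of_five_with_top_archaeal_hit_is_category_3(self):
        p = make_profile(n_total=5, n_arch=2, n_phage=1, bit_arch=110.0, bit_phage=80.0)
        assert p.arch_fraction == Fraction(2, 3)
        assert assign_category(p).category is Category.CAT3

    def test_majority_with_stronger_phage_hit_is_category_2(self):
        p = make_profile(n_total=12, n_arch=7, n_phage=1, bit_arch=90.0, bit_phage=130.0)
        assert assign_category(p).category is Category.CAT2

    def test_quality_floor_failure_rejects(self):
        p = make_profile(n_total=9, n_arch=2, n_phage=4, bit_arch=70.0, bit_phage=60.0)
        assert assign_category(p).category is Category.NONE

    def test_clause_bit_floor_waivable(self):
        p = make_profile(n_total=30, n_arch=1, bit_arch=60.0)
        assert assign_category(p).category is Category.NONE
        relaxed = Thresholds(require_min_bit_in_clause=False)
        assert assign_category(p, relaxed).category is Category.CAT1

    def test_trace_is_nonempty_and_records_decisions(self):
        a = assign_category(make_profile(n_total=52, n_arch=2, bit_arch=150.0))
        assert a.rule_trace
        assert any("pass" in step for step in a.rule_trace)


def _oracle_grid():
    """Profiles over the full rule grid (>= 1,000 cases)."""
    bits = (60.0, 75.0, 76.0, 100.0, 150.0)
    cases = []
    for n_annot in range(0, 7):
        for n_arch in range(0, n_annot + 1):
            rem = n_annot - n_arch
            splits = {(rem, 0, 0), (0, rem, 0), (0, 0, rem)} if rem else {(0, 0, 0)}
            if rem >= 2:  # mixed remainders exercise the denominator rules
                splits |= {(rem - 1, 1, 0), (rem - 1, 0, 1), (1, rem - 1, 0)}
            for n_phage, n_cell, n_euk in sorted(splits):
                for bit_arch in bits if n_arch else (0.0,):
                    for bit_phage in bits if n_phage else (0.0,):
                        cases.append((n_arch, n_phage, n_cell, n_euk,
                                      bit_arch, bit_phage))
    return cases


ORACLE_GRID = _oracle_grid()


def test_oracle_grid_is_large_enough():
    assert len(ORACLE_GRID) >= 1000


@pytest.mark.parametrize("case", ORACLE_GRID,
                         ids=lambda c: "a{}p{}c{}e{}_ba{}_bp{}".format(*c))
def test_assignment_matches_independent_rule_table(case):
    n_arch, n_phage, n_cell, n_euk, bit_arch, bit_phage = case
    p = make_profile(n_total=10, n_arch=n_arch, n_phage=n_phage, n_cell=n_cell,
                     n_euk=n_euk, bit_arch=bit_arch, bit_phage=bit_phage)
    expected = rule_table_category(n_arch, n_phage, n_cell, n_euk, bit_arch, bit_phage)
    got = assign_category(p).category
    assert (got.value if got is not Category.NONE else None) == expected


@given(
    n_arch=st.integers(0, 8), n_phage=st.integers(0, 8), n_cell=st.integers(0, 4),
    bit_arch=st.floats(1.0, 300.0), bit_phage=st.floats(0.0, 300.0),
    boost=st.floats(0.0, 200.0),
)
def test_raising_archaeal_bit_never_moves_positive_to_none(
    n_arch, n_phage, n_cell, bit_arch, bit_phage, boost
):
    if n_arch == 0:
        return
    base = make_profile(n_total=25, n_arch=n_arch, n_phage=n_phage, n_cell=n_cell,
                        bit_arch=bit_arch, bit_phage=bit_phage)
    boosted = make_profile(n_total=25, n_arch=n_arch, n_phage=n_phage, n_cell=n_cell,
                           bit_arch=bit_arch + boost, bit_phage=bit_phage)
    if assign_category(base).category.is_positive:
        assert assign_category(boosted).category.is_positive


def test_boundary_fractions_exact():
    """Share exactly 2/3 is never category 1/2; exactly 1/3 is category-3 eligible."""
    at_two_thirds = make_profile(n_total=9, n_arch=4, n_phage=2, bit_arch=100.0,
                                 bit_phage=60.0)
    assert at_two_thirds.arch_fraction == Fraction(2, 3)
    assert assign_category(at_two_thirds).category is Category.CAT3
    at_one_third = make_profile(n_total=9, n_arch=2, n_phage=4, bit_arch=100.0,
                                bit_phage=60.0)
    assert at_one_third.arch_fraction == Fraction(1, 3)
    assert assign_category(at_one_third).category is Category.CAT3
    below_one_third = make_profile(n_total=13, n_arch=2, n_phage=5, bit_arch=100.0,
                                   bit_phage=60.0)
    assert assign_category(below_one_third).category is Category.NONE


class TestClassifyTable:
    TSV = (
        "contig_id\tgene_id\tgene_index\tlineage\tbit_score\te_value\n"
        # cat1 via clause: 2 of 4 annotated, both archaeal
        "k1\tk1_1\t1\tSulfolobus spindle-shaped virus 1\t150\t1e-40\n"
        "k1\tk1_2\t2\t\t\t\n"
        "k1\tk1_3\t3\tAcidianus two-tailed virus\t96\t1e-20\n"
        "k1\tk1_4\t4\t\t\t\n"
        # cat2: 3 archaeal + 1 phage, phage bit higher
        "k2\tk2_1\t1\tHaloarcula hispanica virus SH1\t90\t1e-18\n"
        "k2\tk2_2\t2\tHalorubrum pleomorphic virus 1\t85\t1e-16\n"
        "k2\tk2_3\t3\tThermoproteus tenax virus 1\t88\t1e-17\n"
        "k2\tk2_4\t4\tEnterobacteria phage T4\t130\t1e-35\n"
        # cat3: 2 archaeal of 3 annotated, archaeal bit dominates
        "k3\tk3_1\t1\tSulfolobus virus STSV2\t110\t1e-25\n"
        "k3\tk3_2\t2\tHaloferax virus HF2\t88\t1e-15\n"
        "k3\tk3_3\t3\tPseudomonas phage phiKZ\t80\t1e-14\n"
        # rejected: all-phage contig
        "k4\tk4_1\t1\tEnterobacteria phage T4\t200\t1e-50\n"
        "k4\tk4_2\t2\tVibrio phage KVP40\t150\t1e-40\n"
        "k4\tk4_3\t3\tMycobacterium phage L5\t120\t1e-30\n"
    )

    def test_partition_of_mixed_table(self):
        result = classify_table(parse_annotation_table(self.TSV))
        part = result.partition()
        assert part == {"cat1": {"k1"}, "cat2": {"k2"}, "cat3": {"k3"},
                        "rejected": {"k4"}}

    def test_partition_covers_every_contig_exactly_once(self):
        result = classify_table(parse_annotation_table(self.TSV))
        part = result.partition()
        union = set().union(*part.values())
        assert union == set(parse_annotation_table(self.TSV).contig_ids())
        assert sum(len(s) for s in part.values()) == len(union)

    def test_empty_table_gives_empty_partition(self):
        result = classify_table(parse_annotation_table(""))
        assert all(len(s) == 0 for s in result.partition().values())

    def test_unreachable_bit_floor_rejects_everything(self):
        result = classify_table(parse_annotation_table(self.TSV),
                                Thresholds(min_bit=1000.0))
        assert result.partition()["rejected"] == {"k1", "k2", "k3", "k4"}
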