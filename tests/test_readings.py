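import itertools

import numpy as np
import pytest

import trnadecode as td
from trnadecode.code_tables import AminoAcidFamily, TrnaIsoacceptor
from trnadecode.readings import (
    InfeasibleReadingError,
    InvalidReadingError,
    ReadingMatrix,
    WobbleOptionSet,
)


def brute_force_count(n_trnas: int, n_codons: int) -> set[str]:
    """Oracle: all binary matrices with no zero row and no zero column."""
    valid = set()
    for cells in itertools.product((0, 1), repeat=n_trnas * n_codons):
        m = np.array(cells).reshape(n_trnas, n_codons)
        if (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all():
            valid.add("-".join("".join(map(str, row)) for row in m))
    return valid


def _family(n_codons):
    return AminoAcidFamily("A", ("GCU", "GCC", "GCA", "GCG")[:n_codons], box="GC")


def _trnas(n):
    anticodons = ("AGC", "UGC", "CGC", "GGC")
    return tuple(TrnaIsoacceptor("A", a, 1 + i) for i, a in enumerate(anticodons[:n]))


def test_single_trna_two_codons_has_one_reading():
    space = td.enumerate_all_readings(_family(2), _trnas(1))
    assert len(space) == 1
    assert space.readings[0].reads == ((1, 1),)


@pytest.mark.parametrize("n_trnas,n_codons", [(2, 2), (2, 4), (3, 3), (2, 3), (3, 4)])
def test_enumeration_matches_bitmask_oracle(n_trnas, n_codons):
    space = td.enumerate_all_readings(_family(n_codons), _trnas(n_trnas))
    got = {r.bits for r in space.readings}
    assert got == brute_force_count(n_trnas, n_codons)


def test_two_trnas_two_codons_has_seven_readings():
    space = td.enumerate_all_readings(_family(2), _trnas(2))
    assert len(space) == 7


def test_require_cognate_restricts_enumeration(ala_family, ala_trnas):
    free = td.enumerate_all_readings(ala_family, ala_trnas)
    strict = td.enumerate_all_readings(ala_family, ala_trnas, require_cognate=True)
    assert len(strict) < len(free)
    assert {r.bits for r in strict.readings} <= {r.bits for r in free.readings}
    ju, ja = ala_family.index_of("GCU"), ala_family.index_of("GCA")
    for r in strict.readings:
        assert r.reads[0][ju] == 1  # AGC must read its cognate GCU
        assert r.reads[1][ja] == 1  # UGC must read its cognate GCA


def test_plausible_subset_of_full_enumeration(ala_family, ala_trnas):
    space = td.enumerate_all_readings(ala_family, ala_trnas)
    plausible = {r.bits for r in td.plausible_readings(ala_family, ala_trnas)}
    assert plausible <= {r.bits for r in space.readings}
    assert sum(space.plausible_flags) == len(plausible)


def test_single_codon_family_is_trivial():
    family = AminoAcidFamily("M", ("AUG",))
    space = td.enumerate_all_readings(family, (TrnaIsoacceptor("M", "CAU", 5),))
    assert space.trivial and len(space) == 1


def test_reading_matrix_rejects_zero_rows_and_columns(ala_family, ala_trnas):
    with pytest.raises(InvalidReadingError):
        ReadingMatrix(ala_family, ala_trnas, ((0, 0, 0, 0), (1, 1, 1, 1)))
    with pytest.raises(InvalidReadingError):
        ReadingMatrix(ala_family, ala_trnas, ((1, 0, 0, 0), (1, 1, 1, 0)))


class TestPlausibleReadings:
    def test_c_wobble_reads_only_g_ending(self):
        family = AminoAcidFamily("Q", ("CAA", "CAG"), box="CA")
        trnas = (TrnaIsoacceptor("Q", "UUG", 9), TrnaIsoacceptor("Q", "CUG", 1))
        readings = td.plausible_readings(family, trnas)
        for r in readings:
            assert r.codons_read_by(1) == ("CAG",)  # CUG row
        assert {r.bits for r in readings} == {"10-01", "11-01"}

    def test_g_wobble_alone_in_pyrimidine_box(self):
        family = AminoAcidFamily("N", ("AAU", "AAC"), box="AA")
        trnas = (TrnaIsoacceptor("N", "GUU", 10),)
        readings = td.plausible_readings(family, trnas)
        assert len(readings) == 1
        assert readings[0].codons_read_by(0) == ("AAU", "AAC")

    def test_infeasible_combination_raises(self):
        # A C-wobble tRNA alone cannot cover a two-codon box
        family = AminoAcidFamily("Q", ("CAA", "CAG"), box="CA")
        trnas = (TrnaIsoacceptor("Q", "CUG", 1),)
        with pytest.raises(InfeasibleReadingError, match="CAA"):
            td.plausible_readings(family, trnas)

    def test_u_wobble_with_g_partner_in_four_box(self, ala_family):
        # restrict U to two options; G covers the pyrimidines
        options = WobbleOptionSet.from_mapping(
            {"U": [["A"], ["A", "G"]], "G": [["C", "U"]]}
        )
        trnas = (TrnaIsoacceptor("A", "UGC", 5), TrnaIsoacceptor("A", "GGC", 3))
        readings = td.plausible_readings(ala_family, trnas, options)
        # cross-product has two combinations; U={A} leaves GCG uncovered,
        # so exactly one reading survives
        assert len(readings) == 1
        assert readings[0].assignment == (
            ("GGC", ("GCU", "GCC")),
            ("UGC", ("GCA", "GCG")),
        )


class TestWobbleOptionSet:
    def test_default_honors_cg_constraints(self):
        options = WobbleOptionSet.default()
        assert options.for_base("C") == (frozenset("G"),)
        assert options.for_base("G") == (frozenset("CU"),)

    def test_rejects_option_without_watson_crick_partner(self):
        with pytest.raises(ValueError, match="Watson-Crick"):
            WobbleOptionSet.from_mapping({"U": [["G"]]})

    def test_rejects_broadened_c(self):
        with pytest.raises(ValueError, match="C must map"):
            WobbleOptionSet.from_mapping({"C": [["G", "U"]]})


class TestWobbleRules:
    def test_u_wobble_reads_purine_ending(self, ala_family):
        trnas = (TrnaIsoacceptor("A", "UGC", 5), TrnaIsoacceptor("A", "AGC", 11))
        reading = td.wobble_rules_reading(ala_family, trnas, variant="original")
        assert set(reading.codons_read_by(0)) == {"GCA", "GCG"}

    @pytest.mark.parametrize(
        "variant,expected",
        [("original", {"GCU", "GCC", "GCA"}), ("restricted", {"GCU", "GCC"})],
    )
    def test_a_wobble_treated_as_inosine(self, ala_family, variant, expected):
        trnas = (TrnaIsoacceptor("A", "AGC", 11), TrnaIsoacceptor("A", "UGC", 5))
        reading = td.wobble_rules_reading(ala_family, trnas, variant=variant)
        assert set(reading.codons_read_by(0)) == expected

    def test_idempotent_and_order_independent(self, ala_family, ala_trnas):
        fwd = td.wobble_rules_reading(ala_family, ala_trnas)
        rev = td.wobble_rules_reading(ala_family, ala_trnas[::-1])
        assert fwd.assignment == rev.assignment
        again = td.wobble_rules_reading(ala_family, ala_trnas)
        assert fwd == again

    def test_uncovered_codon_warns_but_returns(self):
        family = AminoAcidFamily("Q", ("CAA", "CAG"), box="CA")
        trnas = (TrnaIsoacceptor("Q", "CUG", 1),)
        reading = td.wobble_rules_reading(family, trnas)
        assert any("CAA" in w for w in reading.coverage_warnings)


class TestWobbleParsimony:
    def test_full_cognate_set_gives_diagonal(self, ala_family):
        trnas = tuple(
            TrnaIsoacceptor("A", a, 1) for a in ("AGC", "GGC", "UGC", "CGC")
        )
        reading = td.wobble_parsimony_reading(ala_family, trnas)
        assert reading.matrix.tolist() == np.eye(4, dtype=int).tolist()

    def test_yeast_like_alanine_trace(self, ala_family, ala_trnas):
        # pass 1: AGC->GCU, UGC->GCA; pass 2: A:C gives GCC to AGC;
        # pass 3: U:G gives GCG to UGC
        reading = td.wobble_parsimony_reading(ala_family, ala_trnas)
        assert reading.assignment == (
            ("AGC", ("GCU", "GCC")),
            ("UGC", ("GCA", "GCG")),
        )

    def test_a_and_u_wobble_four_box(self):
        family = AminoAcidFamily("P", ("CCU", "CCC", "CCA", "CCG"), box="CC")
        trnas = (TrnaIsoacceptor("P", "AGG", 10), TrnaIsoacceptor("P", "UGG", 2))
        reading = td.wobble_parsimony_reading(family, trnas)
        assert reading.assignment == (
            ("AGG", ("CCU", "CCC")),
            ("UGG", ("CCA", "CCG")),
        )

    def test_refused_for_prokaryotes(self, ala_family, ala_trnas):
        with pytest.raises(ValueError, match="eukaryotes"):
            td.wobble_parsimony_reading(ala_family, ala_trnas, eukaryote=False)
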