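"""The prioritization cascade: genotype quality, consequence, MAF, consensus."""

from itertools import product

import pytest
from hypothesis import given
from hypothesis import strategies as st

from famvarseg.core_io import (
    INDEL_TOOLS,
    SNV_TOOLS,
    AnnotatedVariant,
    VariantCall,
)
from famvarseg.filters import (
    FilterConfig,
    consequence_filter,
    deleteriousness_filter,
    het_call_filter,
    maf_filter,
    shared_candidates,
)
from tests.conftest import make_nuclear


def call(dp: int, ad: int) -> VariantCall:
    return VariantCall("S", "1", 100, "A", "T", dp, ad)


def snv(conseq="missense", maf=None, grid=("D",) * 5, protein=None) -> AnnotatedVariant:
    return AnnotatedVariant(
        "1", 100, "A", "T", "G1", conseq, maf, dict(zip(SNV_TOOLS, grid)), protein
    )


def indel(grid=("D", "N", "N"), conseq="frameshift") -> AnnotatedVariant:
    return AnnotatedVariant(
        "1", 100, "A", "AT", "G1", conseq, None, dict(zip(INDEL_TOOLS, grid))
    )


class TestHetCallFilter:
    @pytest.mark.parametrize(
        "dp,ad,expected",
        [
            (40, 12, True),   # AB 0.30
            (9, 4, False),    # below coverage threshold
            (40, 10, True),   # AB exactly 0.25, inclusive boundary
            (40, 30, True),   # AB exactly 0.75, inclusive boundary
            (40, 9, False),   # AB below 0.25
            (40, 31, False),  # AB above 0.75
            (0, 0, False),    # zero depth fails, no division error
            (10, 5, True),    # minimum coverage passes
        ],
    )
    def test_boundaries(self, dp, ad, expected):
        assert het_call_filter(call(dp, ad)) is expected

    def test_exhaustive_ab_grid_matches_stated_interval(self):
        # independent oracle: direct evaluation of depth >= 10 and
        # 0.25 <= ad/dp <= 0.75 over every (dp, ad) combination
        cfg = FilterConfig()
        for dp in range(0, 41):
            for ad in range(0, dp + 1):
                expected = dp >= 10 and 0.25 <= ad / dp <= 0.75
                assert het_call_filter(call(dp, ad), cfg) is expected


class TestConsequenceAndMaf:
    @pytest.mark.parametrize(
        "conseq,expected",
        [
            ("missense", True),
            ("nonsense", True),
            ("frameshift", True),
            ("inframe_indel", True),
            ("splice", True),
            ("synonymous", False),
            ("other", False),
        ],
    )
    def test_consequence(self, conseq, expected):
        v = indel(conseq=conseq) if conseq in ("frameshift", "inframe_indel") else snv(conseq)
        assert consequence_filter(v) is expected

    @pytest.mark.parametrize(
        "maf,expected",
        [
            (9.99e-04, True),   # just below 0.1%
            (None, True),       # absent from the reference panel
            (0.001, False),     # strict inequality at the threshold
            (0.05, False),
        ],
    )
    def test_maf(self, maf, expected):
        assert maf_filter(snv(maf=maf)) is expected


class TestDeleteriousnessFilter:
    @pytest.mark.parametrize(
        "grid,expected",
        [
            (("D", "D", "P", "N", "N"), True),   # 3 damaging votes
            (("N", "N", "N", "N", "N"), False),
            (("D", "D", "N", "NA", "U"), False),  # 2 votes, NA/U not damaging
            (("D", "D", "D", "NA", "N"), True),   # NA keeps denominator at 5
            (("P", "P", "P", "N", "N"), True),    # possibly-damaging counts
        ],
    )
    def test_snv_consensus(self, grid, expected):
        assert deleteriousness_filter(snv(grid=grid)) is expected

    @pytest.mark.parametrize(
        "grid,expected",
        [
            (("D", "N", "N"), True),  # 1 of 3 suffices for InDels
            (("N", "N", "N"), False),
            (("N", "N", "P"), True),
        ],
    )
    def test_indel_rule(self, grid, expected):
        assert deleteriousness_filter(indel(grid)) is expected

    @pytest.mark.parametrize(
        "grid,expected",
        [
            (("NA", "NA", "NA", "NA", "D"), True),   # MutationTaster D decides
            (("D", "D", "D", "D", "N"), False),      # without MT it fails
            (("NA", "NA", "NA", "NA", "P"), False),  # P is not enough for stop-gains
        ],
    )
    def test_stop_gain_rule(self, grid, expected):
        assert deleteriousness_filter(snv("nonsense", grid=grid)) is expected

    def test_brute_force_enumeration(self):
        # oracle: count >= 3 calls in {D, P} over every 5-tool grid
        n_pass = 0
        for grid in product(["D", "P", "N", "U", "NA"], repeat=5):
            expected = sum(c in ("D", "P") for c in grid) >= 3
            got = deleteriousness_filter(snv(grid=grid))
            assert got is expected
            n_pass += got
        assert n_pass == 992

    def test_whole_candidate_table_passes(self):
        from famvarseg.core_io import load_table1_fixture

        for rec in load_table1_fixture():
            assert deleteriousness_filter(rec.variant)
            assert maf_filter(rec.variant)
            assert consequence_filter(rec.variant)


@given(
    grid=st.tuples(*[st.sampled_from(["D", "P", "N", "U", "NA"])] * 5),
    votes=st.integers(1, 5),
)
def test_relaxing_vote_threshold_is_monotone(grid, votes):
    """Lowering the required vote count never turns a pass into a fail."""
    strict = FilterConfig(snv_min_damaging_votes=votes)
    v = snv(grid=grid)
    if deleteriousness_filter(v, strict):
        for fewer in range(1, votes):
            assert deleteriousness_filter(v, FilterConfig(snv_min_damaging_votes=fewer))


@given(maf=st.floats(1e-7, 0.01), factor=st.floats(1.0, 50.0))
def test_relaxing_maf_threshold_is_monotone(maf, factor):
    v = snv(maf=maf)
    if maf_filter(v, FilterConfig(maf_threshold=0.001)):
        assert maf_filter(v, FilterConfig(maf_threshold=0.001 * factor))


class TestSharedCandidates:
    @staticmethod
    def family_and_calls(member_calls):
        ped = make_nuclear(n_children=3, child_phenos=("BD1", "BD1", "BD1"))
        from dataclasses import replace

        members = [
            replace(m, sequenced=m.individual_id.startswith("C"), dna_available=True)
            for m in ped.members
        ]
        from famvarseg.core_io import Pedigree

        return Pedigree("fam", members), member_calls

    def hetcall(self, sid, pos=100, dp=40, ad=15, ref="A", alt="T"):
        return VariantCall(sid, "1", pos, ref, alt, dp, ad)

    def test_shared_by_all_three_passes(self):
        ped, calls = self.family_and_calls(
            {f"C{i}": [self.hetcall(f"C{i}")] for i in range(3)}
        )
        ann = {("1", 100, "A", "T"): snv()}
        (cand,) = shared_candidates(ped, calls, ann)
        assert cand.passed
        assert cand.carrier_samples == {"C0", "C1", "C2"}
        assert [n for n, _ in cand.filter_trail] == [
            "het_shared", "consequence", "maf", "deleteriousness",
        ]

    def test_two_of_three_excluded(self):
        ped, calls = self.family_and_calls(
            {"C0": [self.hetcall("C0")], "C1": [self.hetcall("C1")], "C2": []}
        )
        ann = {("1", 100, "A", "T"): snv()}
        assert shared_candidates(ped, calls, ann) == []

    def test_low_depth_member_excludes_variant(self):
        ped, calls = self.family_and_calls(
            {
                "C0": [self.hetcall("C0")],
                "C1": [self.hetcall("C1", dp=8, ad=4)],
                "C2": [self.hetcall("C2")],
            }
        )
        ann = {("1", 100, "A", "T"): snv()}
        assert shared_candidates(ped, calls, ann) == []
        # relaxing the depth threshold recovers it (monotonicity)
        relaxed = FilterConfig(min_depth=5)
        assert len(shared_candidates(ped, calls, ann, relaxed)) == 1

    def test_missing_call_file_errors(self):
        ped, calls = self.family_and_calls({"C0": [], "C1": []})
        with pytest.raises(ValueError, match="C2"):
            shared_candidates(ped, calls, {})

    def test_failing_downstream_filter_recorded_in_trail(self):
        ped, calls = self.family_and_calls(
            {f"C{i}": [self.hetcall(f"C{i}")] for i in range(3)}
        )
        ann = {("1", 100, "A", "T"): snv(conseq="synonymous")}
        assert shared_candidates(ped, calls, ann) == []
        (failed,) = shared_candidates(ped, calls, ann, keep_failed=True)
        assert dict(failed.filter_trail)["consequence"] is False
        assert not failed.passed
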