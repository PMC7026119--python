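"""Covariate-matched permutation enrichment and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famvarseg.core_io import GeneSet
from famvarseg.enrichment import (
    MatchingConfig,
    MatchingError,
    bh_adjust,
    enrich_all,
    match_candidates,
    permutation_test,
)


def bh_oracle(ps):
    """Direct step-up formula: q_i = min over j >= rank(i) of p_(j) * m / j."""
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        out[i] = running
    return out.tolist()


class TestBhAdjust:
    def test_frozen_example(self):
        assert bh_adjust([0.001, 0.02, 0.03, 0.9]) == pytest.approx(
            [0.004, 0.04, 0.04, 0.9]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == [pytest.approx(0.123)]

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])

    @given(
        ps=st.lists(
            st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=30
        )
    )
    def test_matches_step_up_oracle(self, ps):
        got = bh_adjust(ps)
        expected = bh_oracle(ps)
        assert got == pytest.approx(expected)
        assert all(0 < q <= 1 for q in got)
        assert all(q >= p for q, p in zip(got, ps))


def toy_universe():
    # candidates C1, C2 plus six pool genes with hand-placed covariates
    return pd.DataFrame(
        {
            "exon_length": [1000, 3000, 1000, 1100, 1190, 2900, 700, 1201],
            "coverage": [60.0, 60.0, 60.0, 60.0, 60.0, 60.0, 60.0, 60.0],
            "constraint_z": [0.0, 1.0, 0.1, 0.4, -0.4, 1.2, 0.0, 0.0],
        },
        index=pd.Index(
            ["C1", "C2", "U1", "U2", "U3", "U4", "U5", "U6"], name="gene"
        ),
    )


class TestMatching:
    def test_window_arithmetic(self):
        """C1 (exon 1000) may match exon lengths in [800, 1200] only."""
        uni = toy_universe()
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(500):
            (m,) = match_candidates(["C1"], uni, rng=rng)
            seen.add(m)
        # U5 (700) and U6 (1201) fall outside +/- 20%; U4 outside the z window
        assert seen == {"U1", "U2", "U3"}

    def test_exact_clone_always_eligible(self):
        uni = toy_universe()
        for _ in range(50):
            (m,) = match_candidates(["C2"], uni, rng=np.random.default_rng(1))
            assert m == "U4"  # the only gene within all three windows of C2

    def test_sampler_support_matches_exhaustive_enumeration(self):
        """Two candidates: the set of drawn pairs equals the enumerated
        eligible pairs (distinct genes within each draw)."""
        uni = toy_universe()
        elig = {"C1": {"U1", "U2", "U3"}, "C2": {"U4"}}
        expected_pairs = {
            (a, b) for a in elig["C1"] for b in elig["C2"] if a != b
        }
        rng = np.random.default_rng(2)
        seen = set()
        for _ in range(10_000):
            a, b = match_candidates(["C1", "C2"], uni, rng=rng)
            seen.add((a, b))
        assert seen == expected_pairs

    def test_empty_window_raises_naming_gene(self):
        uni = pd.DataFrame(
            {
                "exon_length": [1000, 50_000],
                "coverage": [60.0, 60.0],
                "constraint_z": [0.0, 0.0],
            },
            index=pd.Index(["C1", "U1"], name="gene"),
        )
        with pytest.raises(MatchingError, match="C1"):
            match_candidates(["C1"], uni, rng=0)

    def test_z_window_relaxation(self):
        uni = pd.DataFrame(
            {
                "exon_length": [1000, 1000],
                "coverage": [60.0, 60.0],
                "constraint_z": [0.0, 1.5],  # outside 0.5, inside 0.5 * 2^2
            },
            index=pd.Index(["C1", "U1"], name="gene"),
        )
        (m,) = match_candidates(["C1"], uni, rng=0)
        assert m == "U1"

    def test_missing_covariates_raise(self):
        with pytest.raises(MatchingError, match="C9"):
            match_candidates(["C9"], toy_universe(), rng=0)


def random_universe(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "exon_length": np.exp(rng.normal(np.log(1500), 0.6, n)).astype(int) + 100,
            "coverage": rng.normal(68, 5, n).clip(30),
            "constraint_z": rng.normal(0, 1.0, n),
        },
        index=pd.Index([f"G{i:04d}" for i in range(n)], name="gene"),
    )


class TestPermutationTest:
    def test_disjoint_set_is_null(self):
        uni = random_universe()
        candidates = list(uni.index[:10])
        gs = GeneSet("disjoint", frozenset({"X1", "X2"}))
        res = permutation_test(
            candidates, gs, uni, MatchingConfig(n_permutations=200), rng=0
        )
        assert res.n_observed == 0
        assert res.p_empirical == 1.0
        assert res.n_expected == 0.0

    def test_candidates_inside_set_extreme_p(self):
        uni = random_universe()
        candidates = list(uni.index[:8])
        gs = GeneSet("all_in", frozenset(candidates))  # set disjoint from pool
        n = 300
        res = permutation_test(
            candidates, gs, uni, MatchingConfig(n_permutations=n), rng=0
        )
        assert res.n_observed == 8
        assert res.p_empirical == pytest.approx(1 / (n + 1))

    def test_matching_validity_post_hoc(self):
        """Every drawn null gene lies inside its candidate's (possibly
        relaxed) windows, at the relaxation level the sampler recorded."""
        from famvarseg.enrichment import _PROPORTIONAL_RELAX, _eligibility

        uni = random_universe(seed=3)
        candidates = list(uni.index[:6])
        cfg = MatchingConfig()
        _, stages = _eligibility(candidates, uni, cfg)
        rng = np.random.default_rng(4)
        for _ in range(100):
            drawn = match_candidates(candidates, uni, cfg, rng)
            assert len(set(drawn)) == len(drawn)
            for cand, null, stage in zip(candidates, drawn, stages):
                c, n = uni.loc[cand], uni.loc[null]
                widen = _PROPORTIONAL_RELAX ** max(0, stage - cfg.z_relax_max)
                zmax = cfg.constraint_z_tol * cfg.z_relax_factor ** min(
                    stage, cfg.z_relax_max
                )
                assert abs(n.exon_length - c.exon_length) <= 0.2 * widen * c.exon_length
                assert abs(n.coverage - c.coverage) <= 0.2 * widen * c.coverage
                assert abs(n.constraint_z - c.constraint_z) <= zmax

    def test_expected_overlap_converges(self):
        uni = random_universe(seed=5)
        candidates = list(uni.index[:12])
        members = frozenset(uni.index[50:150])
        gs = GeneSet("s", members)
        res1 = permutation_test(
            candidates, gs, uni, MatchingConfig(n_permutations=400), rng=10
        )
        res2 = permutation_test(
            candidates, gs, uni, MatchingConfig(n_permutations=800), rng=11
        )
        null_sd = max(np.sqrt(res1.n_expected), 0.5)
        assert abs(res1.n_expected - res2.n_expected) < 3 * null_sd / np.sqrt(400)

    def test_joint_bh_across_sets(self):
        uni = random_universe(seed=6)
        candidates = list(uni.index[:10])
        sets = [
            GeneSet("a", frozenset(uni.index[20:60])),
            GeneSet("b", frozenset(uni.index[60:100])),
            GeneSet("c", frozenset(candidates)),
        ]
        results = enrich_all(
            candidates, sets, uni, MatchingConfig(n_permutations=200), rng=1
        )
        ps = [r.p_empirical for r in results]
        assert [r.p_adjusted for r in results] == pytest.approx(bh_oracle(ps))
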