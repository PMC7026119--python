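"""The synthetic-cohort generator: pedigrees, gene dropping, phenotypes,
file outputs and ground truth."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from famvarseg.core_io import read_annotations, read_calls, read_pedigrees
from famvarseg.filters import shared_candidates
from famvarseg.simulate import (
    SimulationConfig,
    SimulationError,
    assign_phenotypes,
    drop_variant,
    select_sequenced_trio,
    simulate_cohort,
    simulate_pedigree,
)
from tests.conftest import make_nuclear

CFG = SimulationConfig()


class TestSimulatePedigree:
    def test_two_generations_two_children(self):
        ped = simulate_pedigree(
            SimulationConfig(pedigree_depth=2),
            np.random.default_rng(0),
            children_per_couple=2,
        )
        assert len(ped) == 4
        assert len(ped.founders) == 2

    def test_same_seed_identical(self):
        a = simulate_pedigree(CFG, np.random.default_rng(5))
        b = simulate_pedigree(CFG, np.random.default_rng(5))
        assert a == b

    def test_three_generations_have_multiple_sibships(self):
        # graph-traversal oracle: count distinct parent couples with children
        ped = simulate_pedigree(CFG, np.random.default_rng(1), children_per_couple=2)
        couples = {
            (m.father_id, m.mother_id) for m in ped.members if not m.is_founder
        }
        assert len(couples) >= 2
        assert max(ped.generation_depth(m.individual_id) for m in ped.members) == 2

    def test_parents_sex_consistent(self):
        ped = simulate_pedigree(CFG, np.random.default_rng(2))
        for m in ped.members:
            if not m.is_founder:
                assert ped[m.father_id].sex == "male"
                assert ped[m.mother_id].sex == "female"


class TestDropVariant:
    def test_founder_always_carries(self):
        ped = make_nuclear()
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert "M" in drop_variant(ped, "M", rng)

    def test_non_founder_rejected(self):
        with pytest.raises(ValueError, match="not a founder"):
            drop_variant(make_nuclear(), "C0", np.random.default_rng(0))

    def test_non_descendants_never_carry(self):
        ped = make_nuclear()
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert "F" not in drop_variant(ped, "M", rng)

    def test_grandchild_carries_one_quarter(self):
        """Monte Carlo vs the exact transmission probability 1/4."""
        cfg = SimulationConfig()
        ped = simulate_pedigree(cfg, np.random.default_rng(3), children_per_couple=2)
        grandchildren = [
            m.individual_id
            for m in ped.members
            if ped.generation_depth(m.individual_id) == 2
        ]
        target = grandchildren[0]
        # locate the lineal founder grandparent of the target
        parent = ped[target]
        lineal_parent = (
            ped[parent.father_id]
            if not ped[parent.father_id].is_founder
            else ped[parent.mother_id]
        )
        founder = lineal_parent.father_id
        rng = np.random.default_rng(4)
        n = 100_000
        hits = sum(target in drop_variant(ped, founder, rng) for _ in range(n))
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(hits / n - 0.25) < 3 * se


class TestAssignPhenotypes:
    def test_full_penetrance_no_phenocopies(self):
        ped = make_nuclear(n_children=6)
        cfg = SimulationConfig(causal_penetrance=1.0, phenocopy_rate=0.0)
        carriers = frozenset({"M", "C0", "C3"})
        out = assign_phenotypes(ped, carriers, cfg, np.random.default_rng(0))
        affected = {m.individual_id for m in out.members if m.affected_bd}
        assert affected == set(carriers)

    def test_diagnosis_split_matches_cohort_ratios(self):
        ped = make_nuclear(n_children=30)
        cfg = SimulationConfig(causal_penetrance=1.0, phenocopy_rate=0.0)
        carriers = frozenset(m.individual_id for m in ped.members)
        rng = np.random.default_rng(1)
        counts = {"BD1": 0, "BD2": 0, "BD_NOS": 0}
        total = 0
        for _ in range(300):
            out = assign_phenotypes(ped, carriers, cfg, rng)
            for m in out.members:
                counts[m.phenotype] += 1
                total += 1
        assert counts["BD1"] / total == pytest.approx(69 / 81, abs=0.02)
        assert counts["BD2"] / total == pytest.approx(9 / 81, abs=0.02)
        assert counts["BD_NOS"] / total == pytest.approx(3 / 81, abs=0.01)

    def test_half_penetrance_binomial(self):
        ped = make_nuclear(n_children=38)
        cfg = SimulationConfig(causal_penetrance=0.5, phenocopy_rate=0.0)
        carriers = frozenset(m.individual_id for m in ped.members)
        rng = np.random.default_rng(2)
        n_aff = n_tot = 0
        for _ in range(300):
            out = assign_phenotypes(ped, carriers, cfg, rng)
            n_aff += sum(m.affected_bd for m in out.members)
            n_tot += len(out.members)
        se = np.sqrt(0.25 / n_tot)
        assert abs(n_aff / n_tot - 0.5) < 3 * se

    def test_unknown_carrier_rejected(self):
        with pytest.raises(ValueError, match="ZZ"):
            assign_phenotypes(
                make_nuclear(), {"ZZ"}, CFG, np.random.default_rng(0)
            )


class TestTrioSelection:
    def test_most_distant_members_chosen(self):
        from famvarseg.core_io import Individual, Pedigree

        # grandparents -> two married children -> one grandchild each;
        # the most distant affected triple is the two grandchildren plus
        # one grandparent, not three members of one nuclear unit
        members = [
            Individual("GF", "f", None, None, "male", "BD1", True),
            Individual("GM", "f", None, None, "female", "UNAFFECTED", True),
            Individual("P1", "f", "GF", "GM", "male", "BD1", True),
            Individual("P2", "f", "GF", "GM", "female", "BD1", True),
            Individual("S1", "f", None, None, "female", "UNAFFECTED", True),
            Individual("S2", "f", None, None, "male", "UNAFFECTED", True),
            Individual("K1", "f", "P1", "S1", "male", "BD1", True),
            Individual("K2", "f", "S2", "P2", "female", "BD1", True),
        ]
        ped = Pedigree("f", members)
        trio = select_sequenced_trio(ped, 3)
        assert trio == ["GF", "K1", "K2"]

    def test_insufficient_affecteds_error(self):
        ped = make_nuclear(n_children=1, child_phenos=("BD1",))
        with pytest.raises(SimulationError, match="fam"):
            select_sequenced_trio(ped, 3)


class TestSimulateCohort:
    def test_cohort_shape_and_sequencing(self, cohort_small):
        config, paths, truth = cohort_small
        peds = read_pedigrees(paths["ped"])
        assert len(peds) == config.n_families
        for ped in peds:
            seq = ped.sequenced_members
            assert len(seq) == 3
            assert all(m.affected_bd for m in seq)

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_families=2, n_genes=400, seed=9)
        p1, _ = simulate_cohort(cfg, tmp_path / "a")
        p2, _ = simulate_cohort(cfg, tmp_path / "b")
        for name, path in p1.items():
            if Path(path).is_file():
                assert filecmp.cmp(path, p2[name], shallow=False), name

    def test_mendelian_consistency_of_causal_carriers(self, cohort_small):
        _, paths, truth = cohort_small
        peds = {p.family_id: p for p in read_pedigrees(paths["ped"])}
        for fam, carriers in truth.causal_carriers.items():
            ped = peds[fam]
            founders_in = [c for c in carriers if ped[c].is_founder]
            assert len(founders_in) == 1  # single founder introduction
            for c in carriers:
                m = ped[c]
                if not m.is_founder:
                    assert m.father_id in carriers or m.mother_id in carriers

    def test_maf_spectrum_null_fraction(self, cohort_small):
        config, paths, _ = cohort_small
        ann = pd.read_csv(
            paths["annotations"], sep="\t", dtype=str, keep_default_na=False
        )
        frac_null = (ann["ref_maf"] == "NA").mean()
        # pool and causal variants dilute the background fraction slightly
        n = len(ann)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac_null - config.maf_spectrum.null_fraction) < 5 * se + 0.02

    def test_clean_cohort_recovers_exactly_the_causal_variants(self, tmp_path):
        """With full penetrance and zero background, each family's candidate
        list is exactly its injected causal variant."""
        cfg = SimulationConfig(
            n_families=3,
            causal_gene_count=2,
            causal_penetrance=1.0,
            phenocopy_rate=0.0,
            background_variant_rate=0.0,
            n_shared_pool=0,
            n_genes=300,
            prediction_error_rate=0.0,
            seed=21,
        )
        paths, truth = simulate_cohort(cfg, tmp_path)
        ann = read_annotations(paths["annotations"])
        for ped in read_pedigrees(paths["ped"]):
            calls = {
                m.individual_id: read_calls(
                    tmp_path / "vcf" / f"{m.individual_id}.vcf"
                )
                for m in ped.sequenced_members
            }
            cands = shared_candidates(ped, calls, ann)
            assert len(cands) == 1
            assert cands[0].variant.key == truth.causal_variants[ped.family_id]

    def test_infeasible_family_errors_with_name(self, tmp_path):
        cfg = SimulationConfig(
            n_families=1,
            causal_gene_count=0,
            causal_penetrance=0.0,
            phenocopy_rate=0.0,
            n_genes=100,
            n_shared_pool=0,
            seed=2,
        )
        with pytest.raises(SimulationError, match="0001"):
            simulate_cohort(cfg, tmp_path)
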