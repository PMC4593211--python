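"""Properties of the synthetic-data generator itself."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpipe.hairpin import fold
from mirpipe.io import revcomp
from mirpipe.simulate import (
    SimulationConfig,
    make_reference_dbs,
    narrative_triage_fixture,
    simulate_genome,
    simulate_libraries,
    simulate_ortholog_expression,
)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(mature_fraction=0.9, decoy_fraction=0.9)

    def test_sample_sheet_has_missing_replicate(self):
        sheet = SimulationConfig().sample_sheet()
        assert len(sheet) == 14  # 5 stages x 3 minus the unsequenced one
        assert [l.replicate for l in sheet.by_stage("female_pupa")] == [1, 3]


class TestGenome:
    def test_deterministic_under_seed(self, small_sim):
        cfg, sim, _ = small_sim
        sim2 = simulate_genome(cfg)
        assert [s.sequence for s in sim2.scaffolds] == [s.sequence for s in sim.scaffolds]
        pd.testing.assert_frame_equal(sim2.truth, sim.truth)

    def test_different_seed_same_schema(self, small_sim):
        cfg, sim, _ = small_sim
        from dataclasses import replace

        sim2 = simulate_genome(replace(cfg, seed=cfg.seed + 1))
        assert list(sim2.truth.columns) == list(sim.truth.columns)
        assert len(sim2.planted) == len(sim.planted)
        assert sim2.scaffolds[0].sequence != sim.scaffolds[0].sequence

    def test_planted_sequences_on_genome(self, small_sim):
        _, sim, _ = small_sim
        scaff = {s.name: s for s in sim.scaffolds}
        for p in sim.planted:
            genomic = scaff[p.scaffold].subseq(p.start, p.end)
            expected = p.precursor if p.strand == "+" else revcomp(p.precursor)
            assert genomic == expected
            assert p.precursor.startswith(p.mature)

    def test_planted_hairpins_fold_back(self, small_sim):
        _, sim, _ = small_sim
        for p in sim.planted[:4]:
            structure, mfe = fold(p.precursor)
            # the mature arm is predominantly paired in a real fold-back
            L = len(p.mature)
            paired = sum(1 for c in structure[:L] if c == "(")
            assert paired >= 0.8 * L
            assert mfe < -30

    def test_exon_overlap_categories_exercised(self, small_sim):
        from mirpipe.hairpin import classify_exon_overlap

        _, sim, _ = small_sim
        cats = {
            classify_exon_overlap((p.scaffold, p.start, p.end), sim.exons).category
            for p in sim.planted
        }
        assert {"within_exon", "contains_exon", "overlaps_exon_boundary",
                "intronic", "intergenic"} <= cats

    def test_zero_mirnas_empty_truth(self):
        cfg = SimulationConfig(
            n_known_mirnas=0, n_novel_mirnas=0, n_clusters=0, cluster_members=(),
            n_scaffolds=1, scaffold_len=20_000,
        )
        sim = simulate_genome(cfg)
        assert sim.planted == [] and sim.truth.empty

    def test_insufficient_scaffold_errors(self):
        cfg = SimulationConfig(
            n_scaffolds=1, scaffold_len=3000, n_known_mirnas=20, n_novel_mirnas=5,
        )
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(cfg)


class TestLibraries:
    def test_deterministic(self, small_sim):
        cfg, sim, libs = small_sim
        libs2 = simulate_libraries(sim, cfg)
        assert libs2.reads == libs.reads
        pd.testing.assert_frame_equal(libs2.expected_counts, libs.expected_counts)

    def test_read_lengths_and_short_fraction(self, small_sim):
        cfg, sim, libs = small_sim
        lib = libs.reads["egg_r1"]
        lengths = np.array([len(r) for r in lib])
        short = (lengths < 17).mean()
        assert abs(short - cfg.short_fraction) < 0.01
        assert lengths.max() <= 28 and lengths.min() >= 12

    def test_zero_dispersion_counts_equal_expectation(self):
        cfg = SimulationConfig(
            seed=3, n_scaffolds=2, scaffold_len=45_000,
            n_known_mirnas=6, n_novel_mirnas=0, n_clusters=0, cluster_members=(),
            dispersion=0.0, depth_per_library=2000,
        )
        sim = simulate_genome(cfg)
        libs1 = simulate_libraries(sim, cfg)
        libs2 = simulate_libraries(sim, cfg)
        pd.testing.assert_frame_equal(libs1.expected_counts, libs2.expected_counts)
        # with dispersion 0 the drawn counts are the deterministic means
        stage_cols = [c for c in libs1.expected_counts.columns if c.startswith("egg")]
        sub = libs1.expected_counts[stage_cols]
        assert (sub.nunique(axis=1) == 1).all()

    def test_missing_library_absent(self, small_sim):
        _, _, libs = small_sim
        assert "female_pupa_r2" not in libs.reads
        assert "female_pupa_r2" not in libs.expected_counts.columns

    def test_group_profiles_shape_expected_counts(self, small_sim):
        _, sim, libs = small_sim
        by_stage = libs.expected_counts.T.groupby(
            {l.library_id: l.stage for l in libs.sheet}
        ).mean().T
        for p in sim.planted:
            row = by_stage.loc[p.id]
            if p.group == 2 and row.max() > 50:
                assert row.idxmax() == "larva"
            if p.group == 3 and row.max() > 50:
                assert row[["male_pupa", "female_pupa"]].max() < 0.2 * row.max()


class TestReferenceDbs:
    def test_mutation_classes(self, small_sim):
        from mirpipe.homology import match_mature

        cfg, sim, _ = small_sim
        ref = make_reference_dbs(sim, cfg)
        by_id = {p.id: p for p in sim.planted}
        for sim_id, ref_id in ref.orthologs:
            m = match_mature(by_id[sim_id].mature, ref.mature_db)
            n_mut = ref.mutations[ref_id]
            if n_mut == 0:
                assert m.subject_id == ref_id and m.match_class == "perfect"
            elif n_mut == 1:
                assert m.subject_id == ref_id and m.match_class == "near_perfect"

    def test_novel_omitted(self, small_sim):
        cfg, sim, _ = small_sim
        ref = make_reference_dbs(sim, cfg)
        novel = {p.id for p in sim.planted if p.novel}
        assert novel.isdisjoint({a for a, _ in ref.orthologs})


class TestOrthologExpression:
    def test_configured_rho_recovered(self):
        """Target Spearman 0.8 recovered within +-0.1 at n>=60 pairs."""
        rng = np.random.default_rng(0)
        expr_a = pd.DataFrame(
            {s: np.exp(rng.normal(4, 1.2, 80)) for s in ["egg", "larva", "ovary"]},
            index=[f"m{i}" for i in range(80)],
        )
        expr_b = simulate_ortholog_expression(expr_a, rho=0.8, seed=5)
        for s in expr_a.columns:
            rho = stats.spearmanr(expr_a[s], expr_b[s]).statistic
            assert abs(rho - 0.8) <= 0.1

    def test_rho_range_configurable(self):
        rng = np.random.default_rng(1)
        expr_a = pd.DataFrame({"egg": np.exp(rng.normal(4, 1.2, 80))})
        lo = simulate_ortholog_expression(expr_a, rho=0.3, seed=2)
        hi = simulate_ortholog_expression(expr_a, rho=0.9, seed=2)
        r_lo = stats.spearmanr(expr_a.egg, lo.egg).statistic
        r_hi = stats.spearmanr(expr_a.egg, hi.egg).statistic
        assert r_lo < r_hi and abs(r_hi - 0.9) < 0.1


def test_narrative_fixture_counts():
    counts, star, hp = narrative_triage_fixture()
    assert len(counts) == len(star) == len(hp) == 35
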