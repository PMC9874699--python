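"""Properties of the synthetic cohort generator."""

import numpy as np
import pytest

from famsv import synthetic_cohort as sc
from famsv.brain_enrichment import cell_name, high_expression_set
from famsv.sv_io import CohortManifest


class TestLengthModel:
    def test_minimum_respected(self):
        rng = np.random.default_rng(0)
        lengths = sc.LengthModel().sample(5000, rng)
        assert lengths.min() >= 30

    def test_bimodal_log10_density(self):
        """The mixture shows local maxima at the Alu (~2.5) and L1 (~3.8)
        positions on the log10-length scale."""
        rng = np.random.default_rng(1)
        logs = np.log10(sc.LengthModel().sample(10_000, rng))
        hist, edges = np.histogram(logs, bins=np.arange(1.4, 4.2, 0.1))
        centers = (edges[:-1] + edges[1:]) / 2
        local_max = [centers[i] for i in range(1, len(hist) - 1)
                     if hist[i] >= hist[i - 1] and hist[i] >= hist[i + 1]
                     and hist[i] > 0]
        assert any(abs(c - 2.5) <= 0.15 for c in local_max)
        assert any(abs(c - 3.8) <= 0.15 for c in local_max)

    def test_tail_median_near_60(self):
        rng = np.random.default_rng(2)
        model = sc.LengthModel(weights=(1.0, 0.0, 0.0))
        med = np.median(model.sample(20_000, rng))
        assert 55 <= med <= 65

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            sc.LengthModel(weights=(0.5, 0.5, 0.5))


class TestSimulateTruth:
    def test_deterministic_under_seed(self, manifest):
        a = sc.simulate_truth(manifest, n_shared=50, n_case_specific=10, seed=7)
        b = sc.simulate_truth(manifest, n_shared=50, n_case_specific=10, seed=7)
        assert a.by_sample == b.by_sample
        assert a.case_specific == b.case_specific

    def test_case_specific_only_in_probands(self, manifest):
        truth = sc.simulate_truth(manifest, n_shared=50, n_case_specific=10,
                                  seed=3)
        for rel in manifest.relatives:
            assert not any(sv.case_specific for sv in truth.by_sample[rel])

    def test_shared_reach_a_relative(self, manifest):
        truth = sc.simulate_truth(manifest, n_shared=40, n_case_specific=0,
                                  seed=4)
        rels = set(manifest.relatives)
        for sv in truth.shared:
            carriers = {s for s, lst in truth.by_sample.items() if sv in lst}
            assert carriers & rels

    def test_case_specific_requires_probands(self):
        lone = CohortManifest({"p": "proband"})
        sc.simulate_truth(lone, n_shared=0, n_case_specific=1, seed=0)
        with pytest.raises(ValueError):
            bad = CohortManifest.__new__(CohortManifest)
            object.__setattr__(bad, "roles", {"r": "unaffected_relative"})
            object.__setattr__(bad, "family_id", "F")
            sc.simulate_truth(bad, n_shared=0, n_case_specific=1, seed=0)

    def test_gene_placement(self, manifest):
        models = sc.simulate_gene_models(n_genes=50, seed=1)
        truth = sc.simulate_truth(manifest, n_shared=0, n_case_specific=20,
                                  seed=2, gene_models=models)
        by_name = {m.name: m for m in models}
        for sv in truth.case_specific:
            g = by_name[sv.gene]
            assert g.chrom == sv.chrom
            assert g.start < sv.start <= g.end


class TestEmulateCallers:
    def test_perfect_callers_reproduce_truth(self, manifest):
        truth = sc.simulate_truth(manifest, n_shared=20, n_case_specific=5,
                                  seed=1)
        profiles = sc.default_caller_profiles(
            3, sensitivity=1.0, breakpoint_jitter=0.0, false_rate=0.0)
        calls = sc.emulate_callers(truth, profiles, seed=2)
        for sample, truths in truth.by_sample.items():
            per_caller = {p.caller_id: [] for p in profiles}
            for c in calls[sample]:
                per_caller[c.caller_id].append((c.chrom, c.start, c.length,
                                                c.svtype))
            want = sorted((t.chrom, t.start, t.length, t.svtype)
                          for t in truths)
            for reported in per_caller.values():
                assert sorted(reported) == want

    def test_zero_sensitivity_empty(self, manifest):
        truth = sc.simulate_truth(manifest, n_shared=20, n_case_specific=5,
                                  seed=1)
        profiles = sc.default_caller_profiles(2, sensitivity=0.0,
                                              false_rate=0.0)
        calls = sc.emulate_callers(truth, profiles, seed=2)
        assert all(len(v) == 0 for v in calls.values())

    def test_expected_support_matches_binomial(self):
        """4 callers at sensitivity 0.9: mean support 3.6 over many SVs."""
        man = CohortManifest({"p": "proband"})
        truth = sc.simulate_truth(man, n_shared=0, n_case_specific=1000,
                                  seed=5, min_gap=1000,
                                  genome={"chr1": 500_000_000})
        profiles = sc.default_caller_profiles(4, sensitivity=0.9,
                                              breakpoint_jitter=0.0,
                                              false_rate=0.0)
        calls = sc.emulate_callers(truth, profiles, seed=6)
        support = {}
        for c in calls["p"]:
            support.setdefault(c.truth_uid, set()).add(c.caller_id)
        mean_support = sum(len(v) for v in support.values()) / 1000
        assert mean_support == pytest.approx(3.6, abs=0.1)

    def test_requires_profiles(self, manifest):
        truth = sc.simulate_truth(manifest, n_shared=1, n_case_specific=0,
                                  seed=0)
        with pytest.raises(ValueError):
            sc.emulate_callers(truth, [], seed=0)

    def test_deterministic(self, manifest):
        truth = sc.simulate_truth(manifest, n_shared=30, n_case_specific=5,
                                  seed=8)
        profiles = sc.default_caller_profiles(4)
        a = sc.emulate_callers(truth, profiles, seed=9)
        b = sc.emulate_callers(truth, profiles, seed=9)
        assert a == b


class TestSimulateExpression:
    def test_deterministic(self):
        genes = [f"G{i}" for i in range(50)]
        a = sc.simulate_expression(genes, seed=3)
        b = sc.simulate_expression(genes, seed=3)
        assert a.matrix.equals(b.matrix) and a.fc_a.equals(b.fc_a)

    def test_large_effect_forces_targets_high(self):
        genes = [f"G{i}" for i in range(400)]
        targets = genes[:40]
        bundle = sc.simulate_expression(
            genes, enriched_region_stage=("striatum", "adolescent"),
            target_genes=targets, effect=5.0, seed=4)
        high = high_expression_set(bundle.matrix, "striatum", "adolescent",
                                   0.5, background=genes)
        assert set(targets) <= high

    def test_grid_shape(self):
        bundle = sc.simulate_expression([f"G{i}" for i in range(10)], seed=0)
        assert bundle.matrix.shape == (10, 80)
        assert cell_name("striatum", "adolescent") in bundle.matrix.columns

    def test_target_must_be_subset(self):
        with pytest.raises(ValueError):
            sc.simulate_expression(["a"], target_genes=["zzz"], seed=0)


class TestSimulatePathways:
    def test_planted_term_contains_targets(self):
        genes = [f"G{i}" for i in range(2000)]
        planted = genes[:20]
        pws = sc.simulate_pathways(genes, n_terms=50, planted_genes=planted,
                                   seed=1)
        term = {p.term_id: p for p in pws}["PLANTED"]
        assert set(planted) <= term.genes and len(term.genes) >= 30

    def test_sizes_in_range(self):
        genes = [f"G{i}" for i in range(3000)]
        pws = sc.simulate_pathways(genes, n_terms=100,
                                   size_range=(30, 1000), seed=2)
        assert all(30 <= len(p.genes) <= 1000 for p in pws)
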