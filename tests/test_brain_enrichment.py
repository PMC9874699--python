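"""Quantile high-expression sets, cellwise enrichment and permutation FWER."""

import numpy as np
import pandas as pd
import pytest

from famsv import synthetic_cohort as sc
from famsv.brain_enrichment import (brain_biased_background, cell_name,
                                    high_expression_set, permutation_fwer,
                                    region_stage_enrichment, results_table)


class TestBrainBiasedBackground:
    @pytest.mark.parametrize("fa,fb,included", [
        (0.6, 0.1, True),    # union rule
        (0.1, 0.6, True),
        (0.5, 0.5, False),   # strictly greater than the threshold
        (0.0, 0.0, False),
    ])
    def test_union_rule_strict(self, fa, fb, included):
        a = pd.Series({"g": fa})
        b = pd.Series({"g": fb})
        assert ("g" in brain_biased_background(a, b, 0.5)) is included

    def test_gene_in_one_table_only(self):
        a = pd.Series({"g1": 0.9})
        b = pd.Series({"g2": 0.1})
        assert brain_biased_background(a, b) == {"g1"}


def tiny_matrix(values, region="striatum", stage="adolescent"):
    genes = [f"g{i}" for i in range(len(values))]
    return pd.DataFrame({cell_name(region, stage): values}, index=genes)


class TestHighExpressionSet:
    def test_median_cut(self):
        m = tiny_matrix(list(range(1, 11)))
        high = high_expression_set(m, "striatum", "adolescent", 0.5)
        assert high == {f"g{i}" for i in range(5, 10)}  # values 6..10

    def test_top_decile(self):
        m = tiny_matrix(list(range(1, 11)))
        assert high_expression_set(m, "striatum", "adolescent", 0.9) == {"g9"}

    def test_constant_cell_empty(self):
        m = tiny_matrix([3.0] * 10)
        assert high_expression_set(m, "striatum", "adolescent", 0.5) == set()

    def test_quantile_bounds(self):
        with pytest.raises(ValueError):
            high_expression_set(tiny_matrix([1, 2]), "striatum", "adolescent",
                                1.5)


@pytest.fixture(scope="module")
def planted_bundle():
    genes = [f"G{i}" for i in range(800)]
    targets = genes[:40]
    bundle = sc.simulate_expression(
        genes, enriched_region_stage=("striatum", "adolescent"),
        target_genes=targets, effect=5.0, seed=31)
    background = brain_biased_background(bundle.fc_a, bundle.fc_b)
    return bundle, targets, sorted(background)


class TestRegionStageEnrichment:
    def test_planted_cell_attains_minimum_p(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5,))
        best = min(res, key=lambda r: r.p_value)
        assert (best.region, best.stage) == ("striatum", "adolescent")
        assert best.k == best.n  # every target gene in the high set

    def test_empty_target_errors(self, planted_bundle):
        bundle, _, background = planted_bundle
        with pytest.raises(ValueError):
            region_stage_enrichment(["absent_gene"], bundle.matrix, background)

    def test_grid_size(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5, 0.9))
        assert len(res) == 16 * 5 * 2


class TestPermutationFWER:
    def test_p_equal_one_gives_fwer_one(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5,))
        worst = max(res, key=lambda r: r.p_value)
        if worst.p_value == 1.0:
            out = permutation_fwer([worst], bundle.matrix, background,
                                   target_size=worst.n, R=19, seed=1)
            assert out[0].fwer == 1.0

    def test_floor_of_add_one_estimator(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5,))
        out = permutation_fwer(res, bundle.matrix, background,
                               target_size=len(targets), R=99, seed=2)
        planted = [r for r in out if (r.region, r.stage) ==
                   ("striatum", "adolescent")][0]
        assert planted.fwer == pytest.approx(1 / 100)

    def test_monotone_in_observed_p(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5,))
        out = permutation_fwer(res, bundle.matrix, background,
                               target_size=len(targets), R=49, seed=3)
        ordered = sorted(out, key=lambda r: r.p_value)
        fwers = [r.fwer for r in ordered]
        assert fwers == sorted(fwers)

    def test_deterministic_under_seed(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5,))
        a = permutation_fwer(res, bundle.matrix, background,
                             target_size=len(targets), R=29, seed=4)
        b = permutation_fwer(res, bundle.matrix, background,
                             target_size=len(targets), R=29, seed=4)
        assert a == b

    def test_target_size_validated(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5,))
        with pytest.raises(ValueError):
            permutation_fwer(res, bundle.matrix, background,
                             target_size=10 ** 6, R=9, seed=0)


class TestResultsTable:
    def test_wide_layout_and_signif_count(self, planted_bundle):
        bundle, targets, background = planted_bundle
        res = region_stage_enrichment(targets, bundle.matrix, background,
                                      quantiles=(0.5, 0.7))
        out = permutation_fwer(res, bundle.matrix, background,
                               target_size=len(targets), R=99, seed=5)
        table = results_table(out)
        assert table.shape[0] == 16 * 5
        assert {"region", "stage", "n_signif", "fwer_q0.5",
                "fwer_q0.7"} <= set(table.columns)
        planted = table[(table.region == "striatum") &
                        (table.stage == "adolescent")]
        assert int(planted.n_signif.iloc[0]) >= 1
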