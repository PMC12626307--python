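import itertools

import numpy as np
import pytest
from scipy import stats

from ipascan.coverage import ArrayCoverageSource
from ipascan.differential import (
    chi_squared_2x2,
    differential_no_reps,
    differential_with_reps,
    differential_with_reps_pipeline,
    rank_sum_exact,
    rank_sum_normal,
)
from ipascan.sites import build_catalog
from ipascan.simulate import DifferentialSpec, SimConfig, simulate_pair


class TestChiSquared:
    def test_hand_computed_statistic(self):
        stat, p = chi_squared_2x2([[30, 70], [60, 40]])
        # E = [[45,55],[45,55]]; sum of 225/45 + 225/55 twice = 18.1818...
        assert stat == pytest.approx(2 * (225 / 45 + 225 / 55), rel=1e-12)
        assert stat == pytest.approx(18.1818, abs=1e-3)
        assert 0 < p < 1e-4

    def test_identical_rows_give_zero(self):
        stat, p = chi_squared_2x2([[50, 50], [50, 50]])
        assert stat == 0.0 and p == 1.0

    def test_unit_diagonal_table(self):
        stat, _ = chi_squared_2x2([[1, 0], [0, 1]])
        assert stat == pytest.approx(2.0)

    def test_zero_marginal_warns_and_returns_p_one(self):
        with pytest.warns(UserWarning, match="zero marginal"):
            stat, p = chi_squared_2x2([[0, 0], [5, 5]])
        assert (stat, p) == (0.0, 1.0)

    def test_matches_reference_implementation_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            t = rng.integers(1, 200, size=(2, 2))
            stat, p = chi_squared_2x2(t)
            ref = stats.chi2_contingency(t, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestRankSum:
    def test_most_extreme_3v3_split_has_p_point_one(self):
        _, p = rank_sum_exact([0.10, 0.12, 0.11], [0.50, 0.55, 0.60])
        assert p == pytest.approx(2 / 20)

    def test_fully_separated_5v5(self):
        _, p = rank_sum_exact([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert p == pytest.approx(2 / 252)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_exact([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert p == 1.0
        _, p = rank_sum_normal([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert p == 1.0

    @pytest.mark.parametrize("n,m", [(3, 3), (4, 4)])
    def test_exact_p_matches_reference_for_all_tie_free_configurations(self, n, m):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            _, p = rank_sum_exact(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_matches_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y = rng.normal(size=8), rng.normal(size=9)
            _, p = rank_sum_normal(x, y)
            ref = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_separated_triplicates_significant_under_normal_mode(self):
        # the exact 3v3 test bottoms out at p = 0.1; the normal approximation
        # is the default for triplicate designs and crosses 0.05
        _, p, sig = differential_with_reps([0.1, 0.12, 0.11], [0.5, 0.55, 0.6])
        assert p < 0.05 and sig

    def test_auto_mode_uses_exact_for_4v4(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]
        stat, p, _ = differential_with_reps(x, y, mode="auto")
        _, p_exact = rank_sum_exact(x, y)
        assert p == pytest.approx(p_exact)

    def test_condition_exchange_symmetry(self):
        x, y = [0.1, 0.2, 0.15, 0.3], [0.5, 0.6, 0.55]
        _, p1, _ = differential_with_reps(x, y, mode="normal")
        _, p2, _ = differential_with_reps(y, x, mode="normal")
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_significance_needs_both_criteria(self):
        # clear separation but |delta TR| <= 0.2 -> not significant
        _, p, sig = differential_with_reps([0.10, 0.11, 0.12], [0.20, 0.21, 0.22])
        assert p < 0.05 and not sig


@pytest.fixture(scope="module")
def small_pair():
    cfg = SimConfig(
        n_genes=120, genes_per_chrom=40, seed=13, with_genome=False,
        differential=DifferentialSpec(n_diff=20, n_null=20, n_replicates=3),
    )
    return simulate_pair(cfg)


class TestPipelines:
    def test_self_comparison_yields_zero_significant(self, small_pair):
        catalog = build_catalog(small_pair.genes, db_sites=small_pair.site_entries())
        cov = small_pair.control[0]
        results = differential_no_reps(small_pair.genes, catalog, cov, cov)
        assert results  # events are detected, but none differ
        assert sum(r.significant for r in results) == 0
        for r in results:
            assert r.delta == 0.0

    def test_no_reps_chi_squared_flags_planted_differences(self, small_pair):
        catalog = build_catalog(small_pair.genes, db_sites=small_pair.site_entries())
        results = differential_no_reps(
            small_pair.genes, catalog, small_pair.control[0], small_pair.case[0]
        )
        sig = {(r.chrom, r.pos) for r in results if r.significant}
        diff_truth = {
            (t.chrom, t.pos) for t in small_pair.truth if t.is_differential
        }
        assert len(sig & diff_truth) >= 0.9 * len(diff_truth)
        assert all(r.test == "chi_squared" for r in results)

    def test_replicated_pipeline_recovers_planted_differences(self, small_pair):
        catalog = build_catalog(small_pair.genes, db_sites=small_pair.site_entries())
        results = differential_with_reps_pipeline(
            small_pair.genes, catalog, small_pair.control, small_pair.case
        )
        assert all(r.test == "wilcoxon" for r in results)
        sig = {(r.chrom, r.pos) for r in results if r.significant}
        diff_truth = {(t.chrom, t.pos) for t in small_pair.truth if t.is_differential}
        null_truth = {(t.chrom, t.pos) for t in small_pair.truth if not t.is_differential}
        assert sig >= diff_truth  # every planted difference found
        assert not (sig & null_truth)  # no false positives on null events

    def test_null_design_controls_type_one_error(self):
        cfg = SimConfig(
            n_genes=120, genes_per_chrom=40, seed=29, with_genome=False,
            differential=DifferentialSpec(n_diff=0, n_null=40, n_replicates=3),
        )
        pair = simulate_pair(cfg)
        catalog = build_catalog(pair.genes, db_sites=pair.site_entries())
        results = differential_with_reps_pipeline(
            pair.genes, catalog, pair.control, pair.case
        )
        assert results
        frac = np.mean([r.significant for r in results])
        n = len(results)
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)
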