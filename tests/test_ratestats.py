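import numpy as np
import pytest

import clockdrift as cd
from clockdrift.estimates import BranchRateEstimates
from clockdrift.ratestats import (
    DistributionChecks,
    distribution_checks,
    exceedance_counts,
    fold_variation,
    group_rate_contrast,
    node_density_regression,
    poisson_expected_fold,
    summarize_dataset,
)
from clockdrift.trees import unrooted_branches

#: expected Poisson fold variation at 1 kb for the 11-length grid, one decimal
POISSON_ROW = {
    0.01: 4.4, 0.02: 2.6, 0.05: 1.8, 0.1: 1.5, 0.2: 1.3, 0.4: 1.2,
    0.6: 1.2, 0.8: 1.2, 1.0: 1.1, 1.2: 1.1, 1.4: 1.1,
}


class TestPoissonExpectation:
    @pytest.mark.parametrize("L,expected", sorted(POISSON_ROW.items()))
    def test_full_grid_one_decimal(self, L, expected):
        assert poisson_expected_fold(L, 1000).rounded(1) == pytest.approx(expected)

    def test_monotone_decreasing_toward_one(self):
        folds = [poisson_expected_fold(L, 1000).expected_fold for L in sorted(POISSON_ROW)]
        assert np.all(np.diff(folds) < 0)
        assert poisson_expected_fold(100.0, 1_000_000).expected_fold == pytest.approx(1.0, abs=1e-2)

    def test_undefined_below_mu_4(self):
        with pytest.raises(ValueError):
            poisson_expected_fold(0.004, 1000)


class TestFoldVariation:
    def test_constant_rates_give_one(self):
        assert fold_variation([0.3] * 13) == pytest.approx(1.0)

    def test_simple_ratio(self):
        assert fold_variation([1, 2, 4, 0.5]) == pytest.approx(8.0)

    def test_zero_flagged_branches_excluded(self):
        rates = [1.0, 2.0, 0.0, 4.0]
        flags = [False, False, True, False]
        assert fold_variation(rates, flags) == pytest.approx(4.0)

    def test_all_but_one_flagged_undefined(self):
        with pytest.raises(ValueError):
            fold_variation([1.0, 0.0, 0.0], [False, True, True])


def _estimates_with_rates(rates_by_branch):
    """8-taxon estimates object with given per-branch rates (by unrooted index)."""
    tree = cd.build_8taxon_tree(0.1)
    branches = unrooted_branches(tree)
    spans = np.array([b.time_span for b in branches])
    lengths = np.asarray(rates_by_branch) * spans
    return BranchRateEstimates(branches, lengths, spans, estimator="ml")


class TestGroupContrast:
    def test_equal_rates_fold_one_not_significant(self):
        est = _estimates_with_rates(np.full(13, 0.4))
        for grouping in ("depth", "clade"):
            c = group_rate_contrast(est, grouping)
            assert c.fold == pytest.approx(1.0)
            assert not c.significant

    def test_disjoint_error_bars_significant(self):
        # clade A branches 3x faster, tiny within-group spread
        rates = np.empty(13)
        est0 = _estimates_with_rates(np.full(13, 1.0))
        for b in est0.branches:
            rates[b.index] = 3.0 if b.clade == "A" else 1.0
        rates[[b.index for b in est0.branches if b.is_central]] = 2.0
        rng = np.random.default_rng(0)
        rates += rng.normal(0, 0.01, 13)
        est = _estimates_with_rates(rates)
        c = group_rate_contrast(est, "clade")
        assert c.fold > 1.4
        assert c.significant

    def test_orientation_is_at_least_one(self):
        rates = np.empty(13)
        est0 = _estimates_with_rates(np.full(13, 1.0))
        for b in est0.branches:
            rates[b.index] = 0.5 if b.clade == "A" else 2.0
        rates[[b.index for b in est0.branches if b.is_central]] = 1.0
        c = group_rate_contrast(_estimates_with_rates(rates), "clade")
        assert c.fold >= 1.0

    def test_central_branch_counts_in_both_clades(self):
        est = _estimates_with_rates(np.full(13, 1.0))
        groups = est.group_rates("clade")
        assert len(groups["A"]) == 7 and len(groups["B"]) == 7
        depth_groups = est.group_rates("depth")
        assert len(depth_groups["1"]) == 8 and len(depth_groups["2"]) == 4


class TestExceedanceCounts:
    def test_all_ones(self):
        c = exceedance_counts([1.0] * 5, 1.8)
        assert c.n_over_2fold == 0 and c.n_over_expected == 0

    def test_mixed(self):
        c = exceedance_counts([1.5, 2.5, 3.0], 1.8)
        assert c.n_over_2fold == 2 and c.n_over_expected == 2

    def test_stochastic_attribution_flag(self):
        # 70 of 100 below expected -> plausible; 10 below -> not
        c_ok = exceedance_counts([1.0] * 70 + [3.0] * 30, 2.0)
        c_bad = exceedance_counts([1.0] * 10 + [3.0] * 90, 2.0)
        assert c_ok.stochastic_only_plausible
        assert not c_bad.stochastic_only_plausible


class TestDistributionChecks:
    def test_nominal_normality_rejection_rate(self):
        rng = np.random.default_rng(1)
        datasets = [rng.normal(0.4, 0.05, 13) for _ in range(100)]
        checks = distribution_checks(datasets)
        assert 0 <= checks.n_normality_rejected <= 15
        assert checks.anova_p > 1e-4

    def test_shifted_dataset_fails_anova(self):
        rng = np.random.default_rng(2)
        datasets = [rng.normal(0.4, 0.05, 13) for _ in range(20)]
        datasets.append(rng.normal(0.9, 0.05, 13))
        assert distribution_checks(datasets).anova_p < 1e-6

    def test_constant_rates_recorded_not_crashed(self):
        checks = distribution_checks([[0.4] * 13, list(np.linspace(0.3, 0.5, 13))])
        assert np.isnan(checks.shapiro_p[0])
        assert np.isfinite(checks.shapiro_p[1])


class TestNodeDensityRegression:
    def test_balanced_tree_has_zero_predictor_variance(self):
        tree = cd.build_8taxon_tree(0.3)
        r = node_density_regression(tree)
        assert not r.defined

    def test_proportional_paths_give_positive_significant_slope(self):
        # caterpillar tree: tip k passes k nodes; lengths proportional to node count
        nwk = "(((((a:1,b:1):1,c:1):1,d:1):1,e:1):1,f:1);"
        tree = cd.read_newick(nwk)
        r = node_density_regression(tree)
        assert r.defined and r.slope > 0 and r.p_value < 0.01

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            node_density_regression(cd.read_newick("((a:1,b:1):1,c:2);"))


class TestSummarizeDataset:
    def test_flags_consistent_with_values(self):
        rng = np.random.default_rng(3)
        est = _estimates_with_rates(rng.uniform(0.3, 0.9, 13))
        poisson = poisson_expected_fold(0.4, 1000)
        s = summarize_dataset(est, poisson)
        assert s.exceeds_2fold == (s.fold_variation_overall > 2)
        assert s.exceeds_poisson_expectation == (s.fold_variation_overall > poisson.expected_fold)
        assert s.fold_variation_depths >= 1 and s.fold_variation_clades >= 1
        assert s.n_branches_used == 13
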