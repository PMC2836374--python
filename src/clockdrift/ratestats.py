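"""Among-lineage rate-variation statistics for clock-true data.

Given per-branch rate estimates from one dataset, the summaries are:

* overall fold variation — maximum/minimum estimated rate across branches
  (zero-flagged branches excluded, since they would give infinity);
* depth contrast — ratio of mean depth-2 to mean depth-1 branch rates,
  oriented to be >= 1;
* clade contrast — ratio of the two root-subtree mean rates, oriented >= 1.

The analytic yardstick is the fold variation expected from the Poisson
substitution process alone: with mu = branch_length * n_sites expected
substitutions per branch and sigma = sqrt(mu), about 95% of realised counts
fall in mu +/- 2*sigma, so rate estimates on a clock-true tree are expected
to span roughly (mu + 2*sigma)/(mu - 2*sigma)-fold. Observed fold variation
above this cannot be blamed on the stochastic substitution process and
indicates estimation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .estimates import BranchRateEstimates
from .trees import DatedTree


@dataclass(frozen=True)
class PoissonExpectation:
    """Fold variation expected from Poisson substitution counts alone."""

    mu: float
    sigma: float
    expected_fold: float

    def rounded(self, decimals: int = 1) -> float:
        return round(self.expected_fold, decimals)


def poisson_expected_fold(branch_length: float, n_sites: int) -> PoissonExpectation:
    """(mu + 2*sigma)/(mu - 2*sigma) with mu = branch_length * n_sites.

    Undefined (raises) when mu <= 4, where mu - 2*sigma is non-positive.
    """
    mu = branch_length * n_sites
    if mu <= 4.0:
        raise ValueError(f"Poisson expectation undefined for mu = {mu:g} <= 4")
    sigma = np.sqrt(mu)
    return PoissonExpectation(mu, sigma, (mu + 2 * sigma) / (mu - 2 * sigma))


def fold_variation(rates: Sequence[float], zero_flags: Optional[Sequence[bool]] = None) -> float:
    """Max/min rate over non-flagged branches."""
    rates = np.asarray(rates, dtype=float)
    if zero_flags is not None:
        rates = rates[~np.asarray(zero_flags, dtype=bool)]
    if len(rates) < 2:
        raise ValueError("fold variation needs at least 2 usable rates")
    return float(rates.max() / rates.min())


class GroupContrast(NamedTuple):
    fold: float
    significant: bool  # 1-SD error bars of the two group means disjoint
    group_means: dict
    group_sds: dict
    t_pvalue: float  # Welch t-test, supplementary


def group_rate_contrast(estimates: BranchRateEstimates, grouping: str) -> GroupContrast:
    """Ratio (oriented >= 1) of mean rates between the two branch groups.

    Significance follows the 1-standard-deviation error-bar overlap rule:
    the contrast is significant iff [mean - SD, mean + SD] of the two groups
    are disjoint. A Welch t-test p-value is reported alongside as a
    conventional supplement.
    """
    groups = estimates.group_rates(grouping)
    if len(groups) != 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError(f"need exactly 2 non-empty groups for {grouping!r} contrast")
    (ka, va), (kb, vb) = sorted(groups.items())
    ma, mb = va.mean(), vb.mean()
    sa = va.std(ddof=1) if len(va) > 1 else 0.0
    sb = vb.std(ddof=1) if len(vb) > 1 else 0.0
    fold = max(ma / mb, mb / ma)
    disjoint = (ma + sa < mb - sb) or (mb + sb < ma - sa)
    if len(va) > 1 and len(vb) > 1 and (sa > 0 or sb > 0):
        t_p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
    else:
        t_p = float("nan")
    return GroupContrast(float(fold), bool(disjoint), {ka: ma, kb: mb}, {ka: sa, kb: sb}, t_p)


class ExceedanceCounts(NamedTuple):
    n_over_2fold: int
    n_over_expected: int
    n_datasets: int
    stochastic_only_plausible: bool


def exceedance_counts(folds: Sequence[float], expected_fold: float) -> ExceedanceCounts:
    """Counts of datasets with fold variation > 2 and > the Poisson expectation.

    With 100 datasets of 13 branches each, about 65 branch rates are
    expected outside mu +/- 2*sigma; were those spread evenly, at least 35
    datasets would stay below the expected fold. The
    ``stochastic_only_plausible`` flag records that diagnostic: when fewer
    than 35 datasets (scaled to the replicate count) stay below, estimation
    error beyond the stochastic process is indicated.
    """
    folds = np.asarray(folds, dtype=float)
    n = len(folds)
    if n == 0:
        raise ValueError("need at least one dataset summary")
    n2 = int(np.sum(folds > 2.0))
    ne = int(np.sum(folds > expected_fold))
    below = n - ne
    return ExceedanceCounts(n2, ne, n, below >= 0.35 * n)


class DistributionChecks(NamedTuple):
    shapiro_p: np.ndarray  # per dataset; nan where degenerate (constant rates)
    n_normality_rejected: int
    anova_p: float


def distribution_checks(rates_per_dataset: Sequence[Sequence[float]], alpha: float = 0.05) -> DistributionChecks:
    """Shapiro-Wilk normality per dataset and one-way ANOVA across datasets.

    The ANOVA tests whether mean estimated rates differ between datasets
    (branches within a dataset treated as independent samples).
    """
    ps = []
    for rates in rates_per_dataset:
        rates = np.asarray(rates, dtype=float)
        if len(rates) < 3 or np.ptp(rates) == 0.0:
            ps.append(np.nan)
        else:
            ps.append(float(stats.shapiro(rates).pvalue))
    ps = np.asarray(ps)
    groups = [np.asarray(r, dtype=float) for r in rates_per_dataset]
    anova_p = float(stats.f_oneway(*groups).pvalue) if len(groups) > 1 else float("nan")
    return DistributionChecks(ps, int(np.nansum(ps < alpha)), anova_p)


class NodeDensityRegression(NamedTuple):
    slope: float
    p_value: float
    n_tips: int
    defined: bool


def node_density_regression(tree_with_lengths: DatedTree) -> NodeDensityRegression:
    """Regress root-to-tip path length on the number of nodes along the path.

    A significant positive slope is the node-density-effect signature:
    tip paths through more speciation events accumulate more inferred
    substitutions. Undefined (flagged) when every tip passes the same
    number of nodes.
    """
    tree = tree_with_lengths
    if tree.n_tips < 4:
        raise ValueError("node-density regression needs >= 4 tips")
    path_lengths = tree.root_to_tip_lengths()
    node_counts = {}
    for tip in tree.tips:
        n, node = 0, tip
        while tree.parent[node] >= 0:
            node = tree.parent[node]
            n += 1
        node_counts[tip] = n
    x = np.array([node_counts[t] for t in tree.tips], dtype=float)
    y = np.array([path_lengths[t] for t in tree.tips])
    if np.ptp(x) == 0.0:
        return NodeDensityRegression(float("nan"), float("nan"), tree.n_tips, False)
    fit = stats.linregress(x, y)
    return NodeDensityRegression(float(fit.slope), float(fit.pvalue), tree.n_tips, True)


@dataclass
class RateVariationSummary:
    """Per-dataset rate-variation statistics (one row of the experiment table)."""

    fold_variation_overall: float
    fold_variation_depths: Optional[float]
    fold_variation_clades: Optional[float]
    exceeds_2fold: bool
    exceeds_poisson_expectation: Optional[bool]
    depth_contrast_significant: Optional[bool]
    clade_contrast_significant: Optional[bool]
    clock_rejected_lrt: Optional[bool]
    clock_rejected_bf: Optional[bool]
    normality_rejected: Optional[bool]
    shapiro_p: Optional[float]
    n_branches_used: int
    estimator: str


def summarize_dataset(
    estimates: BranchRateEstimates,
    poisson: Optional[PoissonExpectation] = None,
    clock_rejected_lrt: Optional[bool] = None,
    clock_rejected_bf: Optional[bool] = None,
    alpha: float = 0.05,
) -> RateVariationSummary:
    """All per-dataset statistics from one set of branch-rate estimates."""
    usable = ~estimates.zero_flags
    rates = estimates.rates[usable]
    fold = fold_variation(estimates.rates, estimates.zero_flags)
    try:
        depth_c = group_rate_contrast(estimates, "depth")
    except ValueError:
        depth_c = None
    try:
        clade_c = group_rate_contrast(estimates, "clade")
    except ValueError:
        clade_c = None
    if len(rates) >= 3 and np.ptp(rates) > 0:
        shapiro_p = float(stats.shapiro(rates).pvalue)
        normality_rejected = shapiro_p < alpha
    else:
        shapiro_p, normality_rejected = None, None
    return RateVariationSummary(
        fold_variation_overall=fold,
        fold_variation_depths=depth_c.fold if depth_c else None,
        fold_variation_clades=clade_c.fold if clade_c else None,
        exceeds_2fold=fold > 2.0,
        exceeds_poisson_expectation=(fold > poisson.expected_fold) if poisson else None,
        depth_contrast_significant=depth_c.significant if depth_c else None,
        clade_contrast_significant=clade_c.significant if clade_c else None,
        clock_rejected_lrt=clock_rejected_lrt,
        clock_rejected_bf=clock_rejected_bf,
        normality_rejected=normality_rejected,
        shapiro_p=shapiro_p,
        n_branches_used=int(usable.sum()),
        estimator=estimates.estimator,
    )
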