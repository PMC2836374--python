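import numpy as np
import pytest

import clockdrift as cd
from clockdrift.ml import BranchLengthML, PruningLikelihood, lrt_clock_test

from conftest import enumeration_loglik


class TestPruningLikelihood:
    def test_three_taxon_matches_enumeration(self, jc):
        tree = cd.DatedTree(
            [3, 4, 4, -1, 3],
            ["a", "b", "c", None, None],
            ages=[0, 0, 0, 2, 1],
            lengths=[0.3, 0.1, 0.2, np.nan, 0.15],
        )
        aln = cd.Alignment.from_sequences(["a", "b", "c"], ["ACGTA", "ACGTC", "AAGTC"])
        got = cd.log_likelihood(aln, tree, jc)
        assert got == pytest.approx(enumeration_loglik(aln, tree, jc), abs=1e-10)

    def test_four_taxon_hky_matches_enumeration(self, hky2, four_taxon_tree):
        tree = four_taxon_tree(0.25)
        aln = cd.Alignment.from_sequences(
            ["a", "b", "c", "d"],
            ["ACGTACGTAC", "ACTTACGGAC", "GCGTACTTAA", "ACGAACGTCC"],
        )
        got = cd.log_likelihood(aln, tree, hky2)
        assert got == pytest.approx(enumeration_loglik(aln, tree, hky2), abs=1e-10)

    def test_identical_sequences_zero_tree_gives_stationary_loglik(self, hky2, four_taxon_tree):
        tree = four_taxon_tree(0.1).with_lengths(np.zeros(7))
        seq = "ACGTAAGGTC"
        aln = cd.Alignment.from_sequences(["a", "b", "c", "d"], [seq] * 4)
        expected = sum(np.log(hky2.base_frequencies[c]) for c in aln.sites[0])
        assert cd.log_likelihood(aln, tree, hky2) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_central_branch_split(self, hky2):
        """Pulley principle: only the sum of the two root-child lengths matters."""
        tree = cd.build_8taxon_tree(0.2)
        aln = cd.simulate_alignment(tree, hky2, 300, 5)
        engine = PruningLikelihood(aln, tree, hky2)
        base = tree.lengths.copy()
        splits = []
        for frac in (0.0, 0.3, 1.0):
            lengths = base.copy()
            c1, c2 = tree.children[tree.root]
            total = base[c1] + base[c2]
            lengths[c1], lengths[c2] = frac * total, (1 - frac) * total
            splits.append(engine.loglike(lengths))
        assert np.ptp(splits) < 1e-8

    def test_taxon_mismatch_rejected(self, hky2, four_taxon_tree):
        aln = cd.Alignment.from_sequences(["a", "b", "c", "x"], ["ACGT"] * 4)
        with pytest.raises(ValueError):
            cd.log_likelihood(aln, four_taxon_tree(0.1), hky2)

    def test_gamma_invariant_mixture_likelihood_increases_consistency(self, four_taxon_tree):
        """Mixture likelihood equals manual category averaging."""
        m = cd.make_hky(ts_tv_ratio=2.0, gamma_shape=0.6, prop_invariant=0.15)
        tree = four_taxon_tree(0.2)
        aln = cd.simulate_alignment(tree, m, 200, 9)
        engine = PruningLikelihood(aln, tree, m)
        got = engine.loglike(tree.lengths)
        plain = cd.make_hky(ts_tv_ratio=2.0)
        rates, weights = m.discrete_gamma_rates()
        manual = 0.0
        pe = PruningLikelihood(aln, tree, plain)
        logs = np.stack([pe._pattern_loglik(np.nan_to_num(tree.lengths) * r, plain) for r in rates])
        from scipy.special import logsumexp

        per_pattern = logsumexp(logs, axis=0, b=weights[:, None])
        manual = float(np.dot(pe.weights, per_pattern))
        assert got == pytest.approx(manual, abs=1e-8)


class TestMLEstimation:
    def test_recovers_truth_at_large_n(self, hky2):
        """Every branch within 0.01 of truth at 10^5 sites (ML consistency)."""
        tree = cd.build_8taxon_tree(0.1)
        aln = cd.simulate_alignment(tree, hky2, 100_000, 13)
        fit = BranchLengthML(aln, tree, hky2).fit()
        want = np.array([0.2 if b.is_central else 0.1 for b in fit.model.branches])
        assert np.abs(fit.lengths - want).max() < 0.01
        assert fit.kappa == pytest.approx(4.0, rel=0.1)

    def test_identical_sequences_flagged_zero(self, hky2, two_taxon_tree):
        tree = two_taxon_tree(0.1, 0.1)
        aln = cd.Alignment.from_sequences(["a", "b"], ["ACGT" * 50] * 2)
        est = cd.estimate_branch_lengths_ml(aln, tree, hky2)
        assert est.zero_flags.all()

    def test_rates_are_lengths_over_time_spans(self, hky2):
        tree = cd.build_8taxon_tree(0.1)
        aln = cd.simulate_alignment(tree, hky2, 500, 3)
        est = cd.estimate_branch_lengths_ml(aln, tree, hky2)
        assert est.n_branches == 13
        assert np.allclose(est.rates, est.lengths / est.time_spans)

    def test_lengths_grow_with_divergence(self, hky2):
        """Estimated total tree length increases with the true branch length."""
        totals = []
        for L in (0.05, 0.2, 0.6):
            tree = cd.build_8taxon_tree(L)
            aln = cd.simulate_alignment(tree, hky2, 1000, 21)
            est = cd.estimate_branch_lengths_ml(aln, tree, hky2)
            totals.append(est.lengths.sum())
        assert totals[0] < totals[1] < totals[2]

    def test_summary_frame(self, hky2):
        tree = cd.build_8taxon_tree(0.1)
        aln = cd.simulate_alignment(tree, hky2, 300, 2)
        fit = BranchLengthML(aln, tree, hky2).fit()
        df = fit.summary()
        assert len(df) == 13
        assert {"length", "rate", "zero_flag", "clade", "depth"} <= set(df.columns)


class TestClockConstrainedFit:
    def test_clock_never_beats_free(self, hky2, four_taxon_tree):
        tree = four_taxon_tree(0.15)
        for rep in range(3):
            aln = cd.simulate_alignment(tree, hky2, 400, rep)
            m = BranchLengthML(aln, tree, hky2)
            free = m.fit(seed=rep)
            clock = m.fit(clock=True, init_free=free, seed=rep)
            assert clock.llf <= free.llf + 1e-6

    def test_clock_close_to_free_on_clock_true_data(self, hky2):
        tree = cd.build_8taxon_tree(0.1)
        aln = cd.simulate_alignment(tree, hky2, 20_000, 8)
        m = BranchLengthML(aln, tree, hky2)
        free = m.fit()
        clock = m.fit(clock=True, init_free=free)
        assert free.llf - clock.llf < 10.0

    def test_parameter_counts_imply_df_6_for_8_taxa(self, hky2):
        tree = cd.build_8taxon_tree(0.1)
        aln = cd.simulate_alignment(tree, hky2, 200, 1)
        m = BranchLengthML(aln, tree, hky2)
        assert m.n_branches == 13  # 2n-3 unconstrained lengths
        clock = m.fit(clock=True)
        assert len(clock.node_heights) == 7  # n-1 heights
        assert m.n_branches - len(clock.node_heights) == m.n_taxa - 2

    def test_clock_heights_nested_and_lengths_nonnegative(self, hky2):
        tree = cd.build_8taxon_tree(0.2)
        aln = cd.simulate_alignment(tree, hky2, 1000, 4)
        clock = BranchLengthML(aln, tree, hky2).fit(clock=True)
        lengths = clock.branch_lengths_by_node()
        nonroot = np.array(tree.parent) >= 0
        assert np.all(lengths[nonroot] >= -1e-12)


class TestClockLRT:
    def test_equal_likelihoods_give_p_one(self):
        r = lrt_clock_test(-100.0, -100.0, 8)
        assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0)
        assert not r.rejected_at_0_05

    def test_chi_square_quantile(self):
        """chi2 df=6 upper 5% point is 12.592."""
        r = lrt_clock_test(-100.0, -100.0 - 12.5916 / 2, 8)
        assert r.df == 6
        assert r.p_value == pytest.approx(0.05, abs=1e-4)

    def test_inverted_likelihoods_rejected(self):
        with pytest.raises(ValueError):
            lrt_clock_test(-105.0, -100.0, 8)
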