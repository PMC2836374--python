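"""Fixed-topology Bayesian branch-length estimation by Metropolis-Hastings.

A deliberately small sampler: single chain, one-parameter-at-a-time
multiplier proposals on branch lengths (and kappa), i.i.d. exponential
priors on lengths and a uniform prior on kappa. The clock-constrained
variant samples a root height (exponential prior) and per-node height
fractions (uniform priors). Marginal likelihoods for the Bayes-factor clock
comparison come from the stepping-stone estimator over power posteriors.

Chain lengths default to desk scale; all settings live in
:class:`ChainConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .alignment import Alignment
from .estimates import BranchRateEstimates
from .ml import PruningLikelihood
from .substmodel import SubstitutionModel
from .trees import DatedTree, unrooted_branches


@dataclass(frozen=True)
class ChainConfig:
    n_generations: int = 50_000
    sample_every: int = 50
    burnin_fraction: float = 0.25
    length_proposal_scale: float = 1.0  # multiplier window: x' = x*exp(s*(u-1/2))
    kappa_proposal_scale: float = 0.4
    fraction_proposal_window: float = 0.15
    min_ess: float = 100.0


@dataclass(frozen=True)
class BayesPriors:
    branch_length_mean: float = 0.1  # exponential prior mean on each length
    kappa_max: float = 100.0
    root_height_mean: float = 1.0  # exponential prior mean (clock model)


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS of a 1-D chain (arviz bulk ESS)."""
    import arviz  # deferred: slow import

    return float(arviz.ess(np.asarray(draws)[None, :]))


class _ParamSpace:
    """Parameter vector with per-entry kind: 'positive' or 'fraction'."""

    def __init__(self, kinds: list[str], log_prior: Callable[[np.ndarray], float]):
        self.kinds = kinds
        self.log_prior = log_prior
        self.n = len(kinds)


def _mh_run(
    space: _ParamSpace,
    log_lik: Callable[[np.ndarray], float],
    x0: np.ndarray,
    config: ChainConfig,
    rng: np.random.Generator,
    beta: float = 1.0,
    n_generations: Optional[int] = None,
):
    """Metropolis-Hastings targeting prior * likelihood^beta.

    Returns (samples, loglik_samples, final_state): one thinned row per
    ``sample_every`` generations, burn-in not yet removed.
    """
    n_gen = n_generations if n_generations is not None else config.n_generations
    x = np.asarray(x0, dtype=float).copy()
    lp = space.log_prior(x)
    ll = log_lik(x) if beta > 0.0 else 0.0
    samples, lls = [], []
    for gen in range(n_gen):
        i = rng.integers(space.n)
        xi = x[i]
        kind = space.kinds[i]
        if kind in ("positive", "kappa"):
            scale = (
                config.kappa_proposal_scale if kind == "kappa" else config.length_proposal_scale
            )
            prop = xi * np.exp(scale * (rng.random() - 0.5))
            log_hastings = np.log(prop / xi)
        else:  # fraction in (0,1): reflected sliding window, symmetric
            prop = xi + config.fraction_proposal_window * (rng.random() - 0.5)
            while prop < 0.0 or prop > 1.0:
                prop = -prop if prop < 0.0 else 2.0 - prop
            log_hastings = 0.0
        x_new = x.copy()
        x_new[i] = prop
        lp_new = space.log_prior(x_new)
        if np.isfinite(lp_new):
            ll_new = log_lik(x_new) if beta > 0.0 else 0.0
            log_alpha = (lp_new - lp) + beta * (ll_new - ll) + log_hastings
            if np.log(rng.random()) < log_alpha:
                x, lp, ll = x_new, lp_new, ll_new
        if (gen + 1) % config.sample_every == 0:
            samples.append(x.copy())
            lls.append(ll if beta > 0.0 else log_lik(x))
    return np.asarray(samples), np.asarray(lls), x


@dataclass
class BranchLengthBayesResults:
    """Posterior samples and posterior-mean branch lengths."""

    model: "BranchLengthBayes"
    samples: np.ndarray  # (n_samples, n_params) post burn-in
    loglik_trace: np.ndarray
    kappa_samples: Optional[np.ndarray]
    ess: np.ndarray
    config: ChainConfig

    @property
    def posterior_mean_lengths(self) -> np.ndarray:
        return self.samples[:, : self.model.n_branches].mean(axis=0)

    @property
    def converged(self) -> bool:
        return bool(np.all(self.ess >= self.config.min_ess))

    @property
    def estimates(self) -> BranchRateEstimates:
        return BranchRateEstimates(
            branches=self.model.branches,
            lengths=self.posterior_mean_lengths,
            time_spans=self.model.time_spans,
            estimator="bayes",
            log_likelihood=float(np.mean(self.loglik_trace)),
            kappa=float(np.mean(self.kappa_samples)) if self.kappa_samples is not None else None,
            zero_threshold=self.model.zero_threshold,
            extras={"ess": self.ess, "ess_warning": not self.converged},
        )

    def summary(self) -> pd.DataFrame:
        df = self.estimates.to_frame()
        df["posterior_sd"] = self.samples[:, : self.model.n_branches].std(axis=0)
        df["ess"] = self.ess[: self.model.n_branches]
        return df

    def trace_frame(self) -> pd.DataFrame:
        cols = [f"branch_{i}" for i in range(self.model.n_branches)]
        if self.kappa_samples is not None:
            return pd.DataFrame(
                np.column_stack([self.samples[:, : self.model.n_branches], self.kappa_samples]),
                columns=cols + ["kappa"],
            )
        return pd.DataFrame(self.samples, columns=cols)


class BranchLengthBayes:
    """Bayesian branch-length model (fixed topology), MH-sampled.

    Same constructor signature as :class:`~clockdrift.ml.BranchLengthML`;
    :meth:`fit` returns posterior samples and posterior-mean estimates.
    """

    def __init__(
        self,
        alignment: Alignment,
        tree: DatedTree,
        subst_model: SubstitutionModel,
        estimate_kappa: bool = True,
        priors: BayesPriors = BayesPriors(),
        zero_threshold: float = 1e-6,
    ):
        self.alignment = alignment
        self.tree = tree
        self.subst_model = subst_model
        self.estimate_kappa = estimate_kappa and subst_model.exchangeabilities is None
        self.priors = priors
        self.zero_threshold = zero_threshold
        self.engine = PruningLikelihood(alignment, tree, subst_model)
        self.branches = unrooted_branches(tree)
        self.time_spans = np.array([b.time_span for b in self.branches])
        self._assign = [b.child[0] for b in self.branches]
        self._zero_nodes = [c for b in self.branches for c in b.child[1:]]

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def _node_lengths(self, lengths: np.ndarray) -> np.ndarray:
        out = np.zeros(self.tree.n_nodes)
        out[self._assign] = lengths
        out[self._zero_nodes] = 0.0
        return out

    def _free_space(self) -> _ParamSpace:
        nb = self.n_branches
        kinds = ["positive"] * nb + (["kappa"] if self.estimate_kappa else [])
        mean = self.priors.branch_length_mean
        kmax = self.priors.kappa_max

        def log_prior(x):
            if np.any(x[:nb] <= 0):
                return -np.inf
            lp = -np.sum(x[:nb]) / mean - nb * np.log(mean)
            if self.estimate_kappa:
                if not (0.0 < x[nb] < kmax):
                    return -np.inf
                lp -= np.log(kmax)
            return lp

        return _ParamSpace(kinds, log_prior)

    def _free_loglik(self) -> Callable[[np.ndarray], float]:
        nb = self.n_branches

        def ll(x):
            kappa = x[nb] if self.estimate_kappa else None
            return self.engine.loglike(self._node_lengths(x[:nb]), kappa)

        return ll

    def _free_x0(self) -> np.ndarray:
        x0 = np.full(self.n_branches, max(self.priors.branch_length_mean, 1e-3))
        if self.estimate_kappa:
            x0 = np.append(x0, self.subst_model.kappa)
        return x0

    def fit(
        self,
        chain_config: ChainConfig = ChainConfig(),
        seed: int = 0,
        prior_only: bool = False,
    ) -> BranchLengthBayesResults:
        """Run the chain; thinned post-burn-in samples, posterior means, ESS.

        ``prior_only=True`` switches the likelihood off (beta = 0), a
        validation mode that must recover the prior.
        """
        rng = np.random.default_rng(seed)
        space = self._free_space()
        ll = self._free_loglik() if not prior_only else (lambda x: 0.0)
        samples, lls, _ = _mh_run(
            space, ll, self._free_x0(), chain_config, rng,
            beta=0.0 if prior_only else 1.0,
        )
        burn = int(len(samples) * chain_config.burnin_fraction)
        samples, lls = samples[burn:], lls[burn:]
        ess = np.array([effective_sample_size(samples[:, j]) for j in range(samples.shape[1])])
        kappa_samples = samples[:, self.n_branches] if self.estimate_kappa else None
        return BranchLengthBayesResults(
            model=self, samples=samples, loglik_trace=lls,
            kappa_samples=kappa_samples, ess=ess, config=chain_config,
        )

    # ------------------------------------------------------------------
    # clock-constrained parameterisation (for the Bayes-factor comparison)

    def _clock_internals(self) -> list[int]:
        tree = self.tree
        return [tree.root] + [
            n for n in tree.preorder() if n != tree.root and tree.children[n]
        ]

    def _clock_space(self) -> _ParamSpace:
        internals = self._clock_internals()
        n_h = len(internals)
        kinds = ["positive"] + ["fraction"] * (n_h - 1) + (
            ["kappa"] if self.estimate_kappa else []
        )
        mean = self.priors.root_height_mean
        kmax = self.priors.kappa_max

        def log_prior(x):
            if x[0] <= 0 or np.any((x[1:n_h] <= 0) | (x[1:n_h] >= 1)):
                return -np.inf
            lp = -x[0] / mean - np.log(mean)
            if self.estimate_kappa:
                if not (0.0 < x[n_h] < kmax):
                    return -np.inf
                lp -= np.log(kmax)
            return lp

        return _ParamSpace(kinds, log_prior)

    def _clock_loglik(self) -> Callable[[np.ndarray], float]:
        tree = self.tree
        internals = self._clock_internals()
        n_h = len(internals)

        def ll(x):
            h = np.zeros(tree.n_nodes)
            h[internals[0]] = x[0]
            for k, node in enumerate(internals[1:], start=1):
                h[node] = h[tree.parent[node]] * x[k]
            lengths = np.zeros(tree.n_nodes)
            for node in range(tree.n_nodes):
                if tree.parent[node] >= 0:
                    lengths[node] = h[tree.parent[node]] - h[node]
            kappa = x[n_h] if self.estimate_kappa else None
            return self.engine.loglike(lengths, kappa)

        return ll

    def _clock_x0(self) -> np.ndarray:
        n_h = len(self._clock_internals())
        x0 = np.concatenate([[max(self.priors.root_height_mean, 0.1)], np.full(n_h - 1, 0.5)])
        if self.estimate_kappa:
            x0 = np.append(x0, self.subst_model.kappa)
        return x0

    # ------------------------------------------------------------------
    def stepping_stone(
        self,
        clock: bool = False,
        n_rungs: int = 8,
        chain_config: ChainConfig = ChainConfig(n_generations=10_000, sample_every=20),
        seed: int = 0,
        alpha: float = 0.3,
    ) -> float:
        """Stepping-stone log marginal likelihood.

        Power-posterior rungs at beta_k = (k/K)^(1/alpha) (beta-quantile
        spacing concentrates rungs near the prior, where the integrand
        changes fastest). Chains are warm-started rung to rung, high beta
        first.
        """
        rng = np.random.default_rng(seed)
        if clock:
            space, ll, x0 = self._clock_space(), self._clock_loglik(), self._clock_x0()
        else:
            space, ll, x0 = self._free_space(), self._free_loglik(), self._free_x0()
        K = n_rungs
        betas = (np.arange(K + 1) / K) ** (1.0 / alpha)
        log_ml = 0.0
        state = x0
        for k in range(K - 1, -1, -1):
            samples, lls, state = _mh_run(
                space, ll, state, chain_config, rng, beta=betas[k]
            )
            burn = int(len(lls) * chain_config.burnin_fraction)
            lls = lls[burn:]
            delta = betas[k + 1] - betas[k]
            m = lls.max()
            log_ml += m * delta + np.log(np.mean(np.exp(delta * (lls - m))))
        return float(log_ml)


# ----------------------------------------------------------------------
# functional wrappers


def sample_posterior(
    alignment: Alignment,
    fixed_topology: DatedTree,
    model: SubstitutionModel,
    chain_config: ChainConfig = ChainConfig(),
    seed: int = 0,
    **kwargs,
) -> BranchLengthBayesResults:
    return BranchLengthBayes(alignment, fixed_topology, model, **kwargs).fit(
        chain_config=chain_config, seed=seed
    )


def stepping_stone_marginal_likelihood(
    alignment: Alignment,
    topology: DatedTree,
    model: SubstitutionModel,
    clock: bool = False,
    **kwargs,
) -> float:
    return BranchLengthBayes(alignment, topology, model).stepping_stone(clock=clock, **kwargs)


def bayes_factor_clock_test(
    alignment: Alignment,
    topology: DatedTree,
    model: SubstitutionModel,
    threshold: float = 10.0,
    seed: int = 0,
    **kwargs,
) -> tuple[float, bool]:
    """2*(lnML_free - lnML_clock) and whether the clock is rejected (> threshold)."""
    mb = BranchLengthBayes(alignment, topology, model)
    ml_free = mb.stepping_stone(clock=False, seed=seed, **kwargs)
    ml_clock = mb.stepping_stone(clock=True, seed=seed + 1, **kwargs)
    stat = 2.0 * (ml_free - ml_clock)
    return stat, stat > threshold
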