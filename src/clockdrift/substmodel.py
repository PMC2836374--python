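"""Nucleotide substitution models and their finite-time transition probabilities.

The same model object drives both sequence simulation and likelihood
computation, so a single calibration convention applies everywhere: the
instantaneous rate matrix Q is scaled so that one unit of branch length
equals one expected substitution per site at stationarity,
``-sum_i pi_i q_ii = 1``.

Nucleotide state order is fixed as A, C, G, T (indices 0..3) throughout the
package.
"""

from __future__ import annotations

from functools import cached_property
from typing import Optional, Sequence

import numpy as np
from scipy import stats

NUCLEOTIDES = "ACGT"
#: index pairs (i, j) that are transitions (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}
_PURINES = (0, 2)  # A, G
_PYRIMIDINES = (1, 3)  # C, T

EQUAL_FREQUENCIES = np.full(4, 0.25)


def _validate_frequencies(freqs: Sequence[float]) -> np.ndarray:
    pi = np.asarray(freqs, dtype=float)
    if pi.shape != (4,):
        raise ValueError("base_frequencies must have exactly 4 entries (A,C,G,T)")
    if np.any(pi <= 0):
        raise ValueError("all base frequencies must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("base frequencies must sum to 1 within 1e-12")
    return pi


def kappa_from_ts_tv_ratio(ts_tv_ratio: float, base_frequencies: Sequence[float]) -> float:
    """Convert an expected transition/transversion *event* ratio R into kappa.

    Under HKY the stationary transition flux is ``2*kappa*(piA*piG + piC*piT)``
    and the transversion flux is ``2*(piA+piG)*(piC+piT)``, so
    ``R = kappa*(piA*piG + piC*piT) / ((piA+piG)*(piC+piT))``.
    With equal frequencies this reduces to ``R = kappa/2``.
    """
    if ts_tv_ratio <= 0:
        raise ValueError("ts_tv_ratio must be > 0")
    pi = _validate_frequencies(base_frequencies)
    ts_term = pi[0] * pi[2] + pi[1] * pi[3]
    tv_term = (pi[0] + pi[2]) * (pi[1] + pi[3])
    return ts_tv_ratio * tv_term / ts_term


class SubstitutionModel:
    """A time-reversible nucleotide substitution model (JC, HKY or GTR).

    Parameters
    ----------
    base_frequencies : length-4 array
        Stationary probabilities of A, C, G, T; must be positive and sum to 1.
    kappa : float
        Transition/transversion *rate* ratio (HKY). ``kappa=1`` with equal
        frequencies is Jukes-Cantor.
    exchangeabilities : length-6 array, optional
        GTR exchangeabilities in the order AC, AG, AT, CG, CT, GT. When given,
        ``kappa`` is ignored and the model is GTR.
    gamma_shape : float, optional
        Shape of the mean-1 gamma distribution of among-site rate
        multipliers. ``None`` means no gamma variation.
    prop_invariant : float, optional
        Probability that a site is invariant (rate multiplier exactly 0).
    gamma_categories : int
        Number of categories for the discrete-gamma approximation used in
        likelihood computation (simulation draws continuous rates).
    """

    def __init__(
        self,
        base_frequencies: Sequence[float] = EQUAL_FREQUENCIES,
        kappa: float = 1.0,
        exchangeabilities: Optional[Sequence[float]] = None,
        gamma_shape: Optional[float] = None,
        prop_invariant: Optional[float] = None,
        gamma_categories: int = 4,
    ):
        self.base_frequencies = _validate_frequencies(base_frequencies)
        if kappa <= 0:
            raise ValueError("kappa must be > 0")
        self.kappa = float(kappa)
        if exchangeabilities is not None:
            ex = np.asarray(exchangeabilities, dtype=float)
            if ex.shape != (6,) or np.any(ex <= 0):
                raise ValueError("GTR needs 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
            self.exchangeabilities = ex
        else:
            self.exchangeabilities = None
        if gamma_shape is not None and gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if prop_invariant is not None and not (0 <= prop_invariant < 1):
            raise ValueError("prop_invariant must be in [0, 1)")
        self.gamma_shape = gamma_shape
        self.prop_invariant = prop_invariant
        self.gamma_categories = int(gamma_categories)

    # ------------------------------------------------------------------
    @property
    def model_name(self) -> str:
        if self.exchangeabilities is not None:
            return "GTR"
        if self.kappa == 1.0 and np.allclose(self.base_frequencies, 0.25):
            return "JC"
        return "HKY"

    @property
    def ts_tv_ratio(self) -> float:
        """Expected transition/transversion event ratio at stationarity."""
        Q = self.rate_matrix
        pi = self.base_frequencies
        ts = sum(pi[i] * Q[i, j] for i, j in _TRANSITION_PAIRS)
        tv = sum(
            pi[i] * Q[i, j]
            for i in range(4)
            for j in range(4)
            if i != j and (i, j) not in _TRANSITION_PAIRS
        )
        return ts / tv

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Calibrated rate matrix Q: rows sum to 0, -sum(pi_i q_ii) = 1."""
        pi = self.base_frequencies
        Q = np.zeros((4, 4))
        if self.exchangeabilities is not None:
            ex = self.exchangeabilities
            order = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            for r, (i, j) in zip(ex, order):
                Q[i, j] = r * pi[j]
                Q[j, i] = r * pi[i]
        else:
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    rate = self.kappa if (i, j) in _TRANSITION_PAIRS else 1.0
                    Q[i, j] = rate * pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        return Q / mu

    @cached_property
    def _eigen(self):
        """Symmetric eigendecomposition of Q for the general reversible case."""
        pi = self.base_frequencies
        sq = np.sqrt(pi)
        S = sq[:, None] * self.rate_matrix / sq[None, :]  # D^1/2 Q D^-1/2, symmetric
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        left = U.T * sq[None, :]      # rows of U^T D^{1/2}
        right = (U.T / sq[None, :]).T  # D^{-1/2} U
        return w, right, left

    @cached_property
    def _hky_beta(self) -> float:
        """Normalisation of the unscaled HKY matrix (q_ij = [kappa]*pi_j)."""
        pi = self.base_frequencies
        ts = pi[0] * pi[2] + pi[1] * pi[3]
        tv = (pi[0] + pi[2]) * (pi[1] + pi[3])
        return 1.0 / (2.0 * self.kappa * ts + 2.0 * tv)

    # ------------------------------------------------------------------
    def transition_probabilities(self, branch_length) -> np.ndarray:
        """Transition probability matrix P(t) for t expected substitutions/site.

        Accepts a scalar (returns 4x4) or an array of lengths
        (returns ``t.shape + (4, 4)``). Rows sum to 1 within 1e-10.
        HKY/JC use the closed form; GTR uses the eigendecomposition.
        """
        t = np.asarray(branch_length, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch length must be >= 0")
        if self.exchangeabilities is not None:
            w, right, left = self._eigen
            expwt = np.exp(np.multiply.outer(t, w))
            P = np.einsum("...k,ik,kj->...ij", expwt, right, left)
            return np.clip(P, 0.0, 1.0)
        return self._hky_closed_form(t)

    def _hky_closed_form(self, t: np.ndarray) -> np.ndarray:
        pi = self.base_frequencies
        piR = pi[0] + pi[2]
        piY = pi[1] + pi[3]
        beta = self._hky_beta
        # class frequency and decay rate per target state j
        PI = np.array([piR, piY, piR, piY])
        A = PI * self.kappa + (1.0 - PI)
        e2 = np.exp(-beta * t)[..., None]            # transversion-type decay
        e3 = np.exp(-beta * np.multiply.outer(t, A))  # transition-type decay, per j
        P = np.empty(t.shape + (4, 4))
        for j in range(4):
            same_class = _PURINES if j in _PURINES else _PYRIMIDINES
            for i in range(4):
                if i == j:
                    P[..., i, j] = (
                        pi[j]
                        + pi[j] * (1.0 / PI[j] - 1.0) * e2[..., 0]
                        + (PI[j] - pi[j]) / PI[j] * e3[..., j]
                    )
                elif i in same_class:
                    P[..., i, j] = (
                        pi[j]
                        + pi[j] * (1.0 / PI[j] - 1.0) * e2[..., 0]
                        - pi[j] / PI[j] * e3[..., j]
                    )
                else:
                    P[..., i, j] = pi[j] * (1.0 - e2[..., 0])
        return np.clip(P, 0.0, 1.0)

    # ------------------------------------------------------------------
    def has_site_rate_variation(self) -> bool:
        return self.gamma_shape is not None or (
            self.prop_invariant is not None and self.prop_invariant > 0
        )

    def site_rate_multipliers(self, n_sites: int, rng) -> np.ndarray:
        """Draw per-site rate multipliers from the +I+Gamma mixture (mean 1).

        With probability ``prop_invariant`` a site gets multiplier exactly 0;
        otherwise it is gamma(shape, mean ``1/(1-prop_invariant)``), so the
        mixture mean is 1. Without gamma/invariant settings, returns ones.
        """
        if n_sites <= 0:
            raise ValueError("n_sites must be > 0")
        rng = np.random.default_rng(rng)
        if not self.has_site_rate_variation():
            return np.ones(n_sites)
        pinv = self.prop_invariant or 0.0
        mult = np.ones(n_sites) / (1.0 - pinv)
        if self.gamma_shape is not None:
            a = self.gamma_shape
            mult = rng.gamma(a, 1.0 / a, size=n_sites) / (1.0 - pinv)
        if pinv > 0:
            mult[rng.random(n_sites) < pinv] = 0.0
        return mult

    def discrete_gamma_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete +I+Gamma mixture used in likelihoods."""
        pinv = self.prop_invariant or 0.0
        if self.gamma_shape is None:
            rates = np.array([1.0 / (1.0 - pinv)]) if pinv > 0 else np.array([1.0])
            weights = np.array([1.0 - pinv])
        else:
            k = self.gamma_categories
            a = self.gamma_shape
            # median-of-category discretisation, renormalised to mean 1
            qs = stats.gamma.ppf((2 * np.arange(k) + 1) / (2 * k), a, scale=1.0 / a)
            rates = qs / qs.mean() / (1.0 - pinv)
            weights = np.full(k, (1.0 - pinv) / k)
        if pinv > 0:
            rates = np.concatenate([[0.0], rates])
            weights = np.concatenate([[pinv], weights])
        return rates, weights

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SubstitutionModel({self.model_name}, kappa={self.kappa:g}, "
            f"freqs={np.round(self.base_frequencies, 4).tolist()})"
        )


def make_hky(
    base_frequencies: Sequence[float] = EQUAL_FREQUENCIES,
    ts_tv_ratio: Optional[float] = None,
    kappa: Optional[float] = None,
    **kwargs,
) -> SubstitutionModel:
    """Build an HKY model from either the event ratio R or the rate ratio kappa.

    Exactly one of ``ts_tv_ratio`` (expected transition/transversion event
    ratio, Seq-Gen's convention) or ``kappa`` (instantaneous rate ratio) must
    be given. With equal base frequencies, ``kappa = 2 * ts_tv_ratio``.
    """
    if (ts_tv_ratio is None) == (kappa is None):
        raise ValueError("give exactly one of ts_tv_ratio or kappa")
    if kappa is None:
        kappa = kappa_from_ts_tv_ratio(ts_tv_ratio, base_frequencies)
    return SubstitutionModel(base_frequencies=base_frequencies, kappa=kappa, **kwargs)


def make_jc(**kwargs) -> SubstitutionModel:
    """Jukes-Cantor: equal frequencies, kappa = 1."""
    return SubstitutionModel(EQUAL_FREQUENCIES, kappa=1.0, **kwargs)


def transition_probabilities(model: SubstitutionModel, branch_length) -> np.ndarray:
    return model.transition_probabilities(branch_length)


def site_rate_multipliers(model: SubstitutionModel, n_sites: int, rng_seed) -> np.ndarray:
    return model.site_rate_multipliers(n_sites, rng_seed)
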