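import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import clockdrift as cd
from clockdrift.substmodel import kappa_from_ts_tv_ratio


class TestHKYConstruction:
    def test_event_ratio_2_gives_kappa_4_at_equal_frequencies(self, hky2):
        assert hky2.kappa == pytest.approx(4.0)
        assert hky2.ts_tv_ratio == pytest.approx(2.0)

    def test_event_ratio_half_collapses_to_jukes_cantor(self):
        m = cd.make_hky(ts_tv_ratio=0.5)
        assert m.kappa == pytest.approx(1.0)
        assert m.model_name == "JC"

    def test_stationary_flux_matches_requested_event_ratio(self):
        """Oracle: sum transition vs transversion flux of the rate matrix."""
        freqs = [0.1, 0.2, 0.3, 0.4]
        for R in (0.7, 2.0, 5.0):
            m = cd.make_hky(base_frequencies=freqs, ts_tv_ratio=R)
            assert m.ts_tv_ratio == pytest.approx(R, rel=1e-12)

    def test_rate_matrix_calibration_and_row_sums(self, hky2):
        Q = hky2.rate_matrix
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.dot(hky2.base_frequencies, np.diag(Q)) == pytest.approx(1.0)

    def test_detailed_balance(self):
        m = cd.make_hky(base_frequencies=[0.1, 0.2, 0.3, 0.4], ts_tv_ratio=3.0)
        pi, Q = m.base_frequencies, m.rate_matrix
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-14)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ts_tv_ratio": -1.0},
            {"ts_tv_ratio": 0.0},
            {"ts_tv_ratio": 2.0, "base_frequencies": [0.5, 0.5, 0.0, 0.0]},
            {"ts_tv_ratio": 2.0, "base_frequencies": [0.5, 0.2, 0.2, 0.2]},
            {"ts_tv_ratio": 2.0, "kappa": 4.0},
            {},
        ],
    )
    def test_invalid_construction_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cd.make_hky(**kwargs)


class TestTransitionProbabilities:
    def test_zero_length_is_identity(self, hky2, jc):
        for m in (hky2, jc):
            assert np.allclose(m.transition_probabilities(0.0), np.eye(4), atol=1e-14)

    def test_jc_closed_form(self, jc):
        t = 0.1
        P = jc.transition_probabilities(t)
        expected_diag = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
        assert np.allclose(np.diag(P), expected_diag, atol=1e-12)
        assert np.allclose(P - np.diag(np.diag(P)), (1 - expected_diag) / 3 * (1 - np.eye(4)), atol=1e-12)

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.6, 2.0])
    def test_hky_matches_matrix_exponential(self, hky2, t):
        P = hky2.transition_probabilities(t)
        assert np.abs(P - expm(hky2.rate_matrix * t)).max() < 1e-10

    def test_unequal_frequency_hky_matches_matrix_exponential(self):
        m = cd.make_hky(base_frequencies=[0.35, 0.15, 0.3, 0.2], ts_tv_ratio=1.7)
        for t in (0.05, 0.4, 1.3):
            assert np.abs(m.transition_probabilities(t) - expm(m.rate_matrix * t)).max() < 1e-10

    def test_gtr_matches_matrix_exponential(self):
        m = cd.SubstitutionModel(
            [0.3, 0.2, 0.2, 0.3], exchangeabilities=[1.0, 3.0, 0.5, 0.8, 2.5, 1.2]
        )
        for t in (0.1, 0.7):
            assert np.abs(m.transition_probabilities(t) - expm(m.rate_matrix * t)).max() < 1e-9

    def test_vectorised_lengths(self, hky2):
        ts = np.array([0.0, 0.1, 0.5])
        P = hky2.transition_probabilities(ts)
        assert P.shape == (3, 4, 4)
        for k, t in enumerate(ts):
            assert np.allclose(P[k], hky2.transition_probabilities(t))

    def test_negative_length_rejected(self, hky2):
        with pytest.raises(ValueError):
            hky2.transition_probabilities(-0.1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        t1=st.floats(0.0, 2.0),
        t2=st.floats(0.0, 2.0),
        kappa=st.floats(0.5, 20.0),
    )
    def test_chapman_kolmogorov(self, t1, t2, kappa):
        m = cd.make_hky(kappa=kappa)
        P1, P2 = m.transition_probabilities(t1), m.transition_probabilities(t2)
        assert np.abs(P1 @ P2 - m.transition_probabilities(t1 + t2)).max() < 1e-9

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(t=st.floats(0.0, 3.0))
    def test_stationarity(self, t):
        m = cd.make_hky(base_frequencies=[0.1, 0.2, 0.3, 0.4], ts_tv_ratio=2.0)
        pi = m.base_frequencies
        assert np.allclose(pi @ m.transition_probabilities(t), pi, atol=1e-12)


class TestSiteRateMultipliers:
    def test_plain_model_gives_ones(self, hky2):
        assert np.all(hky2.site_rate_multipliers(1000, 0) == 1.0)

    def test_huge_shape_degenerates_to_point_mass(self):
        m = cd.make_hky(ts_tv_ratio=2.0, gamma_shape=1e6)
        mult = m.site_rate_multipliers(5000, 1)
        assert np.abs(mult - 1.0).max() < 1e-2

    def test_invariant_gamma_mixture_moments(self):
        m = cd.make_hky(ts_tv_ratio=2.0, gamma_shape=0.5, prop_invariant=0.2)
        mult = m.site_rate_multipliers(100_000, 2)
        assert np.mean(mult) == pytest.approx(1.0, abs=0.02)
        assert np.mean(mult == 0.0) == pytest.approx(0.2, abs=0.01)

    def test_discrete_gamma_rates_mean_one(self):
        m = cd.make_hky(ts_tv_ratio=2.0, gamma_shape=0.7, prop_invariant=0.1)
        rates, weights = m.discrete_gamma_rates()
        assert weights.sum() == pytest.approx(1.0)
        assert np.dot(rates, weights) == pytest.approx(1.0, rel=1e-9)


def test_kappa_from_event_ratio_unequal_frequencies():
    freqs = [0.4, 0.1, 0.1, 0.4]
    kappa = kappa_from_ts_tv_ratio(2.0, freqs)
    m = cd.SubstitutionModel(freqs, kappa=kappa)
    assert m.ts_tv_ratio == pytest.approx(2.0)
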