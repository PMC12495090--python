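"""Causal-inference kernel: cue weighting, posterior, estimate limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpbci.bci import (
    InvalidParameterError,
    ObserverParams,
    TrialStimulus,
    common_cause_posterior,
    forced_fusion_estimate,
    fusion_weights,
    position_estimate,
    sample_sensory,
)


class TestFusionWeights:
    @pytest.mark.parametrize(
        "sigma_v, sigma_p, w_v_expected",
        [
            (5.0, 5.0, 0.5),        # symmetric cues
            (1e-9, 5.0, 1.0),       # perfect vision limit
            (1.0, 2.0, 0.8),        # r_v=1, r_p=0.25 -> 1/(1.25)
        ],
    )
    def test_inverse_variance_weighting(self, sigma_v, sigma_p, w_v_expected):
        w = fusion_weights(sigma_v, sigma_p)
        assert w.w_v == pytest.approx(w_v_expected, abs=1e-9)
        assert w.w_v + w.w_p == pytest.approx(1.0)
        assert min(w.w_v, w.w_p, w.r_v, w.r_p) >= 0

    @pytest.mark.parametrize("bad", [(0.0, 5.0), (5.0, -1.0)])
    def test_nonpositive_sigma_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            fusion_weights(*bad)


class TestForcedFusion:
    @pytest.mark.parametrize(
        "x_v, x_p, sigma_v, sigma_p, expected",
        [
            (10.0, 10.0, 3.0, 7.0, 10.0),   # identical cues
            (0.0, 20.0, 4.0, 4.0, 10.0),    # equal weights midpoint
            (0.0, 10.0, 1.0, 2.0, 2.0),     # 0.8/0.2 weighting
        ],
    )
    def test_weighted_average(self, x_v, x_p, sigma_v, sigma_p, expected):
        assert forced_fusion_estimate(x_v, x_p, sigma_v, sigma_p) == pytest.approx(expected)

    @given(
        x_v=st.floats(-80, 80),
        x_p=st.floats(-80, 80),
        sv=st.floats(0.3, 20),
        sp=st.floats(0.3, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_estimate_between_cues(self, x_v, x_p, sv, sp):
        ff = forced_fusion_estimate(x_v, x_p, sv, sp)
        assert min(x_v, x_p) - 1e-9 <= ff <= max(x_v, x_p) + 1e-9


class TestCommonCausePosterior:
    def test_prior_extremes_pin_posterior(self):
        for x_v, x_p in [(0.0, 0.0), (30.0, -10.0)]:
            p0 = common_cause_posterior(x_v, x_p, ObserverParams(4, 6, 0.0))
            p1 = common_cause_posterior(x_v, x_p, ObserverParams(4, 6, 1.0))
            assert p0.p_com == 0.0
            assert p1.p_com == 1.0

    def test_congruent_cues_equal_sigmas(self):
        # direct evaluation of the posterior formula at delta = 0,
        # sigma_v = sigma_p = 5, flat 0.5 prior (hand-checked)
        post = common_cause_posterior(7.0, 7.0, ObserverParams(5, 5, 0.5))
        assert post.p_com == pytest.approx(0.9103574, abs=1e-4)
        assert post.sigma_s2 == pytest.approx(50.0)
        assert post.alpha == pytest.approx(180 * np.sqrt(2 * np.pi * 50.0))

    def test_monotone_decreasing_in_disparity(self):
        params = ObserverParams(4, 7, 0.6)
        deltas = np.linspace(0, 60, 40)
        pcs = [common_cause_posterior(d, 0.0, params).p_com for d in deltas]
        assert all(a > b for a, b in zip(pcs, pcs[1:]))

    def test_posterior_at_zero_disparity_decreases_with_noise(self):
        pcs = [
            common_cause_posterior(0.0, 0.0, ObserverParams(s, s, 0.5)).p_com
            for s in (2, 5, 10, 20)
        ]
        assert all(a > b for a, b in zip(pcs, pcs[1:]))

    def test_posterior_at_large_disparity_increases_with_proprioceptive_noise(self):
        # wider integration window: a 40 deg conflict is more credible as a
        # single cause when proprioception is noisier
        pcs = [
            common_cause_posterior(40.0, 0.0, ObserverParams(2, sp, 0.5)).p_com
            for sp in (3, 6, 12, 20)
        ]
        assert all(a < b for a, b in zip(pcs, pcs[1:]))


def _grid_posterior_oracle(x_v, x_p, params, n_grid=4001):
    """Brute-force posterior by numerical integration of the generative model
    over the uniform position prior on (-90, 90)."""
    s = np.linspace(-90, 90, n_grid)
    prior = 1.0 / 180.0
    lik_v = np.exp(-((x_v - s) ** 2) / (2 * params.sigma_v**2)) / (
        np.sqrt(2 * np.pi) * params.sigma_v
    )
    lik_p = np.exp(-((x_p - s) ** 2) / (2 * params.sigma_p**2)) / (
        np.sqrt(2 * np.pi) * params.sigma_p
    )
    l1 = np.trapezoid(prior * lik_v * lik_p, s)
    l2 = np.trapezoid(prior * lik_v, s) * np.trapezoid(prior * lik_p, s)
    num = params.p_prior * l1
    return num / (num + (1 - params.p_prior) * l2)


def test_posterior_matches_integration_oracle_spot_checks():
    for sv, sp, delta in [(2, 4, 0), (3, 8, 15), (6, 6, 40)]:
        params = ObserverParams(sv, sp, 0.5)
        ours = common_cause_posterior(delta / 2, -delta / 2, params).p_com
        oracle = _grid_posterior_oracle(delta / 2, -delta / 2, params)
        assert ours == pytest.approx(oracle, abs=1e-3)


class TestPositionEstimate:
    def test_collapses_to_proprioception_without_prior(self):
        post = position_estimate(25.0, -3.0, ObserverParams(3, 5, 0.0))
        assert post.s_hat_p == pytest.approx(-3.0)

    def test_collapses_to_fusion_with_certain_prior(self):
        params = ObserverParams(3, 5, 1.0)
        post = position_estimate(25.0, -3.0, params)
        assert post.s_hat_p == pytest.approx(
            forced_fusion_estimate(25.0, -3.0, 3, 5)
        )

    def test_mixture_arithmetic(self):
        # p_com = 0.5, x_ff = 2, x_p = 10 -> 0.5*2 + 0.5*10 = 6
        assert 0.5 * 2 + (1 - 0.5) * 10 == pytest.approx(6.0)
        # and the implementation respects the same mixing rule
        params = ObserverParams(1, 2, 0.5)
        post = position_estimate(0.0, 10.0, params)
        expected = post.p_com * post.x_ff + (1 - post.p_com) * 10.0
        assert post.s_hat_p == pytest.approx(expected)

    @given(
        x_v=st.floats(-60, 60),
        x_p=st.floats(-60, 60),
        sv=st.floats(0.5, 15),
        sp=st.floats(0.5, 15),
        pp=st.floats(0, 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_convex_combination_of_xp_and_xff(self, x_v, x_p, sv, sp, pp):
        post = position_estimate(x_v, x_p, ObserverParams(sv, sp, pp))
        lo = min(x_p, post.x_ff) - 1e-9
        hi = max(x_p, post.x_ff) + 1e-9
        assert lo <= post.s_hat_p <= hi
        assert 0.0 <= post.p_com <= 1.0


class TestSampleSensory:
    def test_noiseless_limit(self):
        stim = TrialStimulus(s_p=10.0, s_v=30.0)
        s = sample_sensory(stim, ObserverParams(1e-12, 1e-12, 0.5), rng=0)
        assert s.x_v == pytest.approx(30.0, abs=1e-9)
        assert s.x_p == pytest.approx(10.0, abs=1e-9)

    def test_seed_determinism(self):
        stim = TrialStimulus(s_p=0.0, s_v=20.0)
        params = ObserverParams(3, 6, 0.5)
        a = sample_sensory(stim, params, rng=42)
        b = sample_sensory(stim, params, rng=42)
        assert a == b

    def test_noise_magnitude(self):
        stim = TrialStimulus(s_p=0.0, s_v=0.0)
        s = sample_sensory(stim, ObserverParams(3, 8, 0.5), rng=1, size=10_000)
        assert np.std(s.x_p) == pytest.approx(8.0, abs=0.2)

    def test_stimulus_range_validated(self):
        with pytest.raises(InvalidParameterError):
            TrialStimulus(s_p=95.0, s_v=0.0)
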