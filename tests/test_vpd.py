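"""VPD task design, reach simulation, normalisation and ownership coupling."""

import collections
import dataclasses

import numpy as np
import pytest

from vpbci.bci import InvalidParameterError, ObserverParams
from vpbci.vpd import (
    DISPARITIES_MAIN,
    DISPARITIES_RATING,
    TARGETS_MAIN,
    DegenerateStatisticError,
    MissingBaselineError,
    ReachTrial,
    TrialSpec,
    build_vpd_design,
    generate_rating,
    normalize_errors,
    residual_ownership_correlation,
    simulate_participant,
    simulate_reach_trial,
    trials_to_frame,
)


class TestDesign:
    def test_block_composition(self):
        design = build_vpd_design(seed=3)
        by_block = collections.Counter(s.block for s in design.blocks)
        assert by_block == {1: 49, 2: 49, 3: 25}
        for block in (1, 2):
            cells = {
                (s.target, s.disparity)
                for s in design.blocks
                if s.block == block
            }
            assert cells == {(t, d) for t in TARGETS_MAIN for d in DISPARITIES_MAIN}
        block3 = [s for s in design.blocks if s.block == 3]
        assert all(s.collect_rating for s in block3)
        assert {s.disparity for s in block3} == set(DISPARITIES_RATING)
        assert not any(s.collect_rating for s in design.blocks if s.block != 3)

    def test_seed_determinism_and_shuffling(self):
        a = build_vpd_design(seed=5)
        b = build_vpd_design(seed=5)
        c = build_vpd_design(seed=6)
        assert a.blocks == b.blocks
        assert a.blocks != c.blocks


class TestReachSimulation:
    def test_pure_proprioception_unbiased(self):
        spec = TrialSpec(1, 15.0, 26.6, False)
        params = ObserverParams(3, 6, 0.0, sigma_m=0.0)
        rng = np.random.default_rng(0)
        errs = [
            simulate_reach_trial(spec, params, rng).observed_error
            for _ in range(5000)
        ]
        assert np.mean(errs) == pytest.approx(0.0, abs=0.2)

    def test_full_visual_capture_tracks_disparity(self):
        spec = TrialSpec(1, 0.0, 40.0, False)
        params = ObserverParams(0.01, 5.0, 1.0, sigma_m=0.0)
        rng = np.random.default_rng(1)
        errs = [
            simulate_reach_trial(spec, params, rng).observed_error
            for _ in range(5000)
        ]
        assert np.mean(errs) == pytest.approx(-40.0, abs=0.3)

    def test_congruent_hands_unbiased(self, typical_observer):
        spec = TrialSpec(1, -30.0, 0.0, False)
        params = dataclasses.replace(typical_observer, sigma_m=0.0)
        rng = np.random.default_rng(2)
        errs = [
            simulate_reach_trial(spec, params, rng).observed_error
            for _ in range(5000)
        ]
        assert np.mean(errs) == pytest.approx(0.0, abs=0.25)

    def test_visual_attraction_rises_then_wanes(self, typical_observer):
        """Attraction toward the virtual hand grows while the conflict is
        credibly one's own hand, stays positive throughout, and weakens
        once the disparity is large enough to be segregated — the signature
        that separates causal inference from forced fusion."""
        rng = np.random.default_rng(3)
        mean_pull = {}
        for d in (0.0, 13.3, 26.6, 40.0):
            spec = TrialSpec(1, 0.0, d, False)
            errs = [
                simulate_reach_trial(spec, typical_observer, rng).observed_error
                for _ in range(3000)
            ]
            mean_pull[d] = -np.mean(errs)
        assert mean_pull[0.0] == pytest.approx(0.0, abs=0.3)
        assert mean_pull[13.3] > 1.0
        assert all(mean_pull[d] > 0 for d in (13.3, 26.6, 40.0))
        assert mean_pull[40.0] < mean_pull[13.3]

    def test_noisier_proprioception_steeper_attraction_and_higher_ratings(self):
        """Qualitative ageing mirror: at equal priors the high-sigma_p
        observer follows the virtual hand more and owns it more."""
        young = ObserverParams(3.5, 2.5, 0.7, sigma_m=0.0)
        older = ObserverParams(4.5, 9.0, 0.7, sigma_m=0.0)
        out = {}
        for name, params in [("young", young), ("older", older)]:
            trials = simulate_participant(params, seed=9)
            pull = np.mean(
                [
                    -t.normalized_error * np.sign(t.disparity)
                    for t in trials
                    if abs(t.disparity) == 40.0
                ]
            )
            ratings = np.mean([t.rating for t in trials if t.rating is not None])
            out[name] = (pull, ratings)
        assert out["older"][0] > out["young"][0]
        assert out["older"][1] > out["young"][1]


class TestNormalization:
    @staticmethod
    def _make(errors_at_zero, other_error):
        trials = [
            ReachTrial(1, 0.0, 0.0, e, e) for e in errors_at_zero
        ] + [ReachTrial(1, 0.0, 26.6, other_error, other_error)]
        return trials

    @pytest.mark.parametrize(
        "zero_errs, err, expected",
        [([1.0, -1.0], 5.0, 5.0), ([2.0, 4.0], 5.0, 2.0), ([0.0, 0.0], 0.0, 0.0)],
    )
    def test_baseline_subtraction(self, zero_errs, err, expected):
        out = normalize_errors(self._make(zero_errs, err))
        assert out[-1].normalized_error == pytest.approx(expected)
        zero_norm = [t.normalized_error for t in out if t.disparity == 0.0]
        assert np.mean(zero_norm) == pytest.approx(0.0, abs=1e-12)

    def test_missing_baseline_rejected(self):
        trials = [ReachTrial(1, 0.0, 13.3, 1.0, 1.0)]
        with pytest.raises(MissingBaselineError):
            normalize_errors(trials)


class TestRatings:
    def test_anchors_and_rounding(self):
        assert generate_rating(1.0, 0, noise_sd=0.0) == 10
        assert generate_rating(0.0, 0, noise_sd=0.0) == 1
        # round-half-up: 1 + 9*0.5 = 5.5 -> 6
        assert generate_rating(0.5, 0, noise_sd=0.0) == 6

    def test_out_of_range_posterior_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_rating(1.5, 0)

    def test_monotone_in_posterior_expectation(self):
        rng = np.random.default_rng(0)
        means = [
            np.mean([generate_rating(p, rng) for _ in range(2000)])
            for p in (0.1, 0.5, 0.9)
        ]
        assert means[0] < means[1] < means[2]


class TestResidualOwnership:
    @staticmethod
    def _trial(d, err, rating):
        return ReachTrial(3, 0.0, d, err, err, normalized_error=err, rating=rating)

    def test_perfect_coupling(self):
        # construct trials where the sign-corrected residual error equals the
        # residual rating on every trial
        trials = []
        for d in (20.0, -20.0, 40.0, -40.0):
            for k, dev in enumerate((-1.0, 0.0, 1.0)):
                err = -np.sign(d) * dev  # residual error * -sign(d) == dev
                trials.append(self._trial(d, err, 5 + dev))
        assert residual_ownership_correlation(trials) == pytest.approx(1.0)

    def test_independent_ratings_uncorrelated(self):
        rng = np.random.default_rng(4)
        trials = [
            self._trial(
                float(rng.choice([20.0, -20.0, 40.0, -40.0])),
                float(rng.normal(0, 2)),
                int(rng.integers(1, 11)),
            )
            for _ in range(1000)
        ]
        assert abs(residual_ownership_correlation(trials)) < 0.1

    def test_constant_ratings_flagged(self):
        trials = [
            self._trial(d, e, 7)
            for d in (20.0, -20.0)
            for e in (-1.0, 0.0, 1.0)
        ]
        with pytest.raises(DegenerateStatisticError):
            residual_ownership_correlation(trials)

    def test_positive_coupling_in_simulated_observer(self, typical_observer):
        trials = simulate_participant(typical_observer, seed=1)
        assert residual_ownership_correlation(trials) > 0.2


def test_trial_frame_schema(typical_observer):
    trials = simulate_participant(typical_observer, seed=2)
    df = trials_to_frame(trials, "p01", "HO")
    assert len(df) == 123
    assert df["rating"].notna().sum() == 25
    assert set(df.loc[df["rating"].notna(), "block"]) == {3}
    assert (df["observed_error_deg"] == df["endpoint_deg"] - df["target_deg"]).all()
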