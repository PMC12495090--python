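"""Visuo-proprioceptive disparity (VPD) reaching task: design and simulator.

The task: reach a target with the unseen real hand while a virtual hand is
rotated by a disparity angle.  Blocks 1-2 cross 7 targets (0, +-15, +-30,
+-45 deg) with 7 disparities (0, +-13.3, +-26.6, +-40 deg); block 3 crosses
5 targets with 5 disparities (0, +-20, +-40 deg) and collects a 1-10
ownership rating after every reach.

A simulated observer samples noisy representations of the pre-movement hand
position (real hand at the start location, virtual hand displaced by the
disparity), forms the causal-inference estimate ``s_hat_p`` of where its hand
is, and plans the reach from that estimate.  The bias of the estimate toward
the virtual hand therefore displaces the endpoint opposite the disparity:

    endpoint = target - (s_hat_p - x_p) + N(0, sigma_m)

Pure proprioceptive guidance (p_prior = 0) gives zero expected error; full
visual capture (p_prior = 1, sigma_v -> 0) gives an expected error of
-disparity, the "visual following" diagonal.

Observed errors are cleaned per participant by subtracting the mean error at
zero disparity (the ``normalized_error`` column).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bci import InvalidParameterError, ObserverParams, common_cause_posterior

__all__ = [
    "TARGETS_MAIN",
    "DISPARITIES_MAIN",
    "TARGETS_RATING",
    "DISPARITIES_RATING",
    "TrialSpec",
    "VpdDesign",
    "ReachTrial",
    "build_vpd_design",
    "simulate_reach_trial",
    "simulate_participant",
    "normalize_errors",
    "generate_rating",
    "residual_ownership_correlation",
    "trials_to_frame",
]

TARGETS_MAIN = (0.0, 15.0, -15.0, 30.0, -30.0, 45.0, -45.0)
DISPARITIES_MAIN = (0.0, 13.3, -13.3, 26.6, -26.6, 40.0, -40.0)
#: Block-3 target subset (5 of the 7 main targets; configurable in
#: :func:`build_vpd_design`).
TARGETS_RATING = (0.0, 15.0, -15.0, 30.0, -30.0)
DISPARITIES_RATING = (0.0, 20.0, -20.0, 40.0, -40.0)


@dataclass(frozen=True)
class TrialSpec:
    block: int
    target: float
    disparity: float
    collect_rating: bool


@dataclass(frozen=True)
class VpdDesign:
    """Ordered trial list of the three-block VPD session."""

    blocks: tuple[TrialSpec, ...]

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class ReachTrial:
    """One simulated (or observed) reach."""

    block: int
    target: float
    disparity: float
    endpoint: float
    observed_error: float
    normalized_error: float | None = None
    rating: int | None = None
    p_com: float | None = None


class MissingBaselineError(ValueError):
    """No zero-disparity trials available to anchor error normalisation."""


class DegenerateStatisticError(ValueError):
    """A correlation statistic is undefined on the given trials."""


def build_vpd_design(
    seed: int,
    rating_targets: tuple[float, ...] = TARGETS_RATING,
) -> VpdDesign:
    """Build the randomized three-block design (deterministic per seed).

    Blocks 1 and 2 each enumerate the full 7 x 7 target-by-disparity cross
    (49 trials); block 3 enumerates ``rating_targets`` x 5 disparities
    (25 trials) with rating collection on.  Order is shuffled within block.
    """
    rng = np.random.default_rng(seed)
    blocks: list[TrialSpec] = []
    for block in (1, 2):
        cell = [
            TrialSpec(block, t, d, False)
            for t in TARGETS_MAIN
            for d in DISPARITIES_MAIN
        ]
        rng.shuffle(cell)
        blocks.extend(cell)
    cell = [
        TrialSpec(3, t, d, True)
        for t in rating_targets
        for d in DISPARITIES_RATING
    ]
    rng.shuffle(cell)
    blocks.extend(cell)
    return VpdDesign(blocks=tuple(blocks))


def simulate_reach_trial(
    spec: TrialSpec,
    params: ObserverParams,
    rng: np.random.Generator | int,
    rating_noise_sd: float = 1.0,
) -> ReachTrial:
    """Simulate one reach (and its rating when the spec collects one).

    The sensory sample is taken at the pre-movement hand position: the real
    hand at the start location (0 deg) and the virtual hand displaced by the
    trial's disparity.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x_p = gen.normal(0.0, params.sigma_p)
    x_v = spec.disparity + gen.normal(0.0, params.sigma_v)
    post = common_cause_posterior(x_v, x_p, params)
    motor = gen.normal(0.0, params.sigma_m) if params.sigma_m > 0 else 0.0
    endpoint = spec.target - (post.s_hat_p - x_p) + motor
    rating = (
        generate_rating(post.p_com, gen, noise_sd=rating_noise_sd)
        if spec.collect_rating
        else None
    )
    return ReachTrial(
        block=spec.block,
        target=spec.target,
        disparity=spec.disparity,
        endpoint=endpoint,
        observed_error=endpoint - spec.target,
        rating=rating,
        p_com=float(post.p_com),
    )


def simulate_participant(
    params: ObserverParams,
    seed: int,
    design: VpdDesign | None = None,
    rating_noise_sd: float = 1.0,
    normalize: bool = True,
) -> list[ReachTrial]:
    """Simulate a full VPD session for one observer."""
    if design is None:
        design = build_vpd_design(seed)
    gen = np.random.default_rng(seed)
    trials = [
        simulate_reach_trial(spec, params, gen, rating_noise_sd=rating_noise_sd)
        for spec in design.blocks
    ]
    return normalize_errors(trials) if normalize else trials


def normalize_errors(trials: list[ReachTrial]) -> list[ReachTrial]:
    """Subtract the mean zero-disparity reaching error from every trial.

    Removes systematic reach biases (calibration, tracking) so that the mean
    normalized error at 0 deg disparity is exactly zero.
    """
    baseline_errors = [t.observed_error for t in trials if t.disparity == 0.0]
    if not baseline_errors:
        raise MissingBaselineError("no zero-disparity trials to estimate the baseline")
    baseline = float(np.mean(baseline_errors))
    return [replace(t, normalized_error=t.observed_error - baseline) for t in trials]


def generate_rating(
    p_com: float,
    rng: np.random.Generator | int,
    noise_sd: float = 1.0,
) -> int:
    """Map a common-cause posterior to a synthetic 1-10 ownership rating.

    rating = clip(round_half_up(1 + 9 p_com + eps), 1, 10), eps ~ N(0,
    noise_sd).  Purely a synthetic-cohort device; ratings are never used in
    model fitting.
    """
    if not (0.0 <= p_com <= 1.0):
        raise InvalidParameterError(f"p_com must be in [0, 1], got {p_com}")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eps = gen.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
    raw = 1.0 + 9.0 * p_com + eps
    return int(np.clip(math.floor(raw + 0.5), 1, 10))


def residual_ownership_correlation(trials: list[ReachTrial]) -> float:
    """Trial-level implicit/explicit ownership coupling within a participant.

    For rating-block trials at non-zero disparity: residual rating = rating
    minus the mean rating at the same disparity; residual error = (normalized
    error minus its disparity mean) times -sign(disparity), so that a larger
    visual weight maps to a positive residual (under the endpoint - target
    error convention, visual attraction displaces the hand opposite the
    disparity).  Returns the Pearson r between the two residual series.

    Raises
    ------
    DegenerateStatisticError
        If no non-zero-disparity rated trials exist or either residual series
        has zero variance.
    """
    rated = [
        t for t in trials
        if t.rating is not None and t.disparity != 0.0
    ]
    if not rated:
        raise DegenerateStatisticError("no rated trials at non-zero disparity")
    for t in rated:
        if t.normalized_error is None:
            raise MissingBaselineError("trials must be normalized first")
    df = pd.DataFrame(
        {
            "disparity": [t.disparity for t in rated],
            "rating": [float(t.rating) for t in rated],
            "err": [t.normalized_error for t in rated],
        }
    )
    g = df.groupby("disparity")
    df["res_rating"] = df["rating"] - g["rating"].transform("mean")
    df["res_err"] = (df["err"] - g["err"].transform("mean")) * -np.sign(df["disparity"])
    if df["res_rating"].std(ddof=0) == 0 or df["res_err"].std(ddof=0) == 0:
        raise DegenerateStatisticError("residual series constant; correlation undefined")
    return float(np.corrcoef(df["res_err"], df["res_rating"])[0, 1])


def trials_to_frame(
    trials: list[ReachTrial],
    participant_id: str = "p00",
    group: str = "NA",
) -> pd.DataFrame:
    """Flatten trials into the canonical trial-table schema."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "group": group,
            "block": [t.block for t in trials],
            "trial_index": np.arange(len(trials)),
            "target_deg": [t.target for t in trials],
            "disparity_deg": [t.disparity for t in trials],
            "endpoint_deg": [t.endpoint for t in trials],
            "observed_error_deg": [t.observed_error for t in trials],
            "normalized_error_deg": [t.normalized_error for t in trials],
            "rating": [t.rating if t.rating is not None else pd.NA for t in trials],
        }
    )
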