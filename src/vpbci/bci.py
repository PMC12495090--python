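"""Bayesian causal-inference kernel for visuo-proprioceptive hand localisation.

The observer sees a (possibly displaced) virtual hand at angle ``s_v`` while
proprioception signals the real hand at ``s_p`` (both in degrees from the
shoulder).  Each trial yields noisy internal representations

    x_v = s_v + N(0, sigma_v),    x_p = s_p + N(0, sigma_p).

The two cues may share a single cause (the virtual hand *is* one's hand,
C = 1, prior probability ``p_prior``) or have two separate causes (C = 2).
Under a common cause the optimal estimate is the reliability-weighted
(forced-fusion) average; under separate causes vision is irrelevant and the
estimate reduces to ``x_p``.  The reported hand-position estimate marginalises
over the causal structure:

    s_hat_p = P_com * x_ff + (1 - P_com) * x_p

where ``P_com`` is the posterior probability of a common cause given the
sample, computed with a uniform position prior on (-90, 90) degrees, so the
single-cause likelihood is ``exp(-delta^2 / (2 sigma_s^2)) / alpha`` with
``alpha = 180 * sqrt(2 pi sigma_s^2)`` and the two-cause likelihood is
``1 / 180^2``.

All functions are vectorised over their sensory-sample arguments; angles are
degrees throughout and are never wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ObserverParams",
    "TrialStimulus",
    "SensorySample",
    "FusionWeights",
    "PosteriorEstimate",
    "fusion_weights",
    "forced_fusion_estimate",
    "common_cause_posterior",
    "position_estimate",
    "sample_sensory",
]

#: Width of the uniform position prior, degrees.  The prior support is the
#: open interval (-90, 90); this constant enters the likelihood normalisers.
PRIOR_RANGE_DEG = 180.0


class InvalidParameterError(ValueError):
    """Raised when observer parameters violate their domain constraints."""


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one observer.

    Parameters
    ----------
    sigma_v : float
        Visual noise SD, degrees (> 0).
    sigma_p : float
        Proprioceptive noise SD, degrees (> 0).
    p_prior : float
        Prior probability of a common cause, in [0, 1].
    sigma_m : float, default 0
        Motor-execution noise SD, degrees (>= 0).  Additive noise on the
        reach endpoint only; it never enters the perceptual inference.
    """

    sigma_v: float
    sigma_p: float
    p_prior: float
    sigma_m: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_v > 0 and np.isfinite(self.sigma_v)):
            raise InvalidParameterError(f"sigma_v must be > 0, got {self.sigma_v}")
        if not (self.sigma_p > 0 and np.isfinite(self.sigma_p)):
            raise InvalidParameterError(f"sigma_p must be > 0, got {self.sigma_p}")
        if not (0.0 <= self.p_prior <= 1.0):
            raise InvalidParameterError(f"p_prior must be in [0, 1], got {self.p_prior}")
        if not (self.sigma_m >= 0 and np.isfinite(self.sigma_m)):
            raise InvalidParameterError(f"sigma_m must be >= 0, got {self.sigma_m}")


@dataclass(frozen=True)
class TrialStimulus:
    """True hand angles of one trial: real ``s_p``, virtual ``s_v`` (degrees)."""

    s_p: float
    s_v: float

    def __post_init__(self) -> None:
        for name, val in (("s_p", self.s_p), ("s_v", self.s_v)):
            if not (-90.0 <= val <= 90.0):
                raise InvalidParameterError(f"{name} must lie in [-90, 90], got {val}")

    @property
    def disparity(self) -> float:
        """Angular disparity s_v - s_p; positive = clockwise virtual-hand shift."""
        return self.s_v - self.s_p


@dataclass(frozen=True)
class SensorySample:
    """Noisy internal representations of one trial (degrees, unclipped)."""

    x_p: float
    x_v: float


@dataclass(frozen=True)
class FusionWeights:
    """Reliability-based cue weights; r_* are reliabilities 1/sigma^2."""

    w_v: float
    w_p: float
    r_v: float
    r_p: float


@dataclass(frozen=True)
class PosteriorEstimate:
    """Model outputs for one sensory sample (vectorised fields allowed)."""

    p_com: np.ndarray | float
    x_ff: np.ndarray | float
    s_hat_p: np.ndarray | float
    delta_s: np.ndarray | float
    sigma_s2: float
    alpha: float


def _check_sigmas(sigma_v: float, sigma_p: float) -> None:
    if not (np.all(np.asarray(sigma_v) > 0) and np.all(np.asarray(sigma_p) > 0)):
        raise InvalidParameterError("sigma_v and sigma_p must be strictly positive")


def fusion_weights(sigma_v: float, sigma_p: float) -> FusionWeights:
    """Inverse-variance cue weights for forced fusion.

    w_v = r_v / (r_v + r_p) with reliabilities r_i = 1 / sigma_i^2; the two
    weights sum to one.
    """
    _check_sigmas(sigma_v, sigma_p)
    r_v = 1.0 / sigma_v**2
    r_p = 1.0 / sigma_p**2
    w_v = r_v / (r_v + r_p)
    return FusionWeights(w_v=w_v, w_p=1.0 - w_v, r_v=r_v, r_p=r_p)


def forced_fusion_estimate(x_v, x_p, sigma_v: float, sigma_p: float):
    """Reliability-weighted average of the two cues (mandatory integration)."""
    w = fusion_weights(sigma_v, sigma_p)
    return w.w_v * np.asarray(x_v, dtype=float) + w.w_p * np.asarray(x_p, dtype=float)


def common_cause_posterior(x_v, x_p, params: ObserverParams) -> PosteriorEstimate:
    """Posterior probability that vision and proprioception share one cause.

    With a uniform position prior over (-90, 90) the marginal likelihoods are

        L(C=1) = exp(-delta_s^2 / (2 sigma_s^2)) / alpha,
        alpha  = 180 * sqrt(2 pi sigma_s^2),
        L(C=2) = 1 / 180^2,

    where delta_s = |x_v - x_p| and sigma_s^2 = sigma_p^2 + sigma_v^2, and

        P_com = p L(C=1) / (p L(C=1) + (1 - p) L(C=2)).

    Returns a :class:`PosteriorEstimate` with all intermediates populated
    (``s_hat_p`` included, see :func:`position_estimate`).
    """
    x_v = np.asarray(x_v, dtype=float)
    x_p = np.asarray(x_p, dtype=float)
    sigma_s2 = params.sigma_p**2 + params.sigma_v**2
    alpha = PRIOR_RANGE_DEG * np.sqrt(2.0 * np.pi * sigma_s2)
    delta_s = np.abs(x_v - x_p)

    lik_c1 = np.exp(-(delta_s**2) / (2.0 * sigma_s2)) / alpha
    lik_c2 = 1.0 / PRIOR_RANGE_DEG**2
    num = params.p_prior * lik_c1
    denom = num + (1.0 - params.p_prior) * lik_c2
    # p_prior in {0, 1} short-circuits cleanly; denom > 0 otherwise.
    with np.errstate(invalid="ignore"):
        p_com = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    if params.p_prior == 1.0:
        p_com = np.ones_like(delta_s)

    x_ff = forced_fusion_estimate(x_v, x_p, params.sigma_v, params.sigma_p)
    s_hat_p = p_com * x_ff + (1.0 - p_com) * x_p
    if p_com.ndim == 0:
        p_com, x_ff, s_hat_p, delta_s = (
            float(p_com), float(x_ff), float(s_hat_p), float(delta_s),
        )
    return PosteriorEstimate(
        p_com=p_com, x_ff=x_ff, s_hat_p=s_hat_p,
        delta_s=delta_s, sigma_s2=float(sigma_s2), alpha=float(alpha),
    )


def position_estimate(x_v, x_p, params: ObserverParams) -> PosteriorEstimate:
    """Final hand-position estimate marginalising over the causal structure.

    s_hat_p = P_com * x_ff + (1 - P_com) * x_p; collapses to pure
    proprioception when P_com = 0 and to forced fusion when P_com = 1.
    """
    return common_cause_posterior(x_v, x_p, params)


def sample_sensory(
    stimulus: TrialStimulus,
    params: ObserverParams,
    rng: np.random.Generator | int,
    size: int | None = None,
) -> SensorySample:
    """Draw noisy sensory representations of a stimulus.

    ``rng`` may be a seed or a Generator; passing a seed makes the draw
    reproducible.  With ``size`` set, the fields of the returned sample are
    arrays of that length.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x_v = stimulus.s_v + gen.normal(0.0, params.sigma_v, size=size)
    x_p = stimulus.s_p + gen.normal(0.0, params.sigma_p, size=size)
    return SensorySample(x_p=x_p, x_v=x_v)
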