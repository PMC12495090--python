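"""Unisensory protocol simulators and their precision estimators.

Four protocols feed the cohort table:

* **PJ** (proprioceptive judgment, static): the hidden hand is passively
  placed at a target; a virtual hand starts +-30 deg away and a five-step
  converging staircase (each left/right answer moves the probe toward the
  perceived hand by half the previous step) brackets the perceived hand
  position.  The final estimate is the midpoint of the last displayed
  position and the position the algorithm would have shown next.  7
  targets x 4 repetitions x 5 steps = 140 presentations; sigma_PJ is the
  SD of the 28 final estimation errors.
* **OL** (open-loop reaching, dynamic): 50 reaches (5 targets x 10) without
  visual feedback; sigma_OL is the pooled SD of endpoint errors after
  removing per-target means.
* **MJ** (midline judgment): 9 reports of the position perceived as aligned
  with the body midline; sigma_MJ is their SD.
* **2PD** (two-point discrimination): adaptive staircase on probe
  separation -- halve after three successive correct answers, raise to the
  midpoint of the erroneous and the preceding correct separation after an
  error (150% step only when the starting separation itself is missed) --
  terminated after five inversions; the threshold is the mean of the last
  two correctly perceived separations, then verified with 5 double + 5
  single confirmation probes.

Observers are simple response models: a per-trial internal estimate drawn
from N(true + bias, sd) for PJ/OL/MJ, and a hard separation threshold with
an optional lapse rate for 2PD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bci import InvalidParameterError

__all__ = [
    "PointObserver",
    "UnisensoryPrecision",
    "StaircaseState",
    "TpdState",
    "PJ_TARGETS",
    "OL_TARGETS",
    "MJ_STARTS",
    "pj_staircase",
    "pj_protocol",
    "ol_protocol",
    "mj_protocol",
    "tpd_staircase",
]

PJ_TARGETS = (0.0, 10.0, -10.0, 20.0, -20.0, 40.0, -40.0)
PJ_REPETITIONS = 4
PJ_STEPS = 5
PJ_START_OFFSET = 30.0

OL_TARGETS = (0.0, 20.0, -20.0, 40.0, -40.0)
OL_REPETITIONS = 10

MJ_STARTS = (45.0, -45.0, 40.0, -40.0, 35.0, -35.0, 30.0, -30.0)
MJ_TRIALS = 9

TPD_START = {"hand": 2.0, "forearm": 4.0}  # cm
TPD_MIN_SEPARATION = 0.1  # cm floor
TPD_MAX_TRIALS = 60


@dataclass(frozen=True)
class PointObserver:
    """Gaussian response model: internal estimate ~ N(true + bias, sd)."""

    bias: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidParameterError(f"observer sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class UnisensoryPrecision:
    """Per-participant unisensory variabilities (degrees)."""

    sigma_pj: float
    sigma_ol: float
    sigma_mj: float


@dataclass(frozen=True)
class StaircaseState:
    """Trace of one PJ converging staircase.

    ``displayed_offsets`` and ``final_estimate`` are relative to the target
    (degrees); the absolute displayed position is target + offset.
    """

    target: float
    displayed_offsets: tuple[float, ...]
    responses: tuple[str, ...]
    final_estimate: float


@dataclass(frozen=True)
class TpdState:
    """Trace of one two-point discrimination staircase."""

    site: str
    separations: tuple[float, ...]
    outcomes: tuple[bool, ...]
    inversions: int
    threshold: float
    accepted: bool
    floored: bool = False


def pj_staircase(
    observer: PointObserver,
    target: float,
    start_sign: int,
    rng: np.random.Generator | int,
) -> StaircaseState:
    """One five-step converging staircase around ``target``.

    The virtual hand starts +-30 deg from the target; after each left/right
    judgment it moves toward the perceived hand by half the previous step
    (a bisection walk: "virtual right of my hand" sends the next probe
    left), so five presentations bracket any boundary inside the +-30 deg
    window to within the 1.875 deg terminal step.  The observer answers
    "right" when the displayed position is at or beyond a fresh noisy
    internal hand estimate (ties break to "right").  The final estimate is
    the midpoint of the last displayed position and the position the walk
    would have shown next.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sign = 1 if start_sign >= 0 else -1
    position = sign * PJ_START_OFFSET
    step = PJ_START_OFFSET / 2.0
    offsets: list[float] = []
    responses: list[str] = []
    for k in range(PJ_STEPS):
        offsets.append(position)
        internal = target + observer.bias + (
            gen.normal(0.0, observer.sd) if observer.sd > 0 else 0.0
        )
        answer = "right" if target + position >= internal else "left"
        responses.append(answer)
        direction = -1 if answer == "right" else 1
        position += direction * step
        step /= 2.0
    final = (offsets[-1] + position) / 2.0
    return StaircaseState(
        target=target,
        displayed_offsets=tuple(offsets),
        responses=tuple(responses),
        final_estimate=final,
    )


def pj_protocol(
    observer: PointObserver,
    seed: int,
    return_states: bool = False,
):
    """Run the full PJ protocol; returns sigma_PJ (degrees).

    28 staircases (7 targets x 4 repetitions, randomized order, random start
    side) of 5 presentations each: 140 presentations in total.  sigma_PJ is
    the SD of the 28 pooled estimate-minus-target values.
    """
    rng = np.random.default_rng(seed)
    schedule = [t for t in PJ_TARGETS for _ in range(PJ_REPETITIONS)]
    rng.shuffle(schedule)
    states = [
        pj_staircase(observer, t, 1 if rng.random() < 0.5 else -1, rng)
        for t in schedule
    ]
    errors = np.array([s.final_estimate for s in states])
    sigma_pj = float(np.std(errors, ddof=1))
    return (sigma_pj, states) if return_states else sigma_pj


def ol_protocol(observer: PointObserver, seed: int, return_errors: bool = False):
    """Open-loop reaching: 5 targets x 10 reaches; pooled residual SD.

    Endpoint = target + N(bias, sd); per-target mean errors are removed
    before pooling (SD uses n - n_targets degrees of freedom).
    """
    rng = np.random.default_rng(seed)
    targets = np.repeat(OL_TARGETS, OL_REPETITIONS)
    rng.shuffle(targets)
    errors = observer.bias + (
        rng.normal(0.0, observer.sd, size=targets.size) if observer.sd > 0
        else np.zeros(targets.size)
    )
    residual_ss = 0.0
    for t in OL_TARGETS:
        e = errors[targets == t]
        residual_ss += float(((e - e.mean()) ** 2).sum())
    dof = targets.size - len(OL_TARGETS)
    sigma_ol = float(np.sqrt(residual_ss / dof))
    return (sigma_ol, errors) if return_errors else sigma_ol


def mj_protocol(observer: PointObserver, seed: int, return_reports: bool = False):
    """Midline judgment: SD of 9 reported midline positions.

    The moving sphere's start is drawn from the printed +-30..45 deg set
    (randomized; 9 trials over 8 possible starts); only the report
    distribution N(bias, sd) is modelled.
    """
    rng = np.random.default_rng(seed)
    rng.choice(MJ_STARTS, size=MJ_TRIALS)  # start assignment (not modelled further)
    reports = rng.normal(observer.bias, observer.sd, size=MJ_TRIALS) if observer.sd > 0 \
        else np.full(MJ_TRIALS, observer.bias)
    sigma_mj = float(np.std(reports, ddof=1))
    return (sigma_mj, reports) if return_reports else sigma_mj


def _tpd_response(separation: float, threshold: float, lapse: float,
                  rng: np.random.Generator) -> bool:
    """True when the observer correctly reports two points on a double probe."""
    correct = separation >= threshold
    if lapse > 0 and rng.random() < lapse:
        correct = not correct
    return bool(correct)


def tpd_staircase(
    observer_threshold: float,
    site: str = "hand",
    seed: int = 0,
    lapse: float = 0.0,
    max_reruns: int = 3,
) -> TpdState:
    """Adaptive two-point discrimination staircase with confirmation phase.

    Starts at 2 cm (hand) or 4 cm (forearm).  Separation halves after three
    successive correct reports; after an error it rises to the midpoint of
    the erroneous separation and the most recent correctly perceived one
    (x1.5 when the starting separation itself is missed, or when no correct
    separation exists yet).  Five direction inversions terminate the run;
    the threshold is the mean of the last two correctly perceived
    separations, then checked with 5 double + 5 single probes (accepted with
    fewer than 3 errors, otherwise the staircase reruns).
    """
    if observer_threshold <= 0:
        raise InvalidParameterError("observer threshold must be > 0")
    if site not in TPD_START:
        raise InvalidParameterError(f"site must be one of {sorted(TPD_START)}")
    rng = np.random.default_rng(seed)

    for _ in range(max_reruns):
        start = TPD_START[site]
        sep = start
        separations: list[float] = []
        outcomes: list[bool] = []
        inversions = 0
        consecutive_correct = 0
        last_correct_sep: float | None = None
        last_direction = 0  # -1 descending, +1 ascending
        floored = False

        while inversions < 5 and len(separations) < TPD_MAX_TRIALS:
            separations.append(sep)
            correct = _tpd_response(sep, observer_threshold, lapse, rng)
            outcomes.append(correct)
            new_sep = sep
            if correct:
                last_correct_sep = sep
                consecutive_correct += 1
                if consecutive_correct == 3:
                    new_sep = sep * 0.5
                    consecutive_correct = 0
            else:
                consecutive_correct = 0
                if sep == start or last_correct_sep is None:
                    new_sep = sep * 1.5
                else:
                    new_sep = (sep + last_correct_sep) / 2.0
            if new_sep < TPD_MIN_SEPARATION:
                new_sep = TPD_MIN_SEPARATION
                floored = True
            if new_sep != sep:
                direction = 1 if new_sep > sep else -1
                if last_direction != 0 and direction != last_direction:
                    inversions += 1
                last_direction = direction
            sep = new_sep

        correct_seps = [s for s, ok in zip(separations, outcomes) if ok]
        if len(correct_seps) >= 2:
            threshold = float(np.mean(correct_seps[-2:]))
        elif correct_seps:
            threshold = float(correct_seps[-1])
        else:
            threshold = float(sep)

        # confirmation: 5 double + 5 single probes at the estimate
        probes = [True] * 5 + [False] * 5  # True = double
        rng.shuffle(probes)
        errors = 0
        for double in probes:
            if double:
                reported_two = _tpd_response(threshold, observer_threshold, lapse, rng)
                errors += not reported_two
            else:
                reported_two = lapse > 0 and rng.random() < lapse
                errors += reported_two
        if errors < 3:
            return TpdState(
                site=site,
                separations=tuple(separations),
                outcomes=tuple(outcomes),
                inversions=inversions,
                threshold=threshold,
                accepted=True,
                floored=floored,
            )
    return TpdState(
        site=site,
        separations=tuple(separations),
        outcomes=tuple(outcomes),
        inversions=inversions,
        threshold=threshold,
        accepted=False,
        floored=floored,
    )
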