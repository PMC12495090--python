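"""Metric body representation: landmark geometry, ED/EE indices, group tests.

Participants localise five landmarks of the hidden upper limb (index tip,
ring tip, internal wrist, external wrist, elbow) on the table plane; the
same landmarks are also recorded on the real limb.  Limb dimensions are
Euclidean distances between landmark pairs:

* arm length  = mean(internal wrist <-> elbow, external wrist <-> elbow)
* arm width   = internal wrist <-> external wrist
* hand width  = index tip <-> ring tip
* hand length = mean(ring tip <-> external wrist, index tip <-> internal wrist)

For each body part the Estimated Dimension ED = perceived / real quantifies
the direction of the distortion (< 1 underestimation, > 1 overestimation)
and the Estimated Error EE = |ED - 1| its direction-free magnitude.

Group comparisons run Shapiro-Wilk normality checks per group, pick an
unpaired t test when both groups look normal and a rank-sum test otherwise,
and Bonferroni-correct over the four body parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LANDMARK_NAMES",
    "BODY_PARTS",
    "LandmarkSet",
    "DimensionIndex",
    "GroupComparison",
    "limb_dimensions",
    "dimension_indices",
    "group_compare",
]

LANDMARK_NAMES = ("index_tip", "ring_tip", "internal_wrist", "external_wrist", "elbow")
BODY_PARTS = ("hand_length", "hand_width", "arm_length", "arm_width")
N_BODY_PARTS = len(BODY_PARTS)  # Bonferroni correction factor


class DegenerateGeometryWarning(UserWarning):
    """Two nominally distinct landmarks coincide (zero-length dimension)."""


@dataclass(frozen=True)
class LandmarkSet:
    """Five named 2-D landmark coordinates (cm, table-plane frame)."""

    index_tip: tuple[float, float]
    ring_tip: tuple[float, float]
    internal_wrist: tuple[float, float]
    external_wrist: tuple[float, float]
    elbow: tuple[float, float]
    flavor: str = "real"  # "real" | "perceived"

    def point(self, name: str) -> np.ndarray:
        return np.asarray(getattr(self, name), dtype=float)

    def as_frame(self, participant_id: str = "p00") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": participant_id,
                "flavor": self.flavor,
                "landmark": LANDMARK_NAMES,
                "x_cm": [self.point(n)[0] for n in LANDMARK_NAMES],
                "y_cm": [self.point(n)[1] for n in LANDMARK_NAMES],
            }
        )


@dataclass(frozen=True)
class DimensionIndex:
    """Perceived/real ratio (ED) and its absolute error (EE) for one part."""

    body_part: str
    perceived_cm: float
    real_cm: float
    ed: float
    ee: float


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def limb_dimensions(landmarks: LandmarkSet) -> dict[str, float]:
    """Compute the four limb dimensions (cm) from one landmark set."""
    p = {name: landmarks.point(name) for name in LANDMARK_NAMES}
    dims = {
        "hand_length": 0.5 * (
            _dist(p["ring_tip"], p["external_wrist"])
            + _dist(p["index_tip"], p["internal_wrist"])
        ),
        "hand_width": _dist(p["index_tip"], p["ring_tip"]),
        "arm_length": 0.5 * (
            _dist(p["internal_wrist"], p["elbow"])
            + _dist(p["external_wrist"], p["elbow"])
        ),
        "arm_width": _dist(p["internal_wrist"], p["external_wrist"]),
    }
    for part, value in dims.items():
        if value == 0.0:
            warnings.warn(
                f"{part} is zero: coincident landmarks in {landmarks.flavor} set",
                DegenerateGeometryWarning,
                stacklevel=2,
            )
    return dims


def dimension_indices(
    real: LandmarkSet, perceived: LandmarkSet
) -> list[DimensionIndex]:
    """ED and EE per body part from matched real/perceived landmark sets."""
    real_dims = limb_dimensions(real)
    perc_dims = limb_dimensions(perceived)
    out = []
    for part in BODY_PARTS:
        if real_dims[part] == 0.0:
            raise ZeroDivisionError(f"real {part} is zero; ED undefined")
        ed = perc_dims[part] / real_dims[part]
        out.append(
            DimensionIndex(
                body_part=part,
                perceived_cm=perc_dims[part],
                real_cm=real_dims[part],
                ed=ed,
                ee=abs(ed - 1.0),
            )
        )
    return out


@dataclass(frozen=True)
class GroupComparison:
    """One between-group test on an ED or EE index."""

    body_part: str
    index_kind: str
    test_used: str  # "t" | "ranksum"
    statistic: float
    p_value: float
    p_corrected: float
    normal_a: bool
    normal_b: bool
    degenerate_normality: bool = False


def group_compare(
    values_a,
    values_b,
    body_part: str = "arm_length",
    index_kind: str = "ed",
    alpha_normality: float = 0.05,
    correction_factor: int = N_BODY_PARTS,
) -> GroupComparison:
    """Compare one index between two groups with normality-gated test choice.

    Shapiro-Wilk per group; if both pass at ``alpha_normality`` an unpaired
    two-sample t test is used, otherwise a two-sided rank-sum
    (Mann-Whitney U) test.  The p value is Bonferroni-corrected by the
    number of body parts (default 4).  Groups with (near-)constant values
    make the normality check degenerate; the rank-sum branch is then taken
    and flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 observations per group")

    degenerate = bool(np.ptp(a) == 0 or np.ptp(b) == 0)
    if degenerate:
        normal_a = normal_b = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal_a = stats.shapiro(a).pvalue > alpha_normality
            normal_b = stats.shapiro(b).pvalue > alpha_normality

    if normal_a and normal_b:
        res = stats.ttest_ind(a, b)
        test_used = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test_used = "ranksum"

    p_corr = min(1.0, float(res.pvalue) * correction_factor)
    return GroupComparison(
        body_part=body_part,
        index_kind=index_kind,
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        p_corrected=p_corr,
        normal_a=normal_a,
        normal_b=normal_b,
        degenerate_normality=degenerate,
    )
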