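"""Synthetic two-group cohort emulating the study's statistical structure.

The generator stands in for an unreleased dataset.  Its defaults encode the
study conditions being emulated:

* two groups of 23 (healthy older, HO; healthy younger, HY);
* higher proprioceptive noise in HO (lognormal sigma_p, median 9 deg vs
  5 deg) and mildly higher visual noise (median 4 vs 3 deg), so that vision
  dominates proprioception in HO and the reverse holds in HY;
* identical common-cause priors in both groups (Beta(4, 2));
* a unisensory proprioceptive-judgment observer whose noise tracks the
  multisensory sigma_p (multiplicative lognormal link), so measured
  sigma_PJ correlates with the generative sigma_p;
* arm-length underestimation in HO: the signed arm-length misperception is
  linear in cognitive flexibility (pooled-z TMT B-A), midline-judgment
  variability and open-loop variability, plus Gaussian noise; the perceived
  landmark geometry is scaled to match, so landmark-derived indices and the
  regression response agree exactly.

Every participant gets a full VPD session (with block-3 ratings), the four
unisensory protocols, real/perceived landmark sets, and cognitive scores.
The sensorimotor/cognitive battery feeding the arm-error regression is
administered to the older group only, as in the emulated design.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bci import ObserverParams
from .landmarks import LandmarkSet, dimension_indices
from .selection import pooled_zscore
from .unisensory import (
    PointObserver,
    mj_protocol,
    ol_protocol,
    pj_protocol,
    tpd_staircase,
)
from .vpd import simulate_participant, trials_to_frame

__all__ = ["CohortConfig", "Cohort", "generate_cohort", "export_cohort"]


class ConfigError(ValueError):
    """Cohort configuration violates its constraints."""


@dataclass(frozen=True)
class GroupParams:
    """Lognormal medians / log-SDs of one group's observer parameters."""

    sigma_p_median: float
    sigma_v_median: float
    log_sd: float = 0.3
    p_prior_beta: tuple[float, float] = (4.0, 2.0)
    sigma_m: float = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_per_group: int = 23
    # medians ordered as the emulated findings require: within HO vision
    # beats proprioception (sigma_p > sigma_v), within HY the reverse, and
    # HO is noisier than HY in both modalities
    older: GroupParams = field(
        default_factory=lambda: GroupParams(sigma_p_median=9.0, sigma_v_median=4.5)
    )
    younger: GroupParams = field(
        default_factory=lambda: GroupParams(sigma_p_median=2.5, sigma_v_median=3.5)
    )
    # sigma_PJ linkage: pj observer sd = slope * sigma_p + intercept, times
    # exp(N(0, log_noise)); log_noise 0.35 yields a moderate (~0.55) coupling
    pj_link_slope: float = 1.0
    pj_link_intercept: float = 0.0
    pj_link_log_noise: float = 0.35
    # unisensory observer spreads (lognormal medians / log-SDs, degrees)
    ol_sd_median: float = 3.3
    ol_sd_log_sd: float = 0.65
    mj_sd_median: float = 3.0
    mj_sd_log_sd: float = 0.33
    # tactile thresholds (cm)
    tpd_hand_median: float = 1.0
    tpd_forearm_median: float = 2.5
    tpd_log_sd: float = 0.3
    # arm-length misperception model (older group): signed error eta =
    # intercept + c_tmt*tmt_z + c_mj*(sigma_mj - mj_center)
    #           + c_ol*(sigma_ol - ol_center) + N(0, noise_sd);
    # ED_arm = 1 - eta, EE_arm = |eta|
    ee_intercept_older: float = 0.15
    ee_coef_tmt: float = 0.10
    ee_coef_mj: float = 0.09
    ee_coef_ol: float = 0.02
    ee_mj_center: float = 3.0
    ee_ol_center: float = 4.0
    ee_noise_sd: float = 0.10
    # younger group: ED_arm = 1 - N(mean, sd), no battery linkage
    younger_arm_error_mean: float = 0.03
    younger_arm_error_sd: float = 0.05
    rating_noise_sd: float = 1.0
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError("n_per_group must be >= 3")
        for g in (self.older, self.younger):
            if min(g.sigma_p_median, g.sigma_v_median) <= 0 or g.log_sd <= 0:
                raise ConfigError("group sigma medians and log-SD must be > 0")
            if g.sigma_m < 0:
                raise ConfigError("sigma_m must be >= 0")
        if self.pj_link_log_noise < 0:
            raise ConfigError("pj_link_log_noise must be >= 0")
        if self.pj_link_slope <= 0:
            raise ConfigError(
                "pj_link_slope must be > 0 (a non-positive slope makes the "
                "requested sigma_PJ/sigma_p coupling infeasible)"
            )
        for name in ("ol_sd_median", "mj_sd_median", "ee_noise_sd",
                     "tpd_hand_median", "tpd_forearm_median"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass
class Cohort:
    """In-memory synthetic dataset: per-participant table + task files."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    landmarks: pd.DataFrame
    indices: pd.DataFrame
    predictors: pd.DataFrame
    config: CohortConfig
    seed: int


def _real_landmarks(rng: np.random.Generator) -> dict[str, float]:
    """Draw real limb dimensions (cm) from adult anthropometric ranges."""
    return {
        "arm_length": rng.normal(25.0, 1.5),
        "arm_width": rng.normal(6.2, 0.4),
        "hand_length": rng.normal(17.5, 1.0),
        "hand_width": rng.normal(3.2, 0.3),
    }


def _landmarks_from_dims(dims: dict[str, float], flavor: str) -> LandmarkSet:
    """Place the five landmarks on the table plane realising given dims."""
    aw = dims["arm_width"]
    al = dims["arm_length"]
    hw = dims["hand_width"]
    hl = dims["hand_length"]
    wrist_y = float(np.sqrt(max(al**2 - (aw / 2.0) ** 2, 1e-6)))
    dx = abs(hw - aw) / 2.0
    tip_dy = float(np.sqrt(max(hl**2 - dx**2, 1e-6)))
    return LandmarkSet(
        index_tip=(-hw / 2.0, wrist_y + tip_dy),
        ring_tip=(hw / 2.0, wrist_y + tip_dy),
        internal_wrist=(-aw / 2.0, wrist_y),
        external_wrist=(aw / 2.0, wrist_y),
        elbow=(0.0, 0.0),
        flavor=flavor,
    )


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate the full synthetic cohort (deterministic per seed)."""
    config = config or CohortConfig()
    config.validate()
    seed = config.master_seed if seed is None else seed
    rng = np.random.default_rng(seed)

    part_rows: list[dict] = []
    trial_frames: list[pd.DataFrame] = []
    landmark_frames: list[pd.DataFrame] = []
    index_rows: list[dict] = []

    specs = [("HO", config.older), ("HY", config.younger)]
    pid = 0
    for group, gp in specs:
        for _ in range(config.n_per_group):
            pid += 1
            participant_id = f"{group.lower()}{pid:02d}"
            child = int(rng.integers(0, 2**31 - 1))
            prng = np.random.default_rng(child)

            sigma_p = gp.sigma_p_median * np.exp(prng.normal(0.0, gp.log_sd))
            sigma_v = gp.sigma_v_median * np.exp(prng.normal(0.0, gp.log_sd))
            p_prior = prng.beta(*gp.p_prior_beta)
            params = ObserverParams(
                sigma_v=float(sigma_v), sigma_p=float(sigma_p),
                p_prior=float(p_prior), sigma_m=gp.sigma_m,
            )

            vpd_seed = int(prng.integers(0, 2**31 - 1))
            trials = simulate_participant(
                params, seed=vpd_seed, rating_noise_sd=config.rating_noise_sd
            )
            trial_frames.append(trials_to_frame(trials, participant_id, group))

            pj_sd = (config.pj_link_slope * sigma_p + config.pj_link_intercept) * np.exp(
                prng.normal(0.0, config.pj_link_log_noise)
            )
            ol_sd = config.ol_sd_median * np.exp(prng.normal(0.0, config.ol_sd_log_sd))
            mj_sd = config.mj_sd_median * np.exp(prng.normal(0.0, config.mj_sd_log_sd))
            s_pj = pj_protocol(PointObserver(sd=float(pj_sd)), int(prng.integers(2**31)))
            s_ol = ol_protocol(PointObserver(sd=float(ol_sd)), int(prng.integers(2**31)))
            s_mj = mj_protocol(PointObserver(sd=float(mj_sd)), int(prng.integers(2**31)))

            tpd_hand_true = config.tpd_hand_median * np.exp(
                prng.normal(0.0, config.tpd_log_sd)
            )
            tpd_forearm_true = config.tpd_forearm_median * np.exp(
                prng.normal(0.0, config.tpd_log_sd)
            )
            tpd_hand = tpd_staircase(
                float(tpd_hand_true), "hand", int(prng.integers(2**31)), lapse=0.05
            ).threshold
            tpd_forearm = tpd_staircase(
                float(tpd_forearm_true), "forearm", int(prng.integers(2**31)), lapse=0.05
            ).threshold

            digit_fwd = int(prng.choice([2, 3, 4], p=[0.25, 0.45, 0.30]))
            # backward span: deliberately near-constant (the screening case)
            digit_bwd = 4
            population = "IT" if prng.random() < 0.2 else "FR"
            tmt_raw = float(45.0 * np.exp(prng.normal(0.0, 0.4)))

            row = {
                "participant_id": participant_id,
                "group": group,
                "sigma_v_true": params.sigma_v,
                "sigma_p_true": params.sigma_p,
                "p_prior_true": params.p_prior,
                "sigma_m_true": params.sigma_m,
                "sigma_pj": s_pj,
                "sigma_ol": s_ol,
                "sigma_mj": s_mj,
                "tpd_hand_cm": tpd_hand,
                "tpd_forearm_cm": tpd_forearm,
                "digit_span_forward": digit_fwd,
                "digit_span_backward": digit_bwd,
                "tmt_population": population,
                "tmt_raw_s": tmt_raw,
                "vpd_seed": vpd_seed,
                "landmark_seed": int(prng.integers(2**31)),
                "ee_noise": float(prng.normal(0.0, config.ee_noise_sd)),
                "hy_arm_error": float(
                    prng.normal(config.younger_arm_error_mean,
                                config.younger_arm_error_sd)
                ),
            }
            part_rows.append(row)

    table = pd.DataFrame(part_rows)
    # one participant per group breaks the backward-span constancy, as in the
    # emulated screening scenario
    for group in ("HO", "HY"):
        idx = table.index[table["group"] == group][0]
        table.loc[idx, "digit_span_backward"] = 3

    table["tmt_b_minus_a"] = pooled_zscore(
        table["tmt_raw_s"], table["tmt_population"]
    )

    # signed arm-length misperception eta; ED_arm = 1 - eta
    eta = np.where(
        table["group"] == "HO",
        config.ee_intercept_older
        + config.ee_coef_tmt * table["tmt_b_minus_a"]
        + config.ee_coef_mj * (table["sigma_mj"] - config.ee_mj_center)
        + config.ee_coef_ol * (table["sigma_ol"] - config.ee_ol_center)
        + table["ee_noise"],
        table["hy_arm_error"],
    )
    table["ed_arm_length"] = 1.0 - eta
    table["ee_arm_length"] = np.abs(eta)

    # landmark geometry consistent with the drawn dimension ratios
    for _, row in table.iterrows():
        lrng = np.random.default_rng(int(row["landmark_seed"]))
        real_dims = _real_landmarks(lrng)
        ratios = {
            "arm_length": float(row["ed_arm_length"]),
            "arm_width": float(lrng.normal(1.0, 0.04)),
            "hand_length": float(lrng.normal(0.98, 0.05)),
            "hand_width": float(lrng.normal(1.0, 0.06)),
        }
        perc_dims = {k: real_dims[k] * ratios[k] for k in real_dims}
        real_lm = _landmarks_from_dims(real_dims, "real")
        perc_lm = _landmarks_from_dims(perc_dims, "perceived")
        landmark_frames.append(real_lm.as_frame(row["participant_id"]))
        landmark_frames.append(perc_lm.as_frame(row["participant_id"]))
        for di in dimension_indices(real_lm, perc_lm):
            index_rows.append(
                {
                    "participant_id": row["participant_id"],
                    "group": row["group"],
                    "body_part": di.body_part,
                    "perceived_cm": di.perceived_cm,
                    "real_cm": di.real_cm,
                    "ed": di.ed,
                    "ee": di.ee,
                }
            )

    table = table.drop(columns=["ee_noise", "hy_arm_error"])
    older = table[table["group"] == "HO"]
    predictors = older[
        [
            "participant_id",
            "tpd_forearm_cm",
            "tpd_hand_cm",
            "sigma_pj",
            "sigma_ol",
            "sigma_mj",
            "digit_span_forward",
            "digit_span_backward",
            "tmt_b_minus_a",
            "ee_arm_length",
        ]
    ].rename(
        columns={
            "tpd_forearm_cm": "arm_tactile_2pd",
            "tpd_hand_cm": "hand_tactile_2pd",
        }
    ).reset_index(drop=True)

    return Cohort(
        participants=table,
        trials=pd.concat(trial_frames, ignore_index=True),
        landmarks=pd.concat(landmark_frames, ignore_index=True),
        indices=pd.DataFrame(index_rows),
        predictors=predictors,
        config=config,
        seed=seed,
    )


def _config_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    return d


def export_cohort(cohort: Cohort, directory: str | Path) -> dict:
    """Write the cohort CSVs plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "participants.csv": cohort.participants,
        "trials.csv": cohort.trials,
        "landmarks.csv": cohort.landmarks,
        "indices.csv": cohort.indices,
        "unisensory.csv": cohort.participants[
            ["participant_id", "sigma_pj", "sigma_ol", "sigma_mj",
             "tpd_hand_cm", "tpd_forearm_cm"]
        ],
        "predictors.csv": cohort.predictors,
    }
    digest = hashlib.sha256()
    manifest_files = []
    for name, frame in files.items():
        path = directory / name
        frame.to_csv(path, index=False, float_format="%.10g")
        digest.update(path.read_bytes())
        manifest_files.append(name)
    manifest = {
        "seed": cohort.seed,
        "config": _config_dict(cohort.config),
        "files": manifest_files,
        "sha256": digest.hexdigest(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
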