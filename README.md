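# vpbci

Bayesian causal-inference modelling of visuo-proprioceptive body
perception: who does the seen hand belong to, and how large does the arm
feel?

When people reach for a target while a virtual hand is angularly displaced
from their hidden real hand, the brain must decide whether the seen hand is
its own. `vpbci` implements the full computational pipeline used to study
this decision and its relationship to ageing:

* the **causal-inference observer**: noisy visual and proprioceptive
  samples `x_v, x_p`, a common-cause posterior
  `P_com ∝ p_prior · exp(−δ²/2σ_s²)/α` against a uniform-position
  alternative `1/180²`, and the hand-position estimate
  `ŝ_p = P_com·x_ff + (1 − P_com)·x_p`, where `x_ff` is the inverse-variance
  weighted fusion of the two cues;
* the **disparity reaching task** (three blocks, 7×7 + 7×7 + 5×5
  target/disparity cells, 1–10 ownership ratings in the last block) and its
  error normalisation;
* **simulation-based maximum likelihood** fitting of (σ_v, σ_p, P_prior)
  per participant — kernel densities over simulated reaches, common random
  numbers, multi-start Nelder–Mead — packaged as a scikit-learn estimator
  (`CausalInferenceEstimator`);
* the **unisensory protocols** that validate the fits: a five-step
  converging staircase for static proprioception (σ_PJ), open-loop reaching
  (σ_OL), midline judgment (σ_MJ), and an adaptive two-point discrimination
  staircase;
* **metric body representation**: perceived limb dimensions from five
  landmarks, the Estimated Dimension (ED = perceived/real) and Estimated
  Error (EE = |ED − 1|) indices, and normality-gated group tests with
  Bonferroni correction;
* **predictor selection** for the arm-length error: zero-variance
  screening, leave-one-out cross-validated Lasso, and an OLS report
  (`ArmErrorPredictorSelector`);
* a **synthetic cohort generator** that emulates a two-group ageing study
  (older group: noisier proprioception, vision-dominant weighting,
  arm-length underestimation linked linearly to cognitive flexibility and
  proprioceptive variability; priors equal across groups) so the entire
  pipeline runs end-to-end without access to any real dataset.

The intended audience is researchers in computational psychophysics and
multisensory integration who want a tested, reproducible reference
implementation of this analysis chain, or a harness for planning similar
studies.

## Worked example

```python
from vpbci import (ObserverParams, common_cause_posterior, fusion_weights,
                   simulate_participant)
from vpbci.fitting import fit_participant

w = fusion_weights(3.0, 8.0)
print(f"w_v = {w.w_v:.3f}, w_p = {w.w_p:.3f}")

observer = ObserverParams(sigma_v=3.0, sigma_p=8.0, p_prior=0.7)
for d in (0, 13.3, 26.6, 40):
    post = common_cause_posterior(d, 0.0, observer)
    print(f"disparity {d:5.1f} deg -> P_com = {post.p_com:.3f}, "
          f"s_hat_p = {post.s_hat_p:+6.2f} deg")

trials = simulate_participant(observer, seed=42)   # full 123-trial session
fit = fit_participant(trials, n_sim=5000, n_starts=4, seed=42)
print(f"fitted: sigma_p={fit.sigma_p_hat:.2f} p_prior={fit.p_prior_hat:.2f}")
```

prints

```
w_v = 0.877, w_p = 0.123
disparity   0.0 deg -> P_com = 0.951, s_hat_p =  +0.00 deg
disparity  13.3 deg -> P_com = 0.854, s_hat_p =  +9.96 deg
disparity  26.6 deg -> P_com = 0.134, s_hat_p =  +3.11 deg
disparity  40.0 deg -> P_com = 0.000, s_hat_p =  +0.01 deg
fitted: sigma_p=7.08 p_prior=0.68
```

Read the posterior sweep as the model's ownership window: with noisy
proprioception (σ_p = 8°) a 13.3° conflict is still almost certainly one's
own hand (P_com = 0.85) and the estimate is pulled 10° toward the virtual
hand, while a 40° conflict is confidently segregated and the estimate
returns to the proprioceptive sample. Refitting the simulated session
recovers the generating proprioceptive noise (7.1° vs 8°) and prior (0.68
vs 0.7); the visual noise of a single participant is only weakly
identified (see `docs/methods.md`).

There is also a CLI for the pipeline stages:

```bash
vpbci simulate-cohort --out cohort/ --seed 7
vpbci fit --trials cohort/trials.csv --out fits.csv --n-sim 5000 --seed 7
vpbci select --predictors cohort/predictors.csv --seed 7
vpbci screening-rate 31 23     # -> 25.81
```

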