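# Methods

## The observer model

A participant reaching for a target while seeing a displaced virtual hand
must decide, implicitly, whether the seen hand is their own. We model the
decision as Bayesian causal inference over two hypotheses: one cause
(C = 1, the virtual hand is the participant's hand; prior probability
`p_prior`) or two causes (C = 2). On each trial the observer receives noisy
internal representations of the virtual and real hand angles,

    x_v = s_v + N(0, sigma_v),    x_p = s_p + N(0, sigma_p),

in degrees from the shoulder. With a uniform position prior on the open
interval (−90°, 90°), the marginal likelihoods of the sample under the two
hypotheses are

    L(C=1) = exp(−delta_s² / (2 sigma_s²)) / alpha,
    alpha  = 180 · sqrt(2π sigma_s²),     sigma_s² = sigma_p² + sigma_v²,
    L(C=2) = 1 / 180²,

with `delta_s = |x_v − x_p|`. The common-cause posterior is

    P_com = p_prior L(C=1) / (p_prior L(C=1) + (1 − p_prior) L(C=2)),

and the reported hand-position estimate marginalises over the causal
structure,

    s_hat_p = P_com · x_ff + (1 − P_com) · x_p,

where `x_ff` is the reliability-weighted forced-fusion average
(weights ∝ 1/sigma²). Angles are never wrapped; the constant 180 enters the
normalisers exactly as written. The Gaussian tail mass outside ±90° is
neglected, which is accurate to well below 1e−3 for the noise levels used
here (the test suite checks the closed form against brute-force integration
of the generative model on a 125-point parameter grid).

### Assumptions

* Unimodal noises are independent, Gaussian, and stationary within a
  session; cue reliabilities do not depend on eccentricity.
* The position prior is flat over the reachable workspace.
* The causal decision is made independently on every trial (no sequential
  effects).

## The reaching transposition

In the disparity task the pre-movement hand is at the start location
(0°) and the virtual hand is rotated by the trial's disparity `d`. The
observer estimates its hand at `s_hat_p` and plans the reach from there, so
the endpoint is displaced opposite the estimation bias:

    endpoint = target − (s_hat_p − x_p) + N(0, sigma_m).

Two limits anchor the sign convention: with `p_prior = 0` the expected
error is zero (pure proprioceptive guidance), and with `p_prior = 1`,
`sigma_v → 0`, the expected error equals −disparity (full visual
following). The mean attraction is *not* monotone in disparity: it grows
while the conflict is credibly one's own hand and wanes once the conflict
is large enough to be segregated — this rise-then-wane signature is what
distinguishes causal inference from forced fusion, and the property tests
assert it in that form.

`sigma_m` is an optional additive motor-execution noise on the endpoint
(default 0 in the analytic layer, 2° in the cohort generator). It never
enters the perceptual inference; it exists so that endpoint variability is
not forced entirely into the sensory noises.

Observed errors are normalised per participant by subtracting the mean
error over all zero-disparity trials, removing session-level calibration
bias.

## Simulation-based fitting

The error likelihood has no closed form, so (sigma_v, sigma_p, p_prior)
are estimated by simulated maximum likelihood:

* per disparity level present in the data, simulate reaches under the
  candidate parameters (default 50,000 per level; 5,000 in the desk-scale
  test profile, 3,000 in the cohort-mirror profile) and normalise them
  within the simulation;
* form a Gaussian kernel density per level (Silverman bandwidth with a
  0.1° floor, density floor 1e−9) and score the observed normalised errors
  against it, sharing densities across trials of a level.

Two refinements matter in practice:

* **Common random numbers.** The standard-normal draws behind the
  simulations are fixed once per fit, making the objective deterministic
  and nearly smooth in the parameters.
* **Baseline-shift nuisance.** The zero-disparity baseline subtracted from
  the data is estimated from ~19 trials, so its sampling error shifts every
  level of a participant by one common amount. At extreme disparities the
  model predicts a near-point-mass, and an unmodelled common shift is
  misread there as gross misfit, biasing `p_prior` upward (wider predicted
  densities relieve the penalty). The shift is therefore fitted jointly as
  a fourth parameter `c` with its known N(0, sd0²/n0) distribution. In
  simulation this restored the true parameters as the likelihood optimum
  (by tens of nats in the worst diagnosed cases).

Optimisation is derivative-free: Nelder–Mead under box bounds
(sigma_v ∈ [0.25°, 30°], sigma_p ∈ [0.25°, 40°], p_prior ∈ [0, 1],
c ∈ [−5°, 5°]; the sigma bounds span the printed disparity range with
margin), started from a seeded Latin hypercube (8 starts by default, 600
evaluations per start), followed by one fresh-simplex restart from the
incumbent optimum — simplexes otherwise occasionally collapse along the
sigma_v/p_prior ridge.

**What recovery can and cannot do at this design size.** With ~123 trials
per participant, sigma_p recovers well (true-vs-fitted correlation ≈ 0.93
over 20 simulated observers) and `p_prior` adequately (≈ 0.8); `sigma_v` is
only weakly identified because its behavioural footprint overlaps with
`p_prior` (both modulate the attraction profile). Fitting with an assumed
`sigma_m` of 0 when the data contain 2° of motor noise is *not* benign: the
unmodelled endpoint width drives fits to the sigma_v upper bound with
p_prior ≈ 1, destroying sigma_p recovery. The cohort analysis therefore
fits with the generator's known sigma_m = 2°; for real data sigma_m would
have to be measured (e.g., from open-loop reaches) or estimated.

## Unisensory protocols

* **Proprioceptive judgment (PJ).** Five-step converging staircase: the
  probe starts ±30° from the target and moves toward the perceived hand by
  half the previous step after each left/right judgment; the final estimate
  is the midpoint of the last shown and next-would-be positions. 7 targets
  × 4 repetitions × 5 steps = 140 presentations; sigma_PJ is the SD of the
  28 final-estimate errors. A single walk brackets boundaries on its start
  side to within the 1.875° terminal step; the randomized start signs of
  the 28 staircases cover both sides. The deterministic floor of sigma_PJ
  is the ±1.40625° terminal midpoint; above it sigma_PJ tracks observer
  noise at roughly 0.65 × sd.
* **Open-loop reaching (OL).** 50 reaches (5 targets × 10) without vision;
  sigma_OL is the pooled SD of endpoint errors after removing per-target
  means (n − 5 degrees of freedom).
* **Midline judgment (MJ).** SD of 9 reported midline positions; only the
  report distribution is modelled, not the moving sphere's kinematics.
* **Two-point discrimination (2PD).** Separation starts at 2 cm (hand) /
  4 cm (forearm); halves after three successive correct "two-point"
  reports; after an error rises to the midpoint of the erroneous and the
  most recent correct separation (×1.5 when the start itself is missed or
  when no correct separation exists yet); five direction inversions end the
  run, and the threshold is the mean of the last two correctly perceived
  separations, confirmed with 5 double + 5 single probes (accepted at < 3
  errors, else rerun; 3 reruns maximum). Degenerate guards: a 1 mm
  separation floor (flagged) and a 60-trial cap — a deterministic observer
  otherwise approaches its threshold through midpoint updates without ever
  triggering an inversion.

## Body-metric indices

Limb dimensions are Euclidean distances between 2-D landmarks (table
plane): arm length = mean of the two wrist→elbow distances, arm width =
wrist-to-wrist, hand width = index-to-ring fingertip, hand length = mean of
(ring tip↔external wrist, index tip↔internal wrist) — the last pairing is a
documented choice; it is the only pairing that uses all four named points
consistently. ED = perceived/real, EE = |ED − 1|. Group comparisons use
Shapiro–Wilk per group, an unpaired t test when both groups pass and a
two-sided rank-sum test otherwise, Bonferroni-corrected by the four body
parts.

## Predictor selection

Near-constant columns (all but at most one participant sharing a value)
are screened out first. Selection then runs an L1 path over 100 log-spaced
penalties from the smallest all-zero penalty down three decades, with
leave-one-out cross-validation and per-training-fold standardisation
(matching the reference semantics of cv.glmnet); the MSE-minimising
penalty is used (not the 1-SE rule). The retained predictors get an
unpenalised OLS report with per-term t and p, R², adjusted R², the model F
test and Cohen's f² = R²/(1 − R²). At n = 23 the minimising-penalty rule
overselects by design: across seeds the true predictors are retained far
more often than nuisance ones (≈ 90/90/73% vs ≤ 48% at the default effect
pattern), but the single most frequent retained set is usually a superset
of the true set — an inherent property of the rule, reproduced exactly by
cv.glmnet on the same data.

## The synthetic cohort

The generator emulates the statistical structure of a two-group ageing
study; its defaults are the study conditions, chosen once:

* n = 23 per group. Observer parameters are lognormal with medians
  (sigma_p, sigma_v) = (9°, 4.5°) in the older group and (2.5°, 3.5°) in
  the younger group (log-SD 0.3), so vision dominates proprioception in
  the older group and the reverse holds in the younger; the common-cause
  prior is Beta(4, 2) in *both* groups (the emulated finding is that
  priors do not differ); motor noise 2°.
* The PJ observer's noise is the participant's sigma_p times a lognormal
  factor (log-SD 0.35), producing a moderate measured coupling between
  sigma_PJ and sigma_p (Spearman ≈ 0.5–0.6 pooled) without making the two
  identical.
* OL and MJ observer noises are lognormal and identical across groups
  (medians 3.3° and 3.0°; log-SDs 0.65 and 0.33) — the spreads, together
  with the effect sizes below, reproduce the printed t-value pattern of
  the arm-error regression.
* The signed arm-length misperception of an older participant is linear in
  the battery: eta = 0.15 + 0.10·tmt_z + 0.09·(sigma_MJ − 3) +
  0.02·(sigma_OL − 4) + N(0, 0.10); ED_arm = 1 − eta and EE_arm = |eta|.
  The printed coefficients, t values and R² jointly pin the scale of eta,
  which forces a mean older-group EE around 0.15 (ED ≈ 0.85) once realistic
  predictor spreads are fixed; eta occasionally crosses zero, and the
  definition-consistent fold |eta| is kept rather than truncating.
  Younger participants get ED_arm = 1 − N(0.03, 0.05) with no battery
  linkage (the battery is administered to the older group only, as in the
  emulated design). Perceived landmark coordinates are constructed to
  realise each participant's dimension ratios exactly, so landmark-derived
  indices and the regression response agree to machine precision.
* The backward digit span is generated near-constant (all but one
  participant per group at the ceiling score) to exercise the screening
  rule end-to-end.
* Ownership ratings are a synthetic device only: rating =
  clip(round_half_up(1 + 9·P_com + N(0, 1)), 1, 10). They are never used in
  fitting, only in the qualitative rating/disparity and implicit–explicit
  coupling mirrors.

**What the generator does not emulate:** sequential/learning effects,
hand-calibration drift, target-dependent biomechanical biases, non-Gaussian
lapses, demographic covariates, or any radial (non-angular) component of
reaching. Passing tests therefore show that the pipeline recovers the
structure this generator puts in — not that the model is correct for real
reaching data.

## Problem sizes in the shipped checks

The test and acceptance profiles use deliberately reduced simulation sizes,
chosen as the smallest that leave comfortable statistical margins: 5,000
simulated reaches per disparity and 4 starts for the 20-observer recovery
study; 3,000 and 3 starts for the 46 cohort fits; 100 seeds for the
selection-consistency study. The library defaults remain 50,000 and 8.

## Known limitations

* sigma_v is weakly identified at the single-participant level; only its
  group-level tendencies are meaningful.
* The likelihood treats trials as independent given the session-level
  baseline shift; slow drifts within a session are not modelled.
* The KDE bandwidth floor (0.1°) slightly oversmooths genuinely sharp
  error distributions (p_prior ≈ 0, sigma_m = 0 observers).
* The 2PD staircase models a hard threshold with an optional lapse rate,
  not a graded psychometric function.
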