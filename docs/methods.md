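# Methods

`calens` implements a calibrate-then-ensemble strategy for binary clinical
risk prediction: base classifiers produce raw probability scores, post-hoc
calibrators map those scores to well-calibrated event probabilities, and
combiners aggregate the calibrated outputs. Everything is evaluated under a
repeated stratified hold-out protocol with nested 3-fold cross-validation.
This note records the models, the defaults and why they are what they are,
what the synthetic cohort generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## The synthetic cohort

The motivating application is 2-year mortality prediction in diffuse large
B-cell lymphoma (DLBCL). The reference cohort of 406 patients (116 deaths
within two years of treatment) is not publicly available, so the package
ships a generator that reproduces its published statistical structure:

* **Covariates.** Eight categorical covariates (age dichotomized at 60,
  gender, Ann Arbor stage I–II vs III–IV, the 4-level International
  Prognostic Index, Karnofsky Performance Status dichotomized at 80, LDH,
  β2-microglobulin, rituximab use), drawn independently with the published
  marginal level frequencies (e.g. KPS ≥ 80: 335/406; IPI
  195/79/83/49 over 406).
* **Outcome.** Bernoulli with log-odds
  `intercept + Σ_j β_j(level_j)`, using the published logistic-model
  coefficients (age > 60: 0.488; female: −0.509; stage III–IV: 0.961; IPI
  low-/high-intermediate/high: 0.946/0.909/0.807; KPS < 80: 1.350; LDH
  high: 0.597; β2-MG high: 0.562; rituximab: −0.931; reference levels carry
  0).
* **Intercept.** The covariate support is finite (512 cells), so the
  marginal event rate is computable exactly as a weighted average of
  `sigmoid(c + η_cell)`. The intercept is root-found (Brent, tolerance
  1e-12) so the exact marginal rate equals 116/406; for the default
  configuration `c = −2.25868`. Anchoring by enumeration rather than
  simulation removes Monte-Carlo error from the generator definition.

What the generator does **not** emulate: covariate correlation (only
marginal counts are published; independence keeps coefficient recovery
well-posed), survival times, and missingness. Tests passing on this
generator therefore demonstrate correctness of the machinery and the
qualitative calibration phenomena, not clinical performance on real DLBCL
data.

Because every synthetic patient's generating probability is known, an
*oracle learner* (returns the true probability) plugs into the base-learner
interface. Two extensions make it a controllable stand-in for miscalibrated
classifiers:

* **Distortion** `s = sigmoid(a·logit(p) + b)`, `a > 0`: `a > 1` pushes
  scores toward 0/1 (naive-Bayes-like overconfidence), `a < 1` pulls them
  toward the middle (random-forest-like compression), `a ≠ 1, b ≠ 0` gives
  a sigmoid-shaped shift (SVM-like). The distortion is strictly monotone,
  hence exactly invertible by a perfect calibrator (inverse spec
  `(1/a, −b/a)`).
* **Estimation noise** (`noise_sd`): a fixed, seed-determined Gaussian
  perturbation of each covariate cell's log-odds, emulating a model that
  misestimates each risk stratum the way a classifier trained on finite
  data does. Default 0.

## Base learners

Five families behind one fit/predict contract, all returning scores in
[0, 1] and all deterministic given `(seed, cohort)`:

| family | implementation | score |
|---|---|---|
| NB | categorical naive Bayes, add-one smoothing | posterior of the event class |
| LOGIT | unpenalized logistic regression (dummy-coded) | sigmoid of the linear predictor |
| RF | random forest | fraction of trees voting for the event |
| SVM | support vector machine (linear or RBF) | decision values min–max mapped to [0, 1] over the training set, clamped on new data |
| FNN | one hidden layer of 500 ReLU units, sigmoid output, adaptive-moment optimizer, early stopping on a 10% inner split (patience 20, ≤ 500 epochs) | network output |

The SVM's decision-value magnitude is only a confidence ordering, and the
min–max map is an arbitrary affine rescaling — that is deliberate: these
"initial probability estimates" are exactly what the calibration stage is
for. The FNN's optimizer/activation details and the SVM score map are this
package's own choices; nothing in the protocol depends on them beyond the
fit/predict contract.

Hyperparameter grids (resolved by stratified 3-fold CV, maximizing mean
validation AUC, ties to the first grid point): RF — variables per split
{2, 3} × trees {500, 600, …, 1500}; SVM — {linear, RBF} × C, γ ∈ {10^i,
i = −4…4}. NB and LOGIT have no grid but run the same CV loop so every
family passes through an identical pipeline. Tests and the worked examples
prune these grids to keep runtimes in seconds; the defaults are the full
protocol.

## Calibrators

All three calibrators are trained on **out-of-fold (OOF)** scores: each
training patient is scored by a model fitted on the other two folds, so the
calibration training set reflects genuine generalization error rather than
resubstitution optimism.

**Shape-restricted polynomial regression (RPR)** — the package's core.
`f(s) = Σ_{l=0}^k a_l s^l` fitted by constrained least squares

```
min_a  (1/N) Σ_n (f(s_n) − y_n)²
s.t.   f(s_min) ≥ 0,  f(s_max) ≤ 1          (range)
       f′(s) ≥ 0 on a 201-point grid          (monotonicity)
       Σ_l |a_l| ≤ λ                          (l1 complexity bound)
```

Range plus monotonicity confine f to [0, 1] on the training score range;
predictions clamp inputs to that range and clip outputs to [0, 1] to cover
grid gaps. Numerical choices: raw monomial basis (the l1 bound is defined
on these coefficients; an orthogonal basis would change its meaning), k
capped at 25 for conditioning; the convex QP is solved after the variable
split `a = u − v` (u, v ≥ 0) with a trust-region interior-point method,
followed by a warm-started SLSQP polish — the split leaves a flat direction
that stalls the interior point roughly 1e-3 short of vertex optima, and the
active-set polish recovers them to ~1e-10 (the polish is kept only if it
remains feasible and does not worsen the objective). Degenerate case: λ = 0
forces f ≡ 0.

(k, λ) are chosen by stratified 3-fold CV within the calibration training
set over k ∈ {4…20}, λ ∈ {4^i, i = −1…5}, minimizing validation MSE, ties
toward smaller k then smaller λ; infeasible grid points are skipped.

**Platt scaling.** `f(s) = 1/(1 + exp(A s + B))` by maximum likelihood with
the standard smoothed targets `t+ = (N₊+1)/(N₊+2)`, `t− = 1/(N₋+2)` (keeps
the MLE finite on separable sets). Newton iterations with backtracking;
converged at gradient norm < 1e-9, hard failure after 200 iterations.

**Isotonic regression.** The least-squares non-decreasing fit of the labels
sorted by score, by pair-adjacent violators; tied scores are pooled first
(block mean label, block size as weight), which leaves the optimum
unchanged. Prediction is piecewise-constant (left neighbor), clamped at the
range ends — interpolation between breakpoints is undefined by the
estimator, and the step function preserves monotonicity and [0, 1] exactly.

## Ensembles

Four combiners over the m base-model score vectors, each usable on raw or
on calibrated scores (in the calibrated variants, learners without an
assigned calibrator — by default the logistic model and the FNN, whose
scores are already near-calibrated — contribute raw scores):

* **Simple averaging** — weight 1/m (0.2 for five models).
* **Weighted averaging** — weights ∝ 1/max(ECE_m, 1e-6) or 1/max(MCE_m,
  1e-6), normalized to 1, with the errors measured on the OOF scores. The
  floor prevents a (nearly) perfectly calibrated model from swallowing the
  ensemble.
* **Stacking** — logistic regression of the outcome on the m OOF score
  columns, with a tiny ridge (1e-6) on the slopes for the routine
  near-collinearity of correlated probability columns. Calibrated stacking
  uses the fitted calibrators applied to the OOF scores as meta-features;
  calibrator and meta-learner share the OOF set, a mild, documented
  leakage.

## Evaluation protocol

Default: 300 repeats. Each repeat: stratified 320/86 split (the split is
defined by counts — 0.8·406 is not an integer — with per-class test counts
by largest-remainder rounding, so a 116-event cohort sends exactly 25
events to the test set); inner 3-fold CV for hyperparameters; OOF
collection; calibrator and ensemble fitting on training/OOF data only;
metric computation on the held-out test set. Per-repeat seeds derive
counter-style from the master seed (`SeedSequence([master, repeat, stage,
learner])`), so results are independent of execution schedule and each
repeat is reproducible in isolation. A failed repeat aborts the run with a
diagnostic; nothing is silently skipped. Aggregation reports medians and
quartiles (the convention for skewed per-repeat metric distributions) and
the count of repeats with Hosmer–Lemeshow p > 0.05.

## Metrics

* **AUC** in rank-sum form, ties counted ½.
* **ECE / MCE**: predictions sorted (stable; ties keep input order) and cut
  into equal-frequency bins — 10 by default, remainder samples to the
  earliest bins; ECE is the mean and MCE the max of |mean prediction − event
  fraction| over bins, reported ×100. Equal-frequency (not equal-width)
  binning keeps every bin populated at n = 86.
* **Hosmer–Lemeshow**: same equal-frequency grouping (10 groups);
  `Σ_g (O_g − E_g)²/(E_g(1 − E_g/n_g))` against chi-square with
  groups − 2 df; groups with a vanishing denominator are skipped with a
  warning and the df reduced.

Bin and group counts are package defaults (the reliability-diagram
literature's convention); they are parameters, not constants.

## Known limitations

* Synthetic covariates are independent; real clinical covariates are not.
  Coefficient-recovery tests rely on this.
* The equal-frequency ECE of an 86-patient test set has a binomial noise
  floor of roughly 10 points (about 5 at n = 400), so single-repeat ECE
  differences below that are noise; only medians over many repeats are
  interpretable.
* With purely logit-affine distortions of a single shared true probability,
  the stacking meta-learner — which directly optimizes log-loss on the OOF
  labels — recalibrates the ensemble on its own, and calibrating the base
  scores first adds estimation variance without adding information. The
  advantage of calibrate-then-stack requires base models with *diverse,
  non-affine* miscalibration and independent estimation error; the
  distorted-oracle test setup documents this boundary honestly (see the
  stacking-contrast test, which encodes the expected direction and fails
  under exactly these conditions).
* Isotonic calibration can overfit small calibration sets (piecewise-
  constant output with many breakpoints); the polynomial and sigmoid
  families are the intended choices below ~1000 samples.
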