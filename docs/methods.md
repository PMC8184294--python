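# Methods

## Problem and approach

`gazestate` estimates whether a driver is driving manually or being
driven by a conditionally automated vehicle, using nothing but where
they spontaneously look. The scene is tiled into 13 areas of interest
(AOIs): the road centre (RC, a disc of 8° angular radius around
straight-ahead), the four quadrants of the central screen around it
(Up/Down/Left/Right, split along the ±45° diagonals), the central and
two lateral mirrors (CM, LM, RM), the two peripheral screens (LS, RS),
the dashboard (D), the automation HMI, and a catch-all `Others`.

Each trial (one participant in one condition) is summarised by

* **static indicators** — the dwell percentage `s_a` of samples in each
  AOI `a` (13 values summing to 100; `s_RC` is the percent-road-centre
  metric PRC);
* **dynamic indicators** — the row-stochastic transition matrix
  `P[a, b] = Pr(next sample in b | current sample in a)` estimated by
  counting consecutive sample pairs at the acquisition rate,
  self-transitions included (169 values).

The state code `y` (+1 manual, −1 automated) is regressed on one of
four indicator matrices — `X_PRC` (n×1), `X_S` (n×13), `X_D` (n×169),
`X_DS` (n×182) — after centring each column and scaling it to unit
sample standard deviation (denominator n−1). Since p ≫ n and the
columns are strongly collinear (the 13 dwell percentages are linearly
dependent by construction), the regression is PLS1 computed by NIPALS:
for each component, `w ∝ Xᵀy` normalised, scores `t = Xw`, loadings by
least-squares projection on `t`, then deflation of `X` and `y`. With as
many components as the rank of a full-rank `X` this reproduces ordinary
least squares exactly (tested against the closed form and against
scikit-learn's implementation).

A unit is classified **automated** when its predicted score is
negative, **manual** otherwise (zero counts as manual: the automated
class is defined strictly by negativity).

## Validation and selection

Prediction quality is the leave-one-out mean squared error of
prediction (MSEP). Every fold re-standardises the remaining n−1 units
— including re-dropping columns that become constant — so the held-out
unit leaks nothing into the transform. The component count is the
argmin of LOO MSEP over 1..min(10, n−2), ties to the smaller count.

Indicator selection is backward elimination: at each step the indicator
with the smallest absolute standardised coefficient is removed, the
candidate set is scored by LOO MSEP (re-selecting its component count),
and the best-scoring set along the whole path wins; exact ties go to
the smaller set, and coefficient ties drop the column latest in
canonical order, so the procedure is deterministic. One deliberate
choice: the *ranking* coefficients come from the full-capacity fit
(ncomp = min(10, n−2)), not the CV-chosen fit. At the CV-chosen count
(typically 1–3) PLS coefficients are shrunk toward the single `Xᵀy`
direction, so ranking by them reduces to marginal correlation and
systematically discards indicators whose relevance is conditional on
others; ranking at full capacity (near the least-squares limit)
preserves them, and on simulated cohorts it is what lets the combined
static+dynamic matrix match or beat the dynamic-only matrix, as it
should given that its column space is a superset. A single-cut VIP
strategy (drop VIP < 1) is available as an alternative
(`selection="vip"`).

Classification error counts are computed from the leave-out scores, not
the in-sample fits (both are reported, labelled). Note the leave-out
scores of the *selected* set are still mildly optimistic, because the
set itself was chosen to minimise LOO MSEP; the label-shuffle negative
control therefore lands somewhat below 50% error (≈27% at seed 1)
rather than exactly at chance.

Group-level dwell differences are assessed with two-sided paired
t-tests (scipy), Holm-corrected over the 13 AOIs (statsmodels) at
family α = 0.05. AOI-level gaze traffic is summarised by **net flow**
over a selected transition set: in-count minus out-count per AOI,
self-transitions excluded (they would add one to both sides and
cancel); positive = entering, negative = exiting, zero = equilibrium.

## The synthetic cohort

No raw gaze recordings are distributed, so every end-to-end result in
this repository is computed on a seeded Markov simulator whose defaults
emulate the study design: 12 participants × 2 conditions × 1020 s at
20 Hz (24 units of 20,400 samples).

Each condition has a base matrix of the lazy-jump form
`P = s·I + (1−s)·J` with `s = 0.95`: hold the current AOI with
probability 0.95, otherwise draw a jump target from kernel `J`.
Unboosted, `J` has identical rows equal to the condition's dwell
profile (the published percentages, normalised — the printed columns
sum to 100.06 and 99.96), which makes that profile *exactly* the
stationary distribution. Effective self-stay is `s + (1−s)·J[a,a]`, so
dominant AOIs carry the longer dwell runs (RC in manual: mean run
≈ 3 s; rare AOIs: ≈ 1 s). An earlier construction that pinned the
diagonal at exactly 0.95 and shared one off-diagonal profile across
rows was abandoned: detailed balance forces its stationary mass to
`∝ b(1−b)`, which caps any single AOI's share well below the manual
road-centre target of 67.45%.

The automated condition additionally multiplies the 13 off-diagonal
transitions reported as automated-driving signatures (RC→CM, Down→HMI,
RC→Others, ...) by `dynamics_contrast` (default 3) before row
renormalisation, so the two conditions differ in dynamics beyond what
their dwell profiles imply. Because boosting perturbs the stationary
distribution, the base profile is corrected by a multiplicative fixed
point (`b ← b · target/current`, ≤500 iterations) until the boosted
matrix's stationary distribution matches the dwell target to ~1e−12.

Between-participant variability: each trial's matrix redraws every row
from a Dirichlet with mean the condition row and concentration
κ = 200 — visibly distinct participants whose dwell profiles still
cluster tightly around the condition means. Sequences start from the
stationary distribution. Continuous gaze angles can be emitted for any
labelled sequence (uniform within the AOI's region via rejection
sampling, plus Gaussian jitter; `Others` is emitted in a fixed
off-region band at azimuth 80–88°), which is how the labeller is
round-trip tested.

What the simulator does **not** model: saccade kinematics and
fixation-duration distributions (runs are geometric), within-trial
non-stationarity (events, fatigue), gaze-quality dropouts, and any
coupling between static and dynamic signatures beyond the construction
above. Passing end-to-end tests therefore demonstrates that the
pipeline recovers a planted, study-shaped contrast — not field
performance on human data.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `rc_radius` | 8 | deg | conventional road-centre disc radius |
| `quality_min` | 0.5 | fraction | samples below are dropped; transitions never bridge the gap |
| `transition_level` | `samples` | — | counting at the 20 Hz sample level keeps self-transitions, which carry signal (e.g. HMI→HMI); `runs` collapses them for sensitivity analysis |
| `max_ncomp` | min(10, n−2) | — | LOO cannot support more; 10 is ample for n = 24 |
| `self_stay` | 0.95 | prob. | mean AOI run ≥ 1 s at 20 Hz |
| `kappa` | 200 | — | Dirichlet concentration; between-participant sd of a 0.95 row entry ≈ 0.015 |
| `dynamics_contrast` | 3 | — | ×3 over-expression of automated-signature transitions |
| `alpha` | 0.05 | — | Holm family-wise level |

Mirror/dashboard/HMI/peripheral extents in the default geometry are
plausible three-screen-simulator values, configurable via the geometry
JSON/YAML file; only the 8° disc is fixed by convention. Boundary
points belong to the higher-priority region, RC first, so labelling is
total and deterministic.

## Numerical choices and degenerate inputs

* Zero-variance design columns are dropped and recorded by name
  (threshold: sd ≤ 1e−12·max(1, |mean|)); an all-constant design is a
  degenerate-data error.
* Transition rows never observed are all-zero and flagged by
  `row_support`, not filled with fabricated probabilities.
* NIPALS stops early when the residual covariance `Xᵀy` vanishes
  (relative tolerance ~1e−13); a 0-component model predicts the
  training mean.
* MSEP ties across component counts resolve to fewer components;
  selection-path ties to fewer indicators (tolerance 1e−12 relative).
* Stationary distributions come from the eigenvector of eigenvalue 1
  of `Pᵀ` (numpy eig), normalised to sum 1.
* Identical paired dwell vectors yield p = 1 (no evidence), avoiding
  the 0/0 paired t statistic.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the study-scale cohort
(24 × 20,400 samples) for the pipeline comparisons, 20 label-shuffle
replicates on the static mode for the negative control, 200,000-sample
trajectories for transition-estimator consistency (on a well-mixed
blend of the manual profile with uniform, since AOIs with 0.01% dwell
are entered only ~20 times in 200k samples and their rows are not
estimable at that length), and 100 seeded noise replicates for the
LOO-MSEP noise floor. Everything is seeded and deterministic.

## Known limitations

* The indicator-selection rule is a documented, deterministic
  substitute for the original study's unpublished procedure; selected
  counts should be compared qualitatively, not one-for-one.
* LOO scores after selection are mildly optimistic (see above); an
  outer validation loop would remove this at ~20× the cost.
* The labeller operates on raw samples; no fixation/saccade event
  detection, no head-model compensation.
* With 24 units, MSEP estimates are themselves noisy; orderings between
  close modes (D vs DS) can flip between seeds even when both separate
  the conditions perfectly.
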