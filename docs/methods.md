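# Methods

## Signal model

Each participant's recording is a 12-sensor × 29-point baseline phase followed
by a 12 × 29 response phase sampled at 0.97 Hz (time stamps
t_k = (k+1)/0.97 s; a 30 s phase yields floor(30 × 0.97) = 29 points). The
response of sensor *s* for class *c* is a saturating exponential with linear
drift and i.i.d. Gaussian read noise:

    v(t) = baseline_level(s) + A(s, c) · (1 − exp(−t / τ(s))) + drift · t + ε,
    ε ~ N(0, noise_sd²)

The baseline phase is `baseline_level(s) + ε`. Lung-cancer cohorts are planted
with elevated plateau amplitudes `A` on a configurable sensor subset;
everything else is class-exchangeable by construction (verified by an
amplitude-swap test).

### Generator defaults and calibration

| Parameter | Default | Rationale |
|---|---|---|
| cohort | 28 healthy / 18 cancer | study design |
| planted gaps (V) | TGS2602 0.095, TGS2620 0.092, MQ2 0.089, MQ135 0.086 | see below |
| noise_sd (V) | 0.18 | see below |
| drift | 5 × 10⁻⁴ V/s | slow sensor drift, small vs. signal |
| τ (s) | 4.2–7.0 per sensor | typical MOS rise times |

The four planted gaps and the noise level were calibrated once so that a
46-sample cohort has separability comparable to published breathprint studies:
cross-validated AUC of the ablation scorer peaks near 0.98 at subset size ~4,
no single sensor classifies alone, and the planted subset is recoverable by
ablation and attribution in ≥ 90% of cohort seeds (18/20 over seeds 0–19 for
both). The near-equal gap sizes are deliberate: with strongly unequal gaps a
single sensor saturates the CV AUC and the smaller-on-ties selection rule
collapses the "optimal subset" to one sensor, which no longer exercises the
subset-recovery question. These defaults are frozen; they are inputs to the
simulations, not tuned per run.

## Preprocessing

Per sensor, the baseline-phase mean is subtracted from both phases (removes
environmental offsets; idempotent). The corrected response matrix is flattened
sensor-major into 348 features named `SENSOR:k`. Standardization (zero mean,
unit population SD per feature) is always fitted on training rows only;
constant features map to exactly 0 rather than dividing by a vanishing scale
(threshold 10⁻¹²).

## Augmentation

Synthetic samples perturb a uniformly chosen same-class real parent with
isotropic Gaussian noise in standardized space, `x_syn = x_parent + N(0,
σ_a² I)` with σ_a = 0.6; defaults add 35 synthetic cancer and 25 synthetic
healthy samples (53 cancer / 53 healthy rows in total). This preserves class
means and inflates per-feature variance by σ_a². Equivalence validation runs a
Mann–Whitney U test per feature and class between original and synthetic rows
and reports the raw fraction of p < α with **no multiplicity correction** —
under the null ~5% of 696 tests fall below 0.05 by chance, and the report
makes that burden visible instead of hiding it. KDE overlays (Silverman
bandwidth) are attached for chosen features.

## Models

**Ridge logistic regression** minimizes sum-BCE + (λ/2)‖w‖² (intercept
unpenalized) by damped Newton iterations with step-halving; convergence is
declared when the penalized gradient norm falls below 10⁻⁸. When d > n the fit
runs in the row space of X via thin SVD — exact for the ridge objective and
much faster at 46 × 348.

**MLP**: hidden layers 128/64/32, each block affine → batch norm → ReLU →
dropout (rate 0.3), sigmoid output; loss = mean BCE + λ·Σ‖W‖² (λ = 0.001,
biases and batch-norm parameters unpenalized); Adam (lr 10⁻⁴, β = 0.9/0.999,
ε = 10⁻⁸), batch size 8, 100 epochs, He initialization, inverted dropout,
batch-norm running-moment momentum 0.9. Gradients are hand-derived, including
the backprop through batch statistics in train mode, and verified against
central finite differences (in inference mode batch norm is a fixed affine
map, which makes the check exact up to round-off; biases feeding batch norm
have exactly zero gradient). Probabilities are clipped at 10⁻¹² inside the
log; singleton mini-batches are skipped because batch variance is undefined;
training aborts on a non-finite loss.

## Evaluation protocols

- **Leakage-safe (default)**: stratified 5-fold CV; per fold the standardizer
  is fitted on training rows, only training rows are augmented, and the
  strictly real held-out rows are scored at a 0.5 threshold. Single-class test
  partitions report AUC as undefined (`None`), never 0.
- **Paper-faithful**: standardize the whole cohort, augment it, then
  cross-validate over the combined real + synthetic rows. Synthetic rows can
  land in test partitions, which is optimistic; the protocol exists to
  quantify that effect and is labelled in every report.

On the default cohort the MLP reaches ~0.96 accuracy / ~1.0 AUC under the
paper-faithful protocol but ~0.79 / 0.86 under the leakage-safe protocol. The
gap is a property of the setting, not the implementation: scikit-learn's
`MLPClassifier` with the same architecture and hyperparameters on identical
leakage-safe folds scores in the same 0.72–0.87 AUC band. Reported headline
numbers from augment-before-split designs should be read with that gap in
mind.

## Sensor ablation and attribution

Both diagnostics use a ridge-logistic scorer with **λ = 200** rather than the
evaluation recipe's λ = 1. At 46 samples × 348 features a weakly penalized
fit is dominated by overfit noise directions and greedy selection becomes
unstable (planted-subset recovery failed in about half the seeds); strong
shrinkage pulls the scorer toward the stable univariate class-difference
profile while preserving held-out ranking quality. Scores average over
**5 repeated** stratified 5-fold assignments (seeds `plan.seed + r`), because a
single fold's AUC on a ~9-sample test set is too coarse to rank candidate
subsets reliably. Both knobs are exposed in the config.

Backward ablation removes, at each step, the sensor whose removal maximizes
mean CV AUC (ties broken in canonical array order); the minimum-optimal subset
is the remaining set at the size with the best mean AUC, preferring the
smaller subset on ties (tolerance 10⁻¹²).

Attribution uses the closed-form Shapley values of the linear logit scorer,
`φ_j(x) = w_j (x_j − μ_j)` with the training-fold mean as background — exact
and efficient (attributions sum to the logit difference). A permutation-
sampling Monte-Carlo estimator of the general Shapley definition serves as the
independent oracle in tests. Per-sensor importance sums mean |φ| over the
sensor's 29 time points on held-out rows and averages over repeated folds; a
signed variant exists because signed sums can cancel.

## Determinism and numerics

One global seed fans out to per-stage seeds via `SeedSequence([seed,
digest(stage)])`, so any stage can be re-run in isolation and two runs of the
same config are byte-identical (summary JSON is written with sorted keys).
Statistical routines are hand-authored with explicit edge conventions:
midranks and tie-corrected variance (with continuity correction) for the
Mann–Whitney normal approximation, exact subset enumeration for pooled n ≤ 12,
trapezoidal ROC with tied scores collapsed so AUC equals U/(n₊·n₋) exactly,
and metrics with zero denominators reported as `None`. SciPy is used only for
distribution CDFs; scikit-learn appears solely as a cross-check in the tests.

## Limits of the generator's realism

- Noise is i.i.d. Gaussian per time point (an optional shared cross-sensor
  component exists but defaults to off); real MOS arrays show correlated,
  heteroscedastic noise, humidity/temperature sensitivity and 1/f drift.
- The response is a single saturating exponential; real sensors show recovery
  tails, hysteresis and cross-sensitivities between target gases.
- Class difference is a pure amplitude shift on four sensors; real
  breathprints differ in shape and timing as well, and confounders (smoking,
  diet, COPD) are not modelled.
- Participants are i.i.d.; no session, device or batch effects.

The generator is therefore a test harness with known ground truth, not a
substitute for clinical data: absolute performance numbers transfer to real
cohorts only qualitatively.
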