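# Methods

This note documents the models and procedures `lprscreen` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## The assay and its data model

The larval photomotor response (LPR) assay tracks one 5 dpf zebrafish
larva per round well of a 96-well plate through a 24-minute schedule:
6 min dark acclimation, then 3 cycles of 3 min light : 3 min dark, at
25 frames/s. A light→dark transition elicits a swimming burst that decays
over minutes; toxicant exposure perturbs this stereotyped response.
Analysis uses the second cycle only (the first is noisier, the third may
reflect habituation). Each larva-phase is a fixed 4500 × 5 matrix in the
feature order (trial time s, x mm, y mm, distance moved mm, velocity
mm/s), flattened frame-major to a 22500-vector.

Units: positions and the outlier cap are in mm, so readers convert
distance columns exported in μm (`distance_unit="um"`). Larvae flagged in
the morphology table are excluded from all behavioral analysis, since a
physical malformation confounds behavior.

## Preprocessing

* **Well centering.** (x, y) are re-expressed relative to the well center.
  Points outside the 3.25 mm well radius (tracking jitter) are pulled back
  to the boundary circle along the same bearing rather than dropped — a
  deliberate choice so jitter cannot delete frames.
* **Forward fill.** Tracks are placed on the uniform 1/frame-rate grid;
  a missing frame copies the previous frame's x, y and velocity and gets
  distance 0, because the larva was not *observed* to move and copying the
  previous distance would fabricate movement. Leading gaps copy the first
  observation backward.
* **Outlier cap.** Per-frame distance is capped at
  `body_length × startle_multiple / (startle_duration / frame_interval)` =
  3.9 mm × 2.5 / (120 ms / 40 ms) = **3.25 mm/frame**, the farthest a
  larva can plausibly travel in one frame (a full startle response).
  Velocity on capped frames is rescaled to cap × frame rate so the two
  stay consistent; whether the original assay adjusted velocity is
  unknowable from the data, and consistency was preferred.
* **Scaling.** Tensors are z-scored per feature (mean/SD over all frames
  of the stratum's control tensors). Tanh activations saturate on raw
  mm-scale inputs, so some normalization is required even though it is an
  implementation detail rather than part of the assay; the scaler is an
  explicit object that travels with the trained model.
* **Angular velocity** (screening metric option) is defined as the
  wrapped signed difference of successive movement headings
  (atan2 of displacement), divided by the frame interval, in deg/s;
  heading is carried forward through stationary frames. The quantity is
  named in the screening literature without a formula; this construction
  is ours.

## Statistical framework

All tests are two-sided two-sample Kolmogorov–Smirnov tests with the
standard asymptotic p-value and no multiplicity adjustment (deliberately,
matching screening practice: each combination is an independent
hypothesis).

* **Combo screen** (α = 0.05): pooled per-frame cycle-2 metric of the
  combination's larvae vs its same-plate controls. Per-frame pooling is
  the default unit (`ks_unit="frame"`); per-larva summaries are available.
* **Plate stratification** (α = 0.01): each plate's controls vs the
  pooled controls of all *other* plates, per phase. Significant plates are
  split hyper/hypoactive by the sign of the mean per-frame distance
  difference (the grouping rule's direction had to be fixed somewhere).
  Here the default K-S unit is the **per-larva** mean: with per-frame
  pooling the sample sizes are so large (tens of thousands) that any real
  between-plate heterogeneity rejects every plate and nothing is ever
  "normal"; testing at the larva level matches the scale the
  heterogeneity lives at.
* **Abnormal labeling.** Within significant combinations, the per-larva
  metric is total cycle-2 distance; thresholds are the matched same-plate
  controls' 30th and 70th percentiles (linear interpolation). Treated
  larvae at or below the lower or at or above the upper threshold are
  labeled abnormal. The reference population choice matters: percentiles
  of the treated group itself would mechanically label ~60% of every
  combination regardless of effect, so the matched controls are used.

A known property: on data with strong within-window time structure (the
dark-burst decay) the per-frame screen is mildly *conservative* — the
pooled sample is a fixed mixture over time, which shrinks the ECDF-gap
variance below the iid K-S null (measured type-I error ≈ 0.02–0.04 at
α = 0.05, vs 0.036–0.054 under a stationary null). The screen never
errs anti-conservatively from this effect.

## Autoencoder bank

One (autoencoder, logistic head) pair per (activity state, phase) stratum,
six in a complete bank. Each autoencoder sees only its stratum's control
tensors: the semi-supervised premise is that a model of normal behavior
reconstructs (and encodes) controls well and anomalies poorly.

Full-scale architecture (the `AEConfig` defaults): input 22500; encoder
7500 → 3000 → 1500 → 1000 → 750 → 500 → 375 → 250 (eight tanh layers,
normal kernel init, dropout 0.2 after every hidden layer, L1 = L2 = 1e-5);
decoder mirrors with six layers; linear output; MSE loss; adadelta with
learning_rate 0.001, rho 0.95, epsilon 1e-7. The encoder width schedule
is fixed as this explicit list rather than a generation rule, for
reproducibility; all of it is configurable.

The network is implemented directly in numpy — full-batch
backpropagation, inverted dropout, per-parameter adadelta accumulators —
which makes training single-threaded, deterministic given the seed, and
dependency-light. Full-scale training runs to ~1e5 epochs at
learning_rate 0.001; desk-scale configurations (used throughout the tests
and benchmarks) use hundreds of epochs with the classic adadelta
learning_rate of 1.0 to compensate — the accumulator-ratio step is
scale-free, so the larger rate is the standard choice when the epoch
budget is small.

The head is scikit-learn logistic regression (LBFGS, max_iter 4000 — the
"epochs per fold" of the original description read as the solver's
iteration cap) with stratified 100-fold cross-validated accuracy recorded;
the fold count is capped at the minority class size with a warning. Head
training labels: the stratum's encoded controls (normal) vs the stratum's
K-S-labeled abnormal larvae. A stratum with fewer than `min_controls`
controls (default 10) or no labeled abnormals is recorded as missing and
skipped with a warning.

Classification: P(abnormal) from the head on the encoded tensor; a larva
with tensors in both phases is abnormal if either phase's model flags it.
A chemical–concentration pair is flagged when its exposed abnormal
*fraction* (fractions, not counts — group sizes differ) strictly exceeds
its matched controls' and is at least 0.25.

## Evaluation

SE, SP and PPV are reported in percent; ratios with zero denominators are
reported as missing (NaN), never as 0. Cohen's κ uses the marginal-based
chance agreement; AUROC is the Mann–Whitney concordance (scikit-learn's
implementation, cross-checked against exhaustive pair counting in tests).

Permutation feature importance shuffles one of the five tensor features at
a time — jointly across frames and subjects by default (the standard
fully destructive permutation; a within-subject variant is available) —
re-scores the evaluation set, and averages the κ and AUROC drops over
`n_shuffles` (default 1000) with their standard errors. Coefficients of
variation use the population (ddof 0) standard deviation over the mean.

Replicate experiments are compared by fitting a shared vs separate quartic
dose–response curves and testing the extra sum of squares with an F test
(p ≥ 0.05 ⇒ same curve); each curve needs ≥ 6 distinct concentrations
since a quartic has 5 coefficients. The quartic-plus-threshold form is
fixed here as extra-sum-of-squares because only the curve order and the
threshold were given.

## Synthetic data generator

`synthetic_data` emulates the assay's structure with a bounded correlated
random walk in the well disc:

* per-frame step lengths ~ Gamma(shape 2) with phase-dependent mean:
  light mean `light_step_mean` (default 0.02 mm/frame = 0.5 mm/s), dark
  mean adds `dark_burst_amplitude` (0.12 mm/frame) decaying with
  `burst_decay_tau` (60 s) from each dark onset — the burst-and-decay LPR
  signature, with acclimation counting as dark from t = 0;
* heading persists with Gaussian turning noise (`turning_sd` 25°/frame)
  and reflects off the wall; pauses (`pause_prob` 0.35) zero the step;
  recorded distance is the *realized* displacement, so dist ≡ |Δposition|
  exactly and velocity ≡ dist × frame rate;
* tracking dropout deletes frames at `missing_frame_prob` (0.002);
* plate-level activity states scale a plate's step means (hypo 0.4×,
  normal 1×, hyper 2.2×), shared by every well on the plate; treatment
  phenotypes additionally scale activity, bias headings toward the wall
  or center (thigmotaxis-like), or delay the dark-onset response;
* defaults were chosen once as plausible round numbers for a 6.5 mm well
  at 25 frames/s and are all configurable; the generator deliberately does
  not mimic any specific chemical's dose–response.

What it does **not** emulate: O-bend kinematics, bout structure,
habituation across cycles, within-plate spatial (edge) effects, or
correlated tracking noise. Passing benchmarks therefore demonstrate that
the pipeline's machinery — stratification, screening, labeling, training,
calling — behaves correctly on data with the assay's coarse statistical
structure, not that the classifier reaches any particular performance on
real larvae.

## Benchmarks and problem sizes

The `experiments` module holds the package's reference experiments, all
deterministic given a seed and sized for minutes on one CPU:

* **Null calibration**: 500 null combinations (7 treated vs 7 same-plate
  controls drawn from the same stationary behavior model), per-frame K-S
  at α = 0.05. A stationary null isolates the kernel's calibration from
  the conservativeness described above.
* **Three-state bank**: nine plates (three per activity state, eight
  controls each), one strong-phenotype combination per plate, standard
  schedule; tensors downsampled 20× (225 frames), encoder (64, 16),
  40 epochs. A correct run stratifies all plates, finds all combos
  significant, and trains all six pairs.
* **Anomaly recovery**: 200 training controls, head vs 50 hyperactive
  anomalies (2.5× activity), held-out 100 controls + 50 anomalies;
  dark-phase tensors downsampled 5× (900 frames), encoder (256, 64),
  300 epochs. Reported: held-out SE, SP, κ, AUROC.
* **Importance sanity**: a toy fitted classifier reading exactly one
  tensor feature; over 100 repetitions the informative feature should top
  the AUROC-drop ranking essentially always.

Downsampling aggregates frame bins (distance summed, position/velocity at
bin end, time at bin start) so total movement is conserved.

## Numerical notes and limitations

* K-S p-values use the asymptotic two-sided formula everywhere (with the
  Kolmogorov limit as fallback for degenerate sizes); exact small-sample
  p-values are not used, matching the large per-frame samples the screen
  operates on.
* Percentiles use numpy's linear interpolation convention.
* Adadelta updates weights and biases identically; gradients include the
  L1 subgradient sign(W) and 2·L2·W terms on weights only.
* Training loss history records the dropout-free MSE each epoch, so the
  determinism contract ("same seed ⇒ identical history") is exact.
* The model bank serializes to one directory (an .npz weight container
  per stratum plus a JSON manifest embedding config, stratification and
  scalers); preprocessed tensors can be archived to HDF5 keyed by
  subject/phase with the scaler embedded.
* Known limitations: no bout-level features, no GPU path, no
  hyperparameter search driver (sweeps are config edits), and the
  generator's phenotype menu is a testing construction, not a claim about
  any real chemical's mode of action.
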