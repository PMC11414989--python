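# lprscreen

Semi-supervised anomaly detection for larval zebrafish photomotor-response
(LPR) screens.

High-throughput developmental neurotoxicology screens expose zebrafish
embryos to chemicals in 96-well plates and, at 5 days post-fertilization,
record each larva's movement through a light/dark cycling assay (6 min dark
acclimation, then 3 cycles of 3 min light : 3 min dark, tracked at
25 frames/s). The classical readout — a two-sample Kolmogorov–Smirnov test
on distance moved — misses phenotypes that change *how* a larva moves
(spatial preference, response timing) without changing how *much* it moves.

`lprscreen` implements both halves of a richer analysis and is aimed at
screening labs and computational toxicologists:

1. **Statistical framework.** Per-frame distance of each
   chemical–concentration combination is compared to same-plate controls
   with a two-sided two-sample K-S test (significant at p < 0.05, no
   multiplicity adjustment). Control plates are stratified into
   hypoactive / normal / hyperactive activity states by K-S against the
   pooled controls of the other plates (p < 0.01). Within significant
   combinations, larvae whose total cycle-2 distance falls at or below the
   matched controls' 30th percentile or at or above their 70th are labeled
   abnormal.
2. **Stratified deep autoencoders.** For each (activity state, phase)
   stratum — six in all — a fully connected autoencoder
   (22500 → 7500 → … → 250 bottleneck, tanh, dropout 0.2, L1 = L2 = 1e-5,
   adadelta, MSE) is trained on *control* larvae only, so the bottleneck
   encodes quintessential normal behavior. A logistic-regression head
   (LBFGS, 100-fold cross-validation) on the bottleneck separates normal
   encodings from the K-S-labeled abnormal ones and scores every larva as
   P(abnormal). A chemical–concentration pair is called abnormal when its
   exposed abnormal fraction exceeds its controls' **and** is at least 25%.

The input tensor for one larva in one phase is the 4500-frame × 5-feature
matrix (trial time, x, y, distance moved, velocity) of the second
light/dark cycle; preprocessing well-centers coordinates, forward-fills
tracking gaps, and caps per-frame distance at 3.25 mm (the farthest a
3.9 mm larva moving 2.5 body lengths per 120 ms startle can travel in one
40 ms frame). Evaluation tools include Cohen's κ, AUROC, SE/SP/PPV,
permutation feature importance, coefficients of variation, and quartic
dose–response comparison between replicate experiments.

Because real tracking exports are bulky, the package ships a synthetic
study generator (`lprscreen.synthetic_data`) — a bounded correlated random
walk with gamma step lengths, a decaying dark-transition burst, pauses,
plate-level activity heterogeneity and configurable treatment phenotypes —
so the full pipeline is exercisable end-to-end with known ground truth.
The autoencoder itself is implemented directly in numpy (full-batch
backpropagation with an adadelta optimizer), so training is deterministic
given a seed and runs on one CPU.

## Worked example

A three-plate study (one plate per activity state) with a strongly
hypoactive treatment, a strongly hyperactive one, and an inert one, on a
shortened schedule at 10 frames/s:

```python
from lprscreen.autoencoder import AEConfig
from lprscreen.pipeline import run_pipeline
from lprscreen.stats import ActivityState
from lprscreen.synthetic_data import ComboSpec, PhenotypeSpec, StudyConfig, simulate_study
from lprscreen.track_data import AssaySchedule

schedule = AssaySchedule(acclimation=60, cycle_light=60, cycle_dark=60, n_cycles=2)
study = simulate_study(StudyConfig(
    n_plates=3, wells_per_plate=15, controls_per_plate=8,
    combos=(
        ComboSpec("abamectin-like", 0.4, PhenotypeSpec(activity_scale=0.2), 7),
        ComboSpec("pfas-like", 11.1, PhenotypeSpec(activity_scale=2.5), 7),
        ComboSpec("inert", 100.0, PhenotypeSpec(), 7),
    ),
    plate_states=(ActivityState.HYPOACTIVE, ActivityState.NORMAL,
                  ActivityState.HYPERACTIVE),
    schedule=schedule, frame_rate=10.0, seed=1,
))
result = run_pipeline(
    study.tracks, study.plate_map,
    AEConfig(input_dim=750, encoder_layers=(64, 16), decoder_layers=(64,),
             epochs=60, learning_rate=1.0, seed=1),
    schedule=schedule, downsample=4, min_controls=8, head_folds=5,
)
print(result.screen[["chemical", "concentration", "D", "p", "significant"]])
print(f"models trained: {len(result.bank)}  labeled abnormal: {len(result.labels)}")
print(result.chemical_calls[["chemical", "concentration",
      "exposed_abnormal_fraction", "control_abnormal_fraction", "flagged"]])
```

prints

```
      chemical  concentration        D             p  significant
abamectin-like            0.4 0.308348  0.000000e+00         True
         inert          100.0 0.007128  9.755400e-01        False
     pfas-like           11.1 0.195327 3.185377e-150         True

models trained: 4   K-S-labeled abnormal larvae: 14

      chemical  concentration  exposed_abnormal_fraction  control_abnormal_fraction  flagged
abamectin-like            0.4                        1.0                       0.25     True
     pfas-like           11.1                        1.0                       0.00     True
```

The K-S screen finds the two real phenotypes (huge ECDF gaps D with
vanishing p) and passes the inert compound; the 14 treated larvae outside
the control 30th/70th percentile band become the abnormal training labels.
Four of the six strata get models here — the hyperactive plate's only
combo was the inert one, so that stratum has no labeled abnormals to train
a head on and is skipped with a warning. Both real phenotypes are flagged:
every exposed larva scores P(abnormal) ≥ 0.5, well above the 25% call
threshold and their controls' rates.

The same flow is available from the shell:

```sh
lprscreen simulate --config study.yaml --out data/ --seed 1
lprscreen train --tracks data/tracks.csv.gz --plate-map data/plate_map.csv \
                --morphology data/morphology.csv --config model.yaml --out bank/
lprscreen classify --bank bank/ --tracks data/tracks.csv.gz \
                   --plate-map data/plate_map.csv --config model.yaml --out calls.csv
lprscreen evaluate --calls calls.csv --out eval/
```

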