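# Methods

## Problem and pipeline

`gaitspeed` studies whether a small subset of silhouette-derived body
measurements suffices to classify treadmill walking speed into three
classes — slow (2–3 km/h), normal (4–5 km/h), fast (6–7 km/h) — with a
bidirectional LSTM, and whether redundant (highly correlated) measurements
can be dropped without losing accuracy. The pipeline is:

1. **Input**: per-sequence directories of binary lateral-view silhouette
   frames (or pre-extracted signal CSVs). Because the licensed treadmill
   video corpus this protocol was designed around cannot be redistributed,
   the package ships a synthetic generator that emulates its structure:
   34 participants × 6 speeds (2–7 km/h) × 2 sequences = 408 sequences,
   ≥ 240 frames at 60 fps.
2. **Feature extraction**: five dimensionless per-frame measurements
   (HW1, HW2, HW3, A1, A2 — see below), yielding five quasi-periodic
   signals per sequence.
3. **Pattern assembly**: each sequence is cut to its first 240 frames and
   restricted to a feature subset, giving an `n_features × 240` labelled
   walk pattern; the 30 subsets of sizes 1–4 (C(5,1)+C(5,2)+C(5,3)+C(5,4))
   plus the five-feature baseline define 31 combination datasets of 408
   patterns each (136 per class).
4. **Screening**: pairwise R² (squared Pearson correlation) among the five
   signals within each speed class, banded as weak 0.10–0.39 / moderate
   0.40–0.69 / strong 0.70–0.89 / very strong 0.90–1.00 (values < 0.10 are
   labelled `below_weak`).
5. **Classification**: participant-grouped k-fold cross-validation
   (k = 17 for the 34-participant layout → 2 participants, 24 patterns per
   test fold; 16 repeats give the full 272 fold evaluations) of a biLSTM
   per combination dataset.
6. **Selection**: a proper subset is *optimal* if its mean CV accuracy is
   no more than 2 percentage points below the five-feature baseline and
   every within-subset pair has R² < 0.40 in all three speed classes;
   qualifiers are ordered by (fewest features, highest accuracy). Accurate
   but highly correlated subsets are reported separately, not selected.

## The five measurements

With a tight bounding box (height H, width W1) around the silhouette's
foreground, W2 and W3 the maximal horizontal *extents* over the mid-body
and lower-body bands (middle and bottom thirds of the box height — the
extents span the gap between the legs, so leg spread widens them):

    HW1 = H/W1,  HW2 = H/W2,  HW3 = H/W3,
    A1 = foreground pixels in box / (H·W1),
    A2 = background pixels enclosed between the outermost foreground runs
         of each row, summed over the box, / (H·W1).

All five are ratios of pixel counts, hence invariant to where the subject
stands relative to the camera (up to rasterization) and to translation
within the frame. Row gaps are counted for A2 wherever a row has two or
more foreground runs; single-run rows (head, torso, merged legs)
contribute zero, so for a silhouette whose only concavity is the inter-leg
space, A1 + A2 = 1 exactly. The band extents, measured from the box top as
fraction intervals, are configurable (`FeatureConfig`); thirds are the
default because they approximate a head+torso / hip / leg partition.
Degenerate frames (no foreground, or an empty band) are marked missing and
repaired by per-feature linear interpolation; sequences with more than 10%
degenerate frames are rejected.

## Synthetic data

Two generators share one cohort layout (`CohortSpec`).

**Silhouette level** (`simulate_walker_sequence` / `simulate_cohort`): an
articulated walker — head disc, torso rectangle, two rigid legs swinging
in antiphase with leg angle `A·sin(2π·f·t)` — rasterized to binary VGA
frames, vertically centred (treadmill walking ⇒ no horizontal drift).
Cadence and stride amplitude increase linearly with speed
(`f = 0.9 + 0.25·(v−2)` Hz, `A = 0.25 + 0.05·(v−2)` rad by default), so
the inter-leg aperture — and every width/area measurement — oscillates at
twice the cadence, the classic gait signature. Per-participant random
effects: log-normal body scale (sd 0.05) and cadence offset (sd 0.05 Hz).
Arms are omitted by default (the torso occludes arm swing in a lateral
silhouette, and a clean mid-body band keeps W2 well defined); a flag adds
them.

**Signal level** (`simulate_signal_set` / `simulate_signal_cohort`): the
five ratio signals drawn directly from a latent-channel model — sinusoids
at harmonics of twice the cadence plus optional shared white-noise
channels, mixed into features through a loadings matrix, plus per-feature
noise. Orthogonal channels (quadrature phases or distinct harmonics) make
the between-feature correlation structure directly programmable. The
default configuration reproduces the qualitative correlation pattern of
real treadmill silhouettes: a strongly inter-correlated block (HW1, HW3,
A1 — all driven by the same width oscillation), with HW2 and A2 only
weakly correlated with everything; block correlations strengthen from slow
to fast, as observed in practice. This is the default input for classifier
experiments because it is orders of magnitude faster than rasterizing and
re-extracting ~100k frames.

Two named constructions exist for calibration experiments:

* `SignalConfig.separable()` — widely separated class means, near-zero
  noise: a ceiling case any working classifier must solve (≥ 95% grouped
  CV accuracy), also used label-permuted as the chance-level null (~33%).
* `SignalConfig.three_source()` — the redundancy ground truth. HW1, HW2
  and A2 carry three mutually orthogonal latent sources; HW3 duplicates
  HW1 and A1 duplicates HW2 (sharing both the sinusoid and the noise
  channel, so duplicate pairs have R² ≈ 0.99 while no single feature is
  clean). Class information is a channel-level DC shift (±2 channel
  units) masked by per-participant channel offsets (sd 1); cadence is
  deliberately speed-independent here, so the mean cue is the only class
  signal. One feature alone is therefore ambiguous (one noisy source),
  a source-covering triple averages three independent nuisances (√3
  gain), and adding a duplicated feature contributes nothing — the
  redundancy thesis, restated at a testable scale.

**What the synthetic data does not emulate**: real silhouette artefacts
(segmentation noise, clothing, shadows), arm swing, double-support leg
occlusion geometry, and the actual correlation magnitudes of any real
corpus. Passing tests therefore demonstrate that the *pipeline* measures,
screens and selects correctly under known ground truth — not that any
particular accuracy transfers to real video.

## Classifier

One biLSTM layer (default 100 hidden units per direction; the reduced
`BiLstmConfig.fast()` profile uses 16), dense softmax head, Adam
(lr 1e-3 default / 3e-3 fast), mini-batches of 16/32, at most 100/40
epochs with early stopping on a training-loss plateau, global
gradient-norm clipping at 2. Inputs are z-scored per feature channel with
statistics computed on the training patterns only (no leakage); folds are
grouped by participant, and the grouping is asserted in tests. The network
is implemented in NumPy with exact backpropagation through time, verified
against numerical differentiation.

The sequence readout defaults to **time-averaged pooling** of the hidden
states rather than final-state concatenation: with 240-step sequences and
desk-scale training budgets, the final-state readout must transport a
global cue across the whole sequence and trained unreliably (occasional
non-converged folds with large fold-to-fold scatter), whereas mean pooling
feeds gradient to every timestep and was uniformly stable. The textbook
final-state readout remains available (`pool="last"`).

Accuracy is aggregated over fold-level accuracies (mean and SD across the
k × n_repeats folds), not pooled predictions. Training wall time is
recorded per fold (minutes) for report parity but never asserted on —
it is hardware-bound.

## Reproducibility and numerics

Every stochastic stage takes a seed: cohort generation spawns independent
child streams per participant and sequence; cross-validation derives a
seed per (repeat, fold); the sweep derives a per-subset seed as
CRC-32(subset name) XOR master seed, so any subset re-runs in isolation.
Within one sweep the participant-to-fold shuffle is driven by the master
seed alone (`fold_seed`), so every feature subset is evaluated on the
same partitions and subset accuracies are paired — differences between
subsets then reflect the features, not partition luck. Two runs with the
same master seed produce bit-identical reports.

Numerical conventions: 0-based row-major coordinates, y down; boxes and
bands half-open; band row interval `[top + floor(lo·H), top + floor(hi·H))`.
One consequence of integer band edges: under 2× upscaling of a mask whose
height is not divisible by 3, a thirds-band boundary can shift by one
source row, and where the row extent changes steeply across that boundary
(the hip, for W2) the band width can move by more than rasterization
alone would suggest. Scale invariance is therefore quantified by
re-rendering the same walker state at doubled body scale (every ratio
within 2%); HW1, A1 and A2 are exactly invariant under integer upscaling
because boxes and areas scale exactly. Other conventions:
R² clipped to [0, 1]; banding intervals closed at the printed endpoints
with the upper band winning ties (0.39 → weak, 0.40 → moderate); zero
variance makes R² an error, not 0; z-scoring guards zero variance by
substituting unit scale.

## Scaled-down experiment sizes

The full protocol (34 participants, k = 17, 16 repeats, 31 datasets,
100-unit network) is exposed through the library and CLI, but the test
suite and the acceptance script run a reduced profile chosen to keep a
single-CPU run in minutes while preserving every qualitative property:
10 participants (120 sequences), k = 5 grouped folds, 1 repeat, 16 hidden
units, ≤ 40 epochs. Counts and fold-structure checks (408 sequences,
136/class, 17 × 2 × 24, 272 evaluations) always use the full 34-participant
layout, which is cheap at the signal level.

## Known limitations

* The biLSTM is small and CPU-bound; the reduced profile's accuracies
  carry fold-level noise of several percentage points, which is why the
  redundancy experiments are designed with wide margins.
* The walker is a stick figure; its silhouettes are cleaner than real
  segmentations, so the optional small-component cleaning step defaults
  to off and is untested against real noise distributions.
* Band extents for the mid/lower body are a declared convention (thirds),
  not an estimate of any published setup.
* The selection rule formalizes "within 2% of baseline, low correlation"
  with a hard R² < 0.40 cutoff in every class; other operationalizations
  of "low" are one flag away but not explored.
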