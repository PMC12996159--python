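# Methods

## Problem setting

The package decodes motor imagery (MI) from epoched multichannel EEG.  A
trial is an array `x_raw ∈ R^{C×T}` (microvolts) with a class label; the
canonical configuration mirrors a 22-electrode, 250 Hz, 4-second recording
(C = 22, T = 1000) with four imagery classes.  Discriminative structure in
such data is carried chiefly by event-related desynchronisation (ERD):
imagining a movement suppresses mu (8–12 Hz) and beta (18–26 Hz) band power
over the contralateral sensorimotor cortex.

## Model

The decoder combines two spatial views of each trial and two attention
modules, with a deliberately small budget of 13,458 trainable parameters in
the canonical configuration.

**Multi-view decomposition.** A bank of nine band-pass filters (4–8 to
36–40 Hz, 4 Hz steps) maps the trial to `x_fb ∈ R^{9×C×T}`.  The filter
family is not dictated by the architecture; the default is a Chebyshev
type-II design (order 8 as second-order sections, 30 dB stop-band) applied
forward–backward so each view is zero-phase, with an order-4 Butterworth
alternative.  Forward–backward filtering uses the standard 3×order edge
padding; no extra transient trimming is performed.

**Temporal-spectral-spatial branch.** `m = 64` spatial filters with a
(C, 1) receptive field act across all nine views at once (bias-free, since
batch normalisation follows), then BN and ELU give `x_ssf ∈ R^{m×T}`.
A temporal log-variance layer — `log(max(var, 1e-6))` over non-overlapping
half-open windows of `w = 250` samples, population (1/w) variance —
produces the band-power surrogate `x_tssf ∈ R^{m×t}`, `t = ⌊T/w⌋ = 4`.
The variance floor `var_eps = 1e-6` guards `log 0` on constant windows.

**Graph branch.** Each trial's broadband signal defines a functional
connectivity graph: instantaneous phases from the analytic (Hilbert)
signal, pairwise phase-locking values
`PLV_ij = |mean_t exp(i(φ_i − φ_j))|`, and a binary adjacency keeping the
k = 100 largest strict-upper-triangle entries (the k-th value inclusive;
ties broken by PLV descending then lexicographic (i, j) for cross-platform
determinism).  Graphs are computed per trial; a per-subject averaged-PLV
mode exists behind `connectivity.average_plv`.  Node features are the
per-electrode log-variance of a spectrally fused trial (a (1, 1) pointwise
convolution with bias collapsing the nine views, BN, ELU, log-variance),
`H ∈ R^{C×t}`.  A GATv2 layer with 3 heads attends over the graph:
per head, scores `e_ij = aᵏ·LeakyReLU(W_lᵏ h_i + W_rᵏ h_j)` (slope 0.2,
separate source/target transforms `W_l, W_r ∈ R^{t×t}`, no biases;
self-loops added so neighbourhoods are never empty), softmax over
neighbours, value aggregation with `W_rᵏ h_j`, arithmetic mean over heads,
then BN over the feature axis and ELU.  Global sum pooling yields the
graph readout `x_sgf ∈ R^t`, which is broadcast-added to every row of
`x_tssf` (the two branches are aligned in both the temporal and spectral
sense, so simple addition costs no parameters).

**Spectral attention gate (cross-spectral interaction).** From the fused
map `x_estf ∈ R^{m×t}`, per-row max- and mean-pooling give descriptors
`z_max, z_avg ∈ R^m`.  Each is cross-correlated along the spectral axis
with a trainable length-`l = 7` kernel (centred window, zero padding), the
two results are summed and passed through a sigmoid, giving a gate
`u ∈ (0,1)^m` that rescales each spectral row — a fully-connected-free
analogue of squeeze-and-excitation that models local interactions between
neighbouring latent spectral channels.

**Temporal attention pooling.** A trainable matrix `W ∈ R^{m×t}`,
softmaxed per row, weights the `t` windows of each spectral row and sums
them, letting the model discount windows degraded by fatigue or lapses.
Zero initialisation makes both attention modules start neutral (gate 0.5,
uniform window weights).

**Classifier.** One linear layer (with bias) on the pooled `m`-vector.
Dropout (rate 0.1) is applied once to `x_estf` before the gate, so it
regularises both attention modules.

### Parameter budget

spatial conv 64·9·22 = 12,672; its BN 128; pointwise conv 9+1 = 10; its BN
2; GATv2 3·(2·4² + 4) = 108; its BN 8; gate kernels 2·7 = 14; temporal
attention 64·4 = 256; classifier 64·4+4 = 260 — total 13,458.  The
bias/BN placements above are the unique assignment we found that lands
exactly on this figure; changing any of them (e.g. biased GATv2
transforms, concatenated heads) breaks it, which is why the count is
pinned by an acceptance check.

## Training

Cross-entropy loss, Adam (lr 1e-3, weight decay 1e-3 added to the
gradient, uniformly over all parameters including BN affines — the recipe
is silent on exclusions, and training is stable either way), batch size
64, and after every step each spatial filter is projected onto the L2 ball
of radius 2 (max-norm).  Epoch budget, batch size and initialisation are
not part of the published recipe; defaults are 500 epochs (no early
stopping), Glorot-uniform initialisation for convolutional/attention
transforms, zeros for the two attention modules' weights.  All randomness
(init, batch order, dropout) derives from one integer seed; identical
seeds give bitwise-identical loss histories.

Gradients come from a small reverse-mode tape over numpy arrays
(`migraphdec.autodiff`).  The engine is validated by central
finite-difference checks over randomly sampled parameters (worst relative
error ~1e-7 in float64 on the tiny test configuration; entries whose
gradient magnitude is below 1e-6 are skipped, since central differences
are pure cancellation noise there).  Batch-norm and the windowed
log-variance are fused primitives with analytic backward passes.

## Evaluation protocols

* session-dependent — stratified 9:1 split inside session 1; per class the
  test share is `floor(n/10)` with the remainder kept for training;
* session-independent — train on session 1, test on session 2;
* subject-independent — leave-one-subject-out folds.

Metrics: accuracy, macro-F1, and a row-normalisable confusion matrix
(rows = true classes).  A Wilcoxon signed-rank wrapper is provided for
subject-level paired comparisons.

## Synthetic data

The generator emulates exactly the statistics the decoder exploits:

* 1/f^β coloured Gaussian background (β default 1), unit variance per
  channel; the realised log-log PSD slope tracks β within ±0.2 over
  2–40 Hz;
* per class, narrow-band oscillations on class-specific channel groups.
  Every class's target channels carry their band's rhythm in every trial;
  the trial's own class multiplies the amplitude on its target set by
  √erd_factor, so band power scales by erd_factor — a contrast, not an
  absent-vs-present cue.  Oscillations are amplitude-modulated cosines
  whose phase is a carrier drawn uniformly inside the band plus a slow
  random walk (step 0.1 rad), which makes them band-limited and
  decorrelates independent processes;
* oscillation amplitude is set from `snr_db`, defined as the in-band power
  ratio of oscillation to background (measured on the trial's own noise);
* optional coupling blocks share one phase process, mixed with each
  channel's private process by `coupling_strength ∈ [0,1]`, giving
  controllable PLV structure (strength 1 with 25 dB in-band SNR yields
  within-block broadband PLV > 0.9 and cross-block < 0.2).

The canned two-class benchmark places mu-band ERD over the contralateral
motor channel groups (C5/C3/CP3 vs C4/C6/CP4 of the 22-electrode montage);
the four-class variant adds beta-band modulation over midline and parietal
groups.  Difficulty presets: easy (erd 0.2, 6 dB), medium (0.45, 3 dB),
hard (0.7, 0 dB).

What the generator does **not** emulate: volume conduction and realistic
source mixing, non-stationary artefacts (EMG/EOG), inter-subject
variability of rhythm frequency and topography, or session drift.  Passing
tests therefore demonstrate that the implementation is correct and that
the architecture can learn ERD/connectivity structure — not that it
attains any particular accuracy on real recordings.

## Problem sizes in the test suite

Verification experiments are sized for a single CPU: the learnability
check trains on 100 trials/class (easy benchmark, 200 epochs, seed 0) and
tests on 50/class; the spatial-filter band-selectivity check repeats 10
seeded 40-epoch runs at 50 trials/class, counting how often the trained
filters' summed squared weight per band peaks on the ground-truth mu band;
the edge-budget sensitivity experiment sweeps k ∈ {50, 100, 150} at
30 trials/class for 15 epochs.  These sizes are package defaults for the
acceptance experiments, chosen to make the full suite reproducible in
minutes; the library itself has no such limits.

## Known limitations

* The GATv2 variant (separate source/target transforms, bias-free, mean
  head aggregation) is the parameter-budget-consistent reading of the
  architecture, not an externally confirmed one.
* The printed definition of the windowed variance nominally spans w+1
  samples; we use half-open w-sample windows consistent with the 1/w
  prefactor.
* The adjacency threshold rule leaves the threshold entry itself
  undefined as printed (strict inequalities on both sides); we retain it
  (top-k inclusive).
* Batch semantics: operations are defined per trial; batched evaluation
  equals the per-trial loop exactly in eval mode.  Train-mode BN uses
  batch statistics, so batch composition affects training as in any
  BN-based model.
* The real-data adapters (GDF/EDF/MAT) are declared interfaces only; all
  quantitative claims in this repository are about synthetic data.
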