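# Methods

This note documents the models, procedures and design choices behind
`retinattn`: a tested pipeline that decodes visual stimuli from retinal
ganglion cell (RGC) spike trains with a spike-tokenized latent-attention
network and then interrogates the trained network's attention weights as a
scientific instrument (unit importance, causal ablation, entropy dynamics,
stimulus coupling).

All data are synthetic. The simulator is a first-class, tested component:
it defines the ground truth against which every downstream stage is
validated by parameter recovery.

## Synthetic retinal sessions

### Stimuli

* **Full-field flash** — square-wave luminance, 3 s ON / 3 s OFF, repeated
  for 10 trials (60 s), sampled at 60 Hz. Intensities are normalized to
  [0, 1].
* **Moving ball** — a single 20 s trajectory on a 400×400 px field,
  presented for 10 identical trials, sampled at 60 Hz. The trajectory is
  two independent fractional Brownian motion paths with Hurst exponent
  H = 0.9 (persistent motion), synthesized exactly by Davies–Harte
  circulant embedding of fractional Gaussian noise (O(n log n), exact
  covariance). Raw increments are rescaled so the realized mean
  frame-to-frame speed equals 232 px/s, and the path is folded back into
  the field by reflection at the borders (the experimental ball never
  leaves the screen; the choice of boundary rule is ours). The display
  frame rate is not a physiological parameter here; 60 Hz is the default
  and is configurable.

A rescaled-range (R/S) estimator over log-spaced block sizes is provided to
verify the roughness of generated trajectories; at the default H = 0.9 the
seed-averaged estimate is ≈ 0.90 (individual-trajectory estimates scatter
roughly ±0.06).

### Units

Each unit carries ground-truth labels: polarity (ON / OFF / ON-OFF with a
mixing weight), a sustain parameter s ∈ [0, 1] (0 = transient, 1 =
sustained), response latency, baseline and peak firing rates, a spatial
Gaussian receptive field (center, σ), and an `informative_gain` flag.
Default mixture: 40/35/25% ON/OFF/ON-OFF, s ~ U(0, 1), latency
U(30, 250) ms, baseline U(0.2, 2) Hz, response gain U(25, 50) Hz,
RF σ U(35, 60) px.

Rate models (Hz, evaluated on the frame grid):

* **Flash** — λ(t) = baseline + gain · Σ_onsets w · exp(−(t − onset −
  latency)/τ), with the response truncated at the end of its phase. The
  adaptation constant maps geometrically from the sustain parameter,
  τ(s) = 0.1 s · 300^s, so s = 0 gives a ~100 ms transient and s = 1 an
  effectively constant response over a 3 s phase. ON units respond at ON
  onsets, OFF units at OFF onsets, ON-OFF units at both with weights
  (w, 1 − w).
* **Ball** — λ(t) = baseline + gain · [G(t) * k](t − latency), where
  G(t) = exp(−‖ball(t) − rf_center‖²/2σ²) and k is a causal exponential
  kernel with time constant 0.05 s · 4^s (50–200 ms). The ball kernel is
  deliberately much faster than the flash adaptation constant: retinal
  integration under a moving stimulus operates on the RF-crossing
  timescale, and a seconds-long kernel would erase the spatial information
  the decoding task depends on.

**Planted uninformative units.** A unit with `informative_gain = 0` fires
at a rate matched to the *mean and variance* of the response it would
otherwise have produced, but driven by smoothed intrinsic noise
(Gaussian-filtered white noise, 0.4 s autocorrelation) instead of the
stimulus. This is the property that makes the attention-recovery test
meaningful: informative and uninformative units are statistically
indistinguishable at the single-unit level (rates, variability,
burstiness) and differ only in stimulus coupling, so an importance metric
that separates them must be reading out information content, not firing
statistics. In the planted-recovery condition the informative units' RF
centers tile the field on a jittered grid so that each covers a distinct
region; with fully random placement some planted "informative" units
receive almost no drive and the recovery question is ill-posed.

Spikes are drawn from λ(t) by thinning: candidate events from a
homogeneous Poisson process at the unit's peak rate, accepted with
probability λ(t)/λ_max (λ linearly interpolated between frames), giving
continuous-valued spike times. All stochastic stages take explicit seeds
and are reproducible to the bit.

### What the simulator does not emulate

No electrode geometry, spike sorting artifacts, waveform or LFP structure;
no inter-unit noise correlations; no optics or irradiance modelling; the
ball drive ignores polarity (a bright object on dark background, treated as
excitatory for all units). Passing tests therefore demonstrate that the
analysis machinery is correct and sensitive under controlled conditions —
not that real recordings satisfy the assumptions.

## Light-response features

Computed from the trial-averaged PSTH of the flash session (50 ms bins, one
stimulus period):

* **Flash bias response** fBR = (f_ON − f_OFF)/(f_ON + f_OFF), where f is
  the peak PSTH rate within each phase: +1 pure ON, −1 pure OFF, 0
  balanced.
* **Sustain index** S_i = (f_pref − f̄)/(f_pref + f̄). Both terms are
  expressed as rates — f_pref the peak PSTH rate in the preferred phase
  (the phase containing the global peak; ties go to ON), f̄ the mean rate
  over the whole sequence — so the index is dimensionally consistent and a
  constant-rate unit yields exactly 0, a one-bin burst ≈ 1. Because f_pref
  is a maximum, S_i is structurally non-negative under this convention.
* **Latency** — onset-to-peak time in the preferred phase, reported at the
  center of the peak bin; ties break to the earliest bin.
* **Mean rate** — spike count over the full stimulus duration.

Silent units are flagged (NaN indices), never silently dropped.

## The decoder

A perceiver-style encoder–decoder operating on spike tokens, implemented on
a small reverse-mode autodiff engine written for this package (numpy
arrays; gradients verified against finite differences):

1. each spike becomes one token — a learnable per-unit embedding plus a
   sinusoidal encoding of its continuous time within a 1 s context window
   (periods log-spaced 2 ms – 2 s);
2. one cross-attention block compresses the N_i tokens of window i into L
   learned latents — the attention matrices A_{h,i} ∈ R^{L×N_i} read out
   by the encoder-side analyses;
3. a stack of self-attention blocks refines the latents;
4. one cross-attention block queries the latents from output tokens
   (time encoding + session embedding) — the matrices D_h ∈ R^{M×L} read
   out by the decoder-side analyses;
5. an MLP head maps output tokens to the stimulus features (1-D intensity
   or 2-D ball position).

All attention is captured post-softmax, pre-dropout, in evaluation mode.
Blocks are pre-norm residual; activations are GELU. The full-scale profile
(latent dim 128, L = 64, depth 6, 8 heads × 64, dropout 0.3) is the
configuration default; experiments in the test suite use the scaled-down
profile (latent dim 64, L = 32, depth 2, 4 heads × 16, output grid
20 Hz), which trains in minutes on one CPU.

### Training

AdamW (decoupled weight decay on matrices only) on MSE between predicted
and z-scored target features; learning rate decays by ×0.1 over the final
25% of epochs; the checkpoint with the best validation loss is kept.
Scaled-down profile: lr 10⁻³, 30 epochs (flash) / 150 epochs (ball),
batch 16. Splits are 70/10/20 assigned to non-overlapping temporal blocks
*before* windowing (blocks of one stimulus period for the flash, 4 s for
the ball), so no context window spans a split boundary. Windows tile each
block with stride equal to the window length.

Two regularizers matter beyond the usual dropout:

* **Unit dropout** (scaled profile: 0.25 flash / 0.5 ball): each unit's
  tokens are hidden with fixed probability per training window. This
  models the unit-yield variability of real sessions, makes degradation
  under unit removal graceful (the ablation analyses evaluate exactly this
  regime), and spreads the model's reliance across redundant units instead
  of letting it latch onto an arbitrary sufficient subset.
* **Prediction clipping**: decoded features are clipped to the
  training-target range per dimension. Stimulus features are physically
  bounded (screen size, luminance range); unclipped models extrapolate
  wildly when most of the input population is ablated.

Predictions are evaluated as R² = 1 − SS_res/SS_tot on concatenated test
windows, per output dimension and averaged (ball R² is the mean of x and
y). Fine-tuning to a new session copies the attention core and head,
re-initializes unit/session embeddings, and optionally freezes the core.

### OLE baseline

Ridge regression (α = 0.1, `sklearn`) from per-unit spike counts in
output-grid bins to the stimulus features, fit and evaluated on the same
temporal-block splits as the transformer.

## Attention analyses

* **Spike weights**: w̄_{h,i,k} = (1/L) Σ_j A_{h,i}[j,k] (a probability
  vector over the window's spikes) and ŵ = w̄ · N_i (count-normalized,
  mean 1).
* **Encoder entropy**: E(h,i) = −Σ_k w̄ ln w̄ in nats (0·ln 0 := 0), one
  value per head per 1 s window, stamped at the window end; bounded by
  [0, ln N_i].
* **Head divergence**: pairwise two-sample Kolmogorov–Smirnov tests
  between head entropy distributions (`scipy.stats.ks_2samp`); raw
  p-values plus a Bonferroni column (the correction choice is left to the
  reader; both are reported).
* **Unit importance** I(u): the average per-spike attention a unit's
  spikes receive. The normalization is implemented as the mean over heads
  and over the unit's spike-containing windows of the per-window per-spike
  average; equal per-spike weight implies equal importance regardless of
  firing rate. Units with no spikes get NaN and rank last; ties break by
  unit id.
* **Ablation**: units removed sequentially at inference (their tokens
  dropped; no retraining) in descending I(u) order, versus random removal
  orders (default 20) whose mean ± SD forms the control band; R² on the
  test split is recorded at each step. The top-K at threshold 0.5 is the
  smallest removal count at which R² first drops to ≤ 0.5 (flagged if the
  curve never crosses, or starts below, the threshold).
* **Consensus**: units appearing in the top-K lists of at least half of
  the independently trained seeds. Consensus subsets are compared with the
  population on the four light-response features by K-S tests, with 2-D
  Gaussian-KDE grids exported for joint-distribution plots.
* **Decoder entropy and coupling**: E(h,m) = −Σ_j d ln d per output token
  (bounded by [0, ln L]), correlated per head against the light intensity
  (flash), or against the four rectified trajectory components +X, −X,
  +Y, −Y (ball), assembled into positive- and negative-direction vectors.
  "Displacement" is read as the per-frame position difference (positions
  have an arbitrary origin); correlating against rectified position is
  available behind the `mode="position"` flag. Entropy and stimulus are
  aligned to the output-token grid by linear interpolation.

### Single-model versus multi-seed importance

A well-trained decoder can satisfy the decoding task with a redundant
subset of the informative units; which subset is favored is a seed-level
accident. A single model's I(u) ranking therefore reliably separates the
favored informative units from the noise pool but may leave redundant
informative units in the middle of the ranking. The package's experiment
driver trains several seeds (default 8) and the planted-recovery analysis uses the seed-averaged
importance, which restores the full informative set: at the test suite's
study conditions (60 units, 20% informative) the 3-seed-averaged ranking
places ≥ 80% of the planted units in the top n_informative positions,
while single-seed precision saturates near 0.6.

## Numerical choices and degenerate inputs

* float64 throughout; softmax computed with max-subtraction; 0·ln 0 := 0.
* Empty context windows are skipped with a logged warning; a window left
  empty by ablation predicts the training-set mean (chance level).
* Negative rates are clamped to zero with a logged warning.
* Silent units: NaN physiological indices, NaN importance, ranked last.
* Zero-variance targets make R² undefined; flagged, not fabricated.
* All randomness flows through seeded `numpy` generators; experiment seeds
  are `base_seed + run_index` and are logged in every artifact.

## Problem sizes used by the test suite

The suite runs the full pipeline at desk scale as its own study design:
30–60 units, the standard 60 s flash and 200 s ball protocols, and the
scaled-down model profile; the ball experiment trains three seeds. The
acceptance script regenerates only the closed-form anchors and the Hurst
recovery (20 trajectories), which take seconds.

## Known limitations

* The decoder backend is a compact numpy implementation; it reproduces the
  architecture faithfully but not the throughput of GPU frameworks, so
  full-scale profiles (128-dim, depth 6, 8 heads, 100–400 epochs) are
  configuration options rather than test-suite defaults.
* Attention in a small, well-regularized model on low-noise synthetic data
  stays closer to uniform than in large models on real recordings; unit-
  level structure is present (the recovery and ablation tests measure it)
  but entropy dynamic ranges are compressed relative to real data.
* Rotary time embeddings, used by some spike-token decoders, are
  approximated here by sinusoidal continuous-time encodings; the
  number of output query tokens per window is a free choice (20–30 Hz
  grids here).
* K-S p-values across head pairs are reported raw and Bonferroni-adjusted;
  with few windows the tests are underpowered.
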