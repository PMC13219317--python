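# retinattn

Attention-based decoding and interpretability of retinal population codes.

Retinal ganglion cells (RGCs) encode the visual scene in parallel spike
trains. Modern spike-tokenized transformers can decode stimuli from such
populations with high accuracy, but their value as *scientific
instruments* depends on whether their internal attention weights mean
anything physiologically. `retinattn` is a tested, reusable pipeline for
studying exactly that question on fully synthetic multielectrode-style
recordings: it simulates RGC populations responding to a full-field flash
and to a moving ball with a fractional-Brownian trajectory, decodes the
stimuli with a spike-tokenized latent-attention network, and runs the
complete interpretability stack — attention entropy, head divergence,
unit-importance ranking, attention-guided ablation, cross-seed consensus,
physiological characterization, and decoder–stimulus coupling — against
known ground truth.

It is intended for computational neuroscientists who want a controlled
sandbox for attention-based population decoding: every unit is labeled
(polarity, kinetics, latency, receptive field, informativeness), so every
claim the attention analyses make can be checked by parameter recovery.

## The model in brief

Spikes in 1 s context windows become tokens (unit embedding + sinusoidal
encoding of continuous spike time). An encoder cross-attention compresses
the N_i tokens of window i into L learned latents, producing per-head
matrices A_{h,i} ∈ R^{L×N_i}; self-attention refines the latents; a
decoder cross-attention queries them from output tokens on the stimulus
time grid, producing D_h ∈ R^{M×L}; an MLP head emits the stimulus
features. Trained with AdamW on MSE over temporal-block splits.

The analyses derive, among others:

* spike weights w̄_{h,i,k} = (1/L) Σ_j a^{h,i}_{j,k} and ŵ = w̄·N_i,
* attention entropy E(h,i) = −Σ_k w̄ ln w̄ (nats, 1 Hz resolution),
* unit importance I(u): the average per-spike attention across heads and
  windows — independent of the unit's firing rate,
* ablation curves R²(k) under attention-guided vs. random unit removal,
* flash bias response fBR = (f_ON − f_OFF)/(f_ON + f_OFF), sustain index
  S_i = (f_pref − f̄)/(f_pref + f̄), latency and mean rate per unit,
* decoder-entropy coupling r(head, component) against light intensity or
  rectified motion components (±X, ±Y).

A ridge-regression optimal linear estimator (α = 0.1) on binned rates
provides the linear baseline on identical splits.

See `docs/methods.md` for the full model description, parameter defaults
and design rationale.

## Worked example

Simulate a flash session, train the scaled-down decoder, and inspect the
decoder-attention coupling:

```python
import retinattn as r
from retinattn import decoding, decoder_analysis as da

stim   = r.generate_flash(r.FlashStimulusConfig())          # 3 s ON / 3 s OFF, 10 trials
units  = r.generate_population(30, rng_seed=0)
spikes = r.simulate_spikes(stim, units, rng_seed=1)

mcfg = r.ModelConfig.scaled_down(dropout=0.3)
tcfg = r.TrainConfig.scaled_down(epochs=30, rng_seed=0)
ds   = decoding.build_dataset(spikes, stim, mcfg, tcfg)
dec, curve = decoding.train(ds, mcfg, tcfg)

print("test R2:", dec.evaluate_r2(ds.split("test"))["r2"])
ent = da.decoder_entropy(da.collect_decoder_attention(dec, ds.windows))
print(da.flash_coupling(ent, stim.timestamps, stim.values))
```

Output (one CPU, ~1 minute):

```
test R2: 1.0
   head component         r
0     0     flash -0.372151
1     1     flash -0.287040
2     2     flash -0.302612
3     3     flash -0.406567
```

The square-wave luminance is reconstructed essentially perfectly from the
spikes, and every decoder head's latent-selection entropy is negatively
correlated with the light intensity: the decoder focuses (low entropy)
whenever the field is bright and ON-driven spikes dominate, and broadens
during the OFF phase — the attention dynamics track the stimulus, not just
the loss.

The same workflow runs for the moving ball
(`r.generate_ball_trajectory(r.BallStimulusConfig())`), where the
transformer clearly out-decodes the linear baseline (test R² ≈ 0.65 vs
≈ 0.34 at the suite's study conditions) and the importance ranking
recovers the planted informative subpopulation.

A command-line interface mirrors the common workflows:

```bash
retinattn simulate --stimulus flash --n-units 60 --seed 0 --out session/
retinattn train    --stimulus ball  --seed 0 --epochs 120 --out run/
retinattn run      --seeds 2 --out results/     # full multi-seed experiment
```

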