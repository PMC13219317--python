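import numpy as np
import pytest

import retinattn as r
from retinattn import decoding
from retinattn.pipeline import make_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures()


@pytest.fixture(scope="session")
def flash_stim():
    return r.generate_flash(r.FlashStimulusConfig())


@pytest.fixture(scope="session")
def small_flash_session(flash_stim):
    """A 30-unit flash session used by several analysis tests."""
    units = r.generate_population(30, rng_seed=0)
    spikes = r.simulate_spikes(flash_stim, units, rng_seed=1)
    return units, spikes


@pytest.fixture(scope="session")
def tiny_trained_decoder(flash_stim, small_flash_session):
    """A briefly trained tiny decoder on the flash session (fast, shared)."""
    _, spikes = small_flash_session
    mcfg = r.ModelConfig.scaled_down(latent_dim=32, n_latents=8, depth=1,
                                     n_heads=2, head_dim=8, output_rate=10.0)
    tcfg = r.TrainConfig.scaled_down(epochs=3, rng_seed=0)
    ds = decoding.build_dataset(spikes, flash_stim, mcfg, tcfg)
    dec, curve = decoding.train(ds, mcfg, tcfg)
    return dec, ds, curve


def brute_force_spike_weights(attn: np.ndarray):
    """Independent oracle: direct summation over latents for w̄ and ŵ."""
    h, latents, n = attn.shape
    wbar = np.zeros((h, n))
    for hi in range(h):
        for k in range(n):
            s = 0.0
            for j in range(latents):
                s += attn[hi, j, k]
            wbar[hi, k] = s / latents
    return wbar, wbar * n


def brute_force_entropy(wbar: np.ndarray):
    """Independent oracle: elementwise −Σ p ln p with 0·ln0 = 0."""
    out = np.zeros(wbar.shape[0])
    for hi in range(wbar.shape[0]):
        e = 0.0
        for p in wbar[hi]:
            if p > 0:
                e -= p * np.log(p)
        out[hi] = e
    return out
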