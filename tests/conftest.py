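import numpy as np
import pytest

from triphoton import blindspot as bs
from triphoton import synthetic as syn


@pytest.fixture(scope="session")
def default_scene() -> syn.SyntheticScene:
    """The default 64^3 two-channel scene at the default noise regime."""
    return syn.make_scene(syn.SceneParams(seed=1), syn.NoiseParams(seed=1))


@pytest.fixture(scope="session")
def ripple_scene() -> syn.SyntheticScene:
    """Scene whose residual noise is dominated by line-periodic ripple."""
    noise = syn.NoiseParams(poisson_gain=20.0, gaussian_sigma=2.0,
                            ripple_amplitude=40.0, ripple_period_px=8.0,
                            ripple_phase_jitter=0.15, seed=3)
    return syn.make_scene(syn.SceneParams(seed=3), noise)


@pytest.fixture(scope="session")
def trained_tiny_model():
    """A small blind-spot net briefly trained on a flat noisy volume.

    Used by tests that need a *plausible* denoiser (variance reduction,
    tiling consistency) without paying for full training.
    """
    rng = np.random.default_rng(7)
    vol = (20.0 + rng.normal(0.0, 5.0, size=(24, 48, 48))).astype(np.float32)
    net_cfg = bs.UNet3DConfig(levels=2, base_features=4)
    tr_cfg = bs.N2VTrainConfig(epochs=10, patch_shape=(8, 16, 16),
                               batch_size=2, patches_per_epoch=8,
                               val_patches=2, seed=7)
    model, log = bs.train(vol, net_cfg, tr_cfg)
    return {"model": model, "log": log, "vol": vol}
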