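"""3D blind-spot self-supervised denoising (volumetric Noise2Void).

Self-supervised denoising trains on the very volume to be denoised: a small
fraction of voxels ("blind spots") is masked — each replaced by a randomly
drawn neighbor value — and an encoder-decoder network is optimized to
predict the original values of exactly those voxels.  Because Poisson shot
noise and Gaussian readout noise are independent per voxel, the network can
only learn the locally predictable signal component, so its output is the
denoised volume.  Structured (line-periodic) noise violates that
independence assumption and is handled separately by
:mod:`triphoton.perstruc`; training with a patch depth of 16 slices keeps
the restored structured noise low even without that post-processing.

The network is a 3D U-Net: hierarchically organized encoder blocks of two
(conv3d -> leaky ReLU -> group norm) units, geometric feature growth from
the first level, max-pool downsampling (switching to in-plane-only pooling
once the z-extent would drop below 2), and a mirrored decoder with
nearest-neighbor upsampling and skip concatenation.

Defaults follow the reference training recipe: 2% blind spots, combined
L1+L2 loss, Adam with beta1=0.5, beta2=0.99, lr=1e-3, 16x64x64 patches
augmented by rotation and flipping, 300 epochs.  A desk-scale "small"
preset (3 levels, 8 base features, 16x32x32 patches) trains in minutes on
one CPU and is the configuration the test suite exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam, Conv3d, GroupNorm, LeakyReLU, MaxPool, Upsample
from .volume import Volume, as_array


@dataclass(frozen=True)
class UNet3DConfig:
    levels: int = 5
    base_features: int = 16
    growth: int = 2
    kernel: tuple[int, int, int] = (3, 3, 3)
    norm_groups: int = 8
    negative_slope: float = 0.01
    in_channels: int = 1

    def __post_init__(self):
        if self.levels < 1 or self.base_features < 1 or self.growth < 1:
            raise ValueError("levels, base_features and growth must be >= 1")


@dataclass(frozen=True)
class N2VTrainConfig:
    mask_fraction: float = 0.02
    neighborhood: tuple[int, int, int] = (2, 2, 2)  # half-widths: 5x5x5 window
    loss_weights: tuple[float, float] = (0.5, 0.5)
    lr: float = 1e-3
    betas: tuple[float, float] = (0.5, 0.99)
    epochs: int = 300
    patch_shape: tuple[int, int, int] = (16, 64, 64)
    augment: bool = True
    batch_size: int = 4
    patches_per_epoch: int = 100
    val_patches: int = 4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in (0, 1)")
        w1, w2 = self.loss_weights
        if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


def small_preset() -> tuple[UNet3DConfig, N2VTrainConfig]:
    """Desk-scale configuration: trains in minutes on a single CPU core."""
    net = UNet3DConfig(levels=3, base_features=8)
    train_cfg = N2VTrainConfig(epochs=60, patch_shape=(16, 32, 32),
                               batch_size=2, patches_per_epoch=16)
    return net, train_cfg


@dataclass
class BlindSpotBatch:
    input_patch: np.ndarray
    target_patch: np.ndarray
    mask: np.ndarray  # (n_mask, 3) voxel coordinates


class UNet3D:
    """Volumetric encoder-decoder with skip connections (numpy backend)."""

    def __init__(self, cfg: UNet3DConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        feats = [cfg.base_features * cfg.growth ** i for i in range(cfg.levels)]
        self.enc = []
        c_in = cfg.in_channels
        for i, f in enumerate(feats):
            self.enc.append(self._block(c_in, f, rng, f"enc{i}"))
            c_in = f
        self.dec = []
        for i in range(cfg.levels - 2, -1, -1):
            self.dec.append(self._block(feats[i + 1] + feats[i], feats[i],
                                        rng, f"dec{i}"))
        self.head = Conv3d(feats[0], 1, kernel=(1, 1, 1), rng=rng, name="head")
        self._layers = [l for blk in self.enc + self.dec for l in blk] + [self.head]
        # input normalization, set by the trainer
        self.norm_mean = 0.0
        self.norm_std = 1.0

    def _block(self, c_in, c_out, rng, name):
        cfg = self.cfg
        return [
            Conv3d(c_in, c_out, cfg.kernel, rng, f"{name}.conv0"),
            LeakyReLU(cfg.negative_slope),
            GroupNorm(c_out, cfg.norm_groups, name=f"{name}.gn0"),
            Conv3d(c_out, c_out, cfg.kernel, rng, f"{name}.conv1"),
            LeakyReLU(cfg.negative_slope),
            GroupNorm(c_out, cfg.norm_groups, name=f"{name}.gn1"),
        ]

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self._layers:
            for k, v in getattr(l, "params", {}).items():
                out[f"{getattr(l, 'name', id(l))}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for l in self._layers:
            for k, v in getattr(l, "grads", {}).items():
                out[f"{getattr(l, 'name', id(l))}.{k}"] = v
        return out

    def zero_grad(self) -> None:
        for l in self._layers:
            for v in getattr(l, "grads", {}).values():
                v[...] = 0

    def n_params(self) -> int:
        return sum(v.size for v in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.copy() for k, v in self.parameters().items()}
        d["_norm"] = np.array([self.norm_mean, self.norm_std])
        return d

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in state.items():
            if k == "_norm":
                self.norm_mean, self.norm_std = float(v[0]), float(v[1])
            else:
                params[k][...] = v

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as z:
            self.load_state_dict(dict(z.items()))

    # -- forward / backward ------------------------------------------------
    def _pool_factors(self, z: int, y: int, x: int, strict: bool = True):
        fz = 2 if (z >= 2 and z % 2 == 0) else 1
        if strict:
            for name, v in (("y", y), ("x", x)):
                if v < 2 or v % 2:
                    raise ValueError(
                        f"patch axis {name} (size {v}) too small or odd for the "
                        f"requested number of levels ({self.cfg.levels})")
        return (fz, 2, 2)

    def check_patch(self, shape: tuple[int, int, int]) -> None:
        z, y, x = shape
        for _ in range(self.cfg.levels - 1):
            fz, fy, fx = self._pool_factors(z, y, x)
            z, y, x = z // fz, y // fy, x // fx

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """``x``: (batch, 1, z, y, x) normalized input; returns same shape."""
        self.check_patch(x.shape[2:])
        skips, pools, ups = [], [], []
        h = x.astype(np.float32)
        self._tape = []
        for i, blk in enumerate(self.enc):
            for l in blk:
                h = l.forward(h)
                self._tape.append(("layer", l))
            if i < self.cfg.levels - 1:
                skips.append(h)
                pool = MaxPool(self._pool_factors(*h.shape[2:]))
                h = pool.forward(h)
                self._tape.append(("layer", pool))
        for j, blk in enumerate(self.dec):
            up = Upsample(self._tape_pool_factors(j))
            h = up.forward(h)
            self._tape.append(("layer", up))
            skip = skips[-(j + 1)]
            h = np.concatenate([h, skip], axis=1)
            self._tape.append(("concat", skip.shape[1]))
            for l in blk:
                h = l.forward(h)
                self._tape.append(("layer", l))
        h = self.head.forward(h)
        self._tape.append(("layer", self.head))
        self._skip_grads = [None] * len(skips)
        return h

    def _tape_pool_factors(self, dec_index: int):
        pools = [l for kind, l in self._tape if kind == "layer"
                 and isinstance(l, MaxPool)]
        return pools[-(dec_index + 1)].f

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout.astype(np.float32)
        skip_grads = {}
        pool_stack = []
        # replay the tape in reverse; skip-connection gradients are summed
        # into the gradient at the matching pooling position
        tape = self._tape
        skip_pending = []
        for item in reversed(tape):
            kind, payload = item
            if kind == "concat":
                n_skip = payload
                g, g_skip = g[:, :-n_skip], g[:, -n_skip:]
                skip_pending.append(g_skip)
            else:
                l = payload
                if isinstance(l, MaxPool) and skip_pending:
                    g = l.backward(g)
                    g = g + skip_pending.pop()
                else:
                    g = l.backward(g)
        return g

    def predict_patch(self, patch: np.ndarray) -> np.ndarray:
        """Denoise one (z, y, x) patch (handles normalization)."""
        x = (patch.astype(np.float32) - self.norm_mean) / self.norm_std
        out = self.forward(x[None, None], train=False)[0, 0]
        return out * self.norm_std + self.norm_mean


def build_denoiser(cfg: UNet3DConfig | None = None, seed: int = 0) -> UNet3D:
    """Construct the volumetric blind-spot network."""
    return UNet3D(cfg or UNet3DConfig(), seed=seed)


def sample_blind_spots(patch: np.ndarray, cfg: N2VTrainConfig,
                       rng: np.random.Generator) -> BlindSpotBatch:
    """Mask an exact ``round(mask_fraction * N)`` voxel subset of a patch.

    Each masked voxel is replaced by the value of a uniformly chosen voxel
    within the ``(2w+1)^3`` neighborhood window, excluding the center itself
    (coordinates clamped at the patch border).
    """
    patch = np.asarray(patch)
    n = patch.size
    n_mask = int(round(cfg.mask_fraction * n))
    flat = rng.choice(n, size=n_mask, replace=False)
    coords = np.stack(np.unravel_index(flat, patch.shape), axis=1)
    w = np.asarray(cfg.neighborhood)
    dims = np.asarray(patch.shape)
    offsets = rng.integers(-w, w + 1, size=(n_mask, 3))
    # redraw all-zero offsets (the center is excluded) and offsets leaving
    # the patch, so the replacement source is always a true neighbor
    src = coords + offsets
    bad = (np.all(offsets == 0, axis=1)
           | np.any((src < 0) | (src >= dims), axis=1))
    while bad.any():
        offsets[bad] = rng.integers(-w, w + 1, size=(int(bad.sum()), 3))
        src = coords + offsets
        bad = (np.all(offsets == 0, axis=1)
               | np.any((src < 0) | (src >= dims), axis=1))
    inp = patch.copy()
    inp[coords[:, 0], coords[:, 1], coords[:, 2]] = \
        patch[src[:, 0], src[:, 1], src[:, 2]]
    return BlindSpotBatch(input_patch=inp, target_patch=patch, mask=coords)


def n2v_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray,
             weights: tuple[float, float] = (0.5, 0.5)):
    """Combined L1+L2 loss over blind-spot voxels only.

    Returns ``(loss, grad_wrt_pred)``; the gradient is zero off-mask.
    """
    w1, w2 = weights
    mz, my, mx = mask[:, 0], mask[:, 1], mask[:, 2]
    d = pred[mz, my, mx] - target[mz, my, mx]
    n = len(d)
    loss = w1 * np.abs(d).mean() + w2 * (d ** 2).mean()
    grad = np.zeros_like(pred, dtype=np.float32)
    grad[mz, my, mx] = (w1 * np.sign(d) + 2 * w2 * d) / n
    return float(loss), grad


def _augment(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    for ax in range(3):
        if rng.random() < 0.5:
            patch = np.flip(patch, axis=ax)
    if patch.shape[1] == patch.shape[2]:
        k = int(rng.integers(0, 4))
        if k:
            patch = np.rot90(patch, k=k, axes=(1, 2))
    return np.ascontiguousarray(patch)


def _random_patch(vol: np.ndarray, shape, rng) -> np.ndarray:
    starts = [int(rng.integers(0, vol.shape[i] - shape[i] + 1))
              for i in range(3)]
    sl = tuple(slice(s, s + d) for s, d in zip(starts, shape))
    return vol[sl]


def train(vol, net_cfg: UNet3DConfig | None = None,
          train_cfg: N2VTrainConfig | None = None,
          verbose: bool = False) -> tuple[UNet3D, pd.DataFrame]:
    """Self-supervised training on a single noisy volume.

    Returns the trained model (parameters from the epoch with the best
    held-out blind-spot loss) and a per-epoch log with columns
    ``epoch, train_loss, val_loss``.  Raises ``FloatingPointError`` if the
    loss turns non-finite.
    """
    net_cfg = net_cfg or UNet3DConfig()
    train_cfg = train_cfg or N2VTrainConfig()
    a = np.asarray(as_array(vol), dtype=np.float32)
    if a.ndim != 3:
        raise ValueError("train expects a single 3D (z,y,x) volume")
    ps = train_cfg.patch_shape
    if any(a.shape[i] < ps[i] for i in range(3)):
        raise ValueError(f"patch_shape {ps} does not fit volume shape {a.shape}")

    mean, std = float(a.mean()), float(a.std())
    std = std if std > 0 else 1.0
    an = (a - mean) / std

    rng = np.random.default_rng(train_cfg.seed)
    model = UNet3D(net_cfg, seed=int(rng.integers(2 ** 31)))
    model.check_patch(ps)
    model.norm_mean, model.norm_std = mean, std
    opt = Adam(model.parameters(), lr=train_cfg.lr, betas=train_cfg.betas)

    # fixed held-out blind-spot set for early-model selection
    val = [sample_blind_spots(_random_patch(an, ps, rng), train_cfg, rng)
           for _ in range(train_cfg.val_patches)]

    def val_loss() -> float:
        tot = 0.0
        for b in val:
            pred = model.forward(b.input_patch[None, None], train=False)[0, 0]
            l, _ = n2v_loss(pred, b.target_patch, b.mask, train_cfg.loss_weights)
            tot += l
        return tot / len(val)

    n_batches = max(train_cfg.patches_per_epoch // train_cfg.batch_size, 1)
    best = (np.inf, model.state_dict(), 0)
    rows = []
    for epoch in range(1, train_cfg.epochs + 1):
        ep_loss = 0.0
        for _ in range(n_batches):
            batches = []
            for _ in range(train_cfg.batch_size):
                p = _random_patch(an, ps, rng)
                if train_cfg.augment:
                    p = _augment(p, rng)
                batches.append(sample_blind_spots(p, train_cfg, rng))
            x = np.stack([b.input_patch for b in batches])[:, None]
            pred = model.forward(x)
            grad = np.zeros_like(pred)
            loss = 0.0
            for i, b in enumerate(batches):
                li, gi = n2v_loss(pred[i, 0], b.target_patch, b.mask,
                                  train_cfg.loss_weights)
                loss += li
                grad[i, 0] = gi
            loss /= len(batches)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            model.zero_grad()
            model.backward(grad / len(batches))
            opt.step(model.gradients())
            ep_loss += loss
        vl = val_loss()
        rows.append({"epoch": epoch, "train_loss": ep_loss / n_batches,
                     "val_loss": vl})
        if vl < best[0]:
            best = (vl, model.state_dict(), epoch)
        if verbose:
            print(f"epoch {epoch:4d}  train {ep_loss / n_batches:.5f}  val {vl:.5f}")
    model.load_state_dict(best[1])
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = best[2]
    return model, log


def denoise(model: UNet3D, vol, tile_shape=(16, 64, 64),
            overlap=(4, 16, 16)):
    """Tiled inference over an arbitrarily sized volume.

    Tiles overlap and are blended with per-axis triangular ramp weights, so
    seams cancel; a volume equal to one tile reduces to a direct forward
    pass.  Output shape and metadata match the input.
    """
    a = np.asarray(as_array(vol), dtype=np.float32)
    tile = tuple(min(t, s) for t, s in zip(tile_shape, a.shape))
    # tiles must survive the network's pooling: pad each axis to a multiple
    mult = 2 ** (model.cfg.levels - 1)
    step = tuple(max(t - o, 1) for t, o in zip(tile, overlap))

    out = np.zeros(a.shape, dtype=np.float64)
    wsum = np.zeros(a.shape, dtype=np.float64)

    def ramp(n, ov):
        w = np.ones(n)
        e = min(ov, n - 1)
        if e > 0:
            r = (np.arange(e) + 1.0) / (e + 1.0)
            w[:e] = np.minimum(w[:e], r)
            w[-e:] = np.minimum(w[-e:], r[::-1])
        return w

    starts = [list(range(0, max(a.shape[i] - tile[i], 0) + 1, step[i]))
              for i in range(3)]
    for i in range(3):
        last = a.shape[i] - tile[i]
        if starts[i][-1] != last:
            starts[i].append(last)

    single = all(len(s) == 1 for s in starts)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + tile[0]), slice(y0, y0 + tile[1]),
                      slice(x0, x0 + tile[2]))
                patch = a[sl]
                pshape = patch.shape
                # only (y, x) must be divisible through all pooling levels;
                # z pooling switches off automatically on odd/small extents
                pad = [(0, 0),
                       (0, (-pshape[1]) % mult),
                       (0, (-pshape[2]) % mult)]
                padded = np.pad(patch, pad, mode="reflect") \
                    if any(p[1] for p in pad) else patch
                pred = model.predict_patch(padded)
                pred = pred[:pshape[0], :pshape[1], :pshape[2]]
                if single:
                    w = np.ones(pshape)
                else:
                    w = (ramp(pshape[0], overlap[0])[:, None, None]
                         * ramp(pshape[1], overlap[1])[None, :, None]
                         * ramp(pshape[2], overlap[2])[None, None, :])
                out[sl] += pred * w
                wsum[sl] += w
    result = (out / wsum).astype(np.float32)
    if isinstance(vol, Volume):
        return vol.with_data(result, op="n2v_denoise",
                             tile_shape=list(tile), overlap=list(overlap))
    return result
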