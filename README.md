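# triphoton

Denoising, demixing and morphometry for deep three-photon microscopy
(3PM) volumes.

Deep 3PM records brain tumors through two channels — fluorescence (mGFP-
labeled tumor cells with their thin microtubes) and the label-free
third-harmonic-generation (THG) signal, which highlights blood vessels and
myelinated fiber bundles. At depth, frames are dominated by Poisson shot
noise and Gaussian readout noise, plus a line-wise periodic "ripple"
artifact that line scanning folds out of the detector electronics. This
package implements the computational workflow around such acquisitions,
for imaging scientists who want a tested, seed-reproducible reference
implementation:

* **`triphoton.synthetic`** — phantom scenes (tubular vessels, parallel
  myelin bundles, somata + microtube-like processes) with exact
  ground-truth labels, corrupted by the full noise model
  `Poisson(g·clean)/g + N(0, σ) + A·sin(2πx/T + φ(z, r))`, with per-line
  phase drift and bidirectional-scan mirroring.
* **`triphoton.perstruc`** — deterministic removal of the periodic
  structured noise: flip odd rows, pick the lowest-std row as phase
  reference, estimate the dominant spectral bin, align every line by an
  integer circular shift, extract the pure noise line by double median
  projection, subtract, undo, smooth (σ = 1 px along rows), restore the
  median.
* **`triphoton.blindspot`** — self-supervised 3D blind-spot denoising: a
  volumetric U-Net (pure numpy, hand-written backprop, bit-reproducible)
  trained on the noisy volume itself by masking 2% of voxels and
  predicting them from context, with an L1+L2 loss and Adam
  (β₁ = 0.5, β₂ = 0.99, lr = 1e-3).
* **`triphoton.demix`** — two-stage autocontext random-forest
  classification of the THG channel into vessel / myelin / background
  over a multiscale 3D feature bank (σ up to 6), with the denoised image
  as a prediction mask and per-voxel uncertainty
  `u = 1 − (pMax1 − pMax2)`.
* **`triphoton.morphometry`** — SNR (dB), structure-tensor orientation /
  energy / coherency, energy-filtered network orientation statistics,
  polarity angles, circularity (Crofton perimeter), somatokinesis speed
  and MSD, skeleton-based fiber angles near a cell, the THG→FITC vessel
  diameter correction (×1.248373), extravascular intensity, hole-shape
  analysis, and integer drift correction.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Remove structured noise from a phantom whose residual noise is dominated
by detector ripple (amplitude 40 vs structure intensities 50–60, period
8 px, drifting phase, bidirectional scan):

```python
import numpy as np
from triphoton import synthetic as syn, perstruc as ps, morphometry as mm

noise = syn.NoiseParams(poisson_gain=20.0, gaussian_sigma=2.0,
                        ripple_amplitude=40.0, ripple_period_px=8.0,
                        ripple_phase_jitter=0.15, seed=1)
scene = syn.make_scene(syn.SceneParams(seed=1), noise)
vol = scene.noisy_thg.data

out, est = ps.perstruc_denoise(vol, return_estimate=True)

sig, bg = scene.thg_signal_mask, scene.background_mask
k = est.main_freq_bin
supp = ps.row_power_spectrum(vol)[k] / ps.row_power_spectrum(out)[k]
print(f"main ripple frequency bin : {est.main_freq_bin} (period {est.period_px} px)")
print(f"reference row (z, y)      : {est.reference_row}")
print(f"SNR before / after        : {mm.snr_db(vol, sig, bg):.2f} dB / "
      f"{mm.snr_db(out, sig, bg):.2f} dB")
print(f"power suppression at peak : {supp:.1f}x")
```

prints

```
main ripple frequency bin : 8 (period 8 px)
reference row (z, y)      : (48, 50)
SNR before / after        : 6.16 dB / 19.55 dB
power suppression at peak : 34.5x
```

The detector ripple (period 64 px / bin 8 = 8 px, as simulated) has been
located, phase-aligned and subtracted: +13.4 dB of SNR on ground-truth
masks and a 34× reduction of the spectral peak, while the volume's median
intensity is preserved exactly. Training the blind-spot denoiser on the
default low-signal phantom (raw SNR ≈ 5 dB) is one call more —
`model, log = blindspot.train(vol, *blindspot.small_preset())` — and adds
≈ 14 dB on the same masks in a few minutes of CPU time.

The same stages are available from the shell:

```sh
triphoton simulate --config scene.yaml --out scene/ --seed 1
triphoton denoise-perstruc scene/thg.tif thg_ps.tif --report spectrum.csv
triphoton denoise-n2v thg_ps.tif thg_dn.tif --small --seed 1
triphoton classify --raw scene/thg.tif --denoised thg_dn.tif \
    --labels labels.csv --out probs.tif --uncertainty unc.tif
triphoton quantify snr thg_dn.tif scene/labels.tif
```

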