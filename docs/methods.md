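# Methods

This note documents the models, algorithms and numerical choices behind
`triphoton`, and what its synthetic-data tests do and do not demonstrate
about real deep three-photon microscopy (3PM) data.

## The problem

Deep 3PM of brain tumors produces two channels: a fluorescence channel
(membrane-GFP tumor cells with thin, neurite-like microtubes) and the
label-free third-harmonic-generation (THG) channel, in which blood vessels
and myelinated axon bundles dominate. At depth, excitation power is kept
low to avoid photodamage, so raw frames are dominated by Poisson shot
noise and Gaussian detector readout noise, plus a *structured* component:
periodic ripple from the photomultiplier electronics, which line scanning
folds into a row-wise periodic pattern whose phase drifts from line to
line and mirrors on odd rows under bidirectional scanning. The package
implements the computational half of that workflow: simulation of such
acquisitions with ground truth, removal of both noise types, demixing of
the THG channel into vessel / myelin / background, and the downstream
morphometric quantifications.

## Synthetic scenes (`triphoton.synthetic`)

Phantoms rasterize the three structure classes with physically motivated
sizes (units: micrometres, converted through an explicit `(z, y, x)` voxel
size):

* **vessels** — smooth 3D tubes (cubic splines through random control
  points), radius 2–4 µm;
* **myelinated fibers** — straight, mutually parallel cylinders of radius
  1.25 µm running in small bundles of 3 (axons in white matter travel in
  bundles; the bundle count and the in-plane angle are parameters);
* **tumor cells** — ellipsoidal somata (radius 4–6 µm) plus curvilinear
  processes of 10–30 µm length and 0.25–1.25 µm radius, i.e.
  microtube-like protrusions.

Classes are disjoint (precedence vessel > myelin > cell); vessel and
myelin intensity is placed in the THG channel, cell intensity in the
fluorescence channel, so the label grid partitions the volume and every
downstream stage can be scored against exact ground truth.

The noise model is `Poisson(gain·clean)/gain + N(0, σ) + ripple`, with the
ripple for row *r* of slice *z* equal to `A·sin(2πx/period + φ(z,r))`,
`φ` accumulating a Gaussian per-line increment (inconsistent scanning
speed) and the pattern reversed on odd rows (bidirectional scanning). An
optional first harmonic and exponential depth attenuation are available
and off by default. The default regime — intensities 50–60, `σ = 34`,
`gain = 0.5` photons/unit, no ripple — places the raw amplitude SNR at
about 5 dB on ground-truth masks, the low-signal regime of deep imaging.
The ripple frequency and amplitude of the real instrument are not
published; the simulator's defaults (period 8 px, amplitude configurable)
are free parameters recorded in every scene sidecar.

What the phantoms do **not** model: the optical point-spread function,
aberrations, depth-dependent scattering structure, vascular pulsation, or
any real tissue texture. Passing tests therefore demonstrate algorithmic
correctness under the stated noise model, not end-to-end performance on
tissue.

## Structured-noise removal (`triphoton.perstruc`)

Deterministic, no randomness anywhere: flip odd rows to a common scan
direction → choose the row with the lowest standard deviation as phase
reference (the clearest view of the pure ripple) → find the dominant
non-DC bin of the row-averaged power spectrum (rows mean-detrended; bins
0–1 excluded as slow gradients, configurable) → per line, convert the
phase difference at that bin to an integer circular shift
(`round(Δφ/2π · N/k)`; integer shifts keep values exact and make
un-shifting lossless) → align, median-project across rows and then across
slices to extract the single-line noise profile → subtract, un-align,
un-flip → 1D Gaussian along each row (σ = 1 px, truncated at 4σ, reflect
boundary) → restore the original global median.

Two guards added by this implementation:

* **Peak prominence.** Phase-aligning rows of pure white noise would
  itself synthesize a coherent sinusoid at the chosen bin, and the median
  would then subtract a spurious ripple of roughly the per-row noise
  amplitude. The pipeline therefore subtracts only when the candidate
  bin's row-averaged power exceeds 3× the median non-DC power
  (configurable); otherwise it applies only the smoothing and median
  steps. The structured noise this method targets exceeds that threshold
  by orders of magnitude.
* Volumes whose row length is shorter than two ripple periods are
  rejected (alignment is then ill-posed).

Quantization limits: integer shifts leave up to ±0.5 px of phase error,
which bounds the attainable suppression at the main bin to roughly 10–20×
for an 8-px period before smoothing; the σ=1 Gaussian adds another ~2×.
On the ripple-dominated phantom (amplitude 40 vs structure intensity
50–60, σ = 2) the measured SNR gain is ~13 dB with ~35× peak suppression.

## Blind-spot denoising (`triphoton.blindspot`, `triphoton.nn`)

Self-supervised volumetric Noise2Void: 2% of patch voxels are masked —
each replaced by a uniformly drawn neighbor from a 5×5×5 window, center
excluded (offsets are rejection-sampled so border replacements are still
true neighbors) — and a 3D U-Net is trained to predict the original
values at exactly those voxels with a combined loss
`0.5·L1 + 0.5·L2` (the ratio is a free choice) over the masked voxels
only. Because shot and readout noise are voxel-independent, the network
can only learn the locally predictable signal. The optimizer is Adam with
β₁ = 0.5, β₂ = 0.99, lr = 1e-3; patches are augmented by axis flips and
in-plane 90° rotations. Model selection uses a fixed held-out set of
masked patches.

The network is a 3D U-Net: per level two (conv3×3×3 → leaky-ReLU(0.01) →
group-norm) units, feature counts growing geometrically from the first
level, window-2 max-pool downsampling that switches to in-plane-only
pooling when the z-extent would drop below 2 (required to fit deep
hierarchies on 16-slice patches), and a mirrored decoder with
nearest-neighbor upsampling and skip concatenation. The reference
configuration is 5 levels / 16 base features / 300 epochs on 16×64×64
patches; the tested **small preset** is 3 levels / 8 base features,
16×32×32 patches, batch 2, 16 patches per epoch, 60 epochs — it trains in
a few minutes on one CPU core and reaches the converged regime on the
default phantom (held-out loss plateaus in the last third of training).

The whole network stack is a self-contained numpy implementation:
im2col convolutions through BLAS matmuls, hand-written backward passes
(verified against finite differences in the test suite), and a numpy
Adam. It is exactly reproducible from a seed.

**Tiled inference and group norm.** Inference tiles large volumes with
overlap and blends with triangular ramp weights (a partition of unity;
verified exact against a pointwise stub model). Because group
normalization ties every output voxel to whole-tile statistics, different
tilings of the same volume agree only to within a few percent of the data
range — an architectural property, not a blending artifact. Seams are
invisible at converged-model smoothness; applications needing bit-stable
output should fix one tiling.

Measured on the default 64³ phantom (raw SNR ≈ 4.8 dB), the small preset
delivers ≈ 14 dB SNR gain on ground-truth masks. Training with 16-deep
patches restores less structured noise than 4-deep patches on a
ripple-bearing phantom (z-context cannot predict in-row phase), matching
the motivation for the 16-slice patch depth.

## THG demixing (`triphoton.demix`)

Two-stage autocontext pixel classification into vessel (1), myelin (2),
background (3):

* **Features**: raw intensity plus, per scale
  σ ∈ {0.7, 1.0, 1.6, 3.5, 5.0, 6.0} (capped at 6), Gaussian smoothing;
  gradient magnitude, Laplacian, difference of Gaussians; the three
  structure-tensor and three Hessian eigenvalues — all computed in 3D
  with reflect boundaries.
* **Stage 1**: random forest (100 trees, √-features per split, seeded) on
  the feature bank at sparse label coordinates. **Stage 2**: a second
  forest on the same bank concatenated with the stage-1 class probability
  maps smoothed at the same scale set; spatial context corrects isolated
  stage-1 errors, and the mean uncertainty drops from stage 1 to stage 2.
* **Prediction mask**: classification runs on the (optionally z-upsampled,
  bilinear, factor 4) raw stack, but voxels outside the denoised image's
  foreground (Otsu threshold, one dilation; an explicit mask can override)
  are forced to background with probability 1, suppressing noise-induced
  false positives.
* **Uncertainty**: `u = 1 − (pMax1 − pMax2)` with `pMax1 ≥ pMax2` the two
  largest class probabilities; ties give exactly 1. (The ordering is
  enforced regardless of input order.)
* **Feature ranking**: one-vs-rest absolute standardized mean difference,
  averaged over classes — a self-contained marker-score replacing an
  external marker-finding routine; the embedding/visualization step is
  out of scope.

Parameter recovery on the THG phantom at the default 5 dB regime reaches
F1 ≈ 0.96 (vessel) / 0.89 (myelin) with two annotation rounds: a sparse
stratified first round (boundary-aware background labels, as an annotator
would draw) and a second round placed at the classifier's own
highest-uncertainty voxels — the interactive-labeling loop this workflow
is designed around. Thin isolated fibers at 1 µm isotropic sampling cap
myelin F1 near 0.8 because the boundary ring exceeds the core area; the
classification fixtures therefore use the instrument-realistic 0.5 µm
in-plane pixel size.

## Morphometry (`triphoton.morphometry`)

Conventions: 0-based `(z, y, x)` coordinates; in-plane angles measured
from the +x axis, reported on the axial range [−90°, 90°) (wrapping is
idempotent); physical units always via explicit voxel size.

* **SNR**: `20·log10(mean(signal)/std(background))` in dB, masks from
  ground truth (synthetic) or an Otsu split (real data); gains are dB
  differences. Amplitude SNR was chosen because it is scale-invariant and
  directly testable on synthetic ground truth.
* **Orientation**: 2D structure tensor with Gaussian-derivative gradients
  (σ = 0.8, a small spline-like derivative; σ = 1 over-smooths and
  inflates the coherency of pure noise) and a σ = 3 px tensor window;
  θ = ½·atan2(−2Jxy, Jyy−Jxx), energy = trace, coherency =
  (λ₁−λ₂)/(λ₁+λ₂). Recovery on rasterized stripes is within ±0.1°; the
  test bound is ±2°.
* **Energy filter**: keep samples with energy strictly greater than
  mean + population std; with all energies equal nothing survives, and
  the selection is shift-invariant. Homogeneously textured images
  therefore yield empty selections by design — the filter expects sparse
  structures on background.
* **Orientation spread**: linear std of wrapped values (matching a
  spreadsheet-style workflow); a circular (doubled-angle) version is
  available via `circular=True`. Uniform orientations give 180/√12 ≈
  51.96°.
* **Circularity**: `4π·Area/Perimeter²` with the Crofton perimeter
  estimate (a rasterized disk scores ≈ 0.99; the naive pixel-edge count
  would bias low by ~10%); degenerate zero-perimeter regions score 1 by
  convention. Validated against the Ramanujan ellipse perimeter.
* **Somatokinesis**: first-to-last 3D centroid displacement over elapsed
  time (µm/h) — a translocation measure; closed paths score 0.
* **MSD**: origin-anchored, `MSD(τ) = mean_cells |x(t₀+τ) − x(t₀)|²`,
  SEM across cells. Ballistic motion reproduces (vτ)² exactly; the
  isotropic random walk reproduces 3s²·(τ/dt), checked at the curve level
  (the per-lag estimator at 1000 cells has ~2.6% standard deviation and
  lags are strongly correlated, so a pointwise maximum test would fail
  for about half of all seeds regardless of correctness).
* **Fiber angles near a cell**: dilate the cell by 5 µm (Euclidean
  distance transform, anisotropy-aware), intersect with the fiber mask,
  skeletonize, delete branch points (≥3 neighbors), drop segments of ≤4
  pixels, take each segment's direction from its two extremal endpoints,
  and report angles relative to the cell's major axis.
* **Vessel diameter**: THG-measured diameters are multiplied by the
  empirical THG→FITC factor 1.248373.
* **Extravascular intensity**: mean outside the vessel mask normalized to
  the whole-region mean — monotone in simulated leakage.
* **Hole analysis**: connected components of the THG-signal complement in
  a region of interest, each flagged by tumor-mask overlap and scored by
  circularity.
* **Drift correction**: per-frame integer offset to frame 0 by phase
  cross-correlation, applied with edge padding.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; scenes, training runs and
classifications are bit-reproducible from (parameters, seed). The tested
problem sizes are 64³ phantoms for denoising (a size at which the small
preset trains in minutes on one CPU core), 24×64×64 for classification,
and 32×48×48 for the patch-depth comparison; the paper-scale network
preset is available but not exercised by the default suite. The
acceptance script (`scripts/acceptance.py`) regenerates all inputs from
its `--seed` and recomputes every reported number at run time.

## Known limitations

* No PSF/optics model; noise is voxel-independent by construction except
  for the explicit ripple term.
* The structured-noise remover assumes a single dominant ripple frequency
  per volume and integer-pixel alignment; multi-component or sub-pixel
  drifting patterns are only attenuated.
* Group normalization makes tiled inference tile-dependent at the
  few-percent level (see above).
* The classifier's reported recovery uses phantom annotations; real
  annotation noise and class ambiguity (e.g. vessel walls vs myelin) are
  not modeled.
* Hypothesis testing, 3D rendering, and registration beyond integer
  drift correction are out of scope.
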