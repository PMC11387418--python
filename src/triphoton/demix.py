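"""Demixing of the label-free THG channel into vessel / myelin / background.

The third-harmonic-generation channel carries several structures at once —
blood vessels and myelinated fiber bundles on a noisy background.  This
module separates them with a two-stage "autocontext" pixel classification:
stage 1 is a random forest over a multiscale 3D feature bank (intensity
smoothing, edge and texture features up to sigma = 6); stage 2 is a second
forest whose inputs additionally include the smoothed stage-1 class
probability maps, which lets spatial context correct isolated stage-1
errors on noisy data.  Prediction runs on the (z-upsampled) raw stack but
uses the denoised stack as a prediction mask: voxels outside the denoised
foreground are forced to background, limiting noise-induced false
positives.

Class codes follow the segmentation convention used throughout the
package: vessel = 1, myelin = 2, background = 3.  Per-voxel classifier
uncertainty is ``1 - (pMax1 - pMax2)`` with ``pMax1 >= pMax2`` the two
largest class probabilities: near-tied predictions give uncertainty near 1,
confident ones near 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters
from sklearn.ensemble import RandomForestClassifier

from .volume import Volume, as_array

CLASSES = (1, 2, 3)  # vessel, myelin, background
DEFAULT_SCALES = (0.7, 1.0, 1.6, 3.5, 5.0, 6.0)


def upsample_z(vol, factor: int = 4):
    """Linearly interpolate between z-slices; (y, x) untouched.

    The output has ``factor * nz`` slices whose positions span the original
    slice range end to end (``linspace(0, nz-1, factor*nz)``).
    """
    a = np.asarray(as_array(vol))
    if factor == 1:
        out = a.copy()
    else:
        nz = a.shape[0]
        pos = np.linspace(0.0, nz - 1.0, nz * factor)
        i0 = np.floor(pos).astype(int)
        i1 = np.minimum(i0 + 1, nz - 1)
        frac = (pos - i0).astype(a.dtype if np.issubdtype(a.dtype, np.floating)
                                 else np.float64)
        out = (a[i0] * (1 - frac)[:, None, None]
               + a[i1] * frac[:, None, None]).astype(np.float32)
    if isinstance(vol, Volume):
        vz, vy, vx = vol.voxel_size_um
        res = Volume(out.astype(np.float32), voxel_size_um=(vz / factor, vy, vx),
                     channel=vol.channel, provenance=list(vol.provenance))
        return res.log("upsample_z", factor=factor)
    return out


@dataclass
class FeatureStack:
    """Per-voxel feature vectors: ``data`` is (n_features, z, y, x)."""

    data: np.ndarray
    names: list[str]

    def __post_init__(self):
        if len(self.names) != self.data.shape[0]:
            raise ValueError("one name per feature plane required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def matrix(self) -> np.ndarray:
        """Features as an (n_voxels, n_features) design matrix."""
        return self.data.reshape(self.n_features, -1).T

    def at(self, coords: np.ndarray) -> np.ndarray:
        """Feature vectors at (n, 3) voxel coordinates."""
        return self.data[:, coords[:, 0], coords[:, 1], coords[:, 2]].T


def compute_features(vol, scales=DEFAULT_SCALES) -> FeatureStack:
    """Deterministic multiscale 3D feature bank.

    Per scale sigma: Gaussian smoothing; gradient magnitude, Laplacian and
    difference of Gaussians (edges); the three structure-tensor and three
    Hessian eigenvalues (texture).  The raw intensity is included as the
    first feature.  All features are computed in 3D.
    """
    a = np.asarray(as_array(vol), dtype=np.float32)
    planes = [a.copy()]
    names = ["raw"]
    for s in scales:
        g = ndimage.gaussian_filter(a, s)
        planes.append(g)
        names.append(f"gauss_s{s:g}")
        planes.append(ndimage.gaussian_gradient_magnitude(a, s))
        names.append(f"gradmag_s{s:g}")
        planes.append(ndimage.gaussian_laplace(a, s))
        names.append(f"laplace_s{s:g}")
        planes.append(g - ndimage.gaussian_filter(a, 0.66 * s))
        names.append(f"dog_s{s:g}")
        st = skfeature.structure_tensor(a, sigma=s, order="rc",
                                        mode="reflect")
        st_eig = skfeature.structure_tensor_eigenvalues(st)
        for i in range(3):
            planes.append(st_eig[i])
            names.append(f"st_eig{i}_s{s:g}")
        hm = skfeature.hessian_matrix(a, sigma=s, order="rc", mode="reflect",
                                      use_gaussian_derivatives=True)
        h_eig = skfeature.hessian_matrix_eigvals(hm)
        for i in range(3):
            planes.append(h_eig[i])
            names.append(f"hess_eig{i}_s{s:g}")
    data = np.stack(planes).astype(np.float32)
    if not np.all(np.isfinite(data)):
        raise FloatingPointError("non-finite value in feature stack")
    return FeatureStack(data=data, names=names)


def _coerce_labels(labels, shape) -> np.ndarray:
    """Accept (n, 4) rows of (z, y, x, class); validate bounds and classes."""
    arr = np.asarray(labels, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("sparse labels must be (n, 4) rows of (z, y, x, class)")
    coords, cls = arr[:, :3], arr[:, 3]
    if np.any(coords < 0) or np.any(coords >= np.asarray(shape)):
        raise ValueError("label coordinates out of bounds")
    if not np.all(np.isin(cls, CLASSES)):
        raise ValueError(f"classes must be in {CLASSES}")
    if len(np.unique(cls)) < 2:
        raise ValueError("training labels must cover at least 2 classes")
    return arr


@dataclass
class AutocontextBundle:
    """Both forest stages plus the feature configuration used to train them."""

    stage1: RandomForestClassifier
    stage2: RandomForestClassifier
    scales: tuple
    feature_names: list[str] = field(default_factory=list)


def _proba_full(rf: RandomForestClassifier, X: np.ndarray,
                shape) -> np.ndarray:
    """(3, z, y, x) probability grid with zero planes for absent classes."""
    p = rf.predict_proba(X)
    out = np.zeros((len(CLASSES), X.shape[0]), dtype=np.float32)
    for j, c in enumerate(rf.classes_):
        out[int(c) - 1] = p[:, j]
    return out.reshape((len(CLASSES),) + tuple(shape))


def _stage2_stack(base: FeatureStack, prob: np.ndarray,
                  scales) -> FeatureStack:
    names = list(base.names)
    extra = []
    for ci in range(prob.shape[0]):
        for s in scales:
            extra.append(ndimage.gaussian_filter(prob[ci], s))
            names.append(f"prob{ci + 1}_s{s:g}")
    data = np.concatenate([base.data, np.stack(extra).astype(np.float32)])
    return FeatureStack(data=data, names=names)


def train_autocontext(raw_up, labels, stages: int = 2, seed: int = 0,
                      scales=DEFAULT_SCALES, n_trees: int = 100
                      ) -> AutocontextBundle:
    """Train the two-stage pixel classifier from sparse labels.

    ``labels`` are (n, 4) rows of ``(z, y, x, class)`` with class in
    {vessel=1, myelin=2, background=3}; at least two classes must be
    present.  Both forests use ``n_trees`` trees with sqrt-feature splits
    and are fully seeded, so identical inputs give identical forests.
    """
    if stages != 2:
        raise ValueError("autocontext is defined here with exactly 2 stages")
    a = np.asarray(as_array(raw_up), dtype=np.float32)
    lab = _coerce_labels(labels, a.shape)
    coords, y = lab[:, :3], lab[:, 3]

    fs1 = compute_features(a, scales)
    rf1 = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 random_state=seed, n_jobs=1)
    rf1.fit(fs1.at(coords), y)

    prob1 = _proba_full(rf1, fs1.matrix(), a.shape)
    fs2 = _stage2_stack(fs1, prob1, scales)
    rf2 = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 random_state=seed + 1, n_jobs=1)
    rf2.fit(fs2.at(coords), y)
    return AutocontextBundle(stage1=rf1, stage2=rf2, scales=tuple(scales),
                             feature_names=fs2.names)


@dataclass
class ProbabilityMap:
    """Per-voxel class probabilities; ``probs`` is (3, z, y, x), classes 1..3."""

    probs: np.ndarray
    classes: tuple = CLASSES

    def __post_init__(self):
        s = self.probs.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("per-voxel probabilities must sum to 1")

    @property
    def argmax_class(self) -> np.ndarray:
        """Most probable class code per voxel."""
        return np.asarray(self.classes, dtype=np.uint8)[
            self.probs.argmax(axis=0)]

    def uncertainty_map(self) -> np.ndarray:
        return uncertainty(self.probs)


def uncertainty(probs) -> np.ndarray:
    """Classifier uncertainty ``1 - (pMax1 - pMax2)``.

    ``pMax1 >= pMax2`` are the two largest class probabilities of a voxel
    (ties give uncertainty exactly 1).  Accepts a ProbabilityMap, a
    (K, ...) probability grid, or a 1D probability vector; returns the same
    spatial shape.
    """
    if isinstance(probs, ProbabilityMap):
        probs = probs.probs
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim == 1:
        p = p[:, None]
        squeeze = True
    else:
        squeeze = False
    part = np.sort(p, axis=0)
    u = 1.0 - (part[-1] - part[-2])
    return float(u[0]) if squeeze and u.size == 1 else u


def foreground_mask(denoised_up, dilate: int = 1) -> np.ndarray:
    """Prediction mask from a denoised volume: Otsu threshold + dilation.

    A constant volume has no foreground.
    """
    a = np.asarray(as_array(denoised_up), dtype=np.float32)
    if np.isclose(a.max(), a.min()):
        return np.zeros(a.shape, dtype=bool)
    fg = a > filters.threshold_otsu(a)
    if dilate > 0:
        fg = ndimage.binary_dilation(fg, iterations=dilate)
    return fg


def predict(bundle: AutocontextBundle, raw_up, denoised_up=None,
            mask: np.ndarray | None = None) -> ProbabilityMap:
    """Classify every voxel; optionally mask by the denoised image.

    Probabilities come from the stage-2 forest applied to raw-image
    features plus smoothed stage-1 probabilities.  If ``denoised_up`` is
    given, voxels outside its Otsu foreground (dilated by one voxel) are
    forced to background with probability 1; an explicit boolean ``mask``
    overrides the Otsu rule.
    """
    a = np.asarray(as_array(raw_up), dtype=np.float32)
    fs1 = compute_features(a, bundle.scales)
    prob1 = _proba_full(bundle.stage1, fs1.matrix(), a.shape)
    fs2 = _stage2_stack(fs1, prob1, bundle.scales)
    prob2 = _proba_full(bundle.stage2, fs2.matrix(), a.shape)
    if mask is None and denoised_up is not None:
        mask = foreground_mask(denoised_up)
    if mask is not None:
        fg = np.asarray(mask, bool)
        prob2[:, ~fg] = 0.0
        prob2[2, ~fg] = 1.0  # background class (code 3)
    return ProbabilityMap(probs=prob2)


def rank_discriminative_features(stack: FeatureStack, labels, k: int = 100
                                 ) -> list[tuple[str, float]]:
    """Rank features by one-vs-rest class separation.

    The statistic is the absolute standardized mean difference between one
    class and the rest (difference of means over the pooled standard
    deviation), averaged over classes — a self-contained marker-style
    score.  Returns up to ``k`` ``(name, score)`` pairs, best first; ``k``
    larger than the feature count returns all features.
    """
    lab = np.asarray(labels, dtype=int)
    if lab.ndim == 2 and lab.shape[1] == 4:
        X = stack.at(lab[:, :3])
        y = lab[:, 3]
    elif lab.shape == stack.data.shape[1:]:
        X = stack.matrix()
        y = lab.reshape(-1)
    else:
        raise ValueError("labels must be (n,4) sparse rows or a dense class grid")
    scores = np.zeros(stack.n_features)
    classes = np.unique(y)
    for c in classes:
        inc = y == c
        if inc.all() or not inc.any():
            continue
        mu1, mu0 = X[inc].mean(axis=0), X[~inc].mean(axis=0)
        v1, v0 = X[inc].var(axis=0), X[~inc].var(axis=0)
        pooled = np.sqrt(0.5 * (v1 + v0))
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.abs(mu1 - mu0) / pooled
        d[~np.isfinite(d)] = 0.0
        scores += d
    scores /= max(len(classes), 1)
    order = np.argsort(scores)[::-1][: min(k, stack.n_features)]
    return [(stack.names[i], float(scores[i])) for i in order]
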