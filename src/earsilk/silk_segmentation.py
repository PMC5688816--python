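"""Silk pixel extraction from close-up ear images.

Silks are hundreds of thin filaments whose colour can resemble husks and
leaves; what separates them reliably is texture.  Each pixel is described by
5 features — its 3 colour channels Gaussian-smoothed at 5 px, plus the two
eigenvalues of the luminance structure tensor at integration scale 1.6 px —
and classified silk / non-silk by a seeded random forest, restricted to an
HSV plant mask.  The structure tensor's eigenvalue anisotropy (lambda1 >>
lambda2 along a filament) is what a colour-only classifier lacks.
"""

from __future__ import annotations

from dataclasses import dataclass
import pickle
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.ensemble import RandomForestClassifier

from .plant_segmentation import hsv_mask

# HSV bounds for close-up ear images: green husk/leaf + yellow-to-red silks.
EAR_HSV_BOUNDS = (
    ((35.0, 170.0), (0.12, 1.0), (0.1, 1.0)),   # green plant tissue
    ((10.0, 70.0), (0.15, 1.0), (0.25, 1.0)),   # yellow/brown silks
    ((300.0, 20.0), (0.2, 1.0), (0.2, 1.0)),    # red/purple silk morphs (hue wrap)
)

N_FEATURES = 5


def plant_mask_hsv(ear_image: np.ndarray, bounds=EAR_HSV_BOUNDS) -> np.ndarray:
    """Plant (husk + leaf + silk) pixels of a close-up ear image by HSV thresholds."""
    return hsv_mask(ear_image, bounds)


def compute_features(ear_image: np.ndarray, colour_sigma: float = 5.0,
                     tensor_sigma: float = 1.6, deriv_sigma: float = 1.0) -> np.ndarray:
    """(H, W, 5) per-pixel features: smoothed colour + structure tensor eigenvalues.

    Gradients are taken on luma (0.299 R + 0.587 G + 0.114 B) at derivative
    scale ``deriv_sigma``; the tensor elements are integrated at
    ``tensor_sigma``.  Eigenvalues are ordered lambda1 >= lambda2 >= 0.
    """
    img = np.asarray(ear_image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    if min(img.shape[:2]) < 16:
        raise ValueError("image too small (min side 16 px)")
    smoothed = np.stack([gaussian_filter(img[..., c], colour_sigma) for c in range(3)],
                        axis=-1)
    luma = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    gy = gaussian_filter(luma, deriv_sigma, order=(1, 0))
    gx = gaussian_filter(luma, deriv_sigma, order=(0, 1))
    jxx = gaussian_filter(gx * gx, tensor_sigma)
    jxy = gaussian_filter(gx * gy, tensor_sigma)
    jyy = gaussian_filter(gy * gy, tensor_sigma)
    # closed-form eigenvalues of the symmetric 2x2 tensor
    tr = jxx + jyy
    disc = np.sqrt(np.maximum((jxx - jyy) ** 2 + 4.0 * jxy**2, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = np.maximum(0.5 * (tr - disc), 0.0)
    return np.concatenate([smoothed, lam1[..., None], lam2[..., None]], axis=-1)


@dataclass
class SilkClassifier:
    forest: RandomForestClassifier
    oob_accuracy: float
    feature_indices: tuple[int, ...] = tuple(range(N_FEATURES))

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "SilkClassifier":
        return pickle.loads(Path(path).read_bytes())


@dataclass
class SilkMask:
    mask: np.ndarray
    silk_pixel_count: int


def train_silk_classifier(images, silk_masks, other_masks, n_trees: int = 100,
                          min_labelled: int = 500, random_state: int = 0,
                          colour_only: bool = False) -> SilkClassifier:
    """Random forest over pixel features from labelled stroke masks.

    ``images`` with parallel boolean ``silk_masks`` / ``other_masks``
    (labelled silk strokes vs labelled husk/leaf strokes).  ``colour_only``
    drops the texture eigenvalues (the baseline the full model is compared
    against).  Out-of-bag accuracy is estimated on the training pixels.
    """
    feats_list, labels_list = [], []
    for img, silk, other in zip(images, silk_masks, other_masks):
        f = compute_features(img)
        feats_list.append(f[np.asarray(silk, dtype=bool)])
        labels_list.append(np.ones(int(np.sum(silk)), dtype=int))
        feats_list.append(f[np.asarray(other, dtype=bool)])
        labels_list.append(np.zeros(int(np.sum(other)), dtype=int))
    X = np.concatenate(feats_list)
    y = np.concatenate(labels_list)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("need labelled pixels from both classes")
    if (y == 1).sum() < min_labelled or (y == 0).sum() < min_labelled:
        raise ValueError(f"need at least {min_labelled} labelled pixels per class")
    idx = tuple(range(3)) if colour_only else tuple(range(N_FEATURES))
    forest = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                    random_state=random_state, n_jobs=1)
    forest.fit(X[:, idx], y)
    return SilkClassifier(forest=forest, oob_accuracy=float(forest.oob_score_),
                          feature_indices=idx)


def segment_silks(ear_image: np.ndarray, classifier: SilkClassifier,
                  plant_mask: np.ndarray | None = None) -> SilkMask:
    """Classify plant pixels as silk / non-silk; the mask never leaves ``plant_mask``."""
    if classifier is None or classifier.forest is None:
        raise ValueError("classifier is not trained")
    if plant_mask is None:
        plant_mask = plant_mask_hsv(ear_image)
    plant_mask = np.asarray(plant_mask, dtype=bool)
    out = np.zeros(ear_image.shape[:2], dtype=bool)
    if plant_mask.any():
        feats = compute_features(ear_image)
        sel = feats[plant_mask][:, classifier.feature_indices]
        out[plant_mask] = classifier.forest.predict(sel).astype(bool)
    return SilkMask(mask=out, silk_pixel_count=int(out.sum()))


def strokes_from_truth(truth_silk_mask: np.ndarray, truth_plant_mask: np.ndarray,
                       rng: np.random.Generator, n_per_class: int = 2000):
    """Sample label strokes from generator ground truth (synthetic annotator)."""
    silk = np.asarray(truth_silk_mask, dtype=bool)
    other = np.asarray(truth_plant_mask, dtype=bool) & ~silk
    out_silk = np.zeros_like(silk)
    out_other = np.zeros_like(silk)
    for src, dst in ((silk, out_silk), (other, out_other)):
        coords = np.argwhere(src)
        if len(coords) == 0:
            continue
        take = min(n_per_class, len(coords))
        pick = coords[rng.choice(len(coords), size=take, replace=False)]
        dst[pick[:, 0], pick[:, 1]] = True
    return out_silk, out_other
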