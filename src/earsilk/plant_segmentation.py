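"""Plant/background segmentation for side and top views.

Side views: the twelve views of a rotating plant share their background, so a
per-pixel mean image over the views approximates that background wherever the
plant is not, and dividing each view by the mean flags plant pixels as ratio
deviations from 1.  Pixels the plant occupies in *every* view (notably the
stem, which sits on the rotation axis) cancel in the ratio and are rescued by
an HSV threshold on green/brown hue families.

Top views: a tree classifier over the pixel expressed in seven colour spaces
(RGB, HSV, Luv, Lab, HLS, xyz, Yuv), trained on labelled pixels from
contrasting plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage.morphology import remove_small_objects
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

# Hue in degrees [0, 360); saturation and value in [0, 1].
DEFAULT_HSV_BOUNDS = (
    ((35.0, 85.0), (0.15, 1.0), (0.1, 1.0)),   # green foliage
    ((10.0, 30.0), (0.15, 1.0), (0.1, 1.0)),   # brown stem / senescent tissue
)


def mean_image(side_views) -> np.ndarray:
    """Per-pixel, per-channel arithmetic mean over the side views (float)."""
    views = list(side_views.values()) if isinstance(side_views, dict) else list(side_views)
    if len(views) < 2:
        raise ValueError("need at least 2 side views")
    shapes = {v.shape for v in views}
    if len(shapes) > 1:
        raise ValueError(f"side views differ in shape: {shapes}")
    return np.mean(np.stack([v.astype(float) for v in views]), axis=0)


def hsv_mask(image: np.ndarray, bounds=DEFAULT_HSV_BOUNDS) -> np.ndarray:
    """Union of HSV interval hits; hue intervals may wrap around 360."""
    hsv = skcolor.rgb2hsv(image)
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    out = np.zeros(image.shape[:2], dtype=bool)
    for (h_lo, h_hi), (s_lo, s_hi), (v_lo, v_hi) in bounds:
        if h_lo <= h_hi:
            hue_ok = (h >= h_lo) & (h <= h_hi)
        else:  # wrap-around interval, e.g. (350, 10)
            hue_ok = (h >= h_lo) | (h <= h_hi)
        out |= hue_ok & (s >= s_lo) & (s <= s_hi) & (v >= v_lo) & (v <= v_hi)
    return out


def segment_side_view(view: np.ndarray, mean_img: np.ndarray,
                      ratio_threshold: float = 0.5,
                      hsv_bounds=DEFAULT_HSV_BOUNDS,
                      min_component: int = 30) -> np.ndarray:
    """Mean-image ratio deviation OR HSV rescue, minus sub-``min_component`` speckle.

    The ratio statistic is per channel r_c = (view_c + 1) / (mean_c + 1), so
    a pixel identical to the mean gives exactly 1 at any intensity; a pixel
    passes when max_c |r_c - 1| > ratio_threshold, symmetric for plants
    brighter or darker than the pooled background.
    """
    if view.shape != mean_img.shape:
        raise ValueError("view and mean image must share shape")
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    ratio = (view.astype(float) + 1.0) / (mean_img.astype(float) + 1.0)
    dev = np.max(np.abs(ratio - 1.0), axis=-1)
    mask = (dev > ratio_threshold) | hsv_mask(view, hsv_bounds)
    if min_component > 1:
        mask = remove_small_objects(mask, max_size=min_component - 1)
    return mask


def _rgb_to_hls(rgb01: np.ndarray) -> np.ndarray:
    """Vectorised RGB->HLS, hue in [0,1); matches colorsys conventions."""
    r, g, b = rgb01[..., 0], rgb01[..., 1], rgb01[..., 2]
    maxc = np.max(rgb01, axis=-1)
    minc = np.min(rgb01, axis=-1)
    l = (maxc + minc) / 2.0
    delta = maxc - minc
    s = np.zeros_like(l)
    nz = delta > 0
    low = nz & (l <= 0.5)
    high = nz & (l > 0.5)
    s[low] = delta[low] / (maxc + minc)[low]
    s[high] = delta[high] / (2.0 - maxc - minc)[high]
    h = np.zeros_like(l)
    d = np.where(nz, delta, 1.0)
    rc = (maxc - r) / d
    gc = (maxc - g) / d
    bc = (maxc - b) / d
    h = np.where(maxc == r, bc - gc, np.where(maxc == g, 2.0 + rc - bc, 4.0 + gc - rc))
    h = np.where(nz, (h / 6.0) % 1.0, 0.0)
    return np.stack([h, l, s], axis=-1)


def colour_features(rgb) -> np.ndarray:
    """Pixel(s) expressed in 7 colour spaces -> 21 features.

    Input: RGB in [0, 255], any leading shape.  Blocks in order:
    RGB (0-255), HSV (h,s,v in [0,1]), Luv, Lab, HLS (h,l,s in [0,1]),
    CIE xyz, YUV — sRGB primaries, D65 white point.
    """
    rgb = np.asarray(rgb, dtype=float)
    scalar = rgb.ndim == 1
    if scalar:
        rgb = rgb[None, :]
    if rgb.shape[-1] != 3:
        raise ValueError("expected RGB triplets")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    rgb01 = rgb / 255.0
    blocks = [
        rgb,
        skcolor.rgb2hsv(rgb01),
        skcolor.rgb2luv(rgb01),
        skcolor.rgb2lab(rgb01),
        _rgb_to_hls(rgb01),
        skcolor.rgb2xyz(rgb01),
        skcolor.rgb2yuv(rgb01),
    ]
    feats = np.concatenate(blocks, axis=-1)
    return feats[0] if scalar else feats


@dataclass
class TopClassifier:
    """Tree-based pixel classifier over the 21 colour features."""

    model: object
    training_accuracy: float = 0.0
    classes_: tuple = field(default_factory=tuple)

    def predict(self, rgb_pixels: np.ndarray) -> np.ndarray:
        feats = colour_features(rgb_pixels)
        return self.model.predict(feats.reshape(-1, 21)).reshape(feats.shape[:-1])


def train_top_classifier(rgb_pixels, labels, n_trees: int = 1, max_depth: int = 12,
                         min_per_class: int = 50, random_state: int = 0) -> TopClassifier:
    """Fit a decision tree (or small forest) on labelled (r,g,b) -> is_plant pixels."""
    rgb_pixels = np.asarray(rgb_pixels, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain both plant and background pixels")
    if counts.min() < min_per_class:
        raise ValueError(f"need at least {min_per_class} examples per class")
    feats = colour_features(rgb_pixels)
    if n_trees <= 1:
        model = DecisionTreeClassifier(max_depth=max_depth, random_state=random_state)
    else:
        model = RandomForestClassifier(n_estimators=n_trees, max_depth=max_depth,
                                       random_state=random_state)
    model.fit(feats, labels)
    acc = float(np.mean(model.predict(feats) == labels))
    return TopClassifier(model=model, training_accuracy=acc, classes_=tuple(classes))


def segment_top_view(image: np.ndarray, classifier: TopClassifier,
                     min_component: int = 30) -> np.ndarray:
    """Per-pixel classification of the top view into a boolean plant mask."""
    if classifier is None or classifier.model is None:
        raise ValueError("classifier is not trained")
    h, w = image.shape[:2]
    pred = classifier.predict(image.reshape(-1, 3).astype(float)).reshape(h, w)
    mask = pred.astype(bool)
    if min_component > 1:
        mask = remove_small_objects(mask, max_size=min_component - 1)
    return mask
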