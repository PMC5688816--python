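"""Ground-truthed synthetic maize scenes for exercising the phenotyping pipeline.

Generates multi-view plant image sets (12 side views at 30 deg increments plus
one top view), close-up ear/silk image time series, and chessboard calibration
observations, each with a fully populated ground truth record.

Rendering is deliberately 2D "billboard" style: the plant is a planar object
whose leaves live (up to a small jitter) in one vertical plane; a side view at
camera azimuth theta foreshortens each leaf's horizontal extent by
sin(leaf_azimuth - theta).  All downstream operators consume binary masks or
colour/texture statistics, so silhouette-level realism is what matters, and
this style gives exact pixel-level ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk, polygon

from . import image_io

# Default palette (RGB, 0-255).  Plant hues sit inside the default
# segmentation HSV bounds (leaf green ~ hue 78 deg, stem brown-green),
# the background does not (low saturation grey-blue).
LEAF_COLOUR = (130, 160, 60)
STEM_COLOUR = (120, 150, 55)
EAR_COLOUR = (140, 165, 70)
BACKGROUND_COLOUR = (180, 185, 195)
TUTOR_COLOUR = (150, 100, 60)

SIDE_AZIMUTHS = tuple(range(0, 360, 30))


class SceneSpecError(ValueError):
    """Raised for anatomically or numerically invalid scene specifications."""


@dataclass
class PlantSpec:
    """Parameters of one synthetic maize plant.

    Internode widths run base -> top and must be monotone non-increasing
    before the ear bulge is applied; the primary ear sits on one internode in
    the upper half of the stem and widens it by ``ear_bulge_factor``.
    """

    n_leaves: int = 12
    internode_widths: np.ndarray | None = None
    ear_node_index: int | None = None
    ear_bulge_factor: float = 1.8
    leaf_plane_azimuth: float = 0.0
    leaf_lengths: np.ndarray | None = None
    stem_height: float = 420.0
    pot_top_center: tuple[int, int] = (560, 256)
    leaf_azimuth_jitter: float = 4.0
    image_shape: tuple[int, int] = (612, 512)
    top_shape: tuple[int, int] = (512, 512)
    base_width: float = 19.0
    top_width: float | None = None
    stem_lean_deg: float = 2.5   # real stems lean slightly but consistently
    ear_width_frac: float = 0.78
    drop_width_frac: float = 0.55
    extra_leaf_azimuths: tuple[float, ...] = ()
    nonplanar: bool = False
    crossing_leaves: bool = False
    tutor_rod: bool = False
    tutor_width: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 4:
            raise SceneSpecError("need at least 4 leaves to define an upper half")
        if self.ear_node_index is None:
            self.ear_node_index = int(round(self.n_leaves * 2 / 3))
        if self.ear_node_index <= self.n_leaves / 2:
            raise SceneSpecError(
                f"ear_node_index {self.ear_node_index} not in upper half "
                f"of a {self.n_leaves}-leaf plant"
            )
        if self.ear_node_index >= self.n_leaves:
            raise SceneSpecError("ear_node_index beyond the last internode")
        if self.ear_bulge_factor <= 1.0:
            raise SceneSpecError("ear_bulge_factor must exceed 1")
        if self.internode_widths is None:
            # maize anatomy: width shrinks gently up to the ear internode,
            # then drops sharply — internodes above the ear, initiated after
            # it, are much thinner than basal ones
            if self.top_width is None:
                self.top_width = 0.4 * self.base_width
            e = self.ear_node_index - 1  # 0-based ear internode
            below = np.linspace(self.base_width, self.ear_width_frac * self.base_width,
                                e + 1)
            n_above = self.n_leaves - e - 1
            above = np.linspace(self.drop_width_frac * self.base_width, self.top_width,
                                max(n_above, 1))[:n_above]
            self.internode_widths = np.concatenate([below, above])
        self.internode_widths = np.asarray(self.internode_widths, dtype=float)
        if len(self.internode_widths) != self.n_leaves:
            raise SceneSpecError("need one internode width per leaf")
        if np.any(self.internode_widths <= 0):
            raise SceneSpecError("internode widths must be positive")
        if np.any(np.diff(self.internode_widths) > 1e-9):
            raise SceneSpecError("internode widths must be non-increasing base->top")
        if self.leaf_lengths is None:
            # longest leaves mid-stem, shorter at base and top
            ranks = np.arange(1, self.n_leaves + 1)
            bell = 1.0 - 0.5 * ((ranks - 0.55 * self.n_leaves) / self.n_leaves) ** 2 * 4
            self.leaf_lengths = 175.0 * np.clip(bell, 0.45, 1.0)
        self.leaf_lengths = np.asarray(self.leaf_lengths, dtype=float)
        self.leaf_plane_azimuth = float(self.leaf_plane_azimuth) % 360.0


@dataclass
class SilkScenarioSpec:
    """Parameters of a close-up ear image time series with growing silks.

    The true silk pixel count follows a two-phase (linear rise then plateau)
    curve: count(d) = rate_max * min(d - onset_day, duration) for
    d >= onset_day, 0 before, with multiplicative noise of absolute standard
    deviation ``noise_sd`` pixels.
    """

    rate_max: float = 1000.0
    duration: float = 4.0
    onset_day: float = 0.0
    noise_sd: float = 0.0
    n_days: int = 8
    silk_colour: tuple[int, int, int] = (235, 205, 70)
    silk_texture_scale: float = 2.0
    image_shape: tuple[int, int] = (256, 256)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise SceneSpecError("need at least 2 days")
        if self.duration <= 0:
            raise SceneSpecError("duration must be positive")
        if self.n_days < self.duration + 2:
            raise SceneSpecError("n_days must cover duration + 2")
        if self.noise_sd < 0:
            raise SceneSpecError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    leaf_plane_azimuth: float | None = None
    ear_pixel_position: dict[int, tuple[float, float]] = field(default_factory=dict)
    ear_world_xyz: tuple[float, float, float] | None = None
    internode_length_px: float | None = None
    side_masks: dict[int, np.ndarray] = field(default_factory=dict)
    top_mask: np.ndarray | None = None
    node_rows: np.ndarray | None = None
    silk_masks: list[np.ndarray] = field(default_factory=list)
    silk_counts: list[int] = field(default_factory=list)
    plant_masks: list[np.ndarray] = field(default_factory=list)
    rate_max: float | None = None
    duration: float | None = None
    onset_day: float | None = None


@dataclass
class MultiViewSet:
    """One plant-day's 12 side views plus 1 top view."""

    side_views: dict[int, np.ndarray]
    top_view: np.ndarray
    plant_id: str = "plant"
    day: int = 0

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.side_views.values()}
        if len(shapes) > 1:
            raise ValueError("side views must share dimensions")
        if len(set(self.side_views)) != len(self.side_views):
            raise ValueError("azimuths must be unique")


def random_plant_spec(rng: np.random.Generator) -> PlantSpec:
    """Draw a PlantSpec from the documented default ranges.

    Ranges bracket the variability of a mid-European maize panel at flowering:
    10-14 visible leaves, gently tapering stems, ear on a node at 55-85% of
    stem height, husk-widened ear internode 1.6-2.0x its internode width.
    """
    n = int(rng.integers(10, 15))
    lo = int(np.floor(n / 2)) + 1
    hi = n - 2
    ear = int(rng.integers(lo, hi + 1))
    return PlantSpec(
        n_leaves=n,
        ear_node_index=ear,
        ear_bulge_factor=float(rng.uniform(1.6, 2.0)),
        leaf_plane_azimuth=float(rng.uniform(0, 360)),
        stem_height=float(rng.uniform(380, 460)),
        base_width=float(rng.uniform(16, 22)),
        ear_width_frac=float(rng.uniform(0.74, 0.84)),
        drop_width_frac=float(rng.uniform(0.5, 0.6)),
        stem_lean_deg=float(rng.choice([-1, 1]) * rng.uniform(1.5, 4.0)),
        leaf_azimuth_jitter=4.0,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Constant colour plus a low-amplitude smooth pattern, shared by all side views."""
    from scipy.ndimage import gaussian_filter

    h, w = shape
    pattern = rng.normal(0.0, 1.0, (h, w))
    pattern = gaussian_filter(pattern, 8.0)
    pattern = 4.0 * pattern / (np.abs(pattern).max() + 1e-12)
    img = np.empty((h, w, 3), dtype=float)
    for c, v in enumerate(BACKGROUND_COLOUR):
        img[..., c] = v + pattern
    return np.clip(img, 0, 255).astype(np.uint8)


def _paint_polygon(img, mask, rows, cols, colour) -> None:
    rr, cc = polygon(rows, cols, shape=img.shape[:2])
    img[rr, cc] = colour
    mask[rr, cc] = True


def _leaf_geometry(spec: PlantSpec, rng: np.random.Generator):
    """Per-leaf world azimuth (deg) and length; alternating phyllotaxy with jitter."""
    azimuths = []
    for k in range(spec.n_leaves):
        base = spec.leaf_plane_azimuth + (180.0 if k % 2 else 0.0)
        if spec.nonplanar:
            base = rng.uniform(0, 360)
        azimuths.append(base + rng.normal(0.0, spec.leaf_azimuth_jitter))
    extra = [(az, 0.8 * float(np.median(spec.leaf_lengths))) for az in spec.extra_leaf_azimuths]
    return np.array(azimuths) % 360.0, extra


def _node_rows(spec: PlantSpec) -> np.ndarray:
    """Image rows of leaf nodes 1..n (top of each internode), base -> top."""
    pot_row = spec.pot_top_center[0]
    lengths = np.full(spec.n_leaves, spec.stem_height / spec.n_leaves)
    rows = pot_row - np.cumsum(lengths)
    return rows


def _draw_leaf(img, mask, attach_rc, extent, colour, droop=0.25, rise=0.18,
               base_halfwidth=3.5, tip_halfwidth=1.0) -> None:
    """Arching leaf strip from a stem node; extent is the signed horizontal span in px."""
    r0, c0 = attach_rc
    span = abs(extent)
    if span < 2.0:
        span = 2.0
        extent = np.sign(extent) * span if extent != 0 else span
    t = np.linspace(0.0, 1.0, max(8, int(span / 3)))
    xs = c0 + extent * t
    ys = r0 - rise * span * 4 * t * (1 - t) + droop * span * t**2
    # offset the centerline by its normal to build the strip polygon
    dx = np.gradient(xs)
    dy = np.gradient(ys)
    norm = np.hypot(dx, dy) + 1e-12
    nx, ny = -dy / norm, dx / norm
    hw = base_halfwidth + (tip_halfwidth - base_halfwidth) * t
    poly_r = np.concatenate([ys + ny * hw, (ys - ny * hw)[::-1]])
    poly_c = np.concatenate([xs + nx * hw, (xs - nx * hw)[::-1]])
    _paint_polygon(img, mask, poly_r, poly_c, colour)


def _render_side_view(spec, theta, bg, leaf_azimuths, extra_leaves, node_rows,
                      widths):
    img = bg.copy()
    mask = np.zeros(img.shape[:2], dtype=bool)
    pot_row, cx = spec.pot_top_center
    tan_lean = np.tan(np.radians(spec.stem_lean_deg))

    def axis_x(row):
        return cx + tan_lean * (pot_row - row)

    if spec.tutor_rod:
        rod_c = cx + int(2.2 * spec.base_width)
        top = int(node_rows[-1] + 30)
        img[top:pot_row, rod_c:rod_c + spec.tutor_width] = TUTOR_COLOUR
        mask[top:pot_row, rod_c:rod_c + spec.tutor_width] = True

    # stem, one quadrilateral per internode along the leaning axis; the ear
    # internode uses the bulged width
    y_prev = pot_row
    for k in range(spec.n_leaves):
        y_top = node_rows[k]
        hw = widths[k] / 2.0
        colour = EAR_COLOUR if (k + 1) == spec.ear_node_index else STEM_COLOUR
        rr = np.array([y_top, y_top, y_prev, y_prev])
        cc = np.array([axis_x(y_top) - hw, axis_x(y_top) + hw,
                       axis_x(y_prev) + hw, axis_x(y_prev) - hw])
        _paint_polygon(img, mask, rr, cc, colour)
        y_prev = y_top

    # leaves at nodes, foreshortened by the view azimuth; the sheath wraps the
    # stem at its insertion, widening the silhouette symmetrically (collar)
    for k in range(spec.n_leaves):
        r0, x0 = node_rows[k], axis_x(node_rows[k])
        hw = widths[k] / 2.0 + 3.0
        rr = np.array([r0 - 4.0, r0 - 4.0, r0 + 4.0, r0 + 4.0])
        cc = np.array([x0 - hw, x0 + hw, x0 + hw, x0 - hw])
        _paint_polygon(img, mask, rr, cc, LEAF_COLOUR)
        extent = spec.leaf_lengths[k] * np.sin(np.radians(leaf_azimuths[k] - theta))
        _draw_leaf(img, mask, (r0, x0), extent, LEAF_COLOUR)
    for az, length in extra_leaves:
        extent = length * np.sin(np.radians(az - theta))
        row = node_rows[int(spec.n_leaves * 0.4)]
        _draw_leaf(img, mask, (row, axis_x(row)), extent, LEAF_COLOUR)

    if spec.crossing_leaves or spec.nonplanar:
        # two erect leaves crossing each other well above the stem top: the
        # skeleton's highest junction is then their crossing, off the stem
        # axis, and the extracted "stem" path detours along a leaf
        # (crossing-leaf artefact)
        top_row = node_rows[-1]
        j = int(0.55 * spec.n_leaves)
        p0 = np.array([node_rows[j], axis_x(node_rows[j])])       # leaf A base
        p1 = np.array([max(top_row + 50.0, 190.0), cx + 170.0])   # A x B crossing
        p2 = np.array([top_row - 60.0, cx - 140.0])               # B x C crossing, highest
        strips = [
            (p0, p1 + 0.25 * (p1 - p0) / np.linalg.norm(p1 - p0) * 200.0),  # leaf A
            (p1 + 0.3 * (p1 - p2), p2 + 0.3 * (p2 - p1)),                   # leaf B
            (p2 + np.array([30.0, -50.0]), p2 + np.array([-30.0, 50.0])),   # leaf C
        ]
        for start, end in strips:
            t = np.linspace(0.0, 1.0, 40)[:, None]
            line = start + t * (end - start)
            hw = 4.0 - 2.0 * t[:, 0]
            poly_r = np.concatenate([line[:, 0], line[::-1, 0]])
            poly_c = np.concatenate([line[:, 1] - hw, (line[:, 1] + hw)[::-1]])
            _paint_polygon(img, mask, poly_r, poly_c, LEAF_COLOUR)
    return img, mask


def _render_top_view(spec, leaf_azimuths, extra_leaves, rng):
    h, w = spec.top_shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = BACKGROUND_COLOUR
    mask = np.zeros((h, w), dtype=bool)
    cy, cx = h / 2.0, w / 2.0

    def draw_strip(az_deg, length, base_hw=6.5, tip_hw=1.5):
        t = np.linspace(0.0, 1.0, 40)
        dx, dy = np.cos(np.radians(az_deg)), -np.sin(np.radians(az_deg))
        xs = cx + dx * length * t
        ys = cy + dy * length * t
        hw = base_hw + (tip_hw - base_hw) * t
        nx, ny = -dy, dx
        poly_r = np.concatenate([ys + ny * hw, (ys - ny * hw)[::-1]])
        poly_c = np.concatenate([xs + nx * hw, (xs - nx * hw)[::-1]])
        _paint_polygon(img, mask, poly_r, poly_c, LEAF_COLOUR)

    for k in range(spec.n_leaves):
        # from above, leaves project to most of their length
        draw_strip(leaf_azimuths[k], 0.9 * spec.leaf_lengths[k] * min(1.0, 0.5 + k / spec.n_leaves))
    for az, length in extra_leaves:
        draw_strip(az, 0.9 * length)
    rr, cc = disk((cy, cx), spec.base_width / 2 + 3, shape=(h, w))
    img[rr, cc] = STEM_COLOUR
    mask[rr, cc] = True
    return img, mask


def generate_plant_scene(spec: PlantSpec) -> tuple[MultiViewSet, GroundTruth]:
    """Render one plant-day: 12 side views at 30 deg steps plus a top view.

    The background is bit-identical across side views so that division by the
    mean image cancels exactly off-plant.  Ground truth carries per-view
    silhouettes, the ear pixel position per view, and node geometry.
    """
    rng = np.random.default_rng(spec.rng_seed)
    leaf_azimuths, extra_leaves = _leaf_geometry(spec, rng)
    node_rows = _node_rows(spec)
    widths = spec.internode_widths.copy()
    widths[spec.ear_node_index - 1] *= spec.ear_bulge_factor

    bg = _background(spec.image_shape, rng)
    side_views: dict[int, np.ndarray] = {}
    truth = GroundTruth(
        leaf_plane_azimuth=spec.leaf_plane_azimuth,
        internode_length_px=spec.stem_height / spec.n_leaves,
        node_rows=node_rows,
    )
    ear_top = node_rows[spec.ear_node_index - 1]
    ear_bot = node_rows[spec.ear_node_index - 2] if spec.ear_node_index >= 2 \
        else spec.pot_top_center[0]
    ear_row = 0.5 * (ear_top + ear_bot)
    ear_col = spec.pot_top_center[1] + np.tan(np.radians(spec.stem_lean_deg)) * \
        (spec.pot_top_center[0] - ear_row)
    for theta in SIDE_AZIMUTHS:
        img, mask = _render_side_view(
            spec, theta, bg, leaf_azimuths, extra_leaves, node_rows, widths
        )
        side_views[theta] = img
        truth.side_masks[theta] = mask
        truth.ear_pixel_position[theta] = (ear_row, float(ear_col))
    top_img, top_mask = _render_top_view(spec, leaf_azimuths, extra_leaves, rng)
    truth.top_mask = top_mask
    # notional world position: ear on the rotation axis at its stem height (mm == px here)
    truth.ear_world_xyz = (0.0, 0.0, float(spec.pot_top_center[0] - ear_row))
    views = MultiViewSet(side_views=side_views, top_view=top_img)
    return views, truth


# ---------------------------------------------------------------------------
# close-up ear / silk series

HUSK_COLOUR = (110, 150, 70)
EAR_BG_COLOUR = (70, 74, 88)


def _true_counts(spec: SilkScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    days = np.arange(spec.n_days, dtype=float)
    counts = np.zeros(spec.n_days)
    for i, d in enumerate(days):
        if d < spec.onset_day:
            continue
        base = spec.rate_max * min(d - spec.onset_day, spec.duration)
        if base <= 0:
            counts[i] = 0.0
        elif spec.noise_sd > 0:
            eps = rng.normal(0.0, spec.noise_sd / base)
            counts[i] = max(0.0, base * (1.0 + eps))
        else:
            counts[i] = base
    return counts


def _grow_silks(target: int, pixels: set, walkers: list, rng: np.random.Generator,
                shape: tuple[int, int], seed_point: tuple[int, int]) -> None:
    """Extend filament random walks until the silk pixel set reaches target size."""
    h, w = shape
    guard = 0
    while len(pixels) < target and guard < 500000:
        guard += 1
        if not walkers or rng.random() < 0.002:
            ang = rng.uniform(-1.25 * np.pi, 0.25 * np.pi)  # mostly upward/outward
            walkers.append([float(seed_point[0]), float(seed_point[1]), ang])
        i = int(rng.integers(len(walkers)))
        wlk = walkers[i]
        wlk[2] += rng.normal(0.0, 0.18)
        # gravity-like droop pulls filament tips downward over time
        wlk[2] = 0.985 * wlk[2] + 0.015 * (np.pi / 2 if np.sin(wlk[2]) > 0 else -np.pi / 2) * 0
        wlk[0] += np.sin(wlk[2])
        wlk[1] += np.cos(wlk[2])
        r, c = int(round(wlk[0])), int(round(wlk[1]))
        if not (1 <= r < h - 1 and 1 <= c < w - 1):
            walkers.pop(i)
            continue
        pixels.add((r, c))
        # 2 px thick filaments read better under 5 px colour smoothing
        pixels.add((r, c + 1) if len(pixels) % 2 else (r + 1, c))


def generate_ear_series(spec: SilkScenarioSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Close-up ear images over days with silks accruing as thin filaments.

    Husk/ear regions are smooth in colour; silks are 2-px anisotropic
    filaments in a distinct colour, grown cumulatively so day d+1's silk mask
    contains day d's.  The rendered silk mask size matches the ground-truth
    count exactly (the mask is the set of grown pixels).
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_shape
    counts = _true_counts(spec, rng)

    base = np.empty((h, w, 3), dtype=np.uint8)
    base[...] = EAR_BG_COLOUR
    shade = np.linspace(-8, 8, w)[None, :, None]
    base = np.clip(base.astype(float) + shade, 0, 255).astype(np.uint8)
    plant_mask_static = np.zeros((h, w), dtype=bool)
    # husk: upright ellipse in the lower-centre, smooth interior
    cy, cx = int(h * 0.62), w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    husk = ((yy - cy) / (h * 0.27)) ** 2 + ((xx - cx) / (w * 0.16)) ** 2 <= 1.0
    base[husk] = HUSK_COLOUR
    grad = np.clip(((xx - cx) / (w * 0.16)) * 6.0, -12, 12)
    base[..., 1] = np.clip(base[..., 1].astype(float) + grad * husk, 0, 255).astype(np.uint8)
    plant_mask_static |= husk

    tip = (int(cy - h * 0.27), cx)
    truth = GroundTruth(rate_max=spec.rate_max, duration=spec.duration,
                        onset_day=spec.onset_day)
    images: list[np.ndarray] = []
    pixels: set[tuple[int, int]] = set()
    walkers: list[list[float]] = []
    for d in range(spec.n_days):
        _grow_silks(int(round(counts[d])), pixels, walkers, rng, (h, w), tip)
        img = base.copy()
        mask = np.zeros((h, w), dtype=bool)
        if pixels:
            rs, cs = zip(*pixels)
            mask[list(rs), list(cs)] = True
        jitter = rng.normal(0, 6, size=(int(mask.sum()), 3))
        img[mask] = np.clip(np.array(spec.silk_colour)[None, :] + jitter, 0, 255)
        images.append(img)
        truth.silk_masks.append(mask)
        truth.silk_counts.append(int(mask.sum()))
        truth.plant_masks.append(plant_mask_static | mask)
    return images, truth


def true_silk_curve(spec: SilkScenarioSpec) -> np.ndarray:
    """Noiseless two-phase silk count curve on the scenario's day grid."""
    noise_free = SilkScenarioSpec(
        rate_max=spec.rate_max, duration=spec.duration, onset_day=spec.onset_day,
        noise_sd=0.0, n_days=spec.n_days, rng_seed=spec.rng_seed,
    )
    return _true_counts(noise_free, np.random.default_rng(0))


def sample_labelled_pixels(image: np.ndarray, truth_mask: np.ndarray,
                           rng: np.random.Generator, n_per_class: int = 3000):
    """Draw a balanced labelled pixel set from an image + ground-truth mask
    (synthetic stand-in for a human-annotated training set)."""
    mask = np.asarray(truth_mask, dtype=bool)
    pos = image[mask]
    neg = image[~mask]
    n = min(n_per_class, len(pos), len(neg))
    X = np.concatenate([
        pos[rng.choice(len(pos), n, replace=False)],
        neg[rng.choice(len(neg), n, replace=False)],
    ]).astype(float)
    y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    return X, y


# ---------------------------------------------------------------------------
# calibration observations


def generate_chessboard_observations(model, board, angles, noise_sd: float = 0.0,
                                     rng: np.random.Generator | None = None):
    """Project board corners at each turntable angle, with optional pixel noise.

    With noise_sd == 0 the generating model reprojects the output exactly.
    Raises if any corner falls behind the camera.
    """
    from . import camera_geometry as cg

    rng = np.random.default_rng(0) if rng is None else rng
    observations = []
    world = board.corner_world_points()
    for angle in angles:
        px = np.array([cg.project(model, p, angle) for p in world])
        if noise_sd > 0:
            px = px + rng.normal(0.0, noise_sd, px.shape)
        observations.append((float(angle), px))
    return observations


# ---------------------------------------------------------------------------
# scene persistence: plantID/dayN/{side_000.png,...,top.png,truth.json}


def write_scene(root: str | Path, views: MultiViewSet, truth: GroundTruth) -> Path:
    out = Path(root) / views.plant_id / f"day{views.day}"
    out.mkdir(parents=True, exist_ok=True)
    for theta, img in views.side_views.items():
        image_io.write_image(out / f"side_{theta:03d}.png", img)
    image_io.write_image(out / "top.png", views.top_view)
    sidecar = {
        "leaf_plane_azimuth": truth.leaf_plane_azimuth,
        "ear_pixel_position": {str(k): list(v) for k, v in truth.ear_pixel_position.items()},
        "ear_world_xyz": list(truth.ear_world_xyz) if truth.ear_world_xyz else None,
        "internode_length_px": truth.internode_length_px,
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_scene(scene_dir: str | Path) -> tuple[MultiViewSet, dict]:
    scene_dir = Path(scene_dir)
    side_views = {}
    for f in sorted(scene_dir.glob("side_*.png")):
        theta = int(f.stem.split("_")[1])
        side_views[theta] = image_io.read_image(f)
    top = image_io.read_image(scene_dir / "top.png")
    truth = {}
    tf = scene_dir / "truth.json"
    if tf.exists():
        truth = json.loads(tf.read_text())
    views = MultiViewSet(side_views=side_views, top_view=top,
                         plant_id=scene_dir.parent.name,
                         day=int(scene_dir.name.replace("day", "") or 0))
    return views, truth
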