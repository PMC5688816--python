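"""Skeleton graph, stem extraction, width profiling and two-criterion ear scoring."""

import itertools

import networkx as nx
import numpy as np
import pytest

from earsilk import ear_detection as ed
from earsilk import synthetic_scenes as syn


def brute_force_width(mask, pixels):
    """Independent oracle: per path pixel, 2x the distance to the nearest
    background pixel, found by exhaustive search (background = mask==0,
    including an implicit border outside the array)."""
    padded = np.pad(mask, 1)
    bg = np.argwhere(~padded)
    out = []
    for r, c in pixels:
        d = np.sqrt(((bg - np.array([r + 1, c + 1])) ** 2).sum(axis=1)).min()
        out.append(2.0 * d)
    return np.array(out)


class TestSkeletonize:
    def test_horizontal_bar_single_edge(self):
        mask = np.zeros((20, 120), dtype=bool)
        mask[8:13, 10:110] = True
        g = ed.skeletonize(mask)
        ends = [n for n in g.nodes if g.degree(n) == 1]
        assert len(ends) == 2
        assert g.number_of_edges() == 1
        length = list(g.edges(data="weight"))[0][2]
        assert length == pytest.approx(100 - 5, abs=6)
        # the medial row of a symmetric bar is its centre row
        rows = {r for r, _ in itertools.chain.from_iterable(
            d["pixels"] for _, _, d in g.edges(data=True))}
        assert rows == {10}

    def test_plus_shape_has_degree4_junction(self):
        mask = np.zeros((61, 61), dtype=bool)
        mask[28:33, 5:56] = True
        mask[5:56, 28:33] = True
        g = ed.skeletonize(mask)
        degrees = [g.degree(n) for n in g.nodes]
        assert max(degrees) == 4
        assert sum(1 for d in degrees if d >= 3) == 1

    def test_skeleton_within_mask(self, default_scene):
        _, _, truth = default_scene
        mask = truth.side_masks[90]
        g = ed.skeletonize(mask)
        for _, _, d in g.edges(data=True):
            px = d["pixels"]
            assert mask[px[:, 0], px[:, 1]].all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ed.skeletonize(np.zeros((10, 10), dtype=bool))


class TestExtractStem:
    def test_vertical_bar_straight_path(self):
        mask = np.zeros((120, 21), dtype=bool)
        mask[10:110, 8:13] = True
        g = ed.skeletonize(mask)
        stem = ed.extract_stem(g, pot_top_center=(119, 10))
        assert stem.r_squared == pytest.approx(1.0)
        assert np.all(stem.pixels[:, 1] == 10)

    def test_y_shape_path_matches_exhaustive_enumeration(self):
        # stem with one leaf branch: oracle enumerates all simple paths on
        # the skeleton graph and takes the minimum-arc-length one
        mask = np.zeros((120, 80), dtype=bool)
        mask[20:110, 38:43] = True            # vertical stem
        for i in range(30):                   # diagonal leaf from (60, 40)
            mask[60 - i, 43 + i:46 + i] = True
        g = ed.skeletonize(mask)
        stem = ed.extract_stem(g, pot_top_center=(115, 40))
        start = min(g.nodes, key=lambda n: np.hypot(n[0] - 115, n[1] - 40))
        junctions = [n for n in g.nodes if g.degree(n) >= 3]
        end = min(junctions, key=lambda n: n)
        best = min(
            (sum(min(d["weight"] for d in g.get_edge_data(a, b).values())
                 for a, b in zip(p[:-1], p[1:]))
             for p in nx.all_simple_paths(g, start, end)),
            default=None)
        assert stem.arc_length == pytest.approx(best, abs=1e-9)

    def test_crossing_leaf_scene_fails_straightness(self, config):
        from earsilk import plant_segmentation as seg
        spec = syn.PlantSpec(crossing_leaves=True, rng_seed=0)
        views, _ = syn.generate_plant_scene(spec)
        mean = seg.mean_image(views.side_views)
        mask = seg.segment_side_view(views.side_views[90], mean)
        stem = ed.extract_stem(ed.skeletonize(mask), spec.pot_top_center)
        assert stem.r_squared < config.r2_cutoff

    def test_normal_scene_passes_straightness(self, default_scene, config,
                                              mean_side_image):
        from earsilk import plant_segmentation as seg
        spec, views, _ = default_scene
        mask = seg.segment_side_view(views.side_views[120], mean_side_image)
        stem = ed.extract_stem(ed.skeletonize(mask), spec.pot_top_center)
        assert stem.r_squared >= config.r2_cutoff


class TestWidthProfile:
    def test_strip_width_constant(self):
        mask = np.zeros((120, 30), dtype=bool)
        mask[5:115, 10:20] = True
        g = ed.skeletonize(mask)
        stem = ed.extract_stem(g, pot_top_center=(119, 15))
        prof = ed.width_profile(mask, stem)
        inner = prof.widths[8:-8]
        assert np.all(np.abs(inner - 10.0) <= 1.0)

    def test_one_px_strip_has_width_two(self):
        mask = np.zeros((40, 9), dtype=bool)
        mask[5:35, 4] = True
        g = ed.skeletonize(mask)
        stem = ed.extract_stem(g, pot_top_center=(39, 4))
        prof = ed.width_profile(mask, stem)
        assert np.all(prof.widths == 2.0)

    def test_matches_brute_force_on_small_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            mask = np.zeros((48, 24), dtype=bool)
            w = int(rng.integers(3, 7))
            mask[4:44, 12 - w // 2:12 + (w + 1) // 2] = True
            lobe_r = int(rng.integers(10, 30))
            mask[lobe_r:lobe_r + 5, 12:12 + 9] = True
            g = ed.skeletonize(mask)
            stem = ed.extract_stem(g, pot_top_center=(47, 12))
            prof = ed.width_profile(mask, stem)
            oracle = brute_force_width(mask, stem.pixels)
            np.testing.assert_allclose(prof.widths, oracle, atol=1e-9)

    def test_side_lobe_creates_one_peak_region(self):
        strip = np.zeros((150, 40), dtype=bool)
        strip[5:145, 15:23] = True
        mask = strip.copy()
        mask[64:84, 4:34] = True   # rectangular lobe wrapping the strip (sheath)
        g = ed.skeletonize(strip)   # path from the bare strip spans end to end
        stem = ed.extract_stem(g, pot_top_center=(149, 19))
        prof = ed.width_profile(mask, stem)
        assert len(prof.peaks) > 0
        peak_rows = stem.pixels[prof.peaks][:, 0]
        assert peak_rows.min() >= 56 and peak_rows.max() <= 92
        gaps = np.diff(np.sort(prof.peaks))
        assert np.all(gaps == 1)  # a single contiguous peak region


class TestReferenceWidth:
    def _profile(self, widths):
        n = len(widths)
        return ed.WidthProfile(positions=np.arange(n, dtype=float),
                               widths=np.asarray(widths, dtype=float),
                               peaks=np.array([], dtype=int))

    def test_nearest_rank_15th_percentile(self):
        # lower half = first 20 of 40 samples, values 1..20 -> ceil(0.15*20)=3rd
        widths = list(range(1, 21)) + [50] * 20
        assert ed.reference_width(self._profile(widths)) == 3.0

    def test_constant_profile(self):
        assert ed.reference_width(self._profile([20.0] * 30)) == 20.0

    def test_junction_peaks_do_not_move_reference(self):
        base = [10.0 + 0.1 * i for i in range(20)]
        with_peaks = list(base)
        for i in (4, 9, 14):
            with_peaks[i] = 80.0
        p_clean = self._profile(base + [8.0] * 20)
        p_peaky = self._profile(with_peaks + [8.0] * 20)
        assert ed.reference_width(p_peaky) == ed.reference_width(p_clean)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            ed.reference_width(self._profile([5.0] * 5))


def _hand_profile(widths):
    n = len(widths)
    pixels = np.stack([600 - np.arange(n), np.full(n, 50)], axis=1)
    return ed.WidthProfile(positions=np.arange(n, dtype=float),
                           widths=np.asarray(widths, dtype=float),
                           peaks=np.array([], dtype=int), pixels=pixels)


class TestDetectEar:
    """Hand-built profiles with every internode score enumerable by eye."""

    REF = 16.0

    def _bulge_profile(self):
        # 400 samples mimicking a rendered stem: wide base confined to the
        # lower half, short junction bumps every 40 samples, a 30-sample ear
        # bulge at 260..289, thin (10 px) internodes above it
        w = np.full(400, 18.0)
        w[150:] = 15.0
        w[290:] = 10.0
        for j in range(40, 400, 40):
            if not 240 <= j <= 300:
                w[j:j + 6] = w[j] + 12.0
        w[260:290] = 27.0
        return _hand_profile(w)

    def test_bulge_with_thinning_scores_three(self):
        cand = ed.detect_ear(self._bulge_profile(), self.REF)
        assert cand is not None
        assert cand.score == 3.0
        assert cand.criterion1 and cand.criterion2
        assert 260 <= cand.position <= 290

    def test_thinning_only_scores_two(self):
        # junction bumps but no bulge; clear thinning after the node at 240:
        # the internode ending there wins criterion 2 alone
        w = np.concatenate([np.full(240, 16.0), np.full(160, 10.0)])
        for j in range(40, 400, 40):
            w[j:j + 6] = w[j] + 12.0
        cand = ed.detect_ear(_hand_profile(w), self.REF)
        assert cand is not None
        assert cand.score == 2.0
        assert not cand.criterion1 and cand.criterion2
        assert cand.position == pytest.approx(239.0, abs=6.0)

    def test_flat_profile_gives_none(self):
        w = np.full(400, 16.0)
        assert ed.detect_ear(_hand_profile(w), self.REF) is None

    def test_bulge_alone_insufficient(self):
        # a long wide run in the upper half without thinning above: score 1
        w = np.full(400, 16.0)
        w[260:290] = 27.0
        assert ed.detect_ear(_hand_profile(w), self.REF) is None

    def test_rescaling_invariance(self):
        # scaling widths, reference and positions together must not change
        # the detected internode (relative position preserved)
        prof = self._bulge_profile()
        c1 = ed.detect_ear(prof, self.REF)
        scaled = ed.WidthProfile(positions=prof.positions * 2.0,
                                 widths=prof.widths * 2.0,
                                 peaks=prof.peaks, pixels=prof.pixels)
        c2 = ed.detect_ear(scaled, self.REF * 2.0)
        assert c2 is not None
        assert c2.position == pytest.approx(2.0 * c1.position, rel=1e-9)
        assert c2.score == c1.score

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            ed.detect_ear(self._bulge_profile(), 0.0)


class TestConsensus:
    def _cand(self, row, az=0):
        return ed.EarCandidate(view_azimuth=az, position=600.0 - row,
                               pixel=(row, 50.0), score=3.0,
                               criterion1=True, criterion2=True)

    def test_tight_cluster_keeps_all(self):
        est = ed.consensus([self._cand(r, a) for a, r in
                            zip((0, 90, 180), (500, 502, 498))], height_tol=25.0)
        assert est.valid
        assert est.consensus_height == 500.0
        assert not est.discarded

    def test_outlier_discarded_first(self):
        est = ed.consensus([self._cand(r, a) for a, r in
                            zip((0, 90, 180), (500, 502, 900))], height_tol=25.0)
        assert est.consensus_height == pytest.approx(501.0)
        assert len(est.discarded) == 1
        assert est.discarded[0].pixel[0] == 900

    def test_single_candidate_valid(self):
        est = ed.consensus([self._cand(430)], height_tol=25.0)
        assert est.valid and est.consensus_height == 430.0

    def test_no_candidates_invalid(self):
        assert not ed.consensus([None, None]).valid
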