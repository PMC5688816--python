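"""Primary-ear localisation along the stem of segmented side views.

The apparent stem width varies characteristically around the ear: internodes
above the ear, initiated after it, are much thinner than basal ones, and the
ear internode itself — widened by the husks — appears as a long bump in the
width profile.  The procedure:

1. medial-axis skeleton of the plant mask, analysed as a graph;
2. stem = minimum-arc-length path from the skeleton node nearest the top
   centre of the pot to the highest junction node; a straightness statistic
   (principal-axis explained variance) below 0.82 flags crossing-leaf
   artefacts and rejects the view;
3. width along the stem = 2x the Euclidean distance transform sampled on the
   path; junction peaks flagged against a reference width, the nearest-rank
   15th percentile of lower-half widths (robust to artefactual peaks);
4. per upper-half segment, two criteria — a long above-reference run (the
   husk bump) weighted 1, and clearly thinner internodes above weighted 2 —
   score the candidate ear position;
5. candidates from several views are merged by iteratively discarding the
   height farthest from the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import convolve, distance_transform_edt
from skimage.morphology import medial_axis

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class StemPath:
    """Ordered skeleton pixels from pot top to highest leaf junction."""

    pixels: np.ndarray          # (n, 2) int, (row, col), 8-connected
    arc_length: float
    r_squared: float            # straightness in [0, 1]


@dataclass
class WidthProfile:
    positions: np.ndarray       # arc length from the stem base, px
    widths: np.ndarray          # 2x distance transform, px
    peaks: np.ndarray           # indices flagged as junction peaks
    pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.widths):
            raise ValueError("positions and widths must align")


@dataclass
class EarCandidate:
    view_azimuth: int | None
    position: float                        # arc length, px
    pixel: tuple[float, float] | None      # (row, col)
    score: float
    criterion1: bool
    criterion2: bool


@dataclass
class EarEstimate:
    valid: bool
    consensus_height: float | None = None  # image row of the consensus ear
    positions: dict = field(default_factory=dict)
    retained: list = field(default_factory=list)
    discarded: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# skeleton graph


def skeletonize(mask: np.ndarray, prune_px: float = 10.0) -> nx.MultiGraph:
    """Medial-axis skeleton of ``mask`` as a graph.

    Nodes are junction (>=3 skeleton neighbours) and end (1 neighbour)
    pixels, keyed by (row, col); edges are the skeleton branches between
    them, with attributes ``pixels`` (ordered pixel list including both end
    nodes) and ``weight`` (arc length: 1 per axial step, sqrt(2) diagonal).
    Terminal spurs shorter than ``prune_px`` — the diagonal whiskers the
    exact medial axis grows at shape corners — are pruned, and chains left
    with a degree-2 interior node are merged back into single branches.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    skel = medial_axis(mask, rng=0)  # seeded: medial_axis breaks ties randomly
    nbr_count = convolve(skel.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
                         mode="constant")
    graph = nx.MultiGraph()
    skel_set = set(map(tuple, np.argwhere(skel)))
    node_px = {p for p in skel_set if nbr_count[p] != 2}
    if not node_px:  # pure cycle or single pixel: anchor an arbitrary node
        node_px = {min(skel_set)}
    for p in node_px:
        graph.add_node(p, degree_raw=int(nbr_count[p]))

    def neighbours(p):
        r, c = p
        for dr, dc in _NEIGHBOURS:
            q = (r + dr, c + dc)
            if q in skel_set:
                yield q

    visited_steps = set()

    def step_key(a, b):
        return (a, b) if a <= b else (b, a)

    for start in node_px:
        for first in neighbours(start):
            if step_key(start, first) in visited_steps:
                continue
            path = [start, first]
            visited_steps.add(step_key(start, first))
            prev, cur = start, first
            while cur not in node_px:
                nxts = [q for q in neighbours(cur)
                        if q != prev and step_key(cur, q) not in visited_steps]
                if not nxts:
                    break
                nxt = nxts[0]
                visited_steps.add(step_key(cur, nxt))
                path.append(nxt)
                prev, cur = cur, nxt
            end = path[-1]
            if end not in node_px:
                graph.add_node(end, degree_raw=int(nbr_count[end]))
                node_px.add(end)
            arr = np.asarray(path)
            length = float(np.sum(np.hypot(*np.diff(arr, axis=0).T)))
            graph.add_edge(start, end, pixels=arr, weight=length)
    _merge_junction_clusters(graph)
    if prune_px > 0:
        _prune_spurs(graph, prune_px)
    return graph


def _merge_junction_clusters(graph: nx.MultiGraph) -> None:
    """Collapse touching junction pixels (a 2x2 diamond at an X-crossing)
    into a single junction node, dropping the intra-cluster stub edges."""
    junctions = {n for n in graph.nodes if graph.degree(n) >= 3}
    adj = nx.Graph()
    adj.add_nodes_from(junctions)
    for a, b, d in graph.edges(data=True):
        if a in junctions and b in junctions and d["weight"] <= 1.5:
            adj.add_edge(a, b)
    for cluster in list(nx.connected_components(adj)):
        if len(cluster) < 2:
            continue
        centroid = np.mean(np.asarray(list(cluster), dtype=float), axis=0)
        rep = min(cluster, key=lambda n: np.hypot(n[0] - centroid[0], n[1] - centroid[1]))
        for n in cluster:
            if n == rep:
                continue
            for _, other, key, d in list(graph.edges(n, keys=True, data=True)):
                graph.remove_edge(n, other, key)
                if other not in cluster:
                    px = d["pixels"]
                    if tuple(px[0]) != n:
                        px = px[::-1]
                    px = np.concatenate([[rep], px])
                    step = float(np.hypot(rep[0] - n[0], rep[1] - n[1]))
                    graph.add_edge(rep, other, pixels=px, weight=d["weight"] + step)
            graph.remove_node(n)


def _prune_spurs(graph: nx.MultiGraph, prune_px: float) -> None:
    """Remove short terminal branches, then merge through degree-2 nodes."""
    changed = True
    while changed:
        changed = False
        for n in [n for n in graph.nodes if graph.degree(n) == 1]:
            (_, _, data), = graph.edges(n, data=True)
            if data["weight"] < prune_px:
                graph.remove_node(n)
                changed = True
    merged = True
    while merged:
        merged = False
        for n in list(graph.nodes):
            if graph.degree(n) != 2:
                continue
            edges = list(graph.edges(n, keys=True, data=True))
            if len(edges) != 2:
                continue  # double edge to the same neighbour (loop through n)
            (_, u, _, du), (_, v, _, dv) = edges
            if u == n or v == n or u == v:
                continue
            pu = du["pixels"] if tuple(du["pixels"][-1]) == n else du["pixels"][::-1]
            pv = dv["pixels"] if tuple(dv["pixels"][0]) == n else dv["pixels"][::-1]
            graph.remove_node(n)
            graph.add_edge(u, v, pixels=np.concatenate([pu, pv[1:]]),
                           weight=du["weight"] + dv["weight"])
            merged = True


def _junction_nodes(graph: nx.MultiGraph):
    return [n for n in graph.nodes if graph.degree(n) >= 3]


def path_straightness(pixels: np.ndarray) -> float:
    """Straightness of a path as the squared row-col correlation of its pixels.

    A real stem leans slightly but consistently, so its pixels correlate
    almost perfectly; a path that detours along a crossing leaf reverses
    its lateral drift and the correlation collapses.  A path essentially
    parallel to an image axis (lateral spread under 1 px) is straight by
    construction and scores 1.
    """
    pts = np.asarray(pixels, dtype=float)
    if len(pts) < 3:
        return 1.0
    sd = pts.std(axis=0)
    if sd.min() < 1.0:
        return 1.0
    r = np.corrcoef(pts[:, 0], pts[:, 1])[0, 1]
    return float(r * r)


def extract_stem(graph: nx.MultiGraph, pot_top_center: tuple[float, float]) -> StemPath:
    """Shortest skeleton path from the node nearest the pot top to the highest junction."""
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("empty skeleton graph")
    pot = np.asarray(pot_top_center, dtype=float)
    start = min(nodes, key=lambda n: float(np.hypot(n[0] - pot[0], n[1] - pot[1])))
    junctions = _junction_nodes(graph)
    pool = junctions if junctions else nodes
    end = min(pool, key=lambda n: (n[0], n[1]))  # minimal row = highest in image
    try:
        node_seq = nx.dijkstra_path(graph, start, end, weight="weight")
    except nx.NetworkXNoPath as exc:
        raise ValueError(
            f"skeleton disconnected between pot node {start} and top node {end}"
        ) from exc
    pixels = [np.array([start])]
    for a, b in zip(node_seq[:-1], node_seq[1:]):
        datas = graph.get_edge_data(a, b)
        best = min(datas.values(), key=lambda d: d["weight"])
        seg = best["pixels"]
        if tuple(seg[0]) != a:
            seg = seg[::-1]
        pixels.append(seg[1:])
    px = np.concatenate(pixels, axis=0)
    arc = float(np.sum(np.hypot(*np.diff(px, axis=0).T))) if len(px) > 1 else 0.0
    return StemPath(pixels=px, arc_length=arc, r_squared=path_straightness(px))


# ---------------------------------------------------------------------------
# width profile


def width_profile(mask: np.ndarray, stem_path: StemPath,
                  peak_ratio: float = 1.3, min_run: int = 3) -> WidthProfile:
    """Stem width along the path: 2x exact Euclidean distance transform.

    Background pixels have distance 0, a mask pixel adjacent to background
    distance 1 (a 1-px strip therefore has width 2).  Leaf-junction peaks are
    runs of >= ``min_run`` consecutive samples exceeding ``peak_ratio`` times
    a local baseline (rolling 25th percentile over ~1/4 of the profile, which
    tracks the internode width underneath even wide bumps), so the
    alternation of thin internodes and junction bumps is flagged regardless
    of the overall taper.
    """
    mask = np.asarray(mask, dtype=bool)
    px = stem_path.pixels
    edt = distance_transform_edt(mask)
    widths = 2.0 * edt[px[:, 0], px[:, 1]]
    steps = np.hypot(*np.diff(px, axis=0).T) if len(px) > 1 else np.array([])
    positions = np.concatenate([[0.0], np.cumsum(steps)])
    profile = WidthProfile(positions=positions, widths=widths, peaks=np.array([], dtype=int),
                           pixels=px)
    n = len(widths)
    if n >= 2 * min_run:
        from scipy.ndimage import percentile_filter
        win = max(15, 2 * (n // 8) + 1)
        baseline = percentile_filter(widths, percentile=25, size=win, mode="nearest")
        runs = _runs_above(widths - peak_ratio * baseline, 0.0, min_run)
        profile.peaks = np.concatenate([np.arange(a, b) for a, b in runs]) \
            if runs else np.array([], dtype=int)
    return profile


def _runs_above(widths: np.ndarray, threshold: float, min_run: int):
    """Contiguous index runs [a, b) where widths > threshold, length >= min_run."""
    above = widths > threshold
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def reference_width(profile: WidthProfile, percentile: float = 0.15,
                    min_samples: int = 10) -> float:
    """Nearest-rank low percentile of widths over the lower half of the stem.

    The 15th percentile of lower-half widths estimates the undisturbed stem
    width while ignoring junction peaks, occluding leaves and tutor-rod
    artefacts, which all bias widths upward.
    """
    if len(profile.positions) < min_samples:
        raise ValueError(f"profile too short (<{min_samples} samples)")
    half = profile.positions[-1] / 2.0
    lower = profile.widths[profile.positions <= half]
    if len(lower) < 2:
        raise ValueError("profile does not cover the lower half of the stem")
    k = max(1, int(np.ceil(percentile * len(lower))))
    return float(np.sort(lower)[k - 1])


# ---------------------------------------------------------------------------
# two-criterion ear scoring


def detect_ear(profile: WidthProfile, ref_width: float, w1: float = 1.0, w2: float = 2.0,
               above_ratio: float = 1.1, min_run: int = 3,
               min_peak_len: float | None = None, ratio_drop: float = 0.75,
               view_azimuth: int | None = None) -> EarCandidate | None:
    """Score upper-half stem segments with the two ear criteria.

    Segments are the alternation of runs exceeding ``above_ratio`` x the
    reference width (peaks) and the stretches between them (internodes).
    Criterion 1 (weight ``w1``): the segment is a *long* above-reference run
    — the husk-widened ear internode — longer than ``min_peak_len`` (default
    1.5x the median upper-half run length, so ordinary leaf-junction bumps,
    which outnumber the single ear run, fail it).  Criterion 2 (weight
    ``w2``): the internodes above the segment are clearly thinner than the
    reference (mean width < ``ratio_drop`` x reference).  Returns the best
    candidate with score >= 2, else None: a bulge with thinning above scores
    w1+w2, thinning alone w2, a bulge alone (broken leaf, wide junction)
    only w1 and is not trusted.  Ties break toward the lower position (the
    ear is the last initiated lateral axis; thinning starts just above it).
    """
    if ref_width <= 0:
        raise ValueError("reference width must be positive")
    pos, widths = profile.positions, profile.widths
    if len(pos) == 0:
        return None
    total = pos[-1]
    half = total / 2.0
    runs = _runs_above(widths, above_ratio * ref_width, min_run)

    def long_threshold(a: int, b: int) -> float:
        if min_peak_len is not None:
            return min_peak_len
        others = [pos[bb - 1] - pos[aa] for aa, bb in runs
                  if (aa, bb) != (a, b) and pos[bb - 1] > half]
        # junction bumps outnumber the single ear run; compare against them,
        # or against 5% of stem length when the run stands alone
        return 1.5 * float(np.median(others)) if others else 0.05 * total

    segments = []  # (start_idx, end_idx, is_run)
    prev = 0
    for a, b in runs:
        if a > prev:
            segments.append((prev, a, False))
        segments.append((a, b, True))
        prev = b
    if prev < len(pos):
        segments.append((prev, len(pos), False))

    def thin_above(seg_idx: int, n_internodes: int = 2) -> bool:
        # pooled width of the next internodes (non-run segments) above,
        # skipping junction/bulge runs: the decrease sets in immediately
        # above the ear
        pool = []
        taken = 0
        for a, b, is_run in segments[seg_idx + 1:]:
            if is_run:
                continue
            pool.append(widths[a:b])
            taken += 1
            if taken >= n_internodes:
                break
        if not pool:
            return False
        above = np.concatenate(pool)
        if len(above) < 3:
            return False
        return bool(np.mean(above) < ratio_drop * ref_width)

    candidates: list[EarCandidate] = []
    for i, (a, b, is_run) in enumerate(segments):
        mid = 0.5 * (pos[a] + pos[b - 1])
        # upper-half restriction keyed on the segment's top end: the ear NODE
        # (top of the ear internode) is what anatomy places in the upper half
        if pos[b - 1] <= half:
            continue
        c1 = bool(is_run and (pos[b - 1] - pos[a]) > long_threshold(a, b))
        c2 = thin_above(i)
        score = w1 * c1 + w2 * c2
        if score >= 2.0 and (c1 or c2):
            # a bulge run marks the ear at its centre; a thinning-only
            # internode marks it at its top node, where the thinning begins
            idx = (a + b - 1) // 2 if is_run else b - 1
            ear_pos = float(mid) if is_run else float(pos[b - 1])
            pixel = tuple(profile.pixels[idx]) if profile.pixels is not None else None
            candidates.append(EarCandidate(view_azimuth=view_azimuth, position=ear_pos,
                                           pixel=pixel, score=float(score),
                                           criterion1=c1, criterion2=c2))
    if not candidates:
        return None
    best_score = max(c.score for c in candidates)
    best = [c for c in candidates if c.score == best_score]
    return min(best, key=lambda c: c.position)


def consensus(candidates, height_tol: float = 25.0) -> EarEstimate:
    """Merge per-view candidates by trimming outlying heights toward the median.

    Heights are image rows of the candidate pixels.  The candidate whose
    height deviates most from the current median is discarded until every
    deviation is within ``height_tol`` px or one candidate remains; the
    consensus is the median height of the survivors.
    """
    cands = [c for c in candidates if c is not None]
    if not cands:
        return EarEstimate(valid=False)
    heights = {id(c): (c.pixel[0] if c.pixel is not None else c.position) for c in cands}
    retained = list(cands)
    discarded: list[EarCandidate] = []
    while len(retained) > 1:
        med = float(np.median([heights[id(c)] for c in retained]))
        devs = [abs(heights[id(c)] - med) for c in retained]
        worst = int(np.argmax(devs))
        if devs[worst] <= height_tol:
            break
        discarded.append(retained.pop(worst))
    med = float(np.median([heights[id(c)] for c in retained]))
    positions = {c.view_azimuth: (med, c.pixel[1] if c.pixel is not None else None)
                 for c in retained}
    return EarEstimate(valid=True, consensus_height=med, positions=positions,
                       retained=retained, discarded=discarded)
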