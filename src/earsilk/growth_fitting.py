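"""Segmented (piecewise-linear) fits to silk pixel-count time courses.

A silk bundle's visible area rises roughly linearly after silking and
plateaus when silk growth stops (later declining with senescence).  A
continuous piecewise-linear least-squares fit with estimated breakpoints
yields the two target traits: the maximum silk growth rate (steepest segment
slope, px/day) and the duration of silk growth (from onset to the breakpoint
where growth drops off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar


@dataclass
class SilkTimeSeries:
    days: np.ndarray
    counts: np.ndarray
    plant_id: str = "plant"
    genotype: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.days) != len(self.counts):
            raise ValueError("days and counts must align")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class SegmentedFit:
    breakpoints: np.ndarray
    slopes: np.ndarray          # one per segment, px/day
    intercept: float            # fitted value at the first observed day
    rss: float
    n_segments: int
    degenerate: bool = False    # breakpoint did not improve on a single line

    def predict(self, days) -> np.ndarray:
        days = np.asarray(days, dtype=float)
        d0 = self._d0
        y = self.intercept + self.slopes[0] * (days - d0)
        for bp, s_prev, s_next in zip(self.breakpoints, self.slopes[:-1], self.slopes[1:]):
            y = y + (s_next - s_prev) * np.maximum(days - bp, 0.0)
        return y

    _d0: float = 0.0


@dataclass
class SilkGrowthTraits:
    rate_max: float
    duration: float
    onset_day: float


def _design(days: np.ndarray, breakpoints: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(days), days - days[0]]
    cols += [np.maximum(days - bp, 0.0) for bp in breakpoints]
    return np.stack(cols, axis=1)


def _fit_at(days, counts, breakpoints):
    X = _design(days, np.asarray(breakpoints, dtype=float))
    beta, *_ = np.linalg.lstsq(X, counts, rcond=None)
    resid = counts - X @ beta
    return beta, float(resid @ resid)


def fit_segmented(series: SilkTimeSeries, n_breakpoints: int = 1,
                  n_grid: int = 20) -> SegmentedFit:
    """Continuous piecewise-linear least squares with estimated breakpoints.

    Breakpoints are located by a grid search over the observation days plus
    ``n_grid`` uniform interior points (searched jointly for 2 breakpoints),
    then refined one at a time by bounded scalar minimisation of the RSS.
    The fitted RSS never exceeds the single-line RSS; if the improvement is
    negligible the ``degenerate`` flag is set.
    """
    days, counts = series.days, series.counts
    if len(days) < n_breakpoints + 3:
        raise ValueError(f"need at least {n_breakpoints + 3} observations")
    lo, hi = days[0], days[-1]
    margin = 1e-6 * (hi - lo)
    grid = np.unique(np.clip(np.concatenate([
        days[1:-1], np.linspace(lo, hi, n_grid + 2)[1:-1]
    ]), lo + margin, hi - margin))

    _, rss_line = _fit_at(days, counts, [])

    if n_breakpoints == 1:
        combos = [[g] for g in grid]
    elif n_breakpoints == 2:
        combos = [[a, b] for i, a in enumerate(grid) for b in grid[i + 1:]
                  if b - a > (hi - lo) / (2 * len(days))]
    else:
        raise ValueError("n_breakpoints must be 1 or 2")
    rss_all = [_fit_at(days, counts, c)[1] for c in combos]
    best = list(combos[int(np.argmin(rss_all))])

    # coordinate-wise local refinement of each breakpoint, searching within
    # one grid step of the best grid point (the RSS is only piecewise smooth
    # in the breakpoint, so a global bounded search could leave the basin)
    for _ in range(2):
        for j in range(n_breakpoints):
            gi = int(np.searchsorted(grid, best[j]))
            lo_j = grid[max(gi - 1, 0)]
            hi_j = grid[min(gi + 1, len(grid) - 1)]
            if j > 0:
                lo_j = max(lo_j, best[j - 1])
            if j + 1 < n_breakpoints:
                hi_j = min(hi_j, best[j + 1])
            if hi_j - lo_j <= 2 * margin:
                continue
            res = minimize_scalar(
                lambda b: _fit_at(days, counts, best[:j] + [b] + best[j + 1:])[1],
                bounds=(lo_j, hi_j), method="bounded",
                options={"xatol": 1e-8 * (hi - lo)})
            cand = best.copy()
            cand[j] = float(res.x)
            if _fit_at(days, counts, cand)[1] <= _fit_at(days, counts, best)[1]:
                best = cand

    beta, rss = _fit_at(days, counts, best)
    slopes = np.concatenate([[beta[1]], beta[1] + np.cumsum(beta[2:])])
    scale = max(float(np.sum((counts - counts.mean()) ** 2)), 1e-12)
    degenerate = (rss_line - rss) / scale < 1e-9 or \
        bool(np.max(np.abs(np.diff(slopes))) < 1e-6 * max(1.0, np.max(np.abs(slopes))))
    fit = SegmentedFit(breakpoints=np.asarray(best, dtype=float), slopes=slopes,
                       intercept=float(beta[0]), rss=min(rss, rss_line),
                       n_segments=n_breakpoints + 1, degenerate=degenerate)
    fit._d0 = float(days[0])
    return fit


def extract_traits(fit: SegmentedFit, series: SilkTimeSeries,
                   noise_floor_frac: float = 0.02,
                   rate_threshold: float = 0.2) -> SilkGrowthTraits:
    """Maximum growth rate and growth duration from a segmented fit.

    rate_max is the steepest segment slope.  Onset is where the first rising
    segment crosses zero (clipped to the observed day range; silking day by
    construction of the day axis), falling back to the first day the count
    clears a noise floor of ``noise_floor_frac`` x the series maximum.
    Duration runs from onset to the first breakpoint after which the slope
    falls below ``rate_threshold`` x rate_max (the plateau), or to the last
    observed day if growth never drops off.
    """
    if np.all(series.counts <= 0):
        raise ValueError("no silk signal (all counts zero)")
    slopes = fit.slopes
    rate_max = float(np.max(slopes))
    if rate_max <= 0:
        raise ValueError("no rising segment in fit; no silk growth detected")
    d0, d_end = float(series.days[0]), float(series.days[-1])
    first_rising = int(np.argmax(slopes > 0))
    seg_start = d0 if first_rising == 0 else float(fit.breakpoints[first_rising - 1])
    val_at_start = float(fit.predict(seg_start))
    slope0 = float(slopes[first_rising])
    onset = seg_start - val_at_start / slope0 if slope0 > 0 else d0
    if onset < d0:
        onset = d0  # silking before the observation window; clip to it
    elif not np.isfinite(onset) or onset > d_end:
        floor = noise_floor_frac * float(np.max(series.counts))
        above = series.days[series.counts > floor]
        onset = float(above[0]) if len(above) else d0
    end = d_end
    for bp, s_next in zip(fit.breakpoints, slopes[1:]):
        if bp > onset and s_next < rate_threshold * rate_max:
            end = float(bp)
            break
    duration = max(end - onset, 0.0)
    if duration <= 0:
        raise ValueError("degenerate growth duration")
    return SilkGrowthTraits(rate_max=rate_max, duration=float(duration),
                            onset_day=float(onset))


def fit_series(series: SilkTimeSeries, n_breakpoints: int = 1) -> tuple[SegmentedFit, SilkGrowthTraits]:
    fit = fit_segmented(series, n_breakpoints=n_breakpoints)
    return fit, extract_traits(fit, series)


def summarize_panel(traits_table: pd.DataFrame,
                    value_cols=("rate_max", "duration")) -> pd.DataFrame:
    """Per genotype x treatment means and standard errors of the fitted traits."""
    if traits_table.empty:
        raise ValueError("empty traits table")
    grouped = traits_table.groupby(["genotype", "treatment"])
    rows = []
    for (geno, treat), g in grouped:
        row = {"genotype": geno, "treatment": treat, "n": len(g)}
        for col in value_cols:
            row[f"{col}_mean"] = float(g[col].mean())
            row[f"{col}_se"] = float(g[col].std(ddof=1) / np.sqrt(len(g))) \
                if len(g) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
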