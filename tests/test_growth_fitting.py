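"""Segmented growth-curve fitting and silk trait extraction."""

import numpy as np
import pandas as pd
import pytest

from earsilk import growth_fitting as gf


def series(days, counts, **kw):
    return gf.SilkTimeSeries(days=np.asarray(days, dtype=float),
                             counts=np.asarray(counts, dtype=float), **kw)


def dense_grid_oracle(days, counts, n=2000):
    """Independent breakpoint search on a dense grid (no refinement path)."""
    best_rss, best_bp = np.inf, None
    for bp in np.linspace(days[0] + 1e-6, days[-1] - 1e-6, n):
        X = np.stack([np.ones_like(days), days - days[0],
                      np.maximum(days - bp, 0.0)], axis=1)
        beta, *_ = np.linalg.lstsq(X, counts, rcond=None)
        rss = float(np.sum((counts - X @ beta) ** 2))
        if rss < best_rss:
            best_rss, best_bp = rss, bp
    return best_bp, best_rss


class TestFitSegmented:
    def test_exact_rise_plateau(self):
        s = series(np.arange(7), [0, 1000, 2000, 3000, 4000, 4000, 4000])
        fit = gf.fit_segmented(s, 1)
        assert fit.breakpoints[0] == pytest.approx(4.0, abs=1e-6)
        assert fit.slopes[0] == pytest.approx(1000.0, abs=1e-6)
        assert fit.slopes[1] == pytest.approx(0.0, abs=1e-6)
        assert fit.rss < 1e-12

    def test_noisy_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(0)
        days = np.arange(7.0)
        bps, slopes = [], []
        for _ in range(20):
            counts = np.minimum(days, 4.0) * 1000.0 + rng.normal(0, 50, 7)
            s = series(days, np.clip(counts, 0, None))
            fit = gf.fit_segmented(s, 1)
            bp_o, rss_o = dense_grid_oracle(days, s.counts)
            assert fit.rss <= rss_o + 1e-6 or fit.breakpoints[0] == pytest.approx(bp_o, abs=0.05)
            bps.append(fit.breakpoints[0])
            slopes.append(fit.slopes[0])
        assert np.all(np.abs(np.array(bps) - 4.0) <= 0.5)
        assert np.all(np.abs(np.array(slopes) - 1000.0) <= 100.0)

    def test_linear_series_degenerate_flag(self):
        s = series(np.arange(6), np.arange(6) * 500.0)
        fit = gf.fit_segmented(s, 1)
        assert fit.degenerate
        assert fit.slopes[0] == pytest.approx(fit.slopes[1], abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)

    def test_rss_not_worse_than_single_line(self):
        rng = np.random.default_rng(3)
        days = np.arange(9.0)
        counts = np.clip(np.minimum(days, 5.0) * 700 + rng.normal(0, 100, 9), 0, None)
        s = series(days, counts)
        X = np.stack([np.ones_like(days), days], axis=1)
        beta, *_ = np.linalg.lstsq(X, counts, rcond=None)
        rss_line = float(np.sum((counts - X @ beta) ** 2))
        f1 = gf.fit_segmented(s, 1)
        f2 = gf.fit_segmented(s, 2)
        assert f1.rss <= rss_line + 1e-9
        assert f2.rss <= f1.rss + 1e-9

    def test_affine_count_rescaling_rescales_slopes(self):
        days = np.arange(8.0)
        counts = np.minimum(days, 5.0) * 640.0
        f1 = gf.fit_segmented(series(days, counts), 1)
        f2 = gf.fit_segmented(series(days, counts / counts.max()), 1)
        np.testing.assert_allclose(f2.slopes * counts.max(), f1.slopes, atol=1e-6)
        np.testing.assert_allclose(f2.breakpoints, f1.breakpoints, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gf.fit_segmented(series([0, 1, 2], [0, 1, 2]), 1)


class TestExtractTraits:
    def test_rise_plateau_traits(self):
        s = series(np.arange(7), [0, 1000, 2000, 3000, 4000, 4000, 4000])
        fit = gf.fit_segmented(s, 1)
        tr = gf.extract_traits(fit, s)
        assert tr.rate_max == pytest.approx(1000.0, rel=1e-6)
        assert tr.duration == pytest.approx(4.0, abs=1e-6)
        assert tr.onset_day == pytest.approx(0.0, abs=1e-6)

    def test_decreasing_rate_two_segments(self):
        days = np.arange(9.0)
        counts = np.where(days <= 3, 800 * days,
                          np.where(days <= 5, 2400 + 200 * (days - 3), 2800.0))
        s = series(days, counts)
        fit = gf.fit_segmented(s, 2)
        tr = gf.extract_traits(fit, s)
        assert tr.rate_max == pytest.approx(800.0, rel=1e-6)
        assert tr.duration == pytest.approx(5.0, abs=1e-6)

    def test_all_zero_series_rejected(self):
        s = series(np.arange(5), np.zeros(5))
        fit = gf.SegmentedFit(breakpoints=np.array([2.0]),
                              slopes=np.array([0.0, 0.0]), intercept=0.0,
                              rss=0.0, n_segments=2)
        with pytest.raises(ValueError):
            gf.extract_traits(fit, s)

    def test_parameter_recovery_batch(self):
        # 5% plateau-level noise: median relative rate error < 10%,
        # median duration error < 0.5 d
        rng = np.random.default_rng(1)
        rate_errs, dur_errs = [], []
        for _ in range(60):
            rate = rng.uniform(200, 2000)
            dur = rng.uniform(2, 7)
            days = np.arange(0.0, np.ceil(dur) + 4)
            true = rate * np.minimum(days, dur)
            counts = np.clip(true + rng.normal(0, 0.05 * rate * dur, len(days)), 0, None)
            fit, tr = gf.fit_series(series(days, counts))
            rate_errs.append(abs(tr.rate_max - rate) / rate)
            dur_errs.append(abs(tr.duration - dur))
        assert np.median(rate_errs) < 0.10
        assert np.median(dur_errs) < 0.5

    def test_treatment_ordering_preserved(self):
        # when the generator imposes lower water-deficit rates, the fitted
        # mean rates keep the well-watered > water-deficit ordering
        rng = np.random.default_rng(2)
        fitted = {"WW": [], "WD": []}
        for treat, base in (("WW", 1500.0), ("WD", 700.0)):
            for _ in range(10):
                rate = base * rng.uniform(0.85, 1.15)
                dur = rng.uniform(3, 6)
                days = np.arange(0.0, np.ceil(dur) + 4)
                counts = np.clip(rate * np.minimum(days, dur)
                                 + rng.normal(0, 0.05 * rate * dur, len(days)), 0, None)
                _, tr = gf.fit_series(series(days, counts))
                fitted[treat].append(tr.rate_max)
        assert np.mean(fitted["WW"]) > np.mean(fitted["WD"])


class TestSummarizePanel:
    def test_mean_and_se(self):
        df = pd.DataFrame({
            "genotype": ["g1"] * 3, "treatment": ["WW"] * 3,
            "rate_max": [900.0, 1000.0, 1100.0], "duration": [4.0, 4.0, 4.0],
        })
        out = gf.summarize_panel(df)
        assert out.loc[0, "rate_max_mean"] == pytest.approx(1000.0)
        assert out.loc[0, "rate_max_se"] == pytest.approx(57.735, abs=0.01)

    def test_single_replicate_se_nan(self):
        df = pd.DataFrame({"genotype": ["g"], "treatment": ["WD"],
                           "rate_max": [800.0], "duration": [3.0]})
        out = gf.summarize_panel(df)
        assert out.loc[0, "rate_max_mean"] == 800.0
        assert np.isnan(out.loc[0, "rate_max_se"])

    def test_identical_treatments_identical_summaries(self):
        base = pd.DataFrame({"genotype": ["g"] * 3, "rate_max": [1.0, 2.0, 3.0],
                             "duration": [4.0, 5.0, 6.0]})
        df = pd.concat([base.assign(treatment="WW"), base.assign(treatment="WD")])
        out = gf.summarize_panel(df).set_index("treatment")
        for col in ("rate_max_mean", "rate_max_se", "duration_mean"):
            assert out.loc["WW", col] == out.loc["WD", col]
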