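import numpy as np
import pandas as pd
import pytest

from p53pulse.proliferation import CumulativeCurve, DivisionProfile
from p53pulse.signal_core import Trace, area_under_curve
from p53pulse.stats_report import (analyze_trace, build_feature_table,
                                   correlation_heatmap, fold_increase,
                                   group_difference_curves,
                                   group_median_correlation, pairwise_welch,
                                   proliferation_slopes)
from p53pulse.wavelet import RidgeSeries

from conftest import make_trace


class TestFeatureTable:
    def _single_cell(self):
        t = np.arange(0.0, 120.0, 0.5)
        y = 150.0 + 100.0 * np.sin(2 * np.pi * t / 7)
        traces = [Trace("c1", "p53", t, y)]
        divisions = {"c1": DivisionProfile("c1", np.array([10.0, 27.0, 45.0]), 120.0)}
        metadata = pd.DataFrame({"cell_id": ["c1"], "dose_gy": [0.0], "gh2ax": [12.0]})
        return traces, divisions, metadata

    def test_single_cell_row_matches_hand_computation(self):
        traces, divisions, metadata = self._single_cell()
        features, ridges = build_feature_table(traces, divisions, metadata)
        row = features.iloc[0]
        assert row.cell_id == "c1" and row.channel == "p53"
        assert row.total_divisions == 3
        assert row.median_imt == pytest.approx(17.5)
        assert row.age == pytest.approx(75.0)
        assert row.auc == pytest.approx(area_under_curve(traces[0]))
        assert row.median_cwt_amplitude == pytest.approx(100.0, rel=0.05)
        assert row.median_period == pytest.approx(7.0, abs=0.2)
        assert row.detrended_sd == pytest.approx(100.0 / np.sqrt(2), rel=0.05)
        assert bool(row.is_pulsatile)  # 17 pulses in 120 h
        assert row.period_class == "stable"
        assert "c1" in ridges

    def test_cell_without_divisions(self):
        traces, _, metadata = self._single_cell()
        features, _ = build_feature_table(traces, {}, metadata)
        row = features.iloc[0]
        assert row.total_divisions == 0
        assert np.isnan(row.median_imt)
        assert row.age == pytest.approx(119.5)

    def test_duplicate_cell_channel_rejected(self):
        traces, divisions, metadata = self._single_cell()
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(traces + traces, divisions, metadata)


class TestCorrelations:
    def test_self_and_affine_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"dose_gy": 0.0, "a": x, "b": 2 * x + 1,
                           "c": rng.normal(size=200)})
        mats = correlation_heatmap(df, ["a", "b", "c"])
        m = mats[0.0]
        assert np.allclose(np.diag(m), 1.0)
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)

    def test_independent_metrics_rarely_correlate(self):
        rng = np.random.default_rng(1)
        small = 0
        total = 0
        for _ in range(20):
            df = pd.DataFrame(rng.normal(size=(500, 6)),
                              columns=[f"m{i}" for i in range(6)])
            m = correlation_heatmap(df, df.columns, group_by_dose=False).to_numpy()
            off = m[np.triu_indices(6, 1)]
            small += np.sum(np.abs(off) < 0.1)
            total += off.size
        assert small / total >= 0.90

    def test_positive_semidefinite_on_complete_data(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(100, 5)),
                          columns=list("abcde"))
        m = correlation_heatmap(df, df.columns, group_by_dose=False).to_numpy()
        assert np.linalg.eigvalsh(m).min() >= -1e-8

    def test_group_median_correlation_linear_decrease(self):
        df = pd.DataFrame({"g": np.repeat([0, 1, 2, 3], 10),
                           "v": np.repeat([8.0, 6.0, 4.0, 2.0], 10)})
        assert group_median_correlation(df, "v", "g") == pytest.approx(-1.0)

    def test_group_median_correlation_constant_is_nan(self):
        df = pd.DataFrame({"g": np.repeat([0, 1, 2], 5), "v": 1.0})
        assert np.isnan(group_median_correlation(df, "v", "g"))

    def test_amplitude_tracks_damage_on_cohort(self, small_features):
        features, _, _ = small_features
        p53 = features[features.channel == "p53"]
        assert group_median_correlation(p53, "median_cwt_amplitude", "dose_gy") > 0.9


class TestPairwiseWelch:
    def test_identical_groups_p_one_diagonal_zero(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"g": ["a"] * 20 + ["b"] * 20,
                           "v": np.concatenate([x, x])})
        m = pairwise_welch(df, "v", "g")
        assert m.loc["a", "a"] == 0.0
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)

    def test_separated_distributions_tiny_p(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"g": ["a"] * 50 + ["b"] * 50,
                           "v": np.concatenate([rng.normal(0, 1, 50),
                                                rng.normal(5, 1, 50)])})
        assert pairwise_welch(df, "v", "g").loc["a", "b"] < 1e-10

    def test_all_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"g": rng.choice(list("abcd"), 200),
                           "v": rng.normal(size=200)})
        m = pairwise_welch(df, "v", "g").to_numpy()
        assert np.all((m >= 0) & (m <= 1))


class TestDifferenceCurves:
    def _ridges(self, period_fn, n, t):
        return [RidgeSeries(f"c{i}", t, period_fn(t), np.ones(len(t)),
                            np.ones(len(t)), np.ones(len(t), bool))
                for i in range(n)]

    def _curve(self, t, value):
        return CumulativeCurve(t, value, n_iterations=10, reference_n=5)

    def test_identical_groups_vanish(self):
        t = np.arange(0.0, 120.0, 0.5)
        ridges = {"stable": self._ridges(lambda t: np.full_like(t, 5.5), 4, t),
                  "switcher": self._ridges(lambda t: np.full_like(t, 5.5), 4, t)}
        cm = np.linspace(0, 1, len(t))
        curves = {"stable": self._curve(t, cm), "switcher": self._curve(t, cm.copy())}
        _, pdiff, cmdiff = group_difference_curves(ridges, curves, dt=0.5)
        assert np.allclose(pdiff, 0.0, atol=1e-9)
        assert np.allclose(cmdiff, 0.0)

    def test_switcher_drift_appears_after_onset(self):
        t = np.arange(0.0, 120.0, 0.5)
        ridges = {
            "stable": self._ridges(lambda t: np.full_like(t, 5.5), 4, t),
            "switcher": self._ridges(
                lambda t: 5.5 + 0.02 * np.maximum(0.0, t - 60.0), 4, t),
        }
        cm = np.linspace(0, 1, len(t))
        curves = {"stable": self._curve(t, cm), "switcher": self._curve(t, cm)}
        _, pdiff, _ = group_difference_curves(ridges, curves, dt=0.5)
        early = pdiff[(t > 20) & (t < 50)]
        late_slope = np.polyfit(t[t > 70], pdiff[t > 70], 1)[0]
        assert np.max(np.abs(early)) < 0.1
        assert late_slope == pytest.approx(0.02, rel=0.25)

    def test_smoothing_preserves_curve_mean(self):
        t = np.arange(0.0, 120.0, 0.5)
        drift = 0.5 + 0.01 * t
        ridges = {
            "stable": self._ridges(lambda t: np.full_like(t, 5.5), 4, t),
            "switcher": self._ridges(lambda t: 5.5 + drift, 4, t),
        }
        cm = np.linspace(0, 1, len(t))
        curves = {"stable": self._curve(t, cm), "switcher": self._curve(t, cm)}
        _, pdiff, _ = group_difference_curves(ridges, curves, dt=0.5)
        assert np.mean(pdiff) == pytest.approx(np.mean(drift), rel=0.01)


class TestProliferationSlopes:
    def _linear_curve(self, slope, t):
        return CumulativeCurve(t, slope * t, n_iterations=10, reference_n=5)

    def test_fold_from_reported_slopes(self):
        assert f"{fold_increase(0.0109, 0.0065):.2f}" == "1.68"
        assert f"{fold_increase(0.0133, 0.0072):.2f}" == "1.85"
        assert fold_increase(0.0133, 0.0072) == pytest.approx(1.847, abs=5e-4)

    def test_identical_curves_fold_one(self):
        t = np.arange(0.0, 120.0, 0.5)
        c = self._linear_curve(0.008, t)
        s, w, fold = proliferation_slopes(c, c)
        assert s == pytest.approx(0.008)
        assert fold == pytest.approx(1.0)

    def test_fit_restricted_to_late_phase(self):
        t = np.arange(0.0, 120.0, 0.5)
        flat_then_rise = np.where(t < 60.0, 0.0, 0.01 * (t - 60.0))
        c1 = CumulativeCurve(t, flat_then_rise, 10, 5)
        c2 = self._linear_curve(0.005, t)
        s, w, fold = proliferation_slopes(c2, c1, fit_start=60.0)
        assert w == pytest.approx(0.01, rel=1e-6)
        assert fold == pytest.approx(2.0, rel=1e-6)

    def test_nonpositive_stable_slope_flagged_infinite(self):
        t = np.arange(0.0, 120.0, 0.5)
        flat = CumulativeCurve(t, np.zeros_like(t), 10, 5)
        rising = self._linear_curve(0.01, t)
        _, _, fold = proliferation_slopes(flat, rising)
        assert np.isinf(fold)
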