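"""Cross-cell statistics and reporting.

Builds the per-cell feature table from all upstream summaries and computes
correlation heatmaps, group-median correlations, pairwise Welch tests,
stable-vs-switcher difference curves, and proliferation slopes with their
fold increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import period_class as pc
from .proliferation import CumulativeCurve, DivisionProfile, cell_age, median_imt
from .pulses import PeakParams, classify_pulsatile, find_pulses, peak_amplitude_median
from .signal_core import (Trace, area_under_curve, detrended_sd,
                          normalize_by_envelope, sinc_detrend, sinc_smooth)
from .wavelet import cwt_morlet, default_period_grid, extract_ridge, median_ridge_metrics

__all__ = [
    "AnalysisParams",
    "analyze_trace",
    "build_feature_table",
    "correlation_heatmap",
    "group_median_correlation",
    "pairwise_welch",
    "group_difference_curves",
    "proliferation_slopes",
    "fold_increase",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Signal-analysis parameters shared by all per-trace computations."""

    detrend_cutoff: float = 50.0  # h
    envelope_window: float = 50.0  # h
    period_grid: np.ndarray = field(default_factory=default_period_grid)
    peak_params: PeakParams = field(default_factory=PeakParams)
    use_coi_only: bool = True


def analyze_trace(trace: Trace, params: AnalysisParams = AnalysisParams()):
    """All per-trace signal summaries plus the period ridge.

    Returns ``(features: dict, ridge: RidgeSeries)``.  The amplitude ridge is
    computed on the detrended signal; the period ridge (returned, and the
    source of the median period) on the detrended, envelope-normalized
    signal, which removes amplitude modulation before period estimation.
    """
    det = sinc_detrend(trace, params.detrend_cutoff)
    amp_spec = cwt_morlet(det.detrended, trace.t, params.period_grid)
    amp_ridge = extract_ridge(amp_spec, trace.cell_id)
    _, med_amp = median_ridge_metrics(amp_ridge, params.use_coi_only)

    norm = normalize_by_envelope(det.detrended, trace.dt, params.envelope_window)
    per_spec = cwt_morlet(norm.normalized, trace.t, params.period_grid)
    per_ridge = extract_ridge(per_spec, trace.cell_id)
    med_period, _ = median_ridge_metrics(per_ridge, params.use_coi_only)

    pulses = find_pulses(trace, params.peak_params, cutoff_period=params.detrend_cutoff)
    features = {
        "median_cwt_amplitude": med_amp,
        "median_peak_amplitude": peak_amplitude_median(pulses),
        "median_period": med_period,
        "auc": area_under_curve(trace),
        "detrended_sd": float(np.std(det.detrended, ddof=1)),
        "n_pulses": pulses.n_pulses,
        "is_pulsatile": classify_pulsatile(pulses),
    }
    return features, per_ridge


def build_feature_table(
    traces,
    divisions: dict,
    metadata: pd.DataFrame,
    params: AnalysisParams = AnalysisParams(),
    classify_periods: bool = True,
):
    """Join all per-cell summaries into one feature table.

    Parameters
    ----------
    traces : iterable of Trace
        One entry per cell and channel; duplicate (cell_id, channel) pairs
        are an error.
    divisions : dict
        ``cell_id -> DivisionProfile``; cells absent from it count zero
        divisions, an empty intermitotic-time summary, and age equal to the
        observation time.
    metadata : DataFrame
        Columns ``cell_id``, ``dose_gy`` and optionally ``gh2ax``.

    Returns
    -------
    (features: DataFrame, ridges: dict)
        One feature row per cell x channel; `ridges` maps cell_id to the
        p53 period ridge (used downstream for period classification and
        difference curves).
    """
    meta = metadata.set_index("cell_id")
    if meta.index.has_duplicates:
        raise ValueError("duplicate cell_id in metadata")
    rows, ridges, seen = [], {}, set()
    for trace in traces:
        key = (trace.cell_id, trace.channel)
        if key in seen:
            raise ValueError(f"duplicate trace for cell {key[0]!r} channel {key[1]!r}")
        seen.add(key)
        feats, ridge = analyze_trace(trace, params)
        profile = divisions.get(trace.cell_id)
        if profile is None:
            profile = DivisionProfile(trace.cell_id, np.empty(0), t_obs=trace.t[-1])
        row = {
            "cell_id": trace.cell_id,
            "channel": trace.channel,
            "dose_gy": meta.loc[trace.cell_id, "dose_gy"] if trace.cell_id in meta.index else np.nan,
            "gh2ax": meta.loc[trace.cell_id, "gh2ax"] if "gh2ax" in meta.columns and trace.cell_id in meta.index else np.nan,
            "total_divisions": profile.n_divisions,
            "median_imt": median_imt(profile),
            "age": cell_age(profile),
            **feats,
        }
        if trace.channel == "p53":
            ridges[trace.cell_id] = ridge
            if classify_periods:
                row["period_class"] = pc.classify_period_stability(
                    ridge, use_coi_only=params.use_coi_only).label
        rows.append(row)
    return pd.DataFrame(rows), ridges


def correlation_heatmap(features: pd.DataFrame, metric_subset=None,
                        group_by_dose: bool = True):
    """Pairwise Pearson correlation of per-cell metrics.

    Correlations are computed across cells within each dose (pairwise
    complete observations); the result maps dose to a symmetric,
    unit-diagonal correlation matrix.  With ``group_by_dose=False`` a single
    pooled matrix is returned.
    """
    numeric = features.select_dtypes(include=[np.number])
    cols = list(metric_subset) if metric_subset is not None else [
        c for c in numeric.columns if c != "dose_gy"]
    if not group_by_dose:
        return features[cols].corr(method="pearson")
    return {
        dose: grp[cols].corr(method="pearson")
        for dose, grp in features.groupby("dose_gy")
    }


def group_median_correlation(features: pd.DataFrame, value_metric: str,
                             group_metric: str) -> float:
    """Pearson r between group labels and group-wise medians of a metric.

    This is the single correlation coefficient printed on grouped boxplots:
    cells are grouped by `group_metric` (e.g. total divisions or dose), the
    median of `value_metric` is taken per group, and r is computed between
    the sorted group values and those medians.  Returns NaN when either side
    is constant (undefined correlation).
    """
    med = features.groupby(group_metric)[value_metric].median().sort_index()
    if len(med) < 2:
        return float("nan")
    x = np.asarray(med.index, dtype=float)
    y = med.to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0 or np.any(~np.isfinite(y)):
        return float("nan")
    return float(sps.pearsonr(x, y)[0])


def pairwise_welch(features: pd.DataFrame, metric: str, group_col: str) -> pd.DataFrame:
    """Symmetric matrix of two-sided Welch t-test p-values between groups.

    Welch's t-test (unequal variances, Welch-Satterthwaite degrees of
    freedom) compares `metric` between every pair of groups defined by
    `group_col`.  Diagonal entries are reported as 0 by table convention
    (a formatting choice, not a statistic).
    """
    groups = {k: g[metric].dropna().to_numpy() for k, g in features.groupby(group_col)}
    labels = sorted(groups)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            p = sps.ttest_ind(groups[a], groups[b], equal_var=False).pvalue
            mat.loc[a, b] = mat.loc[b, a] = float(p)
    return mat


def group_difference_curves(
    ridges_by_class: dict,
    curves_by_class: dict,
    dt: float,
    smooth_cutoff: float = 10.0,
):
    """Stable-vs-switcher divergence over time.

    Returns ``(t, period_diff, cm_diff)`` where `period_diff` is the
    pointwise median switcher period minus median stable period, smoothed
    with a sinc low-pass of 10 h cutoff, and `cm_diff` is the stable
    cumulative division curve minus the switcher one on the same grid.
    """
    from .wavelet import population_period_band

    t_s, med_stable, *_ = population_period_band(ridges_by_class["stable"])
    t_w, med_switch, *_ = population_period_band(ridges_by_class["switcher"])
    if len(t_s) != len(t_w) or not np.allclose(t_s, t_w):
        raise ValueError("stable and switcher ridges must share a time grid")
    period_diff = sinc_smooth(med_switch - med_stable, dt, smooth_cutoff)

    cs: CumulativeCurve = curves_by_class["stable"]
    cw: CumulativeCurve = curves_by_class["switcher"]
    if len(cs.t) != len(cw.t) or not np.allclose(cs.t, cw.t):
        raise ValueError("cumulative curves must share a time grid")
    cm_diff = cs.value - cw.value
    return t_s, period_diff, cm_diff


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def fold_increase(slope_switcher: float, slope_stable: float) -> float:
    """Proliferation boost of switchers over stables: ratio of growth slopes."""
    if slope_stable <= 0:
        return float("inf")
    return slope_switcher / slope_stable


def proliferation_slopes(
    curve_stable: CumulativeCurve,
    curve_switcher: CumulativeCurve,
    fit_start: float = 60.0,
):
    """Late-phase growth slopes of the two classes and their ratio.

    Each normalized cumulative curve is fitted by OLS on ``t >= fit_start``
    (default 60 h, the observed bifurcation time); the fold increase is the
    switcher slope divided by the stable slope (flagged infinite when the
    stable slope is not positive).

    Returns ``(slope_stable, slope_switcher, fold)``.
    """
    ms = curve_stable.t >= fit_start
    mw = curve_switcher.t >= fit_start
    slope_stable = _ols_slope(curve_stable.t[ms], curve_stable.value[ms])
    slope_switcher = _ols_slope(curve_switcher.t[mw], curve_switcher.value[mw])
    return slope_stable, slope_switcher, fold_increase(slope_switcher, slope_stable)
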