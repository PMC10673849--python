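"""Classification of p53 period trajectories: stable / switcher / irregular.

A cell's instantaneous-period trend (from the wavelet ridge) is fitted by
ordinary least squares; the slope decides the label.  Slopes up to 0.01 h
of period per hour of recording are stable, slopes above 0.01 are
period-switchers (over a 120 h record the 0.01 h/h threshold equals a
1.2 h period trend over 5 days); a strong negative drift, an infeasible
fit, or a noisy super-threshold fit with no credible trend is irregular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelet import RidgeSeries

__all__ = [
    "PeriodClass",
    "SLOPE_THRESHOLD",
    "fit_period_trend",
    "classify_period_stability",
    "random_control_groups",
]

#: stable/switcher boundary: h of period drift per h of recording
SLOPE_THRESHOLD = 0.01
#: minimum number of retained ridge points for a trend fit
MIN_FIT_POINTS = 10
#: super-threshold slopes whose fit r^2 falls below this floor are treated
#: as trendless noise, not as a period switch
R2_FLOOR = 0.05


@dataclass(frozen=True)
class PeriodClass:
    """Per-cell period-stability label with its fitted trend."""

    cell_id: str
    label: str  # {"stable", "switcher", "irregular"}
    slope: float  # h of period per h of time
    intercept: float  # h
    fit_r2: float
    n_points_used: int
    reason: str = ""  # set when the label fell through to irregular


def fit_period_trend(ridge: RidgeSeries, use_coi_only: bool = True):
    """OLS fit of instantaneous period against time.

    Returns ``(slope, intercept, r2, n_points)``; all-NaN when fewer than
    ``MIN_FIT_POINTS`` ridge points are retained (in-COI by default).
    """
    keep = ridge.in_coi if use_coi_only else np.ones(len(ridge.t), bool)
    t, p = ridge.t[keep], ridge.period[keep]
    n = len(t)
    if n < MIN_FIT_POINTS or ridge.flat_power:
        return float("nan"), float("nan"), float("nan"), n
    slope, intercept = np.polyfit(t, p, 1)
    resid = p - (slope * t + intercept)
    ss_tot = np.sum((p - p.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), float(intercept), float(r2), n


def classify_period_stability(
    ridge: RidgeSeries,
    slope_threshold: float = SLOPE_THRESHOLD,
    use_coi_only: bool = True,
    r2_floor: float = R2_FLOOR,
) -> PeriodClass:
    """Label a cell stable, period-switcher, or irregular by its period trend.

    stable:   -slope_threshold < slope <= slope_threshold (upper boundary
              inclusive: a slope of exactly 0.01 h/h is stable);
    switcher: slope > slope_threshold, provided the fit is credible
              (r^2 >= `r2_floor`);
    irregular: slope <= -slope_threshold (a strong shortening trend fits
    neither category), an infeasible fit (too few in-COI points or a flat
    spectrum), or a super-threshold slope with r^2 below `r2_floor`.

    The stable band is symmetric-open below zero because the OLS slope of a
    truly constant period is noise distributed symmetrically around zero;
    sub-threshold negative slopes carry no more evidence of irregularity
    than sub-threshold positive ones.
    """
    slope, intercept, r2, n = fit_period_trend(ridge, use_coi_only)
    if not np.isfinite(slope):
        return PeriodClass(ridge.cell_id, "irregular", slope, intercept, r2, n,
                           reason="fit_infeasible")
    if slope <= -slope_threshold:
        label, reason = "irregular", "negative_trend"
    elif slope <= slope_threshold:
        label, reason = "stable", ""
    elif r2 < r2_floor:
        label, reason = "irregular", "low_fit_quality"
    else:
        label, reason = "switcher", ""
    return PeriodClass(ridge.cell_id, label, slope, intercept, r2, n, reason)


def random_control_groups(
    cell_ids,
    group_size: int = 300,
    n_iterations: int = 20,
    seed: int | np.random.SeedSequence | None = 0,
):
    """Random, disjoint same-sized cell groups for the randomization control.

    Per iteration two disjoint groups of `group_size` cells are drawn
    uniformly without replacement; downstream period and cumulative-division
    differences computed on such pairs estimate the no-effect baseline
    against which the stable/switcher split is judged.

    Returns a list of ``(group_a_ids, group_b_ids)`` tuples, one per
    iteration.
    """
    ids = np.asarray(list(cell_ids))
    if 2 * group_size > len(ids):
        raise ValueError(
            f"cannot draw two disjoint groups of {group_size} from {len(ids)} cells"
        )
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_iterations):
        pick = rng.choice(len(ids), size=2 * group_size, replace=False)
        pairs.append((ids[pick[:group_size]], ids[pick[group_size:]]))
    return pairs
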