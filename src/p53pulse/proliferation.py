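"""Division-profile metrics and population growth statistics.

Per-cell proliferation summaries (intermitotic time, cell age, total
divisions, arrest) and subsampled cumulative division-event distributions
used to compare growth across treatment or classification groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DivisionProfile",
    "CumulativeCurve",
    "intermitotic_times",
    "median_imt",
    "cell_age",
    "arrested_fraction",
    "proliferation_group",
    "cumulative_divisions",
]


@dataclass(frozen=True)
class DivisionProfile:
    """A cell's ordered division times within an observation window."""

    cell_id: str
    division_times: np.ndarray  # strictly increasing, h, all < t_obs
    t_obs: float  # h

    def __post_init__(self) -> None:
        times = np.asarray(self.division_times, dtype=float)
        object.__setattr__(self, "division_times", times)
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError(f"{self.cell_id}: division times must be strictly increasing")
        if times.size and (times[0] < 0 or times[-1] >= self.t_obs):
            raise ValueError(f"{self.cell_id}: division times must lie in [0, t_obs)")

    @property
    def n_divisions(self) -> int:
        return len(self.division_times)


@dataclass(frozen=True)
class CumulativeCurve:
    """Subsample-averaged, normalized cumulative division-event curve."""

    t: np.ndarray  # h
    value: np.ndarray  # mean normalized cumulative count, non-decreasing
    n_iterations: int
    reference_n: int  # subsample size (smallest group)


def intermitotic_times(profile: DivisionProfile) -> np.ndarray:
    """Intervals between successive division events (h); empty if < 2 events."""
    if profile.n_divisions < 2:
        return np.empty(0)
    return np.diff(profile.division_times)


def median_imt(profile: DivisionProfile) -> float:
    """Per-cell intermitotic-time summary: the median interval (NaN if < 2 events)."""
    imts = intermitotic_times(profile)
    return float(np.median(imts)) if imts.size else float("nan")


def cell_age(profile: DivisionProfile) -> float:
    """Time since the last division (h); the full record if the cell never divided."""
    if profile.n_divisions == 0:
        return float(profile.t_obs)
    return float(profile.t_obs - profile.division_times[-1])


def arrested_fraction(profiles, window: float = 48.0) -> float:
    """Fraction of cells that divided zero or one time within the first `window` hours.

    The window is closed: a division exactly at ``t = window`` counts as
    inside it.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no division profiles given")
    arrested = sum(
        1 for p in profiles if np.sum(p.division_times <= window) <= 1
    )
    return arrested / len(profiles)


def proliferation_group(profile: DivisionProfile, threshold: int = 2) -> str:
    """Binary proliferation label: ``"low"`` for up to `threshold` total
    divisions, ``"high"`` for more."""
    return "low" if profile.n_divisions <= threshold else "high"


def cumulative_divisions(
    groups: dict,
    reference: str,
    grid: np.ndarray,
    n_iterations: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
) -> dict:
    """Subsample-matched cumulative division-event curves per group.

    To remove sample-size effects, every group larger than the smallest one
    is repeatedly subsampled (without replacement) to the smallest group's
    size; per iteration all division times of the subsample are pooled into
    one temporal vector and cumulatively counted on `grid`; curves are
    averaged over `n_iterations` iterations and every group's curve is
    divided by the maximum of the `reference` (untreated) group's averaged
    curve.

    Parameters
    ----------
    groups : dict
        Mapping group label -> list of :class:`DivisionProfile`.
    reference : str
        Label of the normalization group; its averaged curve attains 1 at
        its maximum.
    grid : ndarray
        Common time grid (h) on which the step curves are evaluated.
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among groups")
    for name, profiles in groups.items():
        if len(profiles) == 0:
            raise ValueError(f"group {name!r} is empty")
    reference_n = min(len(p) for p in groups.values())
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)

    averaged = {}
    for name, profiles in groups.items():
        profiles = list(profiles)
        acc = np.zeros_like(grid)
        for _ in range(n_iterations):
            if len(profiles) > reference_n:
                pick = rng.choice(len(profiles), size=reference_n, replace=False)
                chosen = [profiles[i] for i in pick]
            else:
                chosen = profiles
            pooled = np.concatenate(
                [p.division_times for p in chosen] or [np.empty(0)]
            )
            pooled.sort()
            acc += np.searchsorted(pooled, grid, side="right")
        averaged[name] = acc / n_iterations

    ref_max = averaged[reference].max()
    if ref_max <= 0:
        raise ValueError("reference group has no division events")
    return {
        name: CumulativeCurve(t=grid.copy(), value=curve / ref_max,
                              n_iterations=n_iterations, reference_n=reference_n)
        for name, curve in averaged.items()
    }
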