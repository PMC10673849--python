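"""Baseline time-series operators for pulsatile single-cell signals.

Provides windowed-sinc low-pass filtering (detrending and smoothing),
amplitude-envelope normalization, area under the curve, and detrended
signal dispersion.  All operators work on regularly sampled traces in
hours and are linear-phase (no time shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson, trapezoid

__all__ = [
    "Trace",
    "DetrendResult",
    "sinc_kernel",
    "sinc_lowpass",
    "sinc_detrend",
    "sinc_smooth",
    "normalize_by_envelope",
    "area_under_curve",
    "detrended_sd",
    "interior_mask",
]

#: kernel half-width as a multiple of the cutoff period (in samples)
KERNEL_HALFWIDTH_FACTOR = 1.2
#: design cutoff frequency as a multiple of 1/cutoff_period; shifting the
#: transition band up keeps periods <= cutoff/2 nearly untouched while
#: still removing periods >= 2*cutoff almost completely
CUTOFF_SHIFT = 1.2

_REL_TOL_GRID = 1e-9


@dataclass(frozen=True)
class Trace:
    """One cell's sampled signal for one channel on a regular time grid.

    Parameters
    ----------
    cell_id : str
        Cell identifier.
    channel : str
        Reporter channel, ``"p53"`` or ``"p21"``.
    t : ndarray
        Strictly increasing, uniformly spaced time grid in hours.
    y : ndarray
        Signal values (arbitrary fluorescence units), same length as `t`.
    """

    cell_id: str
    channel: str
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(t) < 8:
            raise ValueError(f"trace too short: {len(t)} points (minimum 8)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in trace")
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise ValueError("time grid must be strictly increasing")
        dt = dts[0]
        if np.any(np.abs(dts - dt) > _REL_TOL_GRID * max(abs(dt), 1.0)):
            raise ValueError("time grid must be uniformly spaced")

    @property
    def dt(self) -> float:
        """Sampling step in hours."""
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Record length in hours (last minus first time point)."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class DetrendResult:
    """Low-pass trend and residual of a trace.

    ``trend + detrended`` reconstructs the input exactly.
    """

    trend: np.ndarray
    detrended: np.ndarray
    cutoff_period: float
    edge_band: np.ndarray = field(default=None, repr=False)  # bool mask


def _halfwidth(cutoff_period: float, dt: float) -> int:
    return int(round(KERNEL_HALFWIDTH_FACTOR * cutoff_period / dt))


def sinc_kernel(cutoff_period: float, dt: float, halfwidth: int | None = None) -> np.ndarray:
    """Blackman-windowed sinc low-pass kernel.

    The kernel removes components with period larger than `cutoff_period`
    (hours) while passing periods below ``cutoff_period / 2`` nearly
    unattenuated.  Unit DC gain.
    """
    if not np.isfinite(cutoff_period) or cutoff_period <= 2 * dt:
        raise ValueError(f"cutoff_period must exceed 2*dt = {2 * dt} h")
    M = _halfwidth(cutoff_period, dt) if halfwidth is None else int(halfwidth)
    n = np.arange(-M, M + 1)
    fc = CUTOFF_SHIFT * dt / cutoff_period  # cycles per sample
    k = 2 * fc * np.sinc(2 * fc * n)
    k *= np.blackman(2 * M + 1)
    return k / k.sum()


def sinc_lowpass(y: np.ndarray, dt: float, cutoff_period: float) -> np.ndarray:
    """Low-pass filter `y`, reflect-padded, linear phase (no time shift)."""
    y = np.asarray(y, dtype=float)
    M = _halfwidth(cutoff_period, dt)
    if len(y) < M + 1:
        raise ValueError(
            f"signal of length {len(y)} too short for cutoff {cutoff_period} h "
            f"at dt={dt} h: minimum length is {M + 1} samples"
        )
    kernel = sinc_kernel(cutoff_period, dt, halfwidth=M)
    padded = np.pad(y, M, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def interior_mask(n: int, dt: float, cutoff_period: float) -> np.ndarray:
    """Boolean mask of points at least one kernel half-width from each edge.

    Points outside the mask sit in the edge band where reflect-padding can
    distort the filter output; they are retained, not dropped.
    """
    M = _halfwidth(cutoff_period, dt)
    mask = np.zeros(n, dtype=bool)
    if n > 2 * M:
        mask[M : n - M] = True
    return mask


def sinc_detrend(trace: Trace, cutoff_period: float = 50.0) -> DetrendResult:
    """Split a trace into a slow trend and a detrended residual.

    The trend is the windowed-sinc low-pass component with the given cutoff
    period (hours, default 50); the detrended signal is the exact residual
    ``y - trend``, so oscillations faster than half the cutoff survive
    essentially intact while drifts slower than twice the cutoff are removed.
    """
    trend = sinc_lowpass(trace.y, trace.dt, cutoff_period)
    detrended = trace.y - trend
    edge = ~interior_mask(len(trace.y), trace.dt, cutoff_period)
    return DetrendResult(trend=trend, detrended=detrended,
                         cutoff_period=float(cutoff_period), edge_band=edge)


def sinc_smooth(y: np.ndarray, dt: float, cutoff_period: float) -> np.ndarray:
    """Return the low-pass (smoothed) component of a series.

    Same kernel as :func:`sinc_detrend`; used e.g. to smooth group
    difference curves with a 10 h cutoff.
    """
    return sinc_lowpass(y, dt, cutoff_period)


@dataclass(frozen=True)
class EnvelopeResult:
    """Amplitude-normalized signal with its estimated envelope."""

    normalized: np.ndarray
    envelope: np.ndarray
    near_flat: bool  # envelope at floor over most of the record


def normalize_by_envelope(
    detrended: np.ndarray, dt: float, window: float = 50.0
) -> EnvelopeResult:
    """Divide a detrended signal by its slowly varying amplitude envelope.

    The envelope is the sinc-smoothed (cutoff = `window`, default 50 h)
    rectified signal, rescaled by pi/2 so a pure sinusoid's envelope equals
    its amplitude (the mean of a rectified unit sine is 2/pi).  The output
    oscillates with near-unit amplitude, which removes amplitude effects
    before instantaneous period estimation.
    """
    detrended = np.asarray(detrended, dtype=float)
    sd = float(np.std(detrended))
    if sd == 0.0:
        raise ValueError("cannot envelope-normalize an identically constant signal")
    envelope = sinc_lowpass(np.abs(detrended), dt, window) * (np.pi / 2.0)
    eps = 1e-3 * sd
    floored = np.maximum(envelope, eps)
    near_flat = bool(np.mean(envelope < eps) > 0.5)
    return EnvelopeResult(normalized=detrended / floored, envelope=envelope,
                          near_flat=near_flat)


def area_under_curve(trace: Trace) -> float:
    """Area under the raw signal in a.u.*h.

    Mean of the trapezoid-rule and Simpson-rule integrals over the full
    record; the two rules agree to O(dt^2) and their mean is reported as a
    single robust summary.
    """
    if len(trace.t) < 3:
        raise ValueError("AUC needs at least 3 samples")
    a = trapezoid(trace.y, trace.t)
    b = simpson(trace.y, x=trace.t)
    return float(0.5 * (a + b))


def detrended_sd(trace: Trace, cutoff_period: float = 50.0) -> float:
    """Sample standard deviation of the detrended signal."""
    res = sinc_detrend(trace, cutoff_period)
    return float(np.std(res.detrended, ddof=1))
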