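"""Synthetic single-cell trace / division / metadata generator.

Emulates long-term (5-day) single-cell recordings of p53 and p21 reporter
activity after graded ionizing radiation, together with per-cell division
profiles and end-point DNA-damage (gamma-H2AX) readouts, so that every
downstream analysis stage is testable against known ground truth.

The generative model, per cell:

* a latent damage level ``D`` drawn from a dose-conditional lognormal;
* a total-division budget that decreases stepwise with ``D`` (quiescence
  scenario) or a damage-prolonged intermitotic time (IMT scenario);
* a pulsatile p53 signal: baseline + slow trend + ``A(D)`` times a train of
  raised-cosine pulses placed by a phase oscillator with period ``P(t)``
  and Wiener phase jitter, plus additive Gaussian measurement noise;
* period-switchers (a fraction of irradiated cells) drift their period
  upward from a switch time inside the 50-75 h window, and resume dividing
  after the switch — the escape from low proliferation;
* p21 as a gain-scaled first-order low-pass transform of p53 (gain
  proportional to damage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .proliferation import DivisionProfile
from .signal_core import Trace

__all__ = ["SimConfig", "SyntheticTruth", "simulate_population"]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic population.

    Defaults emulate the study conditions: 120 h records sampled every
    0.5 h, doses 0/2/4/10 Gy, pulse periods in the 5.5-7.5 h band,
    ~17 h intermitotic times, a 50-75 h switch-onset window, and a period
    drift of 0.02 h per hour for switchers.
    """

    n_cells: int = 100  # per dose group
    doses: tuple = (0.0, 2.0, 4.0, 10.0)  # Gy
    t_end: float = 120.0  # h
    dt: float = 0.5  # h
    #: dose (Gy) -> (mu, sigma) of the latent lognormal damage level; None
    #: derives mu = log(0.3 + 0.35*dose), sigma = 0.4
    damage_lognorm_mu_sigma: dict | None = None
    imt_mean: float = 17.0  # h
    imt_cv: float = 0.12
    scenario: str = "quiescence_entry"  # or "imt_prolongation"
    imt_damage_gain: float = 0.15  # scenario-1 IMT scaling: IMT*(1 + k*D)
    period_baseline: float = 5.5  # h, irradiated cells
    period_untreated: float = 7.5  # h, 0 Gy cells
    switch_window: tuple = (50.0, 75.0)  # h
    switch_slope: float = 0.035  # h of period per h of time
    switcher_fraction: float = 0.4  # probability an irradiated cell switches
    amp_base: float = 120.0  # a.u., amplitude at zero damage
    amp_gain: float = 40.0  # a.u. of amplitude per unit damage
    #: optional extra lognormal cell-to-cell amplitude spread; the default 0
    #: keeps amplitude a deterministic, monotone function of latent damage
    #: (damage itself already varies between cells)
    amp_cv: float = 0.0
    baseline: float = 100.0  # a.u., constant offset
    trend_amp: float = 30.0  # a.u.
    trend_period: float = 80.0  # h (> 50 h so detrending removes it)
    noise_sd: float = 10.0  # a.u., additive measurement noise
    phase_jitter: float = 0.05  # rad/sqrt(h), Wiener increments on phase
    pulse_fwhm: float = 2.5  # h, raised-cosine pulse width
    p21_tau: float = 5.0  # h, p21 low-pass time constant
    p21_gain: float = 0.5  # p21 gain per unit damage
    gh2ax_gain: float = 100.0  # a.u. of gamma-H2AX per unit damage
    gh2ax_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = {k: v for k, v in asdict(self).items()
                   if isinstance(v, (int, float))}
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite SimConfig parameter {name}={value}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_end < 2 * self.dt:
            raise ValueError("t_end must be at least 2*dt")
        if self.imt_cv < 0 or self.amp_cv < 0 or self.gh2ax_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.noise_sd < 0 or self.phase_jitter < 0:
            raise ValueError("noise parameters must be >= 0")
        lo, hi = self.switch_window
        if not (0 <= lo <= hi <= self.t_end):
            raise ValueError("switch_window must lie within [0, t_end]")
        if self.scenario not in ("quiescence_entry", "imt_prolongation"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 <= self.switcher_fraction <= 1:
            raise ValueError("switcher_fraction must be in [0, 1]")

    def damage_params(self, dose: float) -> tuple:
        """(mu, sigma) of the latent damage lognormal for one dose."""
        if self.damage_lognorm_mu_sigma is not None:
            return tuple(self.damage_lognorm_mu_sigma[dose])
        return (float(np.log(0.3 + 0.35 * dose)), 0.4)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("doses", "switch_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "damage_lognorm_mu_sigma" in raw and raw["damage_lognorm_mu_sigma"]:
            raw["damage_lognorm_mu_sigma"] = {
                float(k): tuple(v) for k, v in raw["damage_lognorm_mu_sigma"].items()
            }
        return cls(**raw)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated population, for parameter-recovery tests."""

    table: pd.DataFrame  # per cell: damage, amplitude, switch flag/time, ...
    period_trajectories: dict  # cell_id -> true P(t) on the time grid
    t: np.ndarray


def _divisions_budget(damage: float, rng: np.random.Generator) -> int:
    """Stepwise-decreasing division budget with one-step uniform jitter.

    More damage, fewer total divisions; the map is a thresholded step
    function of the latent damage plus a uniform {-1, 0, +1} jitter.
    """
    base = max(0, 5 - int(damage / 0.45))
    return max(0, base + int(rng.integers(-1, 2)))


def _raised_cosine_train(t: np.ndarray, pulse_times: np.ndarray, fwhm: float) -> np.ndarray:
    """Sum of unit-height raised-cosine pulses centered at `pulse_times`.

    Each pulse is ``0.5*(1 + cos(pi*(t - tc)/fwhm))`` on ``|t - tc| <=
    fwhm``, so its full width at half maximum equals `fwhm`.
    """
    y = np.zeros_like(t)
    for tc in pulse_times:
        u = (t - tc) / fwhm
        mask = np.abs(u) <= 1.0
        y[mask] += 0.5 * (1.0 + np.cos(np.pi * u[mask]))
    return y


def _phase_pulse_times(t: np.ndarray, period: np.ndarray, jitter: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Pulse centers where the phase oscillator crosses multiples of 2*pi.

    ``dphi/dt = 2*pi / P(t)`` plus Wiener increments; crossing times are
    located by linear interpolation of the cumulative phase.
    """
    dt = t[1] - t[0]
    dphi = 2.0 * np.pi / period * dt
    if jitter > 0:
        dphi = dphi + jitter * np.sqrt(dt) * rng.standard_normal(len(t))
    phi0 = rng.uniform(0, 2 * np.pi)
    phi = phi0 + np.concatenate([[0.0], np.cumsum(dphi)])[:-1]
    # monotone envelope for interpolation; jitter can make phi locally retreat
    phi = np.maximum.accumulate(phi)
    targets = np.arange(np.ceil(phi[0] / (2 * np.pi)),
                        np.floor(phi[-1] / (2 * np.pi)) + 1) * 2 * np.pi
    targets = targets[(targets >= phi[0]) & (targets <= phi[-1])]
    return np.interp(targets, phi, t)


def _division_times(config: SimConfig, damage: float, budget: int,
                    is_switcher: bool, t_switch: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Division event times for one cell under the configured scenario."""
    shape = 1.0 / config.imt_cv**2 if config.imt_cv > 0 else None

    def draw_imt() -> float:
        if shape is None:
            return config.imt_mean
        imt = rng.gamma(shape, config.imt_mean / shape)
        if config.scenario == "imt_prolongation":
            imt *= 1.0 + config.imt_damage_gain * damage
        return imt

    times = []
    t = rng.uniform(0, draw_imt())  # unsynchronized cell-cycle position
    while t < config.t_end:
        if config.scenario == "quiescence_entry" and len(times) >= budget:
            break
        times.append(t)
        t += draw_imt()
    if config.scenario == "quiescence_entry" and is_switcher:
        # the period switch re-licenses proliferation: divisions resume
        # after the switch time at the normal intermitotic rate
        t = t_switch + draw_imt()
        while t < config.t_end:
            times.append(t)
            t += draw_imt()
    times = np.unique(np.asarray(times, dtype=float))
    return times[times < config.t_end]


def simulate_population(config: SimConfig):
    """Generate one synthetic population.

    Returns
    -------
    traces : list of Trace
        p53 and p21 traces for every cell.
    divisions : dict
        ``cell_id -> DivisionProfile`` (cells that never divided have an
        empty profile).
    metadata : DataFrame
        ``cell_id, dose_gy, gh2ax``.
    truth : SyntheticTruth
        Latent damage, amplitude, switch flag/time, division counts, and
        the true period trajectory of every cell.

    The same seed yields byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.t_end, config.dt)

    traces, divisions, meta_rows, truth_rows = [], {}, [], []
    trajectories = {}
    for dose in config.doses:
        mu, sigma = config.damage_params(dose)
        for i in range(config.n_cells):
            cid = f"d{dose:g}_c{i:04d}"
            D = float(rng.lognormal(mu, sigma))
            irradiated = dose > 0
            is_switcher = bool(irradiated and rng.random() < config.switcher_fraction)
            t_switch = float(rng.uniform(*config.switch_window)) if is_switcher else np.nan

            P0 = config.period_baseline if irradiated else config.period_untreated
            period = np.full_like(t, P0)
            if is_switcher:
                period = P0 + config.switch_slope * np.maximum(0.0, t - t_switch)

            amp = (config.amp_base + config.amp_gain * D)
            amp *= float(rng.lognormal(0.0, config.amp_cv)) if config.amp_cv > 0 else 1.0

            pulse_times = _phase_pulse_times(t, period, config.phase_jitter, rng)
            pulses = _raised_cosine_train(t, pulse_times, config.pulse_fwhm)
            trend = config.trend_amp * np.sin(
                2 * np.pi * t / config.trend_period + rng.uniform(0, 2 * np.pi))
            noise = config.noise_sd * rng.standard_normal(len(t)) if config.noise_sd > 0 else 0.0
            p53 = config.baseline + trend + amp * pulses + noise

            # p21: first-order low-pass of p53, gain proportional to damage
            alpha = 1.0 - np.exp(-config.dt / config.p21_tau)
            p21 = np.empty_like(p53)
            p21[0] = p53[0]
            for k in range(1, len(p53)):
                p21[k] = p21[k - 1] + alpha * (p53[k] - p21[k - 1])
            p21 *= config.p21_gain * D

            budget = _divisions_budget(D, rng)
            div_times = _division_times(config, D, budget, is_switcher, t_switch, rng)
            divisions[cid] = DivisionProfile(cid, div_times, t_obs=config.t_end)

            gh2ax = config.gh2ax_gain * D
            gh2ax *= float(rng.lognormal(0.0, config.gh2ax_cv)) if config.gh2ax_cv > 0 else 1.0

            traces.append(Trace(cid, "p53", t, p53))
            traces.append(Trace(cid, "p21", t, p21))
            meta_rows.append({"cell_id": cid, "dose_gy": dose, "gh2ax": gh2ax})
            truth_rows.append({
                "cell_id": cid, "dose_gy": dose, "damage": D,
                "amplitude": amp, "division_budget": budget,
                "n_divisions": len(div_times),
                "is_switcher": is_switcher, "t_switch": t_switch,
                "period_start": float(period[0]), "period_end": float(period[-1]),
            })
            trajectories[cid] = period

    metadata = pd.DataFrame(meta_rows)
    truth = SyntheticTruth(table=pd.DataFrame(truth_rows),
                           period_trajectories=trajectories, t=t)
    return traces, divisions, metadata, truth


def true_imt_draws(config: SimConfig, n: int = 500, seed: int | None = None):
    """Draws from the generator's intermitotic-time distribution per dose.

    Exposes the latent cycle-length distribution (independent of quiescence
    censoring) so its dose-invariance under the quiescence scenario — and
    its dose-dependent prolongation under the IMT scenario — can be tested
    directly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = 1.0 / config.imt_cv**2 if config.imt_cv > 0 else None
    out = {}
    for dose in config.doses:
        mu, sigma = config.damage_params(dose)
        damage = rng.lognormal(mu, sigma, size=n)
        if shape is None:
            imts = np.full(n, config.imt_mean)
        else:
            imts = rng.gamma(shape, config.imt_mean / shape, size=n)
        if config.scenario == "imt_prolongation":
            imts = imts * (1.0 + config.imt_damage_gain * damage)
        out[dose] = imts
    return out
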