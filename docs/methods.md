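# Methods

Conventions, default parameters, and the reasoning behind the numerical
design choices. All times are hours; traces must sit on a uniform grid
(default 0.5 h over 120 h).

## Detrending and smoothing

Trends are estimated with a Blackman-windowed sinc low-pass FIR filter and
subtracted (`sinc_detrend`, cutoff period 50 h); the same kernel at a 10 h
cutoff implements curve smoothing (`sinc_smooth`). Reflection padding keeps
the filter linear-phase and output-length-preserving, so
`trend + detrended == signal` exactly.

**Kernel design.** The kernel half-width is `1.2 × cutoff / dt` samples and
the design cutoff frequency is shifted to `1.2 / cutoff`. A naive kernel with
half-width `1.0 × cutoff / dt` and cutoff `1/cutoff` attenuates the passband
too much near the edge (gain ≈ 0.88 at twice the cutoff period); the chosen
design achieves gain ≥ 0.95 at period `2 × cutoff` while keeping gain ≤ 0.05
at period `cutoff / 2`, which is what "separate a > 50 h trend from < 25 h
oscillations" requires. Both bounds are asserted in the test suite against
the kernel's exact frequency response.

## Amplitude-envelope normalization

For period estimation the detrended signal is divided by its amplitude
envelope: the rectified signal `|y|` is sinc-smoothed at a 50 h window and
multiplied by π/2 (the mean of `|sin|` is 2/π, so a pure sinusoid maps to a
unit-amplitude sinusoid). A floor of `1e-3 × SD(y)` prevents division blow-up
and a `near_flat` flag marks traces whose envelope is essentially zero.

## Continuous wavelet transform

Morlet wavelet with center frequency ω₀ = 2π, computed in the FFT domain on
the mean-subtracted signal (zero-padded to the next power of two of `2n`),
analytic (positive frequencies only). Scales map to Fourier periods through
`T = 4πs / (ω₀ + √(2 + ω₀²))`; the period grid is 2–16 h in 0.1 h steps.

Two normalizations serve two purposes:

- **Amplitude** uses L1 normalization: `amplitude = 2|W| / ψ̂_peak` with
  `ψ̂_peak = π^(-1/4)√(2π)`. This is exact for sinusoids — a unit sinusoid
  yields ridge amplitude 1.000, and amplitude is homogeneous of degree one in
  the signal.
- **Power** (used only to locate the ridge) uses unit-energy normalization,
  `power = |W|² · s / dt`, whose white-noise expectation is flat across
  scales. With L1 power the ridge of pure noise would concentrate at short
  periods; with the flat normalization a Monte-Carlo null shows no
  systematic concentration (asserted in the tests).

The cone of influence is the e-folding time `√2·s` of the wavelet envelope;
ridge summaries use in-COI samples by default (falling back to the full
record when nothing survives). The Fourier-period relation carries a ~1 %
downward bias of the argmax period for a pure tone — about one 0.1 h grid
step at 7 h — which is the standard convention for this wavelet and is
accounted for by the grid-step tolerances in the tests. The ridge is the
per-time-point power argmax; `median_ridge_metrics` reports the median
period and amplitude along it.

## Pulse detection and stationarity

Peaks via `scipy.signal.find_peaks` with height 50 a.u., minimum separation
7 samples (3.5 h at 0.5 h sampling, below the shortest expected 5.5 h
period), and prominence 50 a.u., applied to the detrended trace by default.
A cell is *pulsatile* with ≥ 10 pulses per 120 h of record (scaled to record
length). Stationarity uses the augmented Dickey–Fuller test (constant-only
regression, AIC lag selection); a trace is non-stationary iff p > 0.05.
Constant traces are flagged indeterminate.

## Period-stability classification

The instantaneous period along the ridge (in-COI, envelope-normalized
signal) is fitted by OLS against time. With threshold 0.01 h/h — equivalent
to a 1.2 h period drift over a 120 h record — the label is:

- **stable**: −0.01 < slope ≤ 0.01;
- **switcher**: slope > 0.01 and fit r² ≥ 0.05;
- **irregular**: slope ≤ −0.01, fewer than 10 usable ridge points, or a
  super-threshold slope whose fit explains < 5 % of the variance.

The stable band is symmetric because the fitted slope of a truly constant
period is zero-mean noise; treating every negative estimate as irregular
would mislabel half of all genuinely stable cells. A strong *negative*
drift still counts as irregular — only sustained period lengthening counts
as switching. `random_control_groups` draws disjoint random cell groups as a
negative control for any stable-vs-switcher comparison.

## Proliferation

Intermitotic times are successive division-time differences (median per
cell); cell age is time since last division; a cell is *arrested* with ≤ 1
division in the first 48 h (closed window). Cumulative division curves
compare groups of unequal size by subsampling every group to the smallest
size without replacement, averaging 10 iterations, and normalizing to the
reference group's maximum. Growth slopes are OLS fits to the curves for
t ≥ 60 h; `fold_increase` is the switcher/stable slope ratio. When the
stable group barely divides late in the record its slope approaches zero and
the fold ratio grows without bound (it is set to infinity for non-positive
stable slopes) — read large folds as "stables stopped dividing", not as a
precise ratio.

## Cross-cell statistics

Pairwise group comparisons use Welch's t-test (no equal-variance
assumption); p-value matrices are symmetric with zeros on the diagonal by
convention. Feature correlations are Pearson, computed per dose group.
Stable-vs-switcher difference curves subtract the groups' median
instantaneous-period curves (smoothed with the 10 h sinc filter) and their
cumulative division curves.

## Synthetic data generator

Each cell draws a latent damage level `D` from a dose-conditional lognormal
(`μ = log(0.3 + 0.35·dose)`, `σ = 0.4`). The p53 trace is

```
s(t) = baseline + trend(t) + A(D) · pulses(φ(t)) + noise
```

with raised-cosine pulses (2.5 h FWHM) placed at the 2π-crossings of a phase
oscillator `dφ/dt = 2π/P(t)` with Wiener phase jitter; amplitude
`A = 120 + 40·D`; a slow sinusoidal trend (period 80 h, above the 50 h
detrending cutoff); additive Gaussian noise (SD 10). Untreated cells pulse
at 7.5 h, irradiated cells at 5.5 h; a fraction (default 0.4) of irradiated
cells switch at a uniform time in 50–75 h, after which the period grows at
0.035 h/h — chosen so a mid-window switcher's period rises by ~2 h before
the record ends and its fitted trend clears the 0.01 h/h threshold. p21 is a
first-order low-pass of p53 (τ = 5 h) scaled by `0.5·D`; γH2AX is `100·D`
with lognormal spread.

Two proliferation scenarios: **quiescence_entry** (default) draws a fixed ~17 h
gamma-distributed intermitotic time and stops each cell after a
damage-decreasing division budget — switchers resume dividing after their
switch time; **imt_prolongation** scales the intermitotic time by
`(1 + 0.15·D)` with no budget. The generator returns full ground truth
(damage, amplitude, switch flag and time, period trajectory, division
budget) for parameter-recovery tests, and the same seed yields byte-identical
output.

The generator emulates statistical structure, not biochemistry: there is no
feedback-loop ODE, no cell-to-cell signaling, no lineage inheritance, and
pulse shape/noise models are conventional choices rather than measured ones.
Amplitude is a deterministic function of damage by default (`amp_cv = 0`),
which makes amplitude–dose correlations on synthetic data an upper bound on
what real data would show.

## Numerical choices

- All randomness flows from `numpy.random.default_rng` /`SeedSequence`
  spawning; every public entry point takes an explicit seed.
- AUC is the mean of the trapezoid and Simpson integrals of the raw trace.
- Detrended SD uses one delta degree of freedom.
- The pipeline records a configuration hash in `summary.json` so results can
  be traced to exact settings.

## Limitations

- Period estimates within ~one COI width of the record edges are unreliable;
  summaries exclude them by default.
- The classification threshold assumes ~120 h records; much shorter records
  make the slope fit noisy (fits with < 10 ridge points are refused).
- The pairwise Welch tables are not multiplicity-corrected; apply your own
  correction when reading many cells of a table.
- Subsample-matched curves inherit Monte-Carlo noise of order a few percent
  at the default 10 iterations; raise `n_iterations` for smoother curves.
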