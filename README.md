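# p53pulse

Single-cell analysis of long-term p53/p21 oscillations and their coupling to
proliferation. Given multi-day fluorescence traces (one per cell and channel),
per-cell division times, and per-cell metadata (radiation dose, γH2AX), the
package quantifies each cell's pulsatile dynamics and asks how DNA-damage
levels are encoded in them:

- **Detrending and envelope normalization** — windowed-sinc low-pass filters
  split each trace into a slow trend (periods > 50 h) and an oscillatory
  residual; an amplitude-envelope division yields a unit-amplitude signal for
  period estimation that is insensitive to amplitude drift.
- **Wavelet ridge analysis** — a continuous Morlet wavelet transform over a
  2–16 h period grid; the per-time-point power maximum (the *ridge*) gives
  each cell's instantaneous period and amplitude, with a cone-of-influence
  mask for edge effects.
- **Pulse detection** — peak picking with height/separation/prominence
  filters; cells with ≥ 10 pulses per 120 h count as pulsatile; an augmented
  Dickey–Fuller test flags non-stationary traces.
- **Period-switch classification** — an ordinary-least-squares fit of the
  instantaneous period over time labels each cell *stable* (|slope| ≤ 0.01 h
  of period per hour, i.e. < 1.2 h drift over 5 days), *switcher* (larger
  positive slope with a credible fit), or *irregular* (everything else).
- **Proliferation statistics** — intermitotic times, cell age, arrested
  fraction, and subsample-matched cumulative division curves that compare
  groups of unequal size without size bias; group growth slopes and their
  fold ratios.
- **Cross-cell statistics** — pairwise Welch t-test tables, per-dose Pearson
  correlation heatmaps over the scalar features, and stable-vs-switcher
  difference curves.
- **Synthetic data generator** — a phase-oscillator model with raised-cosine
  pulses, dose-conditional latent damage, damage-dependent amplitude, and two
  proliferation scenarios (early quiescence entry vs. lengthened cell
  cycles), with full ground truth for parameter-recovery testing.

## Worked example

```python
from p53pulse import SimConfig, simulate_population, build_feature_table

config = SimConfig(n_cells=50, seed=11)
traces, divisions, metadata, truth = simulate_population(config)
features, ridges = build_feature_table(traces, divisions, metadata)

p53 = features[features.channel == "p53"]
print(p53.groupby("dose_gy")[["median_cwt_amplitude", "median_period",
                              "total_divisions"]].median().round(2))
print(p53[p53.dose_gy > 0].period_class.value_counts(normalize=True).round(2))
```

Output:

```text
         median_cwt_amplitude  median_period  total_divisions
dose_gy
0.0                     64.51            7.5              5.0
2.0                     82.45            5.5              4.0
4.0                     96.07            5.5              3.0
10.0                   133.30            5.5              1.0
period_class
stable      0.61
switcher    0.39
```

Higher doses give larger-amplitude, faster oscillations and fewer divisions,
and a subset of irradiated cells later "switches" to a longer period — the
signatures the pipeline is built to detect.

### Command line

```bash
p53pulse simulate --seed 3 --out simdata      # traces/divisions/metadata/truth CSVs
p53pulse analyze  --seed 3 --out results      # full pipeline on simulated data
p53pulse analyze  --config run.yaml           # or on your own CSVs
p53pulse report   --features results/features.csv --out report
```

`analyze` writes `features.csv` (one row per cell × channel),
`period_classes.csv`, `cumulative_curves.csv`, `difference_curves.csv`,
per-channel Welch p-value tables, and a `summary.json` with the headline
numbers (arrested/pulsatile fractions per dose, period-class composition,
amplitude–dose correlation, proliferation slopes and fold increases). A
`run.yaml` may set any `RunConfig` field; input CSVs are long-format
(`cell_id,time_h,channel,value`), division tables are
(`cell_id,division_time_h`), metadata is (`cell_id,dose_gy[,gh2ax]`).

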