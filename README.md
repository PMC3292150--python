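# emgfatigue

Surface-EMG muscle fatigue prediction and detection. The package labels
isometric-contraction trials into three states — non-fatigue (NF),
transition-to-fatigue (TF) and fatigue (F) — from elbow-angle kinematics,
extracts per-second spectral fatigue features from the sEMG, and evaluates
pairwise (NF vs TF, TF vs F) longitudinal classification.

The headline feature, `spectro_std`, is built in three steps per trial:

1. per 1-s window, compute the total band power (Welch PSD integral) and the
   median frequency of the periodogram;
2. standardize both streams over the trial and subtract (power minus median
   frequency), producing one dimensionless stream that rises as fatigue
   develops — power grows while the spectrum compresses downward;
3. take the causal 3-window rolling sample SD. The result spikes at the
   transition to fatigue and settles once fatigue is established, which is
   what makes early prediction possible.

Comparison features (median frequency, band power, the Dimitrov-style
spectral moment index FI2, and a db3 level-12 wavelet energy) are reported
through the same 3-s rolling-SD transform so all five are comparable.

Since no recordings are distributed, a synthetic trial generator
(`emgfatigue.simulate`) produces fatiguing-contraction trials with ground
truth: band-limited sEMG whose median frequency declines from ~95 to ~55 Hz
with growing amplitude (and envelope bursts during the transition phase),
plus a goniometer trace held near 90° that develops oscillation at the
transition and drops below 86.5° at fatigue onset.

## Layout

| module | contents |
|---|---|
| `emgfatigue.core` | `Trial` / `LabelSeries` / `FeatureSeries` types, CSV I/O, per-second label alignment |
| `emgfatigue.simulate` | `SyntheticConfig`, `generate_trial`, `generate_cohort` |
| `emgfatigue.preprocess` | zero-phase 1–500 Hz Butterworth band-pass, 1-s windowing, 4-s-block angular oscillation |
| `emgfatigue.labeling` | 6-rule type-1 fuzzy classifier (product inference, winner-take-all) |
| `emgfatigue.features` | `imdf`, `welch_psd`, `total_band_power`, `unify_1d_spectro`, `rolling_std`, `spectro_std`, `fi_nsm`, `wavelet_feature`, `extract_all` |
| `emgfatigue.classify` | Fisher LDA, longitudinal (train-early / test-late) splitting, `run_pairwise` |
| `emgfatigue.report` | confusion rates, separability index (+ canonical variant), rolling-span sweep, comparison tables with improvement deltas |
| `emgfatigue.cli` / `pipeline` | `simulate`, `label`, `extract`, `classify`, `report`, `run` |

## CLI

Run the bundled end-to-end demonstration (3 subjects × 2 trials):

```sh
emgfatigue run --config src/emgfatigue/data/quickstart.yaml --out out/ --seed 1
```

Outputs land in `out/`: trial/label/feature CSVs, `results/results.csv`
(per subject × feature × pair percent-correct and confusion seconds),
comparison tables with AVG/STDEV rows and improvement deltas in
`results/report.md`, the rolling-span separability sweep, and a run
manifest. Individual stages are available as `simulate`, `label`,
`extract`, `classify` and `report` subcommands; every constant of record
(86.5°/89° angle boundaries, 0.6° SD oscillation crossover, 1–500 Hz
order-5 filter, 1-s windows, 3-s rolling SD, 4-s oscillation blocks,
8–500 Hz moment band, db3 level 12) is surfaced in the YAML config.

Exit codes: 0 success, 2 validation error, 1 runtime error.

## Conventions worth knowing

- Sample (n−1) standard deviation everywhere; display rounding is half-up
  to 2 decimals, and improvement deltas are differences of *rounded* column
  means (printed-table arithmetic).
- Windows are half-open `[t, t+1)`; trailing partial seconds are dropped;
  rolling windows are causal (stamped at span end).
- Median frequency is the first periodogram grid frequency whose cumulative
  power reaches half the total (no interpolation).
- Per-second label ties resolve toward the more severe class.
- The separability index follows the source formulation (sum of per-cluster
  SDs of member-to-centroid distances over centroid distance, two clusters);
  `dbi_canonical` provides the textbook Davies–Bouldin index.
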