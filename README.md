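# surgmotion

Tool-tip motion analysis for robot-assisted surgery kinematics.

`surgmotion` reads trial files in the standard 76-column / 30 Hz plain-text
kinematics dialect (19 variables for each of four manipulators: the two
surgeon-side *master* controllers and the two patient-side *slave* arms),
extracts three motion parameters per trial —

* **time** — sample count divided by the sample rate,
* **path length** — sum of Euclidean distances between consecutive raw
  tool-tip positions,
* **movements** — local high peaks of the Gaussian-smoothed per-interval
  displacement (speed) signal,

— and runs the downstream statistics: group mean ± SD by self-declared
skill level (novice / intermediate / expert), pairwise Mann–Whitney U
comparisons, Pearson correlation of each kinematic parameter with the
global rating scale (GRS) total, Spearman correlation of ordinal skill
with GRS, and OLS trend lines for scatter exports.

A synthetic trial generator (minimum-jerk movements with stationary pauses
and Gaussian position noise, plus dataset-shaped cohorts with GRS models)
provides known ground truth so the whole pipeline is testable without the
registered-access dataset.

## CLI

```bash
# generate a synthetic, dataset-shaped cohort (trial files + metadata)
surgmotion simulate --out data/synthetic --seed 1

# analyze a directory of trials (real or synthetic)
surgmotion analyze --input data/synthetic --out report --seed 1 \
    --exercises suturing,knot_tying,needle_passing \
    --manipulators master_left,master_right --sigma 5 --alpha 0.05

# analyze a cohort spec directly, without writing trial files
surgmotion analyze --cohort cohort.yaml --out report --seed 1

# compare a report against bundled published reference values
surgmotion diff --report report
```

`analyze` writes per-trial `metrics.csv`, the three report tables
(`table1_grs.csv`, `table2_metrics.csv`, `table3_comparisons.csv`),
scatter/trend CSVs, per-trial trajectory CSVs, and `manifest.json`
recording every effective parameter (smoothing sigma, peak thresholds,
manipulator selection, SD convention, ordinal coding, seed), so any run is
reproducible from its outputs. Runs are deterministic: the same seed and
config produce byte-identical reports.

`diff` judges only parameter-free quantities (trial counts, time means,
GRS means) pass/fail at printed rounding; path-length and movement-count
rows depend on unpublished smoothing parameters in the original software
and are listed as informational.

Column order of the input files is configurable via `--layout` (default
`master_left,master_right,slave_left,slave_right`).

## Package layout

| module | purpose |
| --- | --- |
| `surgmotion.io_jigsaws` | trial-file/metadata parsing, skill mapping, interchange format, dataset discovery |
| `surgmotion.kinematics` | distances, path length, trial time, Gaussian smoothing, movement counting, metric orchestration |
| `surgmotion.stats` | group summaries, Mann–Whitney U, Pearson/Spearman, strength banding, trend lines, comparison tables |
| `surgmotion.synthetic` | minimum-jerk trial and cohort generators with ground truth |
| `surgmotion.pipeline` | end-to-end runs, report/manifest writers, reference diffing, cohort-spec loading |
| `surgmotion.cli` | `surgmotion analyze | simulate | diff` |
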