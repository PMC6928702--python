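# gaitwb

Walking-bout (WB) detection from shank-worn gyroscopes, with threshold
customization at the population and individual level.

The toolkit implements the classic midswing-peak detector on the shank
pitch angular velocity: candidate peaks above an amplitude threshold
(Th1 = 50 °/s by default) are deduplicated within a refractory window
(Th2 = 0.5 s), and grouped into walking bouts by strict left/right
alternation with a maximal same-side gap (Th3 = 1.5 s) and an adaptive
maximal inter-side gap (Th4 = 3.5 s initially, then 1.5 s + the mean step
interval of the bout). The same machinery runs with thresholds tuned from
supervised laboratory gait trials, either as group extremes ("pop") or per
individual and per side with the amplitude threshold renormalized to the
95th percentile of the out-of-lab signal ("indiv").

Modules:

- `gaitwb.io_preprocess` — CSV/TSV reading, PCA alignment of the tri-axial
  gyroscope onto the medio-lateral axis, zero-phase high-pass filtering
  (order-4 Butterworth, 0.3 Hz default), lying-posture onset detection.
- `gaitwb.detector` — threshold sets, midswing candidate detection,
  deduplication, adaptive Th4, bout segmentation, the 4-step speed-stage
  filter.
- `gaitwb.tuning` — lab feature extraction and the pop/indiv threshold
  formulas.
- `gaitwb.evaluation` — interval activity labels, rasterization, and
  sample-wise confusion metrics with a ±2 s transition tolerance.
- `gaitwb.speed_stats` — distribution descriptors, normality-gated
  comparison (Shapiro–Wilk gate, Wilcoxon rank-sum or F-test + t-test),
  empirical CDFs.
- `gaitwb.synthetic` — seeded simulator emitting labeled gait protocols,
  lab trials, confounding activities (swinging, running, stairs) and full
  ground truth, so every stage is testable without external data.
- `gaitwb.cli` — the command-line workflow.

## CLI

```sh
# synthetic protocol + lab trials into out/
gaitwb simulate default out/ --seed 7

# individual thresholds from the lab trials and the out-of-lab recording
gaitwb tune --mode indiv --lab-dir out/lab \
    --left out/signals_left.csv --right out/signals_right.csv \
    --out thresholds.yaml

# detection, evaluation, and speed-distribution comparison
gaitwb detect --left out/signals_left.csv --right out/signals_right.csv \
    --thresholds thresholds.yaml --out-csv bouts.csv
gaitwb evaluate --bouts bouts.csv --labels out/labels.csv --out metrics.json
gaitwb speedstats --a speeds_init.csv --b speeds_indiv.csv \
    --out report.json --cdf cdf.csv
```

`tune --mode pop` consumes a group feature CSV (one row per subject/side,
see `gaitwb.tuning.features_to_frame`). `detect` without `--thresholds`
uses the fixed default thresholds. Exit codes: 0 success, 2 configuration
error, 3 data error.

## Conventions

- Times are seconds from recording start; intervals are half-open
  `[start, end)`.
- Walking is the positive class; straight and "other" walking both count
  as walking when scoring.
- Quantiles are linear (type 7); kurtosis is raw (normal ≈ 3).
- A metric with a zero denominator is reported as missing, never 0 or 1.
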