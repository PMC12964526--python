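# fragiso

Fragment-specific carbon and nitrogen isotope-ratio processing and
calibration for ESI-Orbitrap-MS scan-level data, built around the
sulfamethoxazole (SMX) fragment pair F92 (C6H6N+) and F99 (C4H7N2O+).

The package covers the full desk-side data chain:

- **chem** — elemental formulas, nuclide masses/abundances, the
  six-isotopologue SMX fragment catalog, exact m/z computation and
  peak assignment, label-mixing enrichment math, and first-order
  delta mass balance between bulk and fragment values.
- **scan_io** — reading/writing delimited scan tables (one row per
  scan x isotopologue: intensity, peak noise, resolution, microscans),
  results tables, standards tables and YAML run configurations.
- **ion_stats** — per-scan ion-count estimation from signal-to-noise
  (`N_IO = S/N * C_N/z * sqrt(R_N/R) * sqrt(mu)`) and summed-count
  isotopologue ratios over a time window with per-scan or bootstrap
  standard errors.
- **bracketing** — segmentation of a timeline into alternating
  reference/sample blocks (18-min blocks, first 3 min discarded),
  reference averaging, delta/delta-shift computation, and replicate
  aggregation with three CI estimators (conservative RMS x t default,
  conventional replicate-SD, and exact Gaussian propagation).
- **uncertainty** — Gaussian propagation of ratio errors into delta
  sigmas, Student t-factors, and 95% CI aggregation.
- **calibration** — labeled-standard definitions, per-(fragment,
  element) regression or two-point calibration, inverse application to
  sample values, and an identical-treatment pathway check.
- **simulate** — synthetic scan tables with Poisson ion statistics,
  configurable true delta shifts, instrument response slopes, spray
  drift, bracketed sequences, labeled-standard series and degradation
  scenarios (including closed-form Rayleigh trajectories). Ground truth
  is serialised next to every dataset.
- **pipeline / cli** — the end-to-end chain plus a `fragiso` command
  with `simulate`, `process` and `calibrate` subcommands, manifests
  with input/output digests, and seeded reproducibility.

## Test

```sh
python -m pytest -q tests/
```

## CLI

Simulate a bracketed sequence (five reference + four sample blocks):

```yaml
# sim.yaml
simulation:
  seed: 3
  scan_period_s: 2.0
  true_deltas: {F99.N: 27.0, F99.C: 4.0}
blocks: {n_reference: 5, n_sample: 4, duration_min: 18.0}
```

```sh
fragiso simulate -c sim.yaml --seed 3 -o sim_out
```

Process it into delta shifts with 95% CIs:

```yaml
# run.yaml
mode: lc_blocks            # or direct_infusion with a roles plan
data_window_min: 15
switch_discard_min: 3
block_duration_min: 18
ci_estimator: eq7          # eq7 | replicate_sd | propagated
```

```sh
fragiso process -s sim_out/scans.tsv -c run.yaml -o proc_out
```

Fit and apply a calibration from measured standards:

```sh
fragiso calibrate -t standards.tsv \
    -m A3=proc_a3/results.tsv -m D3=proc_d3/results.tsv \
    --sample proc_out/results.tsv -o cal_out
```

Exit codes: 0 success, 2 configuration/validation error, 3 processing
error.

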