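# parasdm

A presence–background maximum-entropy species distribution modelling (SDM)
pipeline for parasite–host pairs: tuned habitat-suitability models, area
dynamics under climate-scenario ensembles, and Schoener's D niche-overlap
statistics — exercised end to end on self-contained synthetic climate
rasters and occurrences, so no external data download is needed.

## What it does

- **`parasdm.raster`** — ESRI ASCII grid I/O (corner and center dialects),
  aligned multi-layer stacks, equally weighted GCM ensemble means, shared
  valid-cell masks.
- **`parasdm.occurrences`** — occurrence CSV ingestion with cleaning,
  spatial rarefaction to one record per grid cell, background sampling,
  climate-value extraction.
- **`parasdm.varselect`** — Pearson-correlation variable reduction
  (|r| > 0.7 pairs resolved by pilot-model contribution).
- **`parasdm.maxent`** — the maximum-entropy engine: L/Q/H/P/T feature
  construction, L1-penalized concave objective solved by proximal Newton
  with coordinate descent, raw and logistic suitability output, clamped
  projection, leave-one-variable-out contribution attribution.
- **`parasdm.tuning`** — AICc model selection over the regularization
  multiplier × feature-class grid (8 × 6 = 48 candidates), 75/25 replicate
  evaluation with AUC and maximum TSS, replicate-map aggregation.
- **`parasdm.habitat`** — four-class HSI reclassification, per-scenario
  area percentages, growing/declining/fluctuating trend typology.
- **`parasdm.overlap`** — Schoener's D, five-class overlap labels,
  per-pair mean ± SD, one-way ANOVA plus Tamhane T2 post-hoc with a
  compact letter display.
- **`parasdm.synth`** — Gaussian-random-field climate layers with
  controlled cross-correlation, species with known suitability truth,
  presence sampling, future-scenario perturbations, parasite–host pairs
  with a tunable niche offset.
- **`parasdm.pipeline`** — the orchestrated study (`run_species`,
  `run_pair`, `run_study`) with deterministic per-stage seeding and
  config-hash-stamped CSV artifacts.
- **`parasdm.datasets`** — bundled published per-scenario reference tables
  (habitat-class area percentages and niche-overlap values for four
  parasite–host pairs) used as regression fixtures.

## CLI

```sh
# write a synthetic study directory (grids + occurrences + manifest)
parasdm simulate demo_study --pairs 2 --seed 1

# run the full analysis from a YAML config
cat > config.yml <<EOF
indir: demo_study
outdir: results_demo
pairs: [[parasite1, host1], [parasite2, host2]]
n_background: 2000
n_knots: 8
master_seed: 1
EOF
parasdm run-study config.yml
```

Other subcommands: `thin` (spatial rarefaction), `ensemble` (GCM means),
`select-vars`, `classify`, `overlap`. See `parasdm --help`.

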