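# agrimeta

Hierarchical Bayes meta-analysis of organic vs. conventional farming effects
on species richness, with randomized-transect landscape metrics and a
synthetic-data generator for fully reproducible, download-free testing.

## What it does

- **Effect sizes** — log response ratios `y = ln(mean_org / mean_conv)` with
  sampling variance `v = sd_org^2/(n_org mean_org^2) + sd_conv^2/(n_conv mean_conv^2)`,
  plus the `sqrt(n) * mean / sd` normal-approximation adequacy diagnostic and
  the percent-change transform `100 (exp(y) - 1)`.
- **Hierarchical meta-regression** — `y = X beta + delta + eps` with
  `eps ~ N(0, diag(v))` and `delta ~ N(0, tau^2 M(phi))`, where `M(phi)` is
  block-diagonal by publication (unit diagonal, `phi` within blocks), so
  dependent effect sizes from one publication are downweighted. Flat prior on
  `beta`, DuMouchel prior on `tau`, uniform grid prior on `phi`; coefficient
  posteriors by deterministic (tau, phi) grid integration of the conditional
  GLS solution. Credible intervals scale the posterior SE by a t quantile
  with `N - p` degrees of freedom; heterogeneity is summarised by `tau^2` and
  the Higgins–Thompson `I^2`.
- **Bias diagnostics** — residual-based funnel data, rank-based (L0)
  trim-and-fill, cumulative meta-analysis ordered by sampling variance or
  publication year, and hierarchical slope tests on both covariates.
- **Landscape metrics** — five random, non-crossing 1-km line transects per
  study region on a categorical land-cover raster, yielding % arable fields,
  number of habitats and average field size (ha), with per-country mean
  imputation for studies lacking landscape data.
- **Synthetic data** — meta-analytic tables (~94 publications / ~184
  dependent observations by default, known `beta`, `tau`, `phi`) and
  parcel-tessellated land-cover maps, plus a censoring operator that injects
  small-study publication bias.

## CLI

```bash
# generate a synthetic study table + ground truth
agrimeta simulate --out sim/ --seed 5

# run the full analysis (report JSON + plot-ready CSVs)
agrimeta analyze sim/study_table.csv --config configs/default.yaml --out results/ --seed 1

# landscape metrics for regions on a plain-text land-cover raster
agrimeta landscape --map map.txt --regions regions.csv --out metrics.csv --seed 3
```

`analyze` writes `report.json`, `coefficients.csv`, `effects.csv`,
`funnel.csv`, `cumulative_*.csv` and `rejections.csv`. Exit code is nonzero
with a stage-named message on failure, and no partial outputs are left
behind.

## Layout

| module | contents |
| --- | --- |
| `agrimeta.io` | study-record model, CSV read/write, rejection reports, variance-measure conversion |
| `agrimeta.effects` | log response ratios, adequacy scores, percent change |
| `agrimeta.hblm` | design matrices, hierarchical fit, credible intervals, heterogeneity |
| `agrimeta.bias` | trim-and-fill, cumulative meta-analysis, slope tests |
| `agrimeta.landscape` | land-cover rasters, transect placement and metrics, imputation |
| `agrimeta.simulate` | synthetic meta-datasets, land-cover maps, bias injection |
| `agrimeta.pipeline` | end-to-end orchestration and report writing |
| `agrimeta.cli` | click-based CLI entry point |
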