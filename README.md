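# sipcell

Single-cell stable-isotope-probing ecophysiology toolkit: from nanoSIMS
ion-count tables, ¹⁵N tracer time series and cell counts to per-cell
assimilation and growth rates, cellular C/N quotas, bulk oxidation rates,
catabolic energy fluxes and biomass yields (nmol-C per Joule).

## What it does

- **isotope** — atom fractions from minor/major ion counts, at%-excess
  above natural abundance (0.37% ¹⁵N, 1.11% ¹³C), Poisson counting error
  of plane-summed ratios with a 5% acceptance filter, and labeling
  percentage of tracer-amended substrate pools.
- **rates** — bulk rates from pooled OLS of labeled product on time
  across replicate incubations, with labeling correction and a one-sided
  detection test; non-significant slopes are flagged below detection.
- **singlecell** — per-cell N-assimilation (fg and fmol per cell per day),
  growth rates from the fraction of cellular N replaced (linear or
  exponential model), Redfield-based C-assimilation, multi-substrate
  combination, and Wilcoxon group comparisons.
- **morphology** — capsule/prolate-spheroid biovolumes, projected-area
  inversion, power-law carbon allometry and C:N-based nitrogen quotas.
- **population** — growth rates and doubling times from cell counts,
  per-cell rates from bulk rates, population C stocks and assimilation
  fluxes, FPKM marker-gene fractions.
- **energetics** — ΔG = ΔG° + RT·ln Q for catabolic reactions under in
  situ conditions, energy flux from bulk rates, biomass yield.
- **simulate** — seeded generators for all three measurement channels
  (Gaussian bulk noise, Poisson ion counts, Poisson cell counts) with
  ground truth attached, including a parameterized shelf-water scenario.
- **pipeline / cli** — table I/O, YAML configuration, stage orchestration
  and a JSON/CSV report.

## CLI

```sh
sipcell simulate --seed 1 --out data/            # synthetic dataset + ground truth
sipcell rates --timeseries data/timeseries.csv   # pooled regressions per incubation
sipcell cells --roi data/roi.tsv --label-excess 92.7 --fg-n 15.1
sipcell quotas --shape nob,capsule,1.4,0.5 --area aoa,prolate_spheroid,0.19,1.5
sipcell yield --bulk-rate 564 --delta-g -65 --c-assim 79
sipcell report --config analysis.yaml            # full pipeline
sipcell validate --roi data/roi.tsv              # schema diagnostics
```

The `report` command reads a YAML configuration naming the input tables,
population geometries, constants and thermodynamic reactions; unknown
keys are rejected. See `tests/test_tables_cli.py` for a complete example.

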