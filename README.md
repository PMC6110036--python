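# vesselmorph

Quantitative analysis of balloon-injury intimal hyperplasia as a tested,
reproducible pipeline:

- **synthetic** — seeded generators for vessel cross-section contour cohorts
  (nested EEL / IEL / lumen polygons with concentric or eccentric stenosis)
  and densitometry tables (IHC field IODs, Western-blot band IODs with a
  beta-actin reference), emulating a 10-group rat study design with graded
  treatment effects.
- **morphometry** — shoelace areas from contours and the six per-slice
  indices (MA, IA, MT, IT, HRIA, HRIT), with animal- and group-level
  aggregation (mean ± sample SD). Thicknesses are differences of
  equivalent-circle radii `sqrt(A/pi)`; intimal thickness supports a
  `printed` (outer-membrane reference, default) and an `anatomical`
  (inner-membrane reference) mode.
- **densitometry** — IHC expression intensity (mean field IOD) and WB
  relative expression (target / beta-actin IOD ratio).
- **group_stats** — one-way ANOVA plus pairwise comparisons against
  reference groups (Fisher LSD default, Welch optional) with the two-tier
  p < 0.05 / p < 0.01 significance convention.
- **fuzzy_eval** — single-factor fuzzy comprehensive evaluation: TOPSIS
  normalization (vector / min-max), ideal and anti-ideal distances D+ and
  D−, closeness grade C = D− / (D+ + D−), dense ranking.
- **pipeline** / **cli** — a YAML-configured end-to-end run
  (simulate → morphometry → densitometry → stats → evaluate → report) that
  is byte-deterministic for a fixed seed.

## CLI

```sh
vesselmorph run --config run.yaml --seed 42 --out out/
vesselmorph simulate --seed 1 --out cohort/
vesselmorph morphometry --contours cohort/contours.csv --mode printed --out indices.csv
vesselmorph stats --values animal_values.csv --references Normal,Model --out stats.csv
vesselmorph evaluate --matrix means.csv --criteria HRIA,HRIT --directions cost,cost --scheme vector
```

`vesselmorph run` without `--config` uses the built-in 10-group default
cohort (8 animals x 8 slices per vessel). Output artifacts are CSV/JSON
with the run seed recorded in every CSV header.

## Notes

- Hyperplasia ratios are fractions internally and percentages in reports.
- The TOPSIS criterion directions for HRIA/HRIT are *cost* (lower
  hyperplasia = better efficacy); ranking uses dense ranks on unrounded C.
- The default normalization is classic vector normalization; min-max is
  selectable. The closeness identity C = D−/(D++D−) and the rank order are
  normalization-independent.
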