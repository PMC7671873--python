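# onhmorph

Optic nerve head (ONH) OCT morphometry and diurnal cohort statistics.

The package turns **segmented** OCT scan geometry (no raw pixels) into the
standard ONH structural parameters, and provides the repeatability and
change-from-baseline machinery used to analyse 12-hour seated / head-down
tilt (HDT) imaging cohorts:

* **scan_model** — validated containers and JSON/CSV interchange for
  24-line radial scan sets (7.5° spacing, physical µm, anterior-positive z),
  circumpapillary circular scans (2.7/3.5/4.2/4.9 mm) and per-session
  physiology tables. JSON schemas ship under `src/onhmorph/schemas/`.
* **morphometry** — BMO-MRW (per-point and global minimum rim width),
  BMO height against the 4-mm BM reference chord, anterior lamina surface
  depth over the central 50 % of the BMO chord, best-fit BMO ellipse and
  area (plane fit + direct least-squares conic fit), polar total-retinal-
  thickness map with annular means (BMO→250, 250→500, 500→1000,
  1000→1500 µm eccentricity from the BMO margin), and angular-gap weighted
  circumpapillary RNFL/TRT/choroid means.
* **pressures** — mean IOP, MAP = (2·DBP + SBP)/3, MOPP with the
  0.77 mmHg/cm hydrostatic cuff-to-eye correction, and ONSD measured 3 mm
  (arc length) behind the globe from sheath boundary traces.
* **cohort_stats** — duplicate-design repeatability (Sw, CV, 2.77·Sw),
  change-from-baseline tables, repeated-measures ANOVA with many-to-one
  (Dunnett-type) contrasts against the 7 a.m. seated baseline, simple and
  two-predictor OLS, paired/unpaired group comparison.
* **synthetic** — analytic ONH phantoms whose ground truth is computed by
  dense numeric evaluation of the closed-form surfaces (an oracle that is
  independent of the measurement pipeline), plus seeded simulators for
  diurnal cohorts and duplicate-measurement repeatability tables.
* **pipeline / cli** — deterministic simulate → stats → report bundles
  (TSV/JSON, config-hash stamped).

## CLI

```sh
# sample a phantom and measure it
onh-morph simulate phantom --seed 17 --out phantom/
onh-morph compute --radial phantom/radial_set.json \
    --circles phantom/circle_27.json --circles phantom/circle_35.json \
    --circles phantom/circle_42.json --circles phantom/circle_49.json \
    --out result.json --map trt_map.tsv

# simulate a cohort and analyse it
onh-morph simulate cohort --seed 17 --arm seated --out cohort.csv
onh-morph stats --cohort cohort.csv --arm seated --out report/

# full reproducible pipeline from a YAML config
onh-morph run --config run.yaml      # keys: seed, arm, n_subjects, ...
```

Reports land under `out/{tables,logs,meta}` plus `out/summary.json`; re-runs
with the same config and seed are byte-identical on all machine-readable
outputs.

## Conventions

* All scan coordinates are physical micrometres; `z` increases toward the
  vitreous, so posterior displacements (BMO height, lamina depth) are
  negative.
* `s = 0` is the common rotation centre of the radial set; each radial
  B-scan is a full diameter (negative and positive `s`).
* Global parameters are arithmetic means over the 48 BMO points (MRW, BMO
  height) or over B-scans with a valid value (lamina depth).
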