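# cprgam

A tested, reusable pipeline for modelling rare presence/absence records
from ship-of-opportunity plankton-recorder surveys with spatiotemporal
Bernoulli GAMs, and for deriving spawning-distribution products from the
fitted models.

The pipeline:

1. **geo_time** — WGS84 transverse Mercator (UTM, fixed zone, default 28)
   projection and solar-elevation day/night classification (night = sun
   ≥ 6° below the horizon, civil-dawn convention; all instants UTC).
2. **synthetic_data** — a survey simulator: fixed transect routes sampled
   in ~10-nautical-mile segments with a within-month sampling cycle and
   year-dependent route coverage, thinned through a known two-component
   spawning truth (Gaussian bumps in projected space, Gaussian seasonal
   windows on a circular day-of-year axis, component-specific year
   trends, a day/night catchability offset), reported as abundance
   categories (0, 1, 2, 3, 4-11, 12-25).
3. **smoother_basis** — penalized spline building blocks: cubic B-spline
   bases with difference penalties, periodic (day-of-year) bases,
   tensor-product terms with one penalty per margin, sum-to-zero
   constraint absorption, by-component term duplication.
4. **bernoulli_gam** — penalized IRLS fitting of the Bernoulli GAM,
   UBRE-type smoothness selection (overfit-guard multiplier γ = 1.4),
   effective degrees of freedom, conditional AIC, deviance explained,
   prediction, posterior coefficient draws.
5. **ensemble** — the ten-member model ensemble (additive through fully
   interacting space × season structures, one- and two-component year
   and seasonal terms split at 53°N) and its comparison table (AIC,
   ΔAIC, in-sample AUC with ties counted ½, day/night coefficient).
6. **derived_products** — per-component spatial PDFs, peak-timing maps
   masked to the 75% highest-density core, zonally integrated
   latitude × day-of-year densities, and annual abundance indices with
   central 67% posterior intervals.
7. **cli_io** — CSV readers/writers, region-of-interest polygon
   filtering with an exclusion report, model archives (zip of plain-text
   parts), pipeline configuration (YAML) and the CLI.

## CLI

All verbs accept `--config <file.yaml>` plus overrides:

```sh
cprgam simulate --seed 1 --out out/            # synthetic observations + truth sidecar
cprgam fit --input obs.csv --model-id 10 --out out/
cprgam compare --input obs.csv --out out/      # full ensemble comparison table
cprgam products --model out/model_10.zip --years 1955-1974 --out out/
cprgam run --seed 1 --out out/                 # full pipeline end to end
```

A config file may set any `PipelineConfig` field, e.g.

```yaml
seed: 1
simulate_years: [1955, 1974]
split_latitude: 53.0
basis: {k_uni: 10, k_doy: 10, k_tensor3_space: 6, k_tensor3_doy: 8}
grid_n_east: 50
grid_n_north: 80
grid_doy_step: 5.0
n_draws: 200
```

Unknown keys are rejected at startup. `cprgam run` writes the
observation CSV (when simulating), the exclusion report, the ensemble
comparison table, the best model archive, the four product CSVs and a
run log into the output directory; reruns with the same config and seed
are byte-identical.

## Notes

- Observation CSVs: columns `id, lon, lat, datetime_utc, category_label`;
  dates must be ISO-8601 (interpreted as UTC); presence is any non-`"0"`
  category. Derived columns (`east`, `north`, `solar_elev_deg`, `dn`,
  `doy`, `year`) are appended on read.
- Day of year lives on a fixed 365-day axis (Feb 29 → day 60).
- Component labels: north iff latitude ≥ split (ties north).
- The model archive is a zip of JSON/CSV text parts (spec, knots,
  constraint transforms, coefficients, covariance, smoothing parameters,
  fit log) and reloads into a fully functional model.
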