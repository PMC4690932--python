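# sludgekit

Toolkit for modeling the activated-sludge thickening and settling process
in secondary settlers (clarifiers):

* **`sludgekit.thickening`** — power-law bottom-concentration model
  `X_d = a·t_s^b`: calibration from thickening-test curves, prediction with
  a mass-balance floor at the initial concentration, sludge-blanket height
  `x = x0·X0/X_d`, sensitivity of `X_d` to the exponent, and the
  return-sludge concentration `X_r = k·X_d` (k = 0.7 for scraped
  withdrawal, 0.5–0.7 for suction).
* **`sludgekit.svi`** — cross-plant log-linear link `a = α·ln(SVI) + β`.
  Two presets ship: `printed` (as-published coefficients, kept verbatim
  although they are internally inconsistent with the reference plant
  panel) and `refit` (reproducible OLS refit of the panel, the default).
* **`sludgekit.settling`** — hindered (Vesilind `v = v0·e^{-nX}`)
  calibration from batch settling curves, the compression settling
  velocity law derived from the thickening fit (time and concentration
  forms), compression-onset detection by the bisector-of-tangents
  graphical construction, the integrated piecewise settling law, and
  solids-flux / limiting-flux analysis comparing the hindered-only and
  integrated variants.
* **`sludgekit.fractal`** — floc morphometry from grayscale images
  (threshold → 8-connected labeling → border/area filters → pixel-count
  area + smoothed marching-squares perimeter + area-equivalent-sphere
  volume) and population fractal dimensions D2, D3, DB from log-log
  regressions, plus their trends against SVI.
* **`sludgekit.synthetic`** — seeded generators (thickening curves,
  two-phase settling curves, plant panels, floc images) that return their
  ground truth, enabling closed-loop recovery tests.
* **`sludgekit.io` / `sludgekit.cli`** — CSV/JSON dialects, YAML run
  configuration, and the umbrella command-line interface.

Canonical units everywhere at the public interface: time min, height m,
concentration g/L, SVI mL/g, velocity m/h, flux kg/(m²·h).

## CLI

All subcommands accept `--json` for machine-readable output. Exit codes:
0 success, 1 data/validation error, 2 usage error.

```sh
sludgekit fit-thickening curve.csv --json          # a, b, R², p
sludgekit predict-a --svi 120 --preset refit
sludgekit predict-xr --a 6.493 --b 0.0465 --t 1 --k 0.7 --X0 6.600
sludgekit fit-vesilind --csv b1.csv --X0 2.0 --csv b2.csv --X0 3.0 \
    --csv b3.csv --X0 4.1 --x0 1.0
sludgekit detect-onset batch.csv --X0 6.6 --x0 1.0
sludgekit velocity --model model.json --x 8.0
sludgekit flux --model model.json --underflow 0.3
sludgekit fractal measure flocs.png --out flocs.csv
sludgekit fractal fit flocs.csv
sludgekit fractal trend plants_dims.csv
sludgekit simulate thickening --seed 7 --out curve.csv
```

CSV dialects (`#` comment lines allowed): thickening `time_min,conc_g_L`;
batch settling `time_min,height_m`; plants `plant_id,svi_mL_g,a,b`; flocs
`floc_id,area,perimeter,volume`. Fitted models serialize to JSON with
explicit units, provenance and toolkit version (`sludgekit.io`).

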