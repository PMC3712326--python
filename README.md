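# cnsmooth

Annotation-guided training and evaluation of copy-number profile smoothing
models.

Copy-number profiles (per-probe logratio signals) are smoothed by
piecewise-constant models whose smoothness parameter λ controls the number
of predicted breakpoints. Instead of relying on model-specific heuristics,
`cnsmooth` treats expert *breakpoint-region annotations* — genomic
intervals with an interval-valued expected breakpoint count ([0,0], [1,1]
or [1,∞)) — as the training signal: the best λ is the one whose predicted
breakpoints disagree with the fewest annotations.

The package provides:

- **Segmentation models** — exact least-squares piecewise-constant
  segmentation by dynamic programming with two equivalent penalty-based
  segment-count selectors (`cghseg.k`, `pelt.n`), and an exact 1-D fused
  lasso / total-variation smoother (`flsa`, plus the probe-density
  normalized `flsa.norm`).
- **Annotation error & ROC** — breakpoints are the midpoints between
  adjacent probes with unequal fitted values; each annotated region scores
  a zero-one FP/FN loss, aggregated into per-λ local (per-profile) and
  global error curves and ROC points.
- **Model selection** — global (one λ for all profiles) and local
  (profile-specific λ) training, with a three-rule tie-breaking protocol
  over error-curve plateaus.
- **Cross-validation** — leave-one-annotation-out CV comparing global vs
  local training, and ⌊n/t⌋-fold CV measuring how many annotated profiles
  are needed for a good global model.
- **Synthetic data** — seeded simulation of piecewise-constant profiles
  with Gaussian noise plus truth-consistent annotation databases in both
  the "systematic" and "any" protocols, so the whole pipeline is testable
  offline.

## CLI

All commands are deterministic given their flags; every output gets a
`<out>.config.json` with the resolved parameters.

```sh
# simulate 50 profiles plus annotations with known truth
cnsmooth simulate --n 50 --seed 1 --out profiles.csv \
    --annotations-out annotations.csv --truth-out truth.csv

# smooth over a penalty grid; emits per-lambda breakpoints
cnsmooth segment --profiles profiles.csv --model cghseg.k --kmax 20 \
    --lambda-grid 1e-8:1e4:100 --out breakpoints.csv

# score breakpoints against annotations -> per-lambda error curve
cnsmooth evaluate --breakpoints breakpoints.csv \
    --annotations annotations.csv --out errors.csv

# error curve -> ROC points
cnsmooth roc --errors errors.csv --out roc.csv

# train the smoothness parameter (global or local scope)
cnsmooth train --profiles profiles.csv --annotations annotations.csv \
    --model cghseg.k --scope global --out trained.json

# cross-validate (leave-one-annotation-out, or floor(n/t)-fold)
cnsmooth cv --profiles profiles.csv --annotations annotations.csv \
    --model cghseg.k --protocol ntfold --t 10 --seed 1 --out cv
```

Third-party smoothers can be benchmarked without re-implementation by
passing their per-λ breakpoint CSV (columns `model,lambda,profile_id,
chromosome,position`) to `cnsmooth evaluate --external-breakpoints`.

Input formats: profile CSV (`profile_id,chromosome,position,logratio`) or
one 4-column bedGraph per profile; annotation CSV with either explicit
`min_breakpoints`/`max_breakpoints` columns (blank or `Inf` = unbounded)
or a `label` column (`0breakpoints`, `1breakpoint`, `>0breakpoints`).

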