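# lvshape

Statistical shape modelling of the left ventricle (LV) from stacked
short-axis contours, with a sparse prognostic shape score for arrhythmic
risk and the downstream survival statistics.

The pipeline:

1. **synthetic** — generate synthetic cohorts (anatomy, contour stacks,
   proportional-hazards outcomes, covariates with confounding and
   missingness) with known ground truth, all from one master seed.
2. **io** — plain-text artifacts: JSON contour stacks (mm units, schema
   versioned), CSV cohort tables, VTK/OBJ mesh export, JSON model
   serialization. Readers validate and reject; they never silently repair.
3. **personalize** — basal truncation at the RV-landmark slice, template
   initialization from the contour stack, ICP-style non-rigid fit of a
   fixed-topology two-surface lattice (Laplacian-regularized sparse least
   squares), and rigid cohort alignment (center of mass, apex→base +z,
   +x toward the RV landmark).
4. **metrics** — cavity (blood-pool) volume by divergence theorem, apex-to-
   base length, wall thickness by normal-ray casting, sphericity, and
   16-segment bullseye wall-thickness maps.
5. **pca** — PCA shape model over aligned shape vectors: projection,
   reconstruction, variance explained, mode exaggeration (± n·sd meshes),
   Spearman mode–variable correlation tables.
6. **lvas** — Cox–Lasso over mode coefficients (Efron ties, coordinate
   descent with KKT-verified paths, cross-validated partial likelihood for
   penalty selection), max–min normalized score with frozen training
   bounds and quartile cutpoints.
7. **stats** — Cox regression (incl. counting-process time-varying device
   covariates and case weights), univariate screening, generalized
   propensity scores with stabilized IPW for a continuous exposure,
   chained-equation multiple imputation with Rubin pooling, and
   Mann–Whitney / χ² group comparisons.

## Test

```
python -m pytest tests/
```

The suite includes unit and property tests per module plus
`tests/test_acceptance.py` (oracle equivalence, worked examples,
geometric analytics, and seeded end-to-end recovery on synthetic
cohorts). The full run takes ~10 minutes on one CPU.

## CLI

```
lvshape simulate   --n 156 --seed 1 --out sim/            # cohort + contours + truth
lvshape fit-meshes --contours sim/contours --out meshes/  # template personalization
lvshape metrics    --meshes meshes/ --out metrics.csv
lvshape pca        --meshes meshes/ --out model.json --coeffs coeffs.csv
lvshape lvas-train --coeffs coeffs.csv --cohort sim/cohort.csv \
                   --model model.json --out lvas.json
lvshape score      --lvas lvas.json --model model.json --mesh patient.npy
lvshape survival   --cohort sim/cohort.csv --lvas scores.csv \
                   --model multi2 --out results.json
```

`survival` models: `univariate` (score quartile only), `multi1`
(+ LVEF + NYHA III/IV), `multi2` (+ time-varying ICD), `multi3`
(+ time-varying CRT), `ipw` (propensity-weighted).

## Conventions

- Millimetres everywhere; +z runs apex→base; after alignment the origin
  is the LV center of mass and +x points toward the RV landmark.
- Lattice meshes default to 48 circumferential × 32 longitudinal nodes
  per surface (+1 apex node each); resolution is configurable and must be
  shared across a cohort for PCA correspondence.
- All randomness flows from one integer master seed through named
  substreams (anatomy / outcomes / covariates / render / devices).
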