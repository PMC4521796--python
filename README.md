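# retmap

Spatial statistics for retinoblastoma tumor maps in retinal polar
coordinates.

Retinoblastoma is a childhood cancer of the retina. When the perimeter of
each tumor is mapped in retinal coordinates — eccentricity (degrees of arc
from the fovea) and polar angle (degrees from the superior vertical
meridian) — the cohort-level questions become spatial statistics: where on
the retina does tumor burden concentrate, how does the location of tumor
origin vary with age at diagnosis, tumor size, and germline vs. somatic
RB1 mutation, and do multiple tumors within one eye repel each other?
`retmap` is a toolkit for exactly this analysis, aimed at ocular-oncology
and retinal-development researchers.

The package provides:

- **Spherical geometry** of the 60°-radius retinal window: the azimuthal
  equidistant projection `x = ecc·sin φ, y = ecc·cos φ`, great-circle
  distances, left/right-eye pooling by reflection across the vertical
  meridian, and exact spherical areas/centroids of tumor regions via
  boundary line integrals (validated against Monte Carlo oracles).
- **Tumor maps**: periodic-spline perimeter interpolation, rasterization,
  per-tumor metrics, cumulative burden maps (eyes with tumor per retinal
  location), and boundary-to-boundary margin distances.
- **Point-process modeling** of tumor centroids as a marked inhomogeneous
  Poisson process with log-polynomial intensity,

      log λ(x, y) = Σ_{i+j≤d} β_ij x^i y^j,

  fitted by maximum likelihood with the Berman–Turner quadrature device
  (a weighted Poisson GLM), in statsmodels style: a
  `PoissonIntensityModel` whose `fit()` returns results with coefficients,
  standard errors, log-likelihood/AIC, `summary()`, and `simulate()`.
  Marked fits give one intensity per mark level. Diagnostics include
  Ripley's K with CSR simulation envelopes, nearest-neighbor distances in
  projected-Euclidean and great-circle metrics, kernel relative-density
  maps, and a within-eye permutation test for tumor repulsion.
- **Cohort statistics**: exact Fisher tests (2×2 with conditional-MLE odds
  ratio, 2×K by exact enumeration), Wilcoxon rank-sum, quartile splits,
  small-tumor sector tallies, circular means.
- **A seeded synthetic-cohort generator** reproducing the structure of a
  mapped retinoblastoma cohort (bilateral ⇒ germline, germline patients
  younger and multifocal, tumor area decreasing and eccentricity
  increasing with age quartile, age-quartile-specific spatial clusters),
  so the full pipeline is testable without patient data.
- **I/O and a CLI**: perimeter CSV + metadata JSON round-trips, polar map
  rendering, and a `retmap` command with `simulate`, `metrics`, `burden`,
  `fit-ppm`, `kest`, `permtest`, `tables`, `render`, and `run` subcommands.

## Worked example

```python
from retmap import (CohortConfig, generate_cohort, summarize_cohort,
                    PointPattern, PoissonIntensityModel,
                    within_eye_permutation_test, fisher_exact)

cohort = generate_cohort(seed=42)
s = summarize_cohort(cohort)
print(f"patients={s['n_patients']} eyes={s['n_eyes']} tumors={s['n_tumors']}")

pattern = PointPattern.from_cohort(cohort)
print(PoissonIntensityModel(pattern, degree=2).fit().summary())

print(within_eye_permutation_test(cohort, B=999, seed=42).summary())

fr = fisher_exact([[28, 11], [24, 43]])
print(f"Fisher OR={fr.odds_ratio:.2f}, p={fr.p_value:.2g}")
```

prints

```
patients=67 eyes=97 tumors=133
Inhomogeneous Poisson intensity (log-polynomial)
  n points: 133   degree: 2
  log-likelihood: -683.726   AIC: 1379.453
      term         coef         se
         1    -3.363042   0.136284
         x     0.010015   0.003909
         y     0.004287   0.004046
       x^2    -0.000742   0.000132
        xy     0.000091   0.000184
       y^2    -0.000860   0.000142
within-eye NN permutation test: observed 44.479 deg, null mean 36.492 deg, p = 0.005 (greater, B=999)
Fisher OR=4.49, p=0.00054
```

Reading the output: the synthetic cohort has 67 patients whose 133 mapped
tumors form the fitted point pattern. The negative quadratic terms say
tumor-centroid density falls off away from the posterior pole, and the
positive `x` coefficient says it is higher on the nasal side. Tumors
sharing an eye sit ~8° further from their nearest within-eye neighbor than
size-matched random groups of centroids would (p = 0.005) — the within-eye
repulsion signal. The Fisher call tests a 2×2 mutation-by-mapping-status
table of patient counts: somatic-mutation patients have ≈4.5-fold higher
odds of being unmappable.

The same analysis runs from the shell:

```sh
retmap simulate --seed 42 --out-prefix cohort
retmap run --seed 42 --perimeters cohort_perimeters.csv --metadata cohort_metadata.json
```

## Layout

```
src/retmap/
  geometry.py      spherical coordinates, projection, areas, centroids
  tumors.py        perimeters, rasterization, burden maps, margins
  pointprocess.py  Poisson intensity model, K/envelopes, permutation test
  stats.py         exact contingency, rank, quartile, circular statistics
  synthetic.py     seeded cohort generator
  io.py            perimeter CSV + metadata JSON round-trips
  plots.py         polar map rendering
  pipeline.py      end-to-end pipeline with results bundle
  cli.py           command-line interface
docs/methods.md    models, assumptions, numerical choices, limitations
```
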