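# pglspatial

Cross-cultural and cross-site comparative data violate the independence
assumption of ordinary regression twice over: related societies inherit traits
from common ancestors (Galton's problem), and neighbouring societies exchange
them. `pglspatial` fits generalized least squares regressions whose error
covariance carries both sources of dependence at once, and wraps that fitter
in the machinery a comparative analysis needs: all-subsets AICc model
averaging with relative variable importance, likelihood-ratio tests for each
dependence component, Pagel's-λ phylogenetic-signal estimation, and
replication over a posterior sample of trees with per-site language
resampling. A synthetic-data generator produces island-scale datasets with
known ground truth so every stage is testable end to end.

## The model

For *n* sites the regression `y = Xβ + ε` has errors
`ε ~ N(0, σ² V(λ, φ))` with

```
V(λ, φ) = (1 − φ)[(1 − λ) diag(h) + λ Σ] + φ W
        = γ diag(h) + λ′ Σ + φ W
```

- **Σ** — phylogenetic variance–covariance matrix: shared root-to-tip path
  lengths between the languages assigned to the sites, the expected trait
  covariance under Brownian motion; **h** = diag(Σ).
- **W** — spatial similarity: `W_ij = 1 − D_ij / max(D)` from great-circle
  (haversine) distances `D` in km.
- **λ ∈ [0, 1]** scales phylogenetic covariance (Pagel's λ), **φ ∈ [0, 1]**
  weights the spatial component. Reported as `λ′ = (1 − φ)λ`,
  `γ = (1 − φ)(1 − λ)`: with Σ normalized to unit height and W with unit
  diagonal, (λ′, φ, γ) are the proportions of variance attributable to
  ancestry, space, and independent noise.

β and σ² are profiled analytically; (λ, φ) are estimated by ML with a grid
seed plus bounded quasi-Newton refinement. Candidate models are compared by
AICc; a predictor's relative variable importance (RVI) is the summed Akaike
weight of the models containing it.

## Worked example

```python
import numpy as np
import pglspatial as pg

tree = pg.simulate_tree(100, seed=3, unit_height=True)          # Yule tree
sites, aug = pg.simulate_sites(tree, 0.4, seed=4)               # confounded coordinates
cov = pg.build_covariance_set(aug, sites.primary_taxon,
                              sites.lat, sites.lon,
                              labels=sites.site_id.tolist())

truth = pg.SimulationTruth(lam=0.7, phi=0.2, sigma2=1.0,
                           beta={"i": 1.0, "x": -1.5},
                           discretization=None, seed=0)
X = np.column_stack([np.ones(cov.n), np.random.default_rng(0).normal(size=cov.n)])
y = pg.simulate_outcome(X, truth, cov, seed=5)

fit = pg.fit_pgls_spatial(X, y, cov, mode="both")
print(round(fit.params.lam, 2), round(fit.params.phi, 2),
      np.round(fit.beta, 2))
```

prints

```
0.79 0.06 [ 0.36 -1.47]
```

a single draw's estimate of (λ, φ) and the coefficients: the slope −1.47 is
close to the generating −1.5, while the single-dataset (λ̂, φ̂) = (0.79, 0.06)
scatters around the truth (0.7, 0.2) — across 100 such replicates the means
come back as 0.68 and 0.17 (see the recovery study below).

The full study-shaped analysis — data preparation with log transforms, factor
dummies and listwise deletion, 1024-model averaging, dependence tests, signal
estimation and the variogram, all replicated over trees and language draws —
runs from a YAML config via `run_analysis` or the CLI:

```
pgls-spatial simulate --seed 1 --out results/fixture
pgls-spatial average --config config.yaml
pgls-spatial signal --trees results/fixture/trees.nwk \
    --sites results/fixture/sites.csv --outcome deforestation
```

The numbered scripts under `analysis/` run the same pipeline as a narrative:
`01_simulate_data.py` → `02_phylogenetic_signal.py` → `03_spatial_variogram.py`
→ `04_ecological_model_averaging.py` → `05_cultural_predictors.py`, writing
tables under `results/`.

## Layout

- `src/pglspatial/` — library: `tree_io`, `covariance`, `gls`, `averaging`,
  `replicates`, `simulate`, `pipeline`, `cli`, `evaluation`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite, including the performance studies in
  `tests/test_acceptance.py`
- `docs/methods.md` — model, assumptions, parameter choices, limitations
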