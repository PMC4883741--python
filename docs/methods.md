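# Methods

## The variance model

Site-level trait data from related, spatially clustered societies are doubly
non-independent. We model a continuous outcome as `y = Xβ + ε`,
`ε ~ N(0, σ² V(λ, φ))`, with

```
V(λ, φ) = (1 − φ)[(1 − λ) diag(h) + λ Σ] + φ W = γ diag(h) + λ′ Σ + φ W,
λ′ = (1 − φ) λ,   γ = (1 − φ)(1 − λ).
```

Σ is the Brownian-motion trait covariance implied by the phylogeny: Σ_ij is
the branch length shared by the root-to-tip paths of the languages assigned
to sites i and j, and h = diag(Σ). The inner bracket is Pagel's λ transform —
λ = 1 is pure Brownian motion, λ = 0 is phylogenetic independence. W is a
spatial similarity matrix and φ its weight.

Assumptions worth stating plainly: trait evolution on the tree is adequately
summarized by the λ-scaled Brownian covariance (no directional trends, no
Ornstein–Uhlenbeck pull); spatial dependence is stationary and linear in
great-circle distance; ordinal outcome scores are treated as continuous; and
the two dependence components combine additively.

### Scale conventions

The mixture weights are only interpretable if the components share a scale.
Σ is normalized so that max(h) = 1 and W has unit diagonal; for an
ultrametric tree diag(V) = γ + λ′ + φ = 1, so (γ, λ′, φ) partition the error
variance. Non-ultrametric trees are accepted; all formulas use the general
diag(h) form and the partition then holds only at the deepest tip.

### Distance → similarity

A distance matrix cannot serve as a covariance, so W is built as
`W_ij = 1 − D_ij / max(D)` with D from the haversine formula on a spherical
Earth, R = 6371 km (configurable). The farthest pair in the sample has
similarity 0 and co-located sites similarity 1. This linear-in-distance choice
is simple, parameter-free and monotone; it is not a fitted spatial model.
W is checked for positive semidefiniteness and repaired by eigenvalue
clipping (negative eigenvalues set to zero, diagonal restored to 1, warning
emitted) when the check fails at tolerance 1e−8.

## Estimation

β and σ² have closed forms given V, so the likelihood is profiled down to
(λ, φ) on the unit square. ML rather than REML is used throughout: AICc
comparisons across models with different fixed effects require ML. σ̂² is the
ML (1/n) estimator; the log-likelihood is
`−½[n ln(2π σ̂²) + ln|V| + n]`.

Optimization is an 11-point-per-dimension grid seed followed by L-BFGS-B
refinement from the 3 best grid points (objective tolerance 1e−8). Estimates
within 1e−6 of a bound are reported exactly at 0 or 1. Against an exhaustive
101×101 grid the optimizer agrees to well under 0.01 log-likelihood units
(`tests/test_acceptance.py`). Inside the optimizer the profile likelihood is
evaluated via normal equations on whitened data; final fits use a QR path
that also diagnoses rank deficiency. Cholesky factors of V are cached per
(λ, φ) in a bounded LRU store, and the all-subsets enumeration whitens the
full design once per grid point and scores every subset from the shared
normal matrix — this is what makes 1024 models × 100 replicates feasible.

Degenerate inputs: a perfect fit (residual sum of squares at machine zero)
is flagged on the returned fit and excluded from AICc weighting by its
infinite criterion; constant responses are rejected where a variance ratio
would be undefined; singular V (e.g. duplicated dialect tips under λ = 1)
falls back to a 1e−10 ridge and, failing that, is treated as −∞ likelihood
so the optimizer avoids it.

### Parameter count for AICc

`k = (#regression coefficients incl. intercept) + 1 (for σ²) + #free
dependence parameters`. Candidate models within one enumeration all estimate
the same dependence parameters, so the choice penalizes (λ, φ) symmetrically;
it matters only when comparing across analyses with different modes.

### Tests for the dependence components

Likelihood-ratio tests compare the four nested variance models {both, λ only,
φ only, neither}: p(λ) from {both} vs {φ only}, p(φ) from {both} vs {λ only},
each on 1 df. The null value of each parameter lies on the boundary of
[0, 1], which makes the plain χ²₁ reference conservative. For the λ test the
measured null rejection rate at α = 0.05 is about 0.01–0.015 (and matches
`phytools::phylosig`'s decisions exactly on shared data); for the φ test it
is lower still, about 0.003–0.01 and flat in n, because the dominant
structure of W is absorbed by the intercept and the independent-noise
component, leaving φ̂ at the zero boundary in over 90% of null datasets.
Power is unaffected (98% detection of φ = 0.8 at n = 100). We keep the plain
χ²₁ reference deliberately — a 50:50 mixture correction would halve the
p-values but the conservative convention matches how these tests are usually
reported in comparative analyses.

Phylogenetic signal per trait is the same machinery with an intercept-only
design and V = λ-transform of Σ: λ̂ by ML on [0, 1], significance by 1-df LRT
against λ = 0.

### GLS R²

`R² = 1 − SSreg/SStot`, where SSreg is the V̂-whitened residual sum of squares
of the fitted model at its own (λ̂, φ̂) and SStot comes from an intercept-only
model re-fit with its own dependence optimum. Because numerator and
denominator are whitened by different V̂s, the statistic is not an OLS R² and
can in principle go negative; it is reported as an indication of fit, not a
variance decomposition.

## Model averaging

All 2^k subsets of the candidate predictor terms are fit (the empty,
intercept-only model included), in deterministic binary-counting order.
(λ, φ) are re-optimized inside every candidate model rather than fixed from
the full model, so dependence uncertainty propagates into the weights.
Akaike weights are `exp(−ΔAICc/2)` normalized to sum to one; RVI(p) is the
summed weight of models containing p. Listwise deletion runs once over the
union of outcome and all candidate predictors before enumeration, so every
model is fit on the identical observation set — without this, AICc values are
not comparable.

Averaged coefficients default to the conditional (natural-average)
convention: weights renormalized over the models containing the term, with
the unconditional variance `Σ w̃_i [se_i² + (β̂_i − β̄)²]` and a normal 95%
interval. Full-model averaging (absent terms contribute zero) is available by
flag. The dependence summary (λ′, φ, γ and both LRT p-values) is computed on
the design containing every candidate predictor.

Factor predictors can enter jointly (all dummies together, one term) or
independently (each dummy its own candidate). Independent entry is the
default: it is the only convention under which two dummies of one factor can
earn different RVIs, which is the natural reading of a result table that
reports them separately.

## Replication over trees and language draws

Sites may carry several candidate languages (dialect chains, multilingual
islands). Each replicate draws one tree from the supplied sample (without
replacement when the sample is at least as large as the replicate count,
otherwise with replacement), draws one language per site uniformly among its
candidates, prunes the tree, rebuilds Σ, and reruns the full analysis.
Aggregates are arithmetic means of every reported quantity; p-values are also
mean-aggregated by default (median by flag), a pragmatic summary rather than
a formally calibrated combination. One global seed spawns per-replicate
substreams, so the whole pipeline is bit-reproducible given (seed, inputs,
config) — verified by byte-comparing report JSONs.

## The synthetic-data generator

The generator emulates the structural features of an island-scale
cross-cultural dataset so that every stage of the pipeline can be exercised
with known truth:

- **Tree**: pure-birth (Yule) with unit birth rate; at k lineages the next
  split waits Exp(k), and one further waiting time elapses after the n-th
  lineage, so expected height is Σ_{k=2..n} 1/k (the closed form the tests
  check). Trees are optionally rescaled to unit height.
- **Geography**: tips diffuse on the sphere along the tree (child direction =
  parent rotated by an angle ~ N(0, σ_a² · branch length), σ_a = 0.35 rad);
  the delivered coordinate interpolates along the great circle between an
  independent uniform draw in a Pacific-like window (25°S–10°N band) and the
  diffusion endpoint, with weight ρ. ρ = 0 gives spatially random sites;
  ρ > 0 reproduces the real-data confound that close relatives are
  geographic neighbours (rank correlation > 0.3 at ρ = 0.9).
- **Dialects**: a configurable fraction of sites (default 20%) receives 2–5
  extra tips attached near the site's tip with short terminal branches
  (2% of tree height), giving sites multiple candidate languages.
- **Predictors**: latent draws are multivariate normal with covariance equal
  to the λ-transform of Σ at a per-predictor target signal, then mapped to
  continuous (optionally exponentiated for log-scale variables), factor
  (quantile thresholds) or binary (prevalence threshold) columns; missingness
  is inserted completely at random.
- **Outcomes**: `y = Xβ + ε` with ε ~ N(0, σ²V(λ, φ)); optional monotone
  discretization to ordinal scores (5-level deforestation-like, 4-level
  replacement-like) by marginal quantile cut-points. Discretization is off by
  default: the analysis model treats scores as continuous, and recovery tests
  should not conflate that approximation with estimator performance.

The `pacific80` profile fixes the study-scale conditions used throughout the
tests: 80 sites, a ~116-tip tree (dialect tips included), a posterior-like
sample of 10 branch-length-jittered trees (log-normal jitter, σ = 0.1), ten
ecological predictor columns (four log-scale continuous, absolute latitude, a
percentage, a continuous deposition variable, a 3-level tephra factor entering
as two independent dummies, 3-level substrate age entered ordinal-coded),
five binary cultural predictors, 5% missingness on two predictors, two sites
flagged treeless, ρ = 0.6, and generating coefficients whose largest
standardized effects are ≈ 0.5–0.8 with residual (λ, φ) = (0.5, 0.2) for the
deforestation-like outcome and (0.9, 0.1) for the replacement-like outcome.

What the generator does **not** emulate: realistic island geomorphology,
non-MCAR missingness, measurement error in coordinates or scores, vocabulary
evolution (trees are Yule, not inferred), or horizontal transmission beyond
the smooth spatial component. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to violations of
it.

## Problem sizes used in the validation studies

Enumeration check at 10 predictors (1024 models); OLS equivalence at n = 40;
grid-search oracle at n = 50 taxa on a 101×101 lattice; joint recovery at
n = 200 with 100 Monte-Carlo replicates; signal recovery on a 100-tip tree
with 50 replicates per condition; RVI discrimination at n = 100 with 20
replicates; LRT calibration with 200 simulations at n = 80; determinism on
the pacific80 fixture at 5 replicates. These sizes make each study
informative while keeping the full suite runnable on a laptop core; the
underlying functions accept larger sizes unchanged.

## Known limitations

- Binary outcomes are fit by the same linear GLS (no logistic variant), which
  matches common practice in this literature but is a linear-probability
  approximation.
- The conditional averaging convention can overstate the magnitude of
  coefficients for weak predictors relative to full averaging; both are
  available and the choice is reported in the config echo.
- Mean-aggregated p-values across replicates have no exact frequentist
  interpretation.
- The spatial model is a single linear similarity; no variogram-model fitting
  or anisotropy.
- λ̂ and φ̂ are weakly identified when geography and phylogeny are strongly
  confounded (high ρ) — exactly the situation the joint model is for — so
  single-dataset estimates of the split between λ′ and φ carry wide
  uncertainty even when their sum is well determined.
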