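# Methods

## Model and estimands

We work in the standard whole-genome random-effects model. Dosage genotypes
`X ∈ {0,1,2}^{n×p}` are column-centered by `P = I − 11'/n`; the phenotype
model is `y = μ1 + PXβ + ε` with `β_j ~ N(0, σ_β²)` i.i.d. and
`ε ~ N(0, σ_ε² I)`. The equivalent individual-level model is
`y = μ1 + g + ε`, `g ~ N(0, σ_g² G)` with the VanRaden GRM
`G = PXX'P/c`, `c = 2Σ_j p_j(1−p_j)` and `σ_β² = σ_g²/c`. Allele
frequencies are taken from the sample (`p̂_j` = column mean / 2) and folded
to the minor allele; monomorphic columns (zero sample variance) are dropped
with a warning since they contribute to no estimator.

The estimand is the additive genomic variance as a quadratic form in the
genomic values,

```
s²_{g,B} = g'Bg/(n−1),
```

with `B = I` for the current population and `B = R^{−1/2} P R^{−1/2}` for
the base population of unrelated founders (R a pedigree or genomic
relationship matrix). Because β is random, `s²_{g,B}` is a random variable;
the package computes both its unconditional expectation (V family) and its
best predictor — the conditional expectation given y (W family):

* `E[s²_{g,B}] = σ_g² tr(BG)/(n−1)`; for `B = I` this is
  `V = σ_β² tr(Σ̂_X)` with `Σ̂_X = X'PX/(n−1)`.
* `BP(s²_{g,B}) = tr(B[μ_{g|y}μ_{g|y}' + Σ_{g|y}])/(n−1)`, assembled from
  `E[ββ'|y] = μ_{β|y}μ_{β|y}' + Σ_{β|y}` — never by sampling.

The decomposition `BP = E + L(y)` is exact; `L(y)` is reported as the LD
component of every W-family estimate. Its explicit form — the double sum of
`Σ̂_X` entries weighted by `μ_{β|y}μ_{β|y}' − Cov(μ_{β|y})` — is implemented
as a cross-check path and for the diagonal/off-diagonal breakdown; the
default path computes `W − V`, which is exact at any p in O(n²). Note the
sign convention: the weight matrix uses `Cov(μ_{β|y})` (the covariance of
the BLUP), not `Σ_{β|y}`; conflating the two flips the sign of the
correction. Both are exposed on the fit object for this reason.

## REML

The two-component model is fitted by spectral profile REML: `G = UDU'` is
eigendecomposed once, `(y, 1)` are rotated into the eigenbasis, and the
restricted likelihood of the variance ratio `λ = σ_g²/σ_ε²` — with μ and
σ_ε² profiled out in closed form — is maximized over `log λ` by bounded
derivative-free scalar minimization (search range `[1e−8, 1e8]`, tolerance
`1e−10` in log λ). Each likelihood evaluation is O(n), so replicated fits
on a fixed G are cheap. With exactly two components this profile approach
is exact; no iterative EM/AI updates are involved. σ_ε² uses the REML
(n−1) denominator. The `σ_g² = 0` boundary is evaluated explicitly and
reported with a `boundary` flag rather than as an error; `G = 0` degrades
to the null model with `σ̂_ε²` the sample variance of y. Fixed effects are
intercept-only by design; general designs are out of scope.

BLUPs and conditional covariances use the REML projection
`Q = V⁻¹ − V⁻¹1(1'V⁻¹1)⁻¹1'V⁻¹`, which accounts for intercept estimation:
`μ_{g|y} = σ̂_g² G Q y`, `Cov(μ_{g|y}) = σ̂_g² G Q G σ̂_g²`,
`Σ_{g|y} = σ̂_g² G − Cov(μ_{g|y})`, and on the marker side
`μ_{β|y} = σ̂_β² (PX)' Q y` (identical to the ridge solution with penalty
`σ̂_ε²/σ̂_β²`). This convention is what makes the empirical decomposition
`W + σ̂_ε² = σ̂_y²` hold to ~1e−9 relative at the REML optimum — the
orthogonal-projection property of the conditional expectation — which the
test-suite verifies across 100 simulated fits.

## Base population

`R^{−1/2}` is the Moore–Penrose inverse square root: eigenvalues below
`rank_tol · λ_max` (default `n·eps`) are zeroed and inverted to zero, so for
singular R the transform acts on range(R) only. When the GRM itself is used
as R (`Ws*`), `B = G^{−1/2} P G^{−1/2}` collapses to the pseudo-inverse
`G⁺` because range(G) ⊥ 1. `Vs*` is reported as `σ_g²` directly — the
conventional GREML reading; note that the B-consistent expectation equals
`σ_g² · rank(G)/(n−1)`, which coincides with `σ_g²` exactly when
`rank(G) = n−1` (the usual p ≫ n case) and is what the `W = V + L(y)`
identity uses internally for the Ws* LD component. No heritability is
defined in the base population: σ̂_ε² and σ̂_y² belong to the current one,
and the code refuses to compute it.

## Bayesian cross-check

The Gibbs sampler implements Bayesian ridge regression on the centered
genotypes: single-site normal full conditionals for each β_j with running
residual updates, a flat prior on μ, and scaled-inverse-χ² full
conditionals for (σ_β², σ_ε²) with df = 5 and scales matched to a 50/50
split of var(y) (configurable; defaults chosen as a conventional weakly
informative BRR prior). Defaults: chain 12 000, burn-in 2 000, thinning 10.
`M2` averages `β⁽ᵐ⁾'Σ̂_X β⁽ᵐ⁾ = ‖PXβ⁽ᵐ⁾‖²/(n−1)` over retained draws; its
Monte-Carlo SE uses batch means (50 batches) to absorb autocorrelation.
A `fix_vc` mode pins the variance components; with them fixed at the REML
estimates the posterior is the exact conditional normal of the gBLUP model
and M2 is an unbiased Monte-Carlo estimate of W — the equivalence the
acceptance test asserts within 3 MC SE at 10⁴ draws. With variance
components sampled, M2 systematically differs from the plug-in W because it
integrates over their posterior; that mode is for data analysis, not for
the equivalence check.

## Synthetic data

The generator produces exactly the data-generating process the estimators
assume: dosages, i.i.d. normal effects, Gaussian noise, so every test is a
within-model check. MAFs are uniform on a configurable range (default
0.1–0.5). Two LD regimes:

* `independent`: Binomial(2, p_j) dosages (Hardy–Weinberg, no LD);
* `ar1_haplotype`: each individual is the sum of two independent haplotypes
  simulated as a first-order Markov chain over loci, with exact
  Bernoulli(p_j) marginals and adjacent-locus correlation ρ. Adjacent
  *dosage* correlation is then also ρ. For unequal MAFs, ρ may exceed the
  Fréchet bound of a pair; the chain clips that pair to 0.999 of its
  maximum (`ar1_adjacent_correlation` reports the realized targets; with a
  constant MAF no clipping occurs, which is the regime the calibration test
  uses). This model was chosen over Gaussian-threshold genotypes for its
  exact {0,1,2} support and closed-form adjacent correlation.

Every dataset stores its seed, the true β, and the realized
`s_g² = β'Σ̂_X β`, so predictors can be compared against the realized random
target. What the generator does **not** emulate: LD beyond first order,
allele-frequency/effect-size coupling, population structure beyond
equicorrelated family blocks, non-Gaussian residuals, and incomplete LD
between causal loci and markers (the genotyped markers *are* the causal
loci here). Passing tests therefore demonstrate correctness of the
estimators under the random-effects model, not robustness to model
violations in real data.

## Simulation-study sizes

The standing studies (`genovar.studies`, used by `scripts/acceptance.py`
and the acceptance tests) use: parameter recovery at n = 500, p = 1000,
200 replicates at fixed X with σ_g² = σ_ε² = 0.5; best-predictor
unbiasedness/MSE dominance at n = 300, p = 50, 500 replicates; the Bayesian
equivalence on a 50×8 fixture with 10⁴ retained draws; and the
W + σ̂_ε² = σ̂_y² decomposition across 100 fits at n = 200, p = 300. Holding
X fixed across replicates amortizes the one-time eigendecomposition, so a
full study runs in seconds.

## Numerical choices and limitations

* All floats are double precision; delimited inputs use sample-ID ×
  marker-ID layout; PLINK `.raw` is supported with allele-suffix stripping.
  Missing dosages are kept as NaN at read time and either mean-imputed on
  request (which preserves zero column means after centering) or rejected
  at GRM construction.
* ID alignment sorts samples, so all results are invariant to input row
  order; estimates are likewise invariant to allele-coding flips (up to
  optimizer noise of order 1e−8).
* p×p objects (`Σ̂_X`, marker-effect covariances) are materialized only
  below a cap (default 20 000 markers); every estimator has an O(n²)
  equivalent-model path, so the package scales to p ~ 10⁵ markers.
* The marker-form/equivalent-form agreement is asserted at run time inside
  `best_predictor` for p ≤ 2000 — a cheap internal consistency guard.
* Standard errors / confidence intervals for W are not provided, and
  multi-component or general fixed-effect models are out of scope.
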