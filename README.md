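# genovar

Estimation and **best prediction** of the additive genomic variance in
random-effects marker models (gBLUP / GREML), including the exact
decomposition that isolates the contribution of linkage disequilibrium (LD).

## The problem

In whole-genome regression the phenotypes of *n* individuals are related to
*p* marker dosages `X ∈ {0,1,2}^{n×p}` by

```
y = μ1 + PXβ + ε,      β_j ~ N(0, σ_β²) i.i.d.,   ε ~ N(0, σ_ε² I),
```

where `P = I − 11'/n` centers columns. Equivalently `y = μ1 + g + ε` with
genomic values `g = PXβ ~ N(0, σ_g² G)`, `G = PXX'P/c` the VanRaden genomic
relationship matrix, `c = 2Σ p_j(1−p_j)` and `σ_β² = σ_g²/c`.

The additive genomic variance of the sample,

```
s_g² = g'g/(n−1) = β' Σ̂_X β,        Σ̂_X = X'PX/(n−1),
```

is a **random variable** in this model, because β is random. Classical
GREML-style estimates report its *unconditional* expectation

```
V = E[s_g²] = σ_β² tr(Σ̂_X) = σ_g² tr(G)/(n−1),
```

which uses only the diagonal of `Σ̂_X` — the LD (covariances between
markers) drops out entirely. This package implements the *best predictor*
(conditional expectation given the data),

```
W = BP(s_g²) = tr(Σ̂_X [μ_{β|y} μ_{β|y}' + Σ_{β|y}]) = tr(μ_{g|y} μ_{g|y}' + Σ_{g|y})/(n−1),
```

built from the BLUP `μ_{β|y} = E[β|y]` and its conditional covariance. W
retains the full marker covariance and decomposes exactly as

```
W = V + L(y),
```

where `L(y)` is a double sum of the entries of `Σ̂_X` weighted by
`μ_{β|y}μ_{β|y}' − Cov(μ_{β|y})` — the explicit, data-driven contribution of
LD. Both families are also available in the *base population* (unrelated
founders) via the decorrelation `g* = R^{−1/2} g` with a pedigree or genomic
relationship matrix R: `V*`, `W*` (supplied R) and `Vs* = σ_g²`, `Ws*`
(GRM-based transform, pseudo-inverse square root). A Bayesian ridge
regression Gibbs sampler provides the posterior-mean analogue
`M2 = (1/M) Σ_m β⁽ᵐ⁾' Σ̂_X β⁽ᵐ⁾` as an independent cross-check of W.

The key practical identity: on phenotypes scaled to unit variance,
`W + σ̂_ε² = σ̂_y²` almost exactly, so W gives a self-consistent definition
of genomic heritability in the current population.

Intended users: quantitative geneticists and breeders who fit gBLUP/GREML
models and need variance components and heritabilities that account for LD.

## Worked example

Simulate a dataset with adjacent-marker LD (AR(1) haplotype model, ρ = 0.6)
and a block-family relationship matrix, then run the full pipeline:

```
genovar simulate --n 200 --p 400 --ld-model ar1_haplotype --rho 0.6 \
    --seed 4 --relationship block_family --out-dir demo
genovar estimate --genotypes demo/genotypes.tsv --phenotypes demo/phenotypes.tsv \
    --relationship-matrix demo/relationship.tsv \
    --estimators V,W,Vstar,Wstar,Vsstar,Wsstar --scale-phenotype --out demo/report.json
```

The report (abridged; your numbers will match exactly — the pipeline is
deterministic given the seed):

```json
"variance_components": { "sigma_g2": 0.4548376, "sigma_e2": 0.5472848, "converged": true },
"estimates": [
  { "estimator": "V",      "population": "current", "value": 0.4600499 },
  { "estimator": "W",      "population": "current", "value": 0.4527152, "ld_component": -0.0073346 },
  { "estimator": "V_star", "population": "base",    "value": 0.7699015 },
  { "estimator": "W_star", "population": "base",    "value": 0.7442623, "ld_component": -0.0256392 },
  { "estimator": "V_s_star", "population": "base",  "value": 0.4548376 },
  { "estimator": "W_s_star", "population": "base",  "value": 0.4548376 }
],
"heritability": { "h2_W": 0.4527152, "h2_tilde_W": 0.4527152, "phenotypic_variance": 1.0 }
```

Reading the output: the unconditional expectation `V = 0.460` overstates the
genomic variance here — the realized LD contribution `L(y) = W − V =
−0.0073` is negative, and the best predictor `W = 0.4527` satisfies
`W + σ̂_ε² = 0.4527 + 0.5473 ≈ 1.000`, the scaled phenotypic variance, so
`h²_W` and `h̃²_W` coincide. In the base population the family structure
inflates the variance (`V* = 0.77`), while the GRM-based transform gives
back `σ̂_g²` (`Vs* ≈ Ws*` when the fitted model is internally consistent).

Other subcommands: `genovar fit` (REML components only) and `genovar bayes`
(Gibbs sampler, `--fix-vc` to pin the variance components; prints M2).

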