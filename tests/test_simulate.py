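import numpy as np
import pytest

import genovar as gv
from genovar.io import DataError
from genovar.simulate import ar1_adjacent_correlation

from conftest import make_dataset


def _mean_adjacent_corr(X):
    C = np.corrcoef(X.T)
    return float(np.diagonal(C, offset=1).mean())


def test_dosage_domain_and_reproducibility():
    g1 = gv.simulate_genotypes(2, 1, (0.5, 0.5), seed=1)
    assert set(np.unique(g1.values)) <= {0.0, 1.0, 2.0}
    g2 = gv.simulate_genotypes(50, 20, ld_model="ar1_haplotype", rho=0.5, seed=2)
    g3 = gv.simulate_genotypes(50, 20, ld_model="ar1_haplotype", rho=0.5, seed=2)
    np.testing.assert_array_equal(g2.values, g3.values)
    assert set(np.unique(g2.values)) <= {0.0, 1.0, 2.0}


def test_invalid_parameters():
    with pytest.raises(DataError):
        gv.simulate_genotypes(1, 5)
    with pytest.raises(DataError):
        gv.simulate_genotypes(10, 5, rho=1.0)
    with pytest.raises(DataError):
        gv.simulate_genotypes(10, 5, maf_range=(0.0, 0.5))
    with pytest.raises(DataError):
        gv.simulate_phenotypes(gv.simulate_genotypes(5, 2, seed=0), 0.1, 0.0)


def test_independent_markers_no_adjacent_correlation():
    g = gv.simulate_genotypes(1000, 2000, (0.1, 0.5), "independent", seed=3)
    r = _mean_adjacent_corr(g.values)
    # each pairwise correlation has SE ~ 1/sqrt(n); the mean over p-1 pairs
    # has SE ~ 1/sqrt(n (p-1))
    se = 1.0 / np.sqrt(1000 * 1999)
    assert abs(r) < 3 * se


def test_ar1_adjacent_correlation_matches_analytic_value():
    """Constant MAF: the haplotype chain's dosage correlation is exactly rho."""
    rho, n, p = 0.8, 1500, 400
    g = gv.simulate_genotypes(n, p, (0.3, 0.3), "ar1_haplotype", rho, seed=4)
    analytic = ar1_adjacent_correlation(np.full(p, 0.3), rho)
    np.testing.assert_allclose(analytic, rho)  # no clipping at constant MAF
    r = _mean_adjacent_corr(g.values)
    # SE of a single correlation ~ (1-rho^2)/sqrt(n); adjacent pairs are
    # positively dependent along the chain, so keep the single-pair SE
    se = (1 - rho**2) / np.sqrt(n)
    assert abs(r - rho) < 3 * se


def test_ar1_marginal_frequencies_preserved():
    g = gv.simulate_genotypes(4000, 50, (0.2, 0.2), "ar1_haplotype", 0.7, seed=5)
    freqs = g.values.mean(axis=0) / 2
    se = np.sqrt(0.2 * 0.8 / (2 * 4000))
    assert np.all(np.abs(freqs - 0.2) < 4 * se)


def test_zero_effect_variance():
    X = gv.simulate_genotypes(30, 10, seed=6)
    ds = gv.simulate_phenotypes(X, 0.0, 0.3, mu=2.0, seed=7)
    assert ds.realized_sg2 == 0.0
    assert np.all(ds.true_beta == 0.0)
    assert np.var(ds.phenotypes.values) > 0  # y - mu*1 is pure noise


def test_realized_sg2_consistency_and_seed_determinism():
    X = gv.simulate_genotypes(40, 15, seed=8)
    d1 = gv.simulate_phenotypes(X, 0.01, 0.5, mu=1.0, seed=9)
    d2 = gv.simulate_phenotypes(X, 0.01, 0.5, mu=1.0, seed=9)
    np.testing.assert_array_equal(d1.phenotypes.values, d2.phenotypes.values)
    centered = X.values - X.values.mean(axis=0)
    S = centered.T @ centered / (X.n - 1)
    assert d1.realized_sg2 == pytest.approx(float(d1.true_beta @ S @ d1.true_beta),
                                            rel=1e-12)


def test_mean_realized_sg2_matches_expectation():
    """E[s_g^2] = sigma_b^2 tr(SigmaHat_X) over replicated effect draws."""
    X = gv.simulate_genotypes(50, 30, seed=10)
    centered = X.values - X.values.mean(axis=0)
    tr = float(np.sum(centered**2)) / (X.n - 1)
    sigma_b2 = 0.02
    vals = np.array([
        gv.simulate_phenotypes(X, sigma_b2, 0.5, seed=100 + r).realized_sg2
        for r in range(1000)
    ])
    expected = sigma_b2 * tr
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean() - expected) < 3 * se


def test_make_relationship():
    assert np.array_equal(gv.make_relationship("identity", 4).values, np.eye(4))
    R = gv.make_relationship("block_family", 4, block_size=2, relatedness=0.5)
    np.testing.assert_allclose(R.values[:2, :2], [[1.0, 0.5], [0.5, 1.0]])
    assert R.values[0, 2] == 0.0
    for bs, rel in [(3, 0.9), (5, 0.1), (4, -0.2)]:
        Rr = gv.make_relationship("block_family", 20, block_size=bs, relatedness=rel)
        assert np.linalg.eigvalsh(Rr.values).min() > -1e-10
    with pytest.raises(DataError, match="PSD range"):
        gv.make_relationship("block_family", 10, block_size=5, relatedness=-0.5)


def test_strong_ld_inflates_ld_contribution():
    """|L(y)| is larger on average under strong adjacent LD than under
    independent markers at matched n, p and variance components."""
    n, p, reps = 120, 60, 25
    mags = {}
    for model, rho in [("independent", 0.0), ("ar1_haplotype", 0.9)]:
        vals = []
        for r in range(reps):
            ds = make_dataset(n=n, p=p, seed=900 + r, ld_model=model, rho=rho,
                              maf_range=(0.3, 0.3))
            b = gv.build_grm(ds.genotypes)
            fit = gv.fit_gblup(ds.phenotypes, b)
            vals.append(abs(gv.estimate(fit, b, "W").ld_component))
        mags[model] = np.mean(vals)
    assert mags["ar1_haplotype"] > mags["independent"]


def test_write_dataset_round_trip(tmp_path):
    R = gv.make_relationship("block_family", 12, block_size=3, relatedness=0.4)
    ds = make_dataset(n=12, p=6, seed=12, relationship=R)
    from genovar.simulate import write_dataset
    paths = write_dataset(ds, tmp_path)
    g = gv.read_genotypes(paths["genotypes"], "tsv")
    y = gv.read_phenotypes(paths["phenotypes"])
    r = gv.read_relationship(paths["relationship"])
    np.testing.assert_array_equal(g.values, ds.genotypes.values)
    np.testing.assert_allclose(y.values, ds.phenotypes.values, atol=1e-12)
    np.testing.assert_allclose(r.values, R.values, atol=1e-12)
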