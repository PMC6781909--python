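import numpy as np
import pytest

import genovar as gv


def make_dataset(n, p, seed, h2=0.5, ld_model="independent", rho=0.0,
                 maf_range=(0.1, 0.5), mu=1.0, relationship=None):
    """REM dataset with marker variance set so that E[s_g^2] = h2 (residual 1-h2)."""
    X = gv.simulate_genotypes(n, p, maf_range, ld_model, rho, seed)
    centered = X.values - X.values.mean(axis=0)
    tr_sigma = float(np.sum(centered**2)) / (n - 1)
    sigma_b2 = h2 / tr_sigma
    return gv.simulate_phenotypes(X, sigma_b2, 1.0 - h2, mu=mu, seed=seed + 1,
                                  relationship=relationship)


@pytest.fixture(scope="session")
def rem_fit():
    """A medium REM dataset with its GRM bundle and converged REML fit."""
    ds = make_dataset(n=120, p=60, seed=11)
    bundle = gv.build_grm(ds.genotypes)
    fit = gv.fit_gblup(ds.phenotypes, bundle)
    return ds, bundle, fit


@pytest.fixture(scope="session")
def small_fit():
    """A 30 x 10 dataset, small enough for dense brute-force oracles."""
    ds = make_dataset(n=30, p=10, seed=7)
    bundle = gv.build_grm(ds.genotypes)
    fit = gv.fit_gblup(ds.phenotypes, bundle)
    return ds, bundle, fit
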