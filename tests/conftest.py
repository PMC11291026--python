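import numpy as np
import pandas as pd
import pytest

import diurnalgwas as dg

SCAN_COVARIATES = ["sex", "age", "centre", "array"] + [f"PC{i}" for i in range(1, 11)]


@pytest.fixture
def rng():
    # fresh deterministic generator per test: results never depend on which
    # other tests ran before
    return np.random.default_rng(20240722)


@pytest.fixture(scope="session")
def mtnr1b_cohort():
    """One mtnr1b-like cohort at n=30k with adjusted phenotype columns."""
    cfg = dg.scenario("mtnr1b_like", n_samples=30_000, seed=7)
    geno, samples = dg.simulate_cohort(cfg)
    adj = dg.PhenotypeAdjuster(
        covariates=[
            dg.CovariateSpec("sex"),
            dg.CovariateSpec("age", kind="continuous"),
        ]
    )
    samples = adj.fit_transform(samples)
    return cfg, geno, samples


@pytest.fixture(scope="session")
def null_cohort():
    cfg = dg.scenario("null", n_samples=8_000, seed=11)
    geno, samples = dg.simulate_cohort(cfg)
    samples["log_glucose"] = np.log(samples["glucose_raw"])
    samples["glucose_int"] = dg.inverse_normal_transform(samples["log_glucose"])
    samples["glucose_adj"] = samples["log_glucose"] - samples["log_glucose"].mean()
    return cfg, geno, samples


@pytest.fixture
def small_design(rng):
    n, k = 50, 4
    X = pd.DataFrame(
        rng.standard_normal((n, k)), columns=[f"x{i}" for i in range(k)]
    )
    X.insert(0, "const", 1.0)
    beta = np.array([1.0, 0.5, -0.25, 0.0, 2.0])
    y = X.to_numpy() @ beta + rng.normal(0, 0.3, n)
    return y, X


def normal_equations_ols(y, X):
    """Independent brute-force oracle: solve X'X b = X'y directly."""
    A = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    b = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ b
    sigma2 = resid @ resid / (A.shape[0] - A.shape[1])
    cov = sigma2 * np.linalg.inv(A.T @ A)
    return b, np.sqrt(np.diag(cov))
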