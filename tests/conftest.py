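import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from setmean import DesignSpec, build_design, standardize_columns

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_dataset(rng, n=60, m=5, n_nuisance=3, r_focal=0.74, beta=0.0,
                 gene_corr=0.0, focal_names=("hed", "eud")):
    """Small study-shaped dataset: correlated focal pair, nuisance block,
    optionally correlated genes and an injected effect of the last focal."""
    cols = {f"x{k}": rng.normal(size=n) for k in range(n_nuisance)}
    z1 = rng.normal(size=n)
    z2 = r_focal * z1 + np.sqrt(1 - r_focal**2) * rng.normal(size=n)
    cols[focal_names[0]], cols[focal_names[1]] = z1, z2
    cov = pd.DataFrame(cols)
    if gene_corr > 0:
        S = np.full((m, m), gene_corr)
        np.fill_diagonal(S, 1.0)
        Y = rng.standard_normal((n, m)) @ np.linalg.cholesky(S).T
    else:
        Y = rng.standard_normal((n, m))
    if beta:
        Y = Y + beta * z2[:, None]
    design = build_design(cov, list(focal_names))
    return standardize_columns(Y), design


@pytest.fixture
def toy(rng):
    return make_dataset(rng)


def simple_design(z, nuisance=None):
    """Design with intercept (+ optional nuisance columns) and one focal z."""
    n = len(z)
    X = np.ones((n, 1)) if nuisance is None else np.hstack(
        [np.ones((n, 1)), np.atleast_2d(nuisance.T).T])
    x_names = ["intercept"] + [f"x{k}" for k in range(X.shape[1] - 1)]
    return DesignSpec(X=X, Z=standardize_columns(np.asarray(z, float)[:, None]),
                      x_names=x_names, z_names=["z"])
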