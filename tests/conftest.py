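import numpy as np
import pytest

import phyloacoustics as pa


@pytest.fixture
def three_taxon_tree() -> pa.Phylogeny:
    """((A:1,B:1):1,C:2); — depths all 2, shared path A-B of length 1."""
    return pa.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_pd_covariance(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric positive-definite matrix for GLS oracle checks."""
    A = rng.standard_normal((n, n))
    return A @ A.T + n * np.eye(n)


def whitening_ols_oracle(y, X, C):
    """Independent GLS reference: Cholesky-whiten, then ordinary least squares.

    With C = L L', the transformed model L^-1 y = L^-1 X b + u has iid
    errors, so OLS on the whitened data gives the GLS estimates. Returns
    (beta, se, sigma2_ml, loglik) computed entirely from the whitened OLS,
    with SEs using the unbiased (n - p) residual variance.
    """
    from scipy.linalg import cholesky, solve_triangular

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    L = cholesky(C, lower=True)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, rss, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    se = np.sqrt(rss / (n - p) * np.diag(np.linalg.inv(Xw.T @ Xw)))
    return beta, se, sigma2_ml, loglik
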