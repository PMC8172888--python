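"""Phylogenetic generalized least squares with maximum-likelihood Pagel's lambda.

The model: y = X b + e with e ~ N(0, sigma2 * C(lambda)), where C(lambda)
is the Brownian-motion covariance of the phylogeny with its off-diagonal
(shared-history) entries multiplied by lambda. For fixed lambda the GLS
estimates are closed-form; lambda itself is estimated by maximizing the
profile log-likelihood over [0, 1]. Phylogenetic signal of a single trait
is the same machinery with an intercept-only design.

Estimation is full ML (not REML): AIC-based averaging across alternative
phylogenies needs a likelihood that is comparable across fits, and the ML
log-likelihood is. The AIC parameter count is the number of regression
coefficients plus two (sigma2 and lambda).

Standard errors use the unbiased residual-variance denominator (n - p), the
convention of mainstream GLS software; pass ``se_mode="ml"`` for the plain
ML variance. Per-coefficient P values are two-tailed from a t distribution
with n - p degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .trees import Phylogeny, PhyloCovariance, lambda_transform

__all__ = [
    "PGLSError",
    "GLSResult",
    "PGLSFit",
    "SignalEstimate",
    "gls_fit",
    "fit_lambda",
    "phylogenetic_signal",
    "standardize_coefficient",
]

#: lambda grid step for the coarse profile scan
GRID_STEP = 0.01
#: profile log-likelihood range below which the profile is declared flat
FLAT_TOL = 1e-8


class PGLSError(ValueError):
    """Degenerate or ill-conditioned PGLS problem."""


@dataclass
class GLSResult:
    """Fixed-covariance GLS solution."""

    beta: np.ndarray
    se: np.ndarray
    sigma2_ml: float
    loglik: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    rank: int


@dataclass
class PGLSFit:
    """A lambda-optimized PGLS fit on one tree.

    ``residuals`` are on the response scale (y - X beta). ``beta_st`` holds
    slope estimates standardized by sd(predictor)/sd(response) when the
    caller supplied trait standard deviations (NaN for the intercept).
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lam: float
    sigma2: float
    loglik: float
    aic: float
    n: int
    species: tuple[str, ...]
    residuals: np.ndarray
    fitted: np.ndarray
    beta_st: np.ndarray | None = None
    se_st: np.ndarray | None = None
    profile: np.ndarray | None = field(default=None, repr=False)
    flags: tuple[str, ...] = ()

    @property
    def n_coef(self) -> int:
        return len(self.terms)

    def attach_standardized(self, sd_x: dict[str, float], sd_y: float) -> "PGLSFit":
        """Fill ``beta_st``/``se_st`` from predictor and response SDs."""
        bst = np.full(self.n_coef, np.nan)
        sst = np.full(self.n_coef, np.nan)
        for i, term in enumerate(self.terms):
            if term in sd_x:
                bst[i] = standardize_coefficient(self.beta[i], sd_x[term], sd_y)
                sst[i] = standardize_coefficient(self.se[i], sd_x[term], sd_y)
        self.beta_st = bst
        self.se_st = sst
        return self


@dataclass
class SignalEstimate:
    """Pagel's-lambda phylogenetic signal of a single trait."""

    trait: str
    lam: float
    loglik: float
    n: int
    profile: np.ndarray | None = None
    flags: tuple[str, ...] = ()


def _as_matrix(C) -> np.ndarray:
    return C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)


def _check_design(y: np.ndarray, X: np.ndarray) -> None:
    if y.ndim != 1:
        raise PGLSError("response must be a vector")
    if X.shape[0] != y.shape[0]:
        raise PGLSError("design and response row counts differ")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise PGLSError("non-finite values in model variables")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PGLSError("design matrix is rank deficient")


def gls_fit(y, X, C, se_mode: str = "unbiased") -> GLSResult:
    """Generalized least squares under a fixed covariance.

    Solves beta = (X' C^-1 X)^-1 X' C^-1 y via a Cholesky factorization of
    C; sigma2 is profiled out (ML: e' C^-1 e / n) and the log-likelihood is

        -1/2 [ n log(2 pi sigma2_ml) + log|C| + n ].

    Standard errors scale the (X' C^-1 X)^-1 diagonal by the residual
    variance with denominator n - p (``se_mode="unbiased"``, default) or n
    (``se_mode="ml"``).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and y.shape[0] != 1:
        X = X.T
    _check_design(y, X)
    M = _as_matrix(C)
    n, p = X.shape
    try:
        cf = cho_factor(M, lower=True)
    except np.linalg.LinAlgError as exc:
        raise PGLSError(
            f"covariance not positive definite (cond={np.linalg.cond(M):.3g})"
        ) from exc
    Ci_y = cho_solve(cf, y)
    Ci_X = cho_solve(cf, X)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    fitted = X @ beta
    e = y - fitted
    quad = float(e @ cho_solve(cf, e))
    sigma2_ml = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if sigma2_ml <= 0:
        raise PGLSError("zero residual variance: response is degenerate")
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet + n)
    denom = n - p if se_mode == "unbiased" else n
    if denom <= 0:
        raise PGLSError("not enough observations for the requested SEs")
    s2 = quad / denom
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtCiX)))
    return GLSResult(beta, se, sigma2_ml, loglik, e, fitted, n, p)


def _profile_funcs(y, X, C: PhyloCovariance):
    """Return a loglik(lambda) evaluator for the profile scan.

    Uses the diagonally normalized spectral factorization of the covariance
    (see :meth:`PhyloCovariance.lambda_decomposition`): after one rotation,
    every lambda evaluation is a diagonal-weighted least squares at O(n p^2)
    cost instead of a fresh O(n^3) factorization.
    """
    n = y.shape[0]
    d, w, Q = C.lambda_decomposition()
    root = 1.0 / np.sqrt(d)
    yt = Q.T @ (y * root)
    Xt = Q.T @ (X * root[:, None])
    logdet_d = float(np.log(d).sum())

    def loglik(lam: float) -> float:
        s = lam * w + (1.0 - lam)
        if s.min() <= 0:
            return -np.inf
        wt = 1.0 / s
        Xw = Xt * wt[:, None]
        try:
            beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
        except np.linalg.LinAlgError:
            return -np.inf
        e = yt - Xt @ beta
        quad = float(e @ (e * wt))
        if quad <= 0:
            return -np.inf
        logdet = logdet_d + float(np.log(s).sum())
        return -0.5 * (n * np.log(2.0 * np.pi * quad / n) + logdet + n)

    return loglik


def fit_lambda(
    y,
    X=None,
    tree=None,
    *,
    terms: tuple[str, ...] | None = None,
    species: tuple[str, ...] | None = None,
    se_mode: str = "unbiased",
    grid_step: float = GRID_STEP,
    store_profile: bool = False,
) -> PGLSFit:
    """ML-PGLS with Pagel's lambda estimated on [0, 1].

    ``tree`` may be a :class:`Phylogeny` or a :class:`PhyloCovariance`
    already aligned with the rows of ``y``/``X``. The profile
    log-likelihood is scanned on a coarse grid (default step 0.01) and the
    best point refined by bounded scalar minimization, which avoids local
    optima that a single local search can fall into.

    A flat profile (e.g. a star phylogeny, where lambda has no effect)
    returns lambda = 0 with a ``"profile-flat"`` flag.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if X is None:
        X = np.ones((n, 1))
        terms = terms or ("intercept",)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _check_design(y, X)
    p = X.shape[1]
    if n < p + 2:
        raise PGLSError(f"need at least {p + 2} species to estimate {p} "
                        "coefficients plus sigma2 and lambda")

    if isinstance(tree, Phylogeny):
        C = tree.vcv()
        if species is not None:
            C = C.subset(species)
    elif isinstance(tree, PhyloCovariance):
        C = tree
        if species is not None and tuple(species) != C.taxa:
            C = C.subset(species)
    else:
        raise TypeError("tree must be a Phylogeny or PhyloCovariance")
    if C.n != n:
        raise PGLSError("covariance dimension does not match data rows")

    loglik = _profile_funcs(y, X, C)
    grid = np.arange(0.0, 1.0 + 1e-12, grid_step)
    if grid[-1] < 1.0:
        grid = np.append(grid, 1.0)
    vals = np.array([loglik(l) for l in grid])
    if not np.any(np.isfinite(vals)):
        raise PGLSError("likelihood undefined over the whole lambda grid")

    flags: list[str] = []
    finite = vals[np.isfinite(vals)]
    if finite.max() - finite.min() < FLAT_TOL:
        lam_hat = 0.0
        flags.append("profile-flat")
    else:
        i = int(np.nanargmax(np.where(np.isfinite(vals), vals, -np.inf)))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda l: -loglik(l), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
            lam_hat = float(res.x) if loglik(float(res.x)) >= vals[i] else float(grid[i])
        else:
            lam_hat = float(grid[i])

    fit0 = gls_fit(y, X, lambda_transform(C, lam_hat), se_mode=se_mode)
    tvals = fit0.beta / fit0.se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    k = p + 2  # coefficients + sigma2 + lambda
    aic = 2.0 * k - 2.0 * fit0.loglik
    if terms is None:
        terms = tuple(f"x{i}" for i in range(p))
    profile = np.column_stack([grid, vals]) if store_profile else None
    return PGLSFit(
        terms=tuple(terms),
        beta=fit0.beta,
        se=fit0.se,
        t=tvals,
        p=pvals,
        lam=lam_hat,
        sigma2=fit0.sigma2_ml,
        loglik=fit0.loglik,
        aic=aic,
        n=n,
        species=tuple(species) if species is not None else tuple(C.taxa),
        residuals=fit0.residuals,
        fitted=fit0.fitted,
        profile=profile,
        flags=tuple(flags),
    )


def phylogenetic_signal(
    trait, tree, *, name: str = "trait", store_profile: bool = False
) -> SignalEstimate:
    """Pagel's-lambda signal of one trait: intercept-only ML PGLS.

    ``trait`` is a mapping/Series of species -> value or an array already
    aligned with the covariance. Requires at least 4 species with finite
    values and non-zero variance.
    """
    if hasattr(trait, "index"):  # pandas Series
        species = tuple(sorted(trait.index[np.isfinite(trait.values)]))
        y = np.asarray(trait.loc[list(species)], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        species = None
    if y.shape[0] < 4:
        raise PGLSError("signal estimation needs >= 4 species")
    if np.ptp(y) == 0:
        raise PGLSError(f"trait {name!r} is constant; signal undefined")
    fit = fit_lambda(
        y, None, tree, terms=("intercept",), species=species,
        store_profile=store_profile,
    )
    return SignalEstimate(
        trait=name, lam=fit.lam, loglik=fit.loglik, n=fit.n,
        profile=fit.profile, flags=fit.flags,
    )


def standardize_coefficient(beta: float, sd_x: float, sd_y: float) -> float:
    """Standardized slope beta_st = beta * sd(x) / sd(y).

    Makes slopes unit-free and comparable across responses; standard errors
    standardize with the same factor.
    """
    if sd_y <= 0:
        raise PGLSError("response standard deviation must be positive")
    return beta * sd_x / sd_y
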