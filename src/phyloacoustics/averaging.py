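"""AIC-weighted averaging of PGLS fits across a sample of phylogenies.

Phylogenies are rarely known without error; comparative studies therefore
run the same model on a sample of plausible trees (e.g. a posterior sample)
and average the per-tree outputs. The weight of tree i is the Akaike weight

    w_i = exp(-(AIC_i - AIC_min)/2) / sum_j exp(-(AIC_j - AIC_min)/2),

so trees whose model fits the data better contribute more. Coefficients,
standard errors, standardized slopes, lambda, and per-species residuals are
all averaged with the same weights.

Standard errors are averaged as plain weighted means of the per-tree SEs;
no between-tree variance term is added by default. Pass
``se_mode="unconditional"`` for the model-averaging variance that inflates
the SE by the between-tree spread of the coefficient estimates.
P values are recomputed from the averaged beta and SE on a t reference with
the (mean) per-tree residual degrees of freedom, not averaged directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pgls import PGLSFit

__all__ = ["AveragedFit", "aic_weights", "average_fits"]


class AveragingError(ValueError):
    pass


@dataclass
class AveragedFit:
    """AIC-weight-averaged PGLS quantities across a tree sample."""

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lam: float
    n: int
    species: tuple[str, ...]
    residuals: np.ndarray
    weights: np.ndarray
    n_trees: int
    beta_st: np.ndarray | None = None
    se_st: np.ndarray | None = None
    aics: np.ndarray | None = None

    @property
    def n_coef(self) -> int:
        return len(self.terms)


def aic_weights(aics) -> np.ndarray:
    """Akaike weights of a set of AIC values (shift-invariant, sum to 1)."""
    a = np.asarray(aics, dtype=float)
    if a.size == 0:
        raise AveragingError("empty AIC list")
    if not np.all(np.isfinite(a)):
        raise AveragingError("non-finite AIC values")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def average_fits(fits: list[PGLSFit], se_mode: str = "plain") -> AveragedFit:
    """Average per-tree PGLS fits with Akaike weights from their AICs.

    All fits must share the same model terms and species set (they are the
    same model on alternative trees). Every averaged field is the weighted
    mean of the per-tree values; residuals are averaged per species.
    """
    if not fits:
        raise AveragingError("no fits to average")
    terms = fits[0].terms
    species = fits[0].species
    for f in fits[1:]:
        if f.terms != terms:
            raise AveragingError("fits have mismatched model terms")
        if f.species != species:
            raise AveragingError("fits have mismatched species sets")

    aics = np.array([f.aic for f in fits])
    w = aic_weights(aics)
    beta = w @ np.array([f.beta for f in fits])
    se_each = np.array([f.se for f in fits])
    se = w @ se_each
    if se_mode == "unconditional":
        # model-averaging variance: weighted mean of (se^2 + (b - b_avg)^2)
        betas = np.array([f.beta for f in fits])
        se = np.sqrt(w @ (se_each**2 + (betas - beta) ** 2))
    elif se_mode != "plain":
        raise AveragingError(f"unknown se_mode {se_mode!r}")
    lam = float(w @ np.array([f.lam for f in fits]))
    resid = w @ np.array([f.residuals for f in fits])
    n = int(round(float(np.mean([f.n for f in fits]))))

    tvals = beta / se
    df = max(n - len(terms), 1)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df)

    beta_st = se_st = None
    if all(f.beta_st is not None for f in fits):
        beta_st = w @ np.array([f.beta_st for f in fits])
        se_st = w @ np.array([f.se_st for f in fits])

    return AveragedFit(
        terms=terms, beta=beta, se=se, t=tvals, p=pvals, lam=lam, n=n,
        species=species, residuals=resid, weights=w, n_trees=len(fits),
        beta_st=beta_st, se_st=se_st, aics=aics,
    )
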