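"""Bespoke comparative hypothesis tests.

Three tests used when comparing acoustic allometries across vocalization
classes:

* :func:`compare_slopes` — do two standardized regression slopes differ?
  Large-sample Z test on the difference over the pooled standard error.
* :func:`abs_residual_regression` — does a predictor explain the magnitude
  of deviations from an allometric expectation? PGLS of |averaged residual|
  on the predictor, averaged over a tree sample.
* :func:`repeatability` — one-way-ANOVA intraclass correlation quantifying
  the consistency of repeated within-species measurements, with the
  unbalanced-design correction for the effective group size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .averaging import AveragedFit, average_fits
from .pgls import PGLSError, fit_lambda
from .trees import Phylogeny, PhyloCovariance

__all__ = [
    "SlopeComparison",
    "RepeatabilityResult",
    "compare_slopes",
    "abs_residual_regression",
    "repeatability",
]


@dataclass
class SlopeComparison:
    """Difference between two standardized slopes with its test."""

    diff: float
    se: float
    z: float
    p: float
    method: str = "z"


def compare_slopes(
    b1: float, se1: float, b2: float, se2: float,
    method: str = "z", n1: int | None = None, n2: int | None = None,
) -> SlopeComparison:
    """Test whether two independently estimated slopes differ.

    Z = (b1 - b2) / sqrt(se1^2 + se2^2), referred to the standard normal
    (two-tailed). With several hundred species per regression the normal
    reference is effectively exact; ``method="welch"`` instead uses a t
    reference with Welch-Satterthwaite degrees of freedom computed from the
    per-slope sample sizes.
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    pooled = float(np.hypot(se1, se2))
    if pooled == 0:
        raise ValueError("both standard errors are zero")
    z = (b1 - b2) / pooled
    if method == "z":
        p = 2.0 * stats.norm.sf(abs(z))
    elif method == "welch":
        if n1 is None or n2 is None:
            raise ValueError("welch method needs n1 and n2")
        df = (se1**2 + se2**2) ** 2 / (
            se1**4 / max(n1 - 2, 1) + se2**4 / max(n2 - 2, 1)
        )
        p = 2.0 * stats.t.sf(abs(z), df=df)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SlopeComparison(diff=float(b1 - b2), se=pooled, z=float(z),
                           p=float(p), method=method)


def abs_residual_regression(
    avg_fit: AveragedFit,
    predictor: pd.Series,
    trees: Sequence[Phylogeny | PhyloCovariance],
    *,
    predictor_name: str = "predictor",
) -> AveragedFit:
    """PGLS of |weight-averaged residual| on a predictor, over a tree sample.

    The residuals are first weight-averaged across trees (by the upstream
    fit), then their absolute value is taken — in that order, since the two
    do not commute — and the absolute residuals are regressed on the
    predictor on every tree, with lambda re-estimated, and the fits AIC
    weight-averaged. A positive slope means species with larger predictor
    values deviate more (in either direction) from the allometric
    expectation.
    """
    species = avg_fit.species
    missing = [s for s in species if s not in predictor.index]
    if missing:
        raise PGLSError(f"predictor missing species: {missing[:5]}")
    x = np.asarray(predictor.loc[list(species)], dtype=float)
    if not np.all(np.isfinite(x)):
        raise PGLSError("non-finite predictor values")
    y = np.abs(avg_fit.residuals)
    X = np.column_stack([np.ones_like(x), x])
    terms = ("intercept", predictor_name)
    if np.ptp(y) == 0:
        # constant response: the slope is exactly 0 and the likelihood is
        # degenerate, so report the flat fit rather than failing
        k = len(trees)
        return AveragedFit(
            terms=terms, beta=np.array([float(y[0]), 0.0]),
            se=np.full(2, np.nan), t=np.full(2, np.nan),
            p=np.full(2, np.nan), lam=0.0, n=len(species), species=species,
            residuals=np.zeros(len(species)), weights=np.full(k, 1.0 / k),
            n_trees=k, beta_st=np.array([np.nan, 0.0]),
            se_st=np.full(2, np.nan),
        )
    sd_x = {predictor_name: float(np.std(x, ddof=1))}
    sd_y = float(np.std(y, ddof=1))
    fits = []
    for tr in trees:
        C = tr.vcv() if isinstance(tr, Phylogeny) else tr
        C = C.subset(species) if C.taxa != species else C
        fit = fit_lambda(y, X, C, terms=terms, species=species)
        fit.attach_standardized(sd_x, sd_y)
        fits.append(fit)
    return average_fits(fits)


@dataclass
class RepeatabilityResult:
    """One-way-ANOVA intraclass correlation (repeatability R)."""

    r: float
    ms_among: float
    ms_within: float
    n_groups: int
    n_total: int
    n0: float
    flags: tuple[str, ...] = ()


def repeatability(measurements) -> RepeatabilityResult:
    """Within-group repeatability from a one-way ANOVA.

    ``measurements`` is a mapping of group id -> sequence of values, or a
    long-format DataFrame with ``species`` and ``value`` columns. With a
    groups of sizes n_i (N total), the effective group size is

        n0 = (N - sum(n_i^2)/N) / (a - 1),

    the among-group variance component is s2_A = (MS_A - MS_W)/n0, and

        R = s2_A / (s2_A + MS_W).

    Groups with a single measurement are retained (they contribute to the
    among-group sums of squares). Sampling noise can push R below zero when
    there is no real among-group variance; such values are returned as
    computed, with a ``"negative"`` flag, rather than truncated at 0.
    """
    if isinstance(measurements, pd.DataFrame):
        groups = {
            k: np.asarray(g["value"], dtype=float)
            for k, g in measurements.groupby("species")
        }
    elif isinstance(measurements, Mapping):
        groups = {k: np.asarray(v, dtype=float) for k, v in measurements.items()}
    else:
        raise TypeError("measurements must be a mapping or DataFrame")
    groups = {k: v for k, v in groups.items() if v.size > 0}
    a = len(groups)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([v.size for v in groups.values()], dtype=float)
    N = sizes.sum()
    if N - a <= 0:
        raise ValueError("all groups are singletons; within-group MS undefined")

    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    means = np.array([v.mean() for v in groups.values()])
    ss_among = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - v.mean()) ** 2) for v in groups.values()))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - np.sum(sizes**2) / N) / (a - 1)
    s2_a = (ms_among - ms_within) / n0

    flags: list[str] = []
    denom = s2_a + ms_within
    if denom == 0:
        r = 1.0  # all values identical within and across groups collapse here
        flags.append("degenerate")
    else:
        r = s2_a / denom
    if r < 0:
        flags.append("negative")
    return RepeatabilityResult(
        r=float(r), ms_among=ms_among, ms_within=ms_within,
        n_groups=a, n_total=int(N), n0=float(n0), flags=tuple(flags),
    )
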