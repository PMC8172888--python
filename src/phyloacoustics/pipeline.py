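"""End-to-end analysis orchestration: signal -> per-tree PGLS -> averaging -> tests.

The functions here wire the statistical modules together over a trait table
and a sample of trees, handling species/tree matching, variable transforms,
standardization, and serialization. They are the programmatic counterpart
of the command-line interface and what the examples call.

Conventions:

* Species names are matched by exact string after whitespace->underscore
  normalization; any species present in only one of trait table / trees is
  reported, never silently dropped.
* Body mass and song duration enter models as log10; peak frequency is
  untransformed by default (its empirical distribution is already roughly
  bell-shaped) with an optional log10 switch.
* Missing values are handled per model: each model uses every species with
  complete data for its own variables, so song models typically run on more
  species than call models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .averaging import AveragedFit, average_fits
from .comparative import SlopeComparison, abs_residual_regression, compare_slopes
from .pgls import PGLSError, PGLSFit, fit_lambda
from .trees import Phylogeny, PhyloCovariance

logger = logging.getLogger("phyloacoustics")

__all__ = [
    "AnalysisConfig",
    "load_traits",
    "normalize_name",
    "run_signal",
    "fit_model_over_trees",
    "run_allometry",
    "run_duration_models",
    "write_fit",
]

DEFAULT_COLUMNS = {
    "species": "species",
    "song_peak_freq": "song_peak_freq",
    "call_peak_freq": "call_peak_freq",
    "song_duration": "song_duration",
    "body_mass": "body_mass",
    "forest_prop": "forest_prop",
}

#: transform applied to each model variable (identity unless listed)
DEFAULT_TRANSFORMS = {"body_mass": "log10", "song_duration": "log10"}


@dataclass
class AnalysisConfig:
    """Run-level options shared by the pipeline entry points."""

    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    log10_frequency: bool = False
    n_trees: int | None = None
    se_averaging: str = "plain"  # or "unconditional"
    verbose: bool = False


def normalize_name(name: str) -> str:
    """Canonical species name: stripped, internal whitespace -> underscore."""
    return "_".join(str(name).split())


def load_traits(path, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Read a CSV/TSV trait table, rename to canonical columns, index by species."""
    cfg = config or AnalysisConfig()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    rename = {v: k for k, v in cfg.columns.items() if v in df.columns}
    df = df.rename(columns=rename)
    if "species" not in df.columns:
        raise ValueError("trait table lacks a species column")
    df["species"] = df["species"].map(normalize_name)
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dups[:5]}")
    return df.set_index("species")


def _indexed(traits: pd.DataFrame) -> pd.DataFrame:
    """Accept species either as a column or as the index."""
    if "species" in traits.columns:
        traits = traits.set_index("species")
    return traits.set_axis([normalize_name(s) for s in traits.index])


def _transform(values: pd.Series, how: str) -> pd.Series:
    if how == "identity":
        return values
    if how == "log10":
        if (values <= 0).any():
            raise ValueError(f"log10 transform of non-positive {values.name!r}")
        return np.log10(values)
    raise ValueError(f"unknown transform {how!r}")


def _model_frame(traits: pd.DataFrame, variables: list[str],
                 cfg: AnalysisConfig) -> pd.DataFrame:
    """Transformed, row-complete model frame for the given variables."""
    traits = _indexed(traits)
    cols = {}
    for var in variables:
        if var not in traits.columns:
            raise ValueError(f"trait table lacks column {var!r}")
        how = cfg.transforms.get(var, "identity")
        if var.endswith("peak_freq") and cfg.log10_frequency:
            how = "log10"
        cols[var] = _transform(traits[var], how)
    frame = pd.DataFrame(cols).dropna()
    return frame


def _match_species(frame: pd.DataFrame, trees: list[Phylogeny]) -> list[str]:
    tips = set(trees[0].taxa)
    species = [normalize_name(s) for s in frame.index]
    common = sorted(set(species) & tips)
    only_data = sorted(set(species) - tips)
    only_tree = sorted(tips - set(species))
    if only_data:
        logger.warning("%d species in traits but not trees (e.g. %s)",
                       len(only_data), only_data[:3])
    if only_tree:
        logger.info("%d tree tips without trait rows for this model",
                    len(only_tree))
    if len(common) < 4:
        raise PGLSError("fewer than 4 species shared between traits and trees")
    logger.info("model uses %d species", len(common))
    return common


def _covariances(trees: list[Phylogeny], species: list[str],
                 cache: dict | None = None) -> list[PhyloCovariance]:
    """Per-tree covariances restricted to ``species``, with caching.

    The full-tree covariance is computed once per tree and reused across
    models; eigendecompositions are cached on the objects themselves, so a
    species set shared by several models pays for its decomposition once.
    """
    key = tuple(species)
    out = []
    for i, tree in enumerate(trees):
        if cache is not None:
            full = cache.setdefault(("full", i), tree.vcv())
            if key == full.taxa:
                out.append(full)
            else:
                out.append(cache.setdefault((key, i), full.subset(species)))
        else:
            full = tree.vcv()
            out.append(full if tuple(full.taxa) == key else full.subset(species))
    return out


def run_signal(
    traits: pd.DataFrame,
    trees: list[Phylogeny],
    trait_names: list[str] | None = None,
    config: AnalysisConfig | None = None,
    cache: dict | None = None,
) -> pd.DataFrame:
    """AIC-weight-averaged Pagel's-lambda signal per trait.

    For each trait, an intercept-only lambda-PGLS is fitted on every tree
    and the per-tree lambda estimates are averaged with Akaike weights.
    A degenerate trait (constant, too few species) yields an ``error`` entry
    for that row; the run continues for the remaining traits.
    """
    cfg = config or AnalysisConfig()
    trees = trees[: cfg.n_trees] if cfg.n_trees else trees
    names = trait_names or [c for c in traits.columns if c != "species"]
    rows = []
    for name in names:
        try:
            frame = _model_frame(traits, [name], cfg)
            if np.ptp(frame[name].values) == 0:
                raise PGLSError(f"trait {name!r} is constant")
            species = _match_species(frame, trees)
            y = frame.loc[species, name].values
            fits = [
                fit_lambda(y, None, C, terms=("intercept",),
                           species=tuple(species))
                for C in _covariances(trees, species, cache)
            ]
            avg = average_fits(fits, se_mode=cfg.se_averaging)
            rows.append({"trait": name, "lambda": avg.lam, "n": avg.n,
                         "n_trees": avg.n_trees, "error": ""})
        except (PGLSError, ValueError) as exc:
            logger.warning("signal for %r failed: %s", name, exc)
            rows.append({"trait": name, "lambda": np.nan, "n": 0,
                         "n_trees": 0, "error": str(exc)})
    return pd.DataFrame(rows).set_index("trait")


def fit_model_over_trees(
    traits: pd.DataFrame,
    trees: list[Phylogeny],
    response: str,
    predictors: list[str],
    config: AnalysisConfig | None = None,
    cache: dict | None = None,
) -> tuple[AveragedFit, list[PGLSFit]]:
    """Fit ``response ~ predictors`` (with intercept) on every tree; average.

    Returns the AIC-weight-averaged fit and the per-tree fits. Standardized
    slopes use the sample SDs of the transformed model variables, which are
    identical across trees, so averaging per-tree beta_st equals
    standardizing the averaged beta.
    """
    cfg = config or AnalysisConfig()
    trees = trees[: cfg.n_trees] if cfg.n_trees else trees
    frame = _model_frame(traits, [response] + predictors, cfg)
    species = _match_species(frame, trees)
    frame = frame.loc[species]
    y = frame[response].values
    X = np.column_stack([np.ones(len(species))] +
                        [frame[p].values for p in predictors])
    terms = ("intercept", *predictors)
    sd_x = {p: float(frame[p].std(ddof=1)) for p in predictors}
    sd_y = float(frame[response].std(ddof=1))
    fits = []
    for i, C in enumerate(_covariances(trees, species, cache)):
        fit = fit_lambda(y, X, C, terms=terms, species=tuple(species))
        fit.attach_standardized(sd_x, sd_y)
        if cfg.verbose:
            logger.info("tree %d: lambda=%.3f AIC=%.2f", i, fit.lam, fit.aic)
        fits.append(fit)
    return average_fits(fits, se_mode=cfg.se_averaging), fits


def run_allometry(
    traits: pd.DataFrame,
    trees: list[Phylogeny],
    config: AnalysisConfig | None = None,
    cache: dict | None = None,
) -> tuple[AveragedFit, AveragedFit, SlopeComparison]:
    """Frequency ~ log10(mass) + habitat for songs and calls, plus slope test.

    Fits the multiple PGLS separately per vocalization class (each on its
    own complete-case species set), averages over the tree sample, and
    compares the standardized body-mass slopes with the large-sample Z test
    on the averaged beta_st and SEs.
    """
    cfg = config or AnalysisConfig()
    song, _ = fit_model_over_trees(
        traits, trees, "song_peak_freq", ["body_mass", "forest_prop"], cfg, cache)
    call, _ = fit_model_over_trees(
        traits, trees, "call_peak_freq", ["body_mass", "forest_prop"], cfg, cache)
    i_song = song.terms.index("body_mass")
    i_call = call.terms.index("body_mass")
    comp = compare_slopes(
        song.beta_st[i_song], song.se_st[i_song],
        call.beta_st[i_call], call.se_st[i_call],
    )
    return song, call, comp


def run_duration_models(
    traits: pd.DataFrame,
    trees: list[Phylogeny],
    config: AnalysisConfig | None = None,
    cache: dict | None = None,
) -> dict:
    """Song-duration analyses: extended model, deviation test, collinearity.

    1. frequency ~ log10(mass) + habitat + log10(duration);
    2. |weight-averaged residual| of frequency ~ mass + habitat, regressed
       on log10(duration) over the tree sample — does duration predict the
       magnitude of deviations from the allometric expectation?
    3. pairwise PGLS slopes among the three predictors (collinearity check).
    """
    cfg = config or AnalysisConfig()
    with_duration, _ = fit_model_over_trees(
        traits, trees, "song_peak_freq",
        ["body_mass", "forest_prop", "song_duration"], cfg, cache)

    base, _ = fit_model_over_trees(
        traits, trees, "song_peak_freq", ["body_mass", "forest_prop"], cfg, cache)
    frame = _model_frame(
        traits, ["song_peak_freq", "body_mass", "forest_prop", "song_duration"],
        cfg)
    dur = frame["song_duration"]
    dur = dur[dur.index.isin(base.species)]
    trees_used = trees[: cfg.n_trees] if cfg.n_trees else trees
    covs = _covariances(trees_used, list(base.species), cache)
    abs_resid = abs_residual_regression(
        base, dur, covs, predictor_name="song_duration")

    pairs = [("song_duration", "body_mass"), ("song_duration", "forest_prop"),
             ("body_mass", "forest_prop")]
    rows = []
    for resp, pred in pairs:
        avg, _ = fit_model_over_trees(traits, trees, resp, [pred], cfg, cache)
        i = avg.terms.index(pred)
        rows.append({"response": resp, "predictor": pred,
                     "beta_st": avg.beta_st[i], "p": avg.p[i],
                     "lambda": avg.lam, "n": avg.n})
    collinearity = pd.DataFrame(rows)
    return {"with_duration": with_duration, "abs_residual": abs_resid,
            "collinearity": collinearity, "base": base}


# ---------------------------------------------------------------------------
# serialization

def _sig6(x: float) -> str:
    return f"{x:.6g}"


def write_fit(avg: AveragedFit, path_prefix: str) -> None:
    """Serialize an averaged fit: TSV (6 significant digits) + JSON sidecar."""
    rows = []
    for i, term in enumerate(avg.terms):
        rows.append({
            "term": term,
            "beta": _sig6(avg.beta[i]),
            "se": _sig6(avg.se[i]),
            "beta_st": _sig6(avg.beta_st[i]) if avg.beta_st is not None else "",
            "t": _sig6(avg.t[i]),
            "P": _sig6(avg.p[i]),
        })
    pd.DataFrame(rows).to_csv(f"{path_prefix}.tsv", sep="\t", index=False)
    sidecar = {
        "lambda": avg.lam,
        "n": avg.n,
        "n_trees": avg.n_trees,
        "terms": list(avg.terms),
        "beta": avg.beta.tolist(),
        "se": avg.se.tolist(),
        "beta_st": avg.beta_st.tolist() if avg.beta_st is not None else None,
        "p": avg.p.tolist(),
        "weights": avg.weights.tolist(),
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
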