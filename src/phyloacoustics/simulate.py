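"""Synthetic study generator: trees, tree samples, traits, and recordings.

Emulates the data structure of a large-scale comparative study of passerine
vocal allometry: a species-level trait table (peak song and call frequency,
song duration, body mass, proportion of foraging time in forest), a
pseudo-posterior sample of time-calibrated trees, and repeated noisy
per-species acoustic measurements.

Trait generation follows the generative model that lambda-PGLS assumes:
each trait is one draw from a multivariate normal whose covariance is
sigma2 times the lambda-rescaled Brownian covariance of the tree. Default
parameters plant the structure the analyses are designed to detect —
body mass with high phylogenetic signal (lambda 0.9), song duration with
moderate signal (0.45), a negative allometric slope of frequency on
log10 body mass that is steeper for songs than calls, and a habitat
covariate with no effect on frequency.

Phylogenetic uncertainty is emulated by lognormal branch-length jitter on a
fixed topology — enough structure for AIC weighting to act on, without the
topological variation of a real Bayesian posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .acoustics import Recording
from .trees import Phylogeny, lambda_transform

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_yule_tree",
    "jitter_tree_sample",
    "simulate_trait",
    "simulate_study",
    "make_tone_recording",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with study-scale defaults.

    Frequencies are in kHz, masses in grams, durations in seconds. The
    planted allometry acts on log10 body mass; ``slope_song``/``slope_call``
    are therefore kHz per decade of mass. ``habitat_effect`` defaults to 0:
    habitat has high phylogenetic signal but no causal effect on frequency.
    """

    n_tips: int = 591
    birth_rate: float = 1.0
    n_trees: int = 100
    tree_jitter_cv: float = 0.10
    # phylogenetic signal (Pagel's lambda) of each generated trait
    lambda_mass: float = 0.90
    lambda_duration: float = 0.45
    lambda_habitat: float = 0.75
    lambda_song_resid: float = 0.31
    lambda_call_resid: float = 0.65
    # trait scales
    log_mass_mean: float = 1.5      # log10 g: ~30 g typical passerine
    log_mass_sd: float = 0.5
    log_duration_mean: float = 0.5  # log10 s: ~3 s songs
    log_duration_sd: float = 0.3
    # allometry: freq = intercept + slope * log10(mass) + habitat_effect * habitat + resid
    intercept_song: float = 4.5     # kHz
    slope_song: float = -0.5        # kHz per log10 g
    intercept_call: float = 4.2
    slope_call: float = -0.35
    habitat_effect: float = 0.0
    resid_sd_song: float = 0.40     # kHz, phylogenetically structured residual
    resid_sd_call: float = 0.35
    # within-species measurement replicates
    recordings_per_species: int = 3
    measurement_sd: float = 0.15    # kHz, iid noise per recording
    duration_measurement_sd: float = 0.05  # log10 s, per recording
    call_fraction: float = 505 / 591  # share of species with call data
    seed: int = 0


@dataclass
class StudyData:
    """Everything the analysis pipeline consumes, plus the ground truth."""

    traits: pd.DataFrame
    trees: list[Phylogeny]
    base_tree: Phylogeny
    measurements: pd.DataFrame
    config: SimulationConfig
    latent: pd.DataFrame = field(default=None, repr=False)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None,
                       rescale: bool = True) -> Phylogeny:
    """Pure-birth (Yule) tree, rescaled to unit root-to-tip depth.

    Lineages split at rate ``birth_rate`` each; after the n-th tip appears
    the process runs for one further exponential waiting time so pendant
    edges are never zero. The returned tree is ultrametric with depth 1
    (``rescale=False`` keeps the raw depth, in units of 1/birth_rate) and
    tips are labelled ``sp0001 ...`` in birth order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    origin: dict[int, float] = {id(tree.seed_node): 0.0}
    active = [tree.seed_node]
    t = 0.0
    root_split = None
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        if node is tree.seed_node:
            root_split = t
        else:
            node.edge.length = t - origin[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            origin[id(child)] = t
            active.append(child)
    # run past the last split so pendant branches have positive length
    present = t + rng.exponential(1.0 / (n_tips * birth_rate))
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = present - origin[id(leaf)]
        leaf.taxon = tns.new_taxon(label=f"sp{i + 1:0{width}d}")
    depth = (present - root_split) if rescale else 1.0
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    tree.seed_node.edge.length = None
    return Phylogeny(tree)


def jitter_tree_sample(tree: Phylogeny, n_trees: int, cv: float, seed=None
                       ) -> list[Phylogeny]:
    """Pseudo-posterior of trees: lognormal branch-length noise, fixed topology.

    Each branch length is multiplied by an independent lognormal factor
    with mean 1 and coefficient of variation ``cv``; ``cv = 0`` returns
    identical copies.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = _rng(seed)
    if cv == 0:
        return [tree.copy() for _ in range(n_trees)]
    sigma2 = np.log1p(cv**2)
    mu = -0.5 * sigma2
    n_edges = sum(
        1 for nd in tree.dendropy_tree.preorder_node_iter()
        if nd.edge.length is not None
    )
    out = []
    for _ in range(n_trees):
        factors = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n_edges))
        out.append(tree.scale_branches(factors))
    return out


def simulate_trait(
    tree, lambda_true: float, sigma2: float = 1.0, root_mean: float = 0.0,
    seed=None,
) -> pd.Series:
    """One multivariate-normal draw under lambda-rescaled Brownian motion.

    Tip values ~ N(root_mean, sigma2 * C(lambda_true)) where C is the
    tree's Brownian covariance. At lambda 0 the tips are independent with
    variance sigma2 * depth; at lambda 1 this is standard Brownian motion.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = _rng(seed)
    C = tree.vcv() if isinstance(tree, Phylogeny) else tree
    M = lambda_transform(C, lambda_true).matrix * sigma2
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        # lambda < 1 keeps valid trees PD; guard tiny negative eigenvalues
        w, V = np.linalg.eigh(M)
        L = V * np.sqrt(np.clip(w, 0.0, None))
    x = root_mean + L @ rng.standard_normal(C.n)
    return pd.Series(x, index=list(C.taxa), name="trait")


def simulate_study(config: SimulationConfig | None = None, seed=None) -> StudyData:
    """End-to-end synthetic study: tree sample, trait table, measurements.

    The species value of each acoustic trait in the trait table is the mean
    of its noisy per-recording measurements (as in a real measurement
    pipeline); with ``measurement_sd = 0`` it equals the latent value. Mass
    and habitat carry no measurement error. A random subset of species
    (``1 - call_fraction``) lacks call data, so call models run on fewer
    species than song models.
    """
    cfg = config or SimulationConfig()
    rng = _rng(cfg.seed if seed is None else seed)

    base = simulate_yule_tree(cfg.n_tips, cfg.birth_rate, rng)
    trees = jitter_tree_sample(base, cfg.n_trees, cfg.tree_jitter_cv, rng)
    C = base.vcv()
    species = list(C.taxa)

    log_mass = simulate_trait(C, cfg.lambda_mass, cfg.log_mass_sd**2,
                              cfg.log_mass_mean, rng)
    log_dur = simulate_trait(C, cfg.lambda_duration, cfg.log_duration_sd**2,
                             cfg.log_duration_mean, rng)
    habitat_latent = simulate_trait(C, cfg.lambda_habitat, 1.0, 0.0, rng)
    habitat = 1.0 / (1.0 + np.exp(-1.5 * habitat_latent))  # squash to [0, 1]

    resid_song = simulate_trait(C, cfg.lambda_song_resid,
                                cfg.resid_sd_song**2, 0.0, rng)
    resid_call = simulate_trait(C, cfg.lambda_call_resid,
                                cfg.resid_sd_call**2, 0.0, rng)
    song_freq = (cfg.intercept_song + cfg.slope_song * log_mass
                 + cfg.habitat_effect * habitat + resid_song)
    call_freq = (cfg.intercept_call + cfg.slope_call * log_mass
                 + cfg.habitat_effect * habitat + resid_call)
    duration = 10.0**log_dur

    n_call = int(round(cfg.call_fraction * cfg.n_tips))
    call_species = set(rng.choice(species, size=n_call, replace=False)) \
        if n_call < cfg.n_tips else set(species)

    rows = []
    k = cfg.recordings_per_species
    for sp in species:
        for j in range(k):
            rows.append({
                "species": sp, "voc_class": "song", "recording": j + 1,
                "peak_freq": song_freq[sp] + rng.normal(0, cfg.measurement_sd),
                "duration": 10.0 ** (log_dur[sp] + rng.normal(
                    0, cfg.duration_measurement_sd)),
            })
        if sp in call_species:
            for j in range(k):
                rows.append({
                    "species": sp, "voc_class": "call", "recording": j + 1,
                    "peak_freq": call_freq[sp] + rng.normal(0, cfg.measurement_sd),
                    "duration": np.nan,
                })
    measurements = pd.DataFrame(rows)

    def class_mean(cls, col):
        sub = measurements[measurements["voc_class"] == cls]
        return sub.groupby("species")[col].mean()

    song_obs = class_mean("song", "peak_freq") if k > 0 else song_freq
    dur_obs = class_mean("song", "duration") if k > 0 else duration
    call_obs = class_mean("call", "peak_freq") if k > 0 else \
        call_freq[call_freq.index.isin(call_species)]

    traits = pd.DataFrame({
        "species": species,
        "song_peak_freq": song_obs.reindex(species).values,
        "call_peak_freq": call_obs.reindex(species).values,
        "song_duration": dur_obs.reindex(species).values,
        "body_mass": (10.0**log_mass).reindex(species).values,
        "forest_prop": habitat.reindex(species).values,
    })
    latent = pd.DataFrame({
        "species": species,
        "log_mass": log_mass.values,
        "log_duration": log_dur.values,
        "habitat": habitat.values,
        "song_freq": song_freq.values,
        "call_freq": call_freq.values,
    })
    return StudyData(traits=traits, trees=trees, base_tree=base,
                     measurements=measurements, config=cfg, latent=latent)


def make_tone_recording(
    freqs_hz, amps=None, duration_s: float = 1.0, rate: float = 44_100.0,
    noise_sd: float = 0.0, species: str = "synthetic", voc_class: str = "song",
    seed=None,
) -> Recording:
    """Synthetic tone-mixture recording for exercising the acoustic pipeline.

    A sum of sinusoids (optionally with white noise) annotated over its full
    extent; the peak frequency of the result is the strongest component.
    """
    rng = _rng(seed)
    freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    amps = np.ones_like(freqs_hz) if amps is None else \
        np.atleast_1d(np.asarray(amps, dtype=float))
    t = np.arange(int(duration_s * rate)) / rate
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs_hz, amps))
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, size=t.size)
    return Recording(samples=x, rate=rate, species=species,
                     voc_class=voc_class, segment=(0.0, duration_s))


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
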