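# Methods

## The statistical model

All analyses rest on the Brownian-motion model of trait evolution on a
rooted phylogeny with branch lengths. Under that model the tip values of a
trait are multivariate normal with covariance proportional to **C**, the
matrix of shared root-to-MRCA path lengths (diagonal: root-to-tip depths).
Pagel's λ relaxes the model by multiplying the off-diagonal (shared-history)
entries of **C** by λ ∈ [0, 1]: λ = 0 is a star phylogeny (no phylogenetic
structure), λ = 1 is pure Brownian motion. λ is capped at 1 because values
above 1 can destroy positive definiteness; 1 is therefore also the upper
bound of the likelihood search, and this is a deliberate restriction, not a
numerical limitation.

**PGLS.** For a regression y = Xβ + ε with ε ~ N(0, σ²C(λ)), the
fixed-λ estimates are closed-form GLS:

    β̂ = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹y,   σ̂²_ML = êᵀC⁻¹ê / n,
    logL = −½ [ n log(2π σ̂²_ML) + log|C| + n ].

λ is estimated by maximizing the profile log-likelihood over [0, 1].
Estimation is full ML rather than REML: the package's central operation is
AIC-weighted averaging of the *same* model across *different* trees, and
that comparison needs a likelihood defined on a common footing. The AIC
parameter count is k = (number of regression coefficients) + 2, counting σ²
and λ as free parameters.

**Standard errors and P values.** Coefficient SEs use the unbiased residual
variance êᵀC⁻¹ê/(n − p) — the convention of mainstream GLS software —
rather than the ML σ̂²; `gls_fit(se_mode="ml")` switches to the ML version.
Per-coefficient P values are two-tailed from a t distribution with n − p
degrees of freedom. Phylogenetic signal of a single trait is the same
machinery with an intercept-only design.

**Standardized slopes.** β_st = β · sd(x)/sd(y), computed on the transformed
model variables; SEs are standardized by the same factor. β_st is invariant
to unit changes in either variable, which is what makes song and call
allometries comparable.

## λ optimization and numerics

The profile log-likelihood is scanned on a coarse grid (step 0.01 over
[0, 1]) and the best grid point is refined by bounded scalar minimization
(tolerance 1e-8 in λ). The grid-first strategy guards against local optima,
which λ profiles can have on real trees.

Each λ evaluation would naively cost an O(n³) factorization. Instead, with
D = diag(C), the normalized matrix B = D^(−1/2) C D^(−1/2) has unit
diagonal, so C(λ) = D^(1/2)[λB + (1−λ)I]D^(1/2) for *every* λ: one
eigendecomposition of B reduces each profile point to a diagonally weighted
least squares at O(np²). This is exact for any tree, ultrametric or not,
and is verified in the tests against direct per-λ GLS factorizations to
1e-8. Decompositions are cached on the covariance objects, so several
models fitted on the same tree and species set pay for one
eigendecomposition.

Degenerate cases: a flat λ profile (range < 1e-8, e.g. a star tree where λ
has no effect) returns λ̂ = 0 with a `profile-flat` flag; a constant
response, rank-deficient design, or non-positive-definite covariance raises
an error rather than returning numbers. Ties in the coarse grid resolve to
the refined local optimum only if it genuinely improves the likelihood.

## Averaging over a tree sample

Given per-tree fits of one model, tree i receives Akaike weight
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2) with Δ_i = AIC_i − min AIC. β, SE, β_st,
λ, and per-species residuals are all averaged with these weights. Design
choices here:

- SEs are averaged as plain weighted means, matching the convention of
  reporting the weighted average of per-tree standard errors; the
  model-averaging variance that adds the between-tree spread of β is
  available as `se_mode="unconditional"` and is never smaller.
- λ is averaged on its natural scale (no logit transform).
- P values are recomputed from the averaged β and SE on a t reference with
  the mean per-tree residual degrees of freedom, rather than averaging
  per-tree P values, which would have no sampling interpretation.

## The bespoke tests

**Slope comparison.** Two standardized slopes estimated on independent
responses are compared with Z = (b₁ − b₂)/√(se₁² + se₂²) against the
standard normal, two-tailed. With hundreds of species the normal reference
is indistinguishable from a t; a Welch-df t reference is available for
small samples.

**Absolute-residual regression.** Residuals of the allometric model are
weight-averaged across trees first, and the absolute value is taken
second — the order matters and is fixed by design, since |mean| ≤ mean| |.
The absolute residuals are then regressed (λ-PGLS, λ re-estimated) on the
predictor over every tree and averaged. Type-I error of the full procedure
is checked by simulation in the acceptance battery (nominal 5% ± 2 points).

**Repeatability.** One-way-ANOVA intraclass correlation with the
unbalanced-design effective group size n₀ = (N − Σn_i²/N)/(a − 1):
s²_A = (MS_A − MS_W)/n₀ and R = s²_A/(s²_A + MS_W). Species with a single
recording stay in (they inform MS_A); sampling noise can push R below 0 and
such values are reported as computed with a `negative` flag, not truncated,
so that downstream users see the evidence as it is.

## Acoustic measurement

Peak frequency is the frequency whose cumulative magnitude across
spectrogram windows is highest: Hann windows of 1024 samples, 50% overlap,
magnitude (not power) spectrum, analysis band 0.2–12 kHz. All four choices
are conventional for passerine vocalizations and are exposed as arguments;
none is claimed to replicate any particular field protocol. Ties between
bins break to the lowest frequency so the measurement is deterministic (the
test suite constructs an exactly flat spectrum to pin this down). The
measurement is invariant to global amplitude scaling. Durations come only
from explicit segment annotations — no onset detection is attempted.
Species summaries cap at 3 recordings per vocalization class, taken in
input order.

## The synthetic-data generator

`simulate_study` emulates the data layout of a large comparative study of
passerine vocal allometry: one trait row per species, a pseudo-posterior of
trees, and repeated per-species measurements. Defaults (all overridable in
`SimulationConfig`):

| quantity | default | rationale |
|---|---|---|
| species | 591 | study-scale clade size (505 of them with call data) |
| trees | 100 | enough for the weight distribution to matter |
| branch jitter CV | 0.10 | moderate branch-length uncertainty |
| λ body mass | 0.90 | strong signal, as body size typically shows |
| λ song duration | 0.45 | labile trait |
| λ habitat (latent) | 0.75 | structured but bounded covariate |
| λ song / call residual | 0.31 / 0.65 | more labile song than call frequencies |
| slope (song / call) | −0.5 / −0.35 kHz per log10 g | steeper song allometry |
| habitat effect | 0 | null covariate |
| residual SD (song/call) | 0.40 / 0.35 kHz | β_st(mass) ≈ −0.5 / −0.4 |
| measurement SD | 0.15 kHz | within:between variance ≈ 1:9, ICC ≈ 0.9 |
| recordings/species | 3 | capped sampling design |

Mechanics: a Yule (pure-birth) tree rescaled to unit depth (the extra
post-n-th-split waiting time keeps pendant edges positive); branch-length
jitter is i.i.d. lognormal with mean 1 and the configured CV on a fixed
topology; each trait is a single multivariate-normal draw with covariance
σ²·C(λ_true); habitat is a λ-structured latent trait squashed through a
logistic to [0, 1]; the species value of each acoustic trait is the mean of
its noisy per-recording measurements, as in a real measurement pipeline.
Masses and durations are exponentiated to natural units (g, s) in the trait
table and log10-transformed again by the analysis, closing the loop.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: topological uncertainty across trees (only
branch lengths vary), non-Brownian evolution (no Ornstein–Uhlenbeck pull,
rate shifts, or punctuation), correlated measurement error, taxon-sampling
bias, and real birdsong spectro-temporal structure (audio fixtures are tone
mixtures plus white noise).

## Problem sizes used in the shipped checks

Recovery and calibration checks run at deliberately reduced scale chosen as
the smallest designs where the targeted effects are comfortably
identifiable: parameter recovery at 200 tips × 50 trees × 100 replicates;
test calibration at 100 and 60 tips × 500 replicates; the acceptance script
at 300 tips × 30 trees. Statistical conclusions (unbiasedness, nominal
type-I error) are scale-free properties verified at these sizes.

## Known limitations

- λ > 1 and other signal statistics (Blomberg's K) are out of scope, as are
  OU models and within-species measurement-error (SIMEX-style) corrections.
- Tree averaging assumes every fit shares one model structure; multimodel
  inference across predictor sets is not implemented.
- The slope-comparison Z treats the two averaged slopes as independent;
  when song and call models share the same predictor values on overlapping
  species the true covariance between β̂s is nonzero but small, since the
  responses are independent.
- Nexus input, tree dating, and topology manipulation beyond pruning are
  not supported; trees must arrive with branch lengths (a missing length is
  an error, never silently imputed).
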