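# Methods

## The model

`varcallkit` classifies missense variants by the effect they have on a
quantitative functional readout — here, the transcriptional-activation
(TA) capacity of a GAL4-DBD fusion protein measured with a
dual-luciferase reporter. The raw observable per well is a firefly
luminescence reading normalized to a co-transfected Renilla control;
the modelled quantity is the natural-log activity relative to the
wild-type construct of the same batch,

    y = ln[(firefly/renilla) / GM_WT(batch)],

where GM_WT is the geometric mean of the batch's wild-type ratios.
Geometric-mean centering makes the per-batch mean wild-type
log-activity exactly zero and cancels any common multiplicative factor
(transfection efficiency, reagent lot), which is why the batch effect
enters the model additively on the log scale.

For measurement *i* of variant *v* in batch *b*:

    y_i = x_i'γ + β_b + η_v + ε_i,   ε_i ~ N(0, σ_e²)
    β_b ~ N(0, σ_b²)
    η_v | Z_v = 0 ~ N(μ₀, τ₀²)      (neutral component)
    η_v | Z_v = 1 ~ N(μ₁, τ₁²)      (pathogenic component)
    Z_v ~ Bernoulli(π) for unlabelled variants

with the ordering constraint μ₁ < μ₀ (the pathogenic component has
lower activity), which removes label switching: every retained draw
satisfies it by construction. Labelled variants — the wild-type and
negative controls plus any reference panel — have Z observed and fixed
during fitting (a switch allows treating panel labels as unknown).
The posterior probability of pathogenicity, **PrDel**, is the posterior
mean of Z_v; for fixed-label variants it is exactly 0 or 1.

The fixed-effect term x'γ accommodates per-measurement covariates such
as an indicator for the longer expression construct (aa 1,315–1,863 vs
aa 1,396–1,863). It defaults to empty: the covariates that matter are a
property of each experiment's design, so they are caller-supplied
rather than guessed.

### Priors

All activities are wild-type-centred, so the neutral-component mean
carries a Normal(0, 1) prior. The pathogenic-component mean is anchored
at the observed mean activity of the negative-control measurements
(M1775R-like allele), Normal(m_neg, 1) truncated to μ₁ < μ₀ — the two
assay controls anchor the two components exactly as the assay design
intends. The four scale parameters τ₀, τ₁, σ_b, σ_e carry
half-Normal(1) priors (weakly informative on a log-activity scale where
a complete loss of function is about −2), π carries Beta(1, 1), and γ
Normal(0, 10²) per coefficient. All prior locations and scales are
fields of `ModelSpec`.

### Sampler

Inference is blocked Gibbs. Location-type updates are conjugate:
γ (multivariate normal), β (normal per batch), μ₀ and μ₁
(truncated-normal draws enforcing the ordering), π (Beta). Component
membership and the variant effect are updated *jointly*: Z_v is drawn
from the two-component posterior with η_v integrated out analytically
(normal–normal marginal likelihood of the variant's residual mean),
then η_v from its conditional given the new Z_v. This mixes much
faster than conditioning Z on the current η. The four scale parameters
are not conjugate under half-normal priors, so they are updated by
stepping-out slice sampling on the standard deviation — tuning-free and
exact.

Two further numerical points:

- **Recentering sweep.** The likelihood is flat along
  (β − c, η + c, μ₀ + c, μ₁ + c); only the priors identify the split
  between a global batch offset and the component locations. A
  dedicated Gibbs move samples c from its normal full conditional each
  iteration and applies the shift. Without it the split-Rhat of μ₀, μ₁
  sits near 1.3 at typical problem sizes; with it, near 1.005.
- **Truncated-normal draws** use the inverse-CDF method via
  `scipy.special.ndtr/ndtri`, pinning to the nearer boundary when the
  truncation probability mass underflows.

Defaults: 4 chains × 5,000 iterations, 2,500 burn-in, no thinning.
Each chain's generator comes from `numpy.random.SeedSequence(seed).spawn`,
so a fit is a pure function of (data, spec, seed). After fitting,
split-Rhat and effective sample sizes (via ArviZ) are computed for all
scalar parameters; max Rhat above the 1.01 threshold raises a
`ConvergenceWarning`, never silent success. The tests and the
acceptance script use 2 chains × 1,500 iterations — the problems there
(≈750 measurements, 62 variants) reach Rhat < 1.01 comfortably at that
length, and a fit takes about a second.

## Classification

PrDel maps to the five-tier functional scheme: fClass 1 below 0.001,
fClass 2 up to 0.05, fClass 3 (uncertain) up to 0.95, fClass 4 up to
0.99, fClass 5 above. The published inequalities leave PrDel exactly
0.001 unassigned; the implementation closes the fClass 2 lower bound
there (the conservative tie-break toward "likely not pathogenic"),
configurable via `ClassificationScheme(t1_boundary_class=1)`. VUS
reduction among previously unclassified variants is
100·(1 − n_fClass3/n_unclassified), rounded to the nearest integer.

## Validation machinery

- **Leave-one-out.** One full refit per reference-panel variant with
  only that label masked — a literal re-run, not an importance
  approximation, so its cost is panel size × one fit (chain length is
  reducible by config). Per-refit seeds are SHA-256-derived from the
  master seed and the variant label, so any single refit can be
  reproduced in isolation. The binary call for metric computation is
  PrDel > 0.5 by default (a symmetric, configurable choice).
- **Exact binomial intervals.** Clopper–Pearson via the beta-quantile
  closed form; the test suite checks it against an independent
  brute-force inversion of the binomial CDF for every (x, n) with
  n ≤ 50, and against statsmodels. For an all-correct panel split the
  lower bound is (0.025)^(1/n): 0.753 at 13/13 and 0.832 at 20/20.
- **QQ envelope.** Simultaneous band for normal order statistics built
  by Monte Carlo: sort `mc_draws` standard-normal samples of size n,
  band each order statistic symmetrically about its Monte-Carlo mean,
  and widen the common multiplier until the joint coverage of the
  simulated samples reaches the level. A symmetric band (rather than
  pointwise quantile bands) keeps degenerate all-zero residual vectors
  inside at small n and has essentially the same power against
  heavy-tailed alternatives.
- **Predictor concordance.** External predictions are consumed as
  tables and binarized: SIFT D/T, PolyPhen-2 D and P (possibly
  damaging) pooled as damaging vs B, MutationTaster2 A/D vs N/P, CADD
  phred ≥ 20 (configurable). Concordance is tabulated per fClass group
  {1–2, 3, 4–5} with missing predictions tallied separately.

## Annotation transfer

Alignments are consumed, not computed (aligned FASTA, with
Stockholm-style `id/start-end` headers or explicit start offsets);
coordinates are 1-based protein positions, alignment columns internal
and 0-based. A target-protein variant is IMPACT_SUPPORTED when its
reference-equivalent residue carries any class-4/5 annotation,
NO_IMPACT_SUPPORTED when it carries only class-1/2 annotation, and
UNINFORMATIVE (with a recorded reason) at gaps, unannotated residues,
or positions outside the aligned span. Compound variants take the most
impact-supporting verdict across their substitutions. Segment-level
tolerance summarizes, per secondary-structure segment, the fraction of
tested variants in fClass 4–5, excluding segments with fewer than three
variants tested.

## The synthetic-data generator

`generate()` emulates the assay's design: every batch carries wild-type
(η = 0 by the normalization convention) and a shared negative-control
allele (one η draw from the pathogenic component, as a single M1775R-like
allele would have); every variant appears in triplicate in each of
2 experiments × 2 batches. Defaults: 60 variants, 30% pathogenic,
μ₀ = 0, μ₁ = −2, τ₀ = τ₁ = 0.25, σ_b = 0.2, σ_e = 0.3, a 10-variant
labelled panel (half pathogenic where the realization allows).
These are declared fixture constants describing a well-separated,
well-replicated assay, not estimates of any real dataset. By default
the generator emits normalized log-activities directly; `emit_raw=True`
emits firefly/Renilla pairs so the normalization path itself can be
exercised end to end.

What the generator deliberately does *not* emulate: plate layouts and
raw luminescence count noise, variants of genuinely intermediate effect
(a third mode), heavy-tailed measurement errors, and batch effects that
interact with variant identity. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness of the assay model to real-data pathologies — the residual
QQ envelope is the tool for interrogating the latter on real data.

## Known limitations

- With components only ~1 SD apart the posterior is honestly uncertain;
  the pipeline reports degraded LOO metrics rather than clamping (a
  test asserts this).
- A rare neutral variant whose true effect falls ~4 component-SDs into
  the overlap region is assigned high PrDel — correct inference on an
  atypical realization, and the irreducible error floor of any
  two-component classifier at the declared separation.
- τ₁ (pathogenic-component spread) is informed by few variants in small
  panels and leans on its prior; its posterior can sit above the
  generating value.
- The LOO exercise is O(panel size) full refits; for large panels
  reduce chain length via `ModelSpec` rather than approximating.
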