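# Methods

This note documents the statistical model behind `repliscore`, the design
choices that were genuinely open, and what the synthetic calibration does and
does not demonstrate about real replication data.

## Effect standardization

All criteria operate on the SMD scale. Cohen's *d*, Cohen's *d_z* and
Glass' Δ are treated as already-standardized and pass through with their
reported standard errors; no Hedges small-sample correction is applied, so
small-*n* estimates retain the usual upward bias of *d* (the empirical
tables this package emulates report the *d* family uncorrected, and
applying a correction on one side only would distort pair comparisons).
Log hazard ratios are multiplied by √3/π ≈ 0.5513, the ratio of the normal
to the logistic standard deviation, which treats the proportional-hazards
linear predictor as a logistic latent variable — an approximation that is
adequate for pooling but not for survival inference. Pearson correlations
use a 1-SD contrast on the independent variable: smd = r/√(1−r²), with the
delta-method standard error

    se = 1 / (√(1−r²) · √(n−1)),

obtained from d(smd)/dr = (1−r²)^(−3/2) and var(r) = (1−r²)²/(n−1); the
Monte-Carlo oracle in the test suite confirms this within 5% at n = 50.
Cliff's delta and other nonparametric effects are not force-converted: they
carry through for the direction and significance criteria and are excluded
from SMD arithmetic, flagged by a `None` standardization.

When a record supplies a confidence interval but no SE, the SE is
back-computed as (hi − lo)/(2 z₀.₉₇₅). All intervals use normal (z)
critical values rather than t: the SMD standard errors are themselves
large-sample approximations, and a single convention keeps every criterion
mutually consistent (the PI/p_orig equivalence below is exact only under a
common critical value).

## Pairwise criteria

Conventions that needed pinning:

- **Strict significance**: p < α succeeds, p = α fails (α defaults 0.05).
- **Closed intervals**: a point exactly on a CI/PI boundary counts as
  inside. The event has measure zero; a convention is needed only so that
  deterministic tests are well-defined.
- **Interpretation labels override p-values**: an effect its original
  authors called positive is scored as positive even if its p ≥ 0.05.
- **A replication estimate of exactly 0** fails the direction criterion for
  positive originals — a nil estimate does not support the claimed
  direction.
- **Native-scale p-values win** for the significance criterion when
  recorded; otherwise the SMD normal-theory p is used. Both routes exist
  because source tables mix exact native tests with standardized summaries.
- The **meta-analysis criterion** for positive originals requires the
  pooled effect to be significant *in the original's direction* (a pooled
  estimate significant with flipped sign is a failure); for null originals
  success means the pool stays non-significant ("stayed null").
- **τ (within-pair heterogeneity SD)** enters p_orig, the prediction
  interval, and expected significance only. CI-inclusion criteria never use
  τ: they are confidence intervals for one experiment's effect, not
  predictions about another's.

p_orig and the prediction interval are algebraically linked:
the replication lies inside the level-ℓ PI iff p_orig > 1 − ℓ. The test
suite asserts exact agreement on 10,000 random pairs.

`expected_significance` is the probability that a replication drawn from
Normal(θ̂ₒ, σₒ² + σᵣ² + τ²) is significant at α in the original's
direction — averaged over pairs it gives the significance-agreement rate
one would see if every original were accurately estimated, the natural
benchmark against which an observed agreement rate is judged.

## Hierarchical aggregation

Outcome rows sharing an effect ID are internal replications of one
experiment and are pooled by fixed-effect inverse-variance meta-analysis
(they estimate the same quantity). A shared original result is deduplicated
before pooling rather than being counted once per internal replication.
Effects pool into experiments, and experiments into papers, with
random-effects models, because different effects in one experiment are
genuinely different quantities. τ² is estimated by REML — the profiled
restricted likelihood is maximized directly by bounded scalar
optimization — with the DerSimonian–Laird moment estimator as an explicit
method option and as the fallback if the optimizer fails. With two units
the τ² estimate is unstable and a debug message notes this; with one unit
aggregation is the identity.

Positive- and null-interpreted originals are kept in separate strata at
every level, as are numeric and image-based originals, so one experiment
can contribute aggregate records to several strata. Effects with no SMD on
either side (image-only originals without an estimated mean difference,
nonparametric scales) are carried forward unchanged at the effect level —
the direction criteria still apply there — but cannot enter experiment- or
paper-level pools. Binary criteria at the experiment/paper level are
recomputed from the level-aggregated estimates rather than majority-voted
from children; child-share percentages remain available by summarizing the
finer level directly.

Ensemble statistics: the harmonic-mean p-value k/Σ(1/pᵢ) (valid under
dependence; an asymptotically calibrated tail probability via the Landau
distribution is available behind `calibrated=True` — the raw harmonic mean
is the default because it is the more conservative, assumption-light
summary); Fisher's combined-probability test −2Σln pᵢ ~ χ²(2k) (which, by
contrast, assumes independence); the exact two-sided binomial sign test
min(1, 2·min(P(X≤k), P(X≥k))) at null ½; and Spearman's ρ with average
ranks.

Displayed percentages round half away from zero to integers; machine
outputs keep full precision.

## Moderator meta-regression

Each replication-success metric is regressed on all candidate moderators
simultaneously: animal experiment, CRO lab, core-facility lab, materials
shared (three levels, two indicator contrasts against reference "no"), and
clarification quality (0–5, treated as continuous). Binary success metrics
use a linear-probability specification — coefficients are directly
interpretable as percentage-point differences and the cluster-robust
machinery applies unchanged; a logistic link would complicate CR2 small-
sample behavior for no inferential gain at these sample sizes.

The working model has random intercepts for experiments nested in papers;
variance components are estimated by REML (the objective is evaluated with
batched per-cluster Cholesky factorizations), and metrics that carry
sampling variances (the effect-size difference and the pooled estimate) are
additionally weighted by inverse variance, making those fits a form of
random-effects meta-regression. When a variance component collapses to the
boundary the model degrades gracefully to (weighted) least squares. Fixed
effects agree with `statsmodels` MixedLM to ~3 decimals on shared test
fixtures, which serves as the independent cross-check of the estimation
route.

Inference uses CR2 cluster-robust standard errors at the paper level,
computed on the whitened (GLS) model: each cluster's residuals are rescaled
by the symmetric inverse square root of (I − H_gg), removing the leading
small-sample bias of the plain sandwich. Reference distribution is t with
(number of clusters − 1) degrees of freedom; Satterthwaite refinements are
out of scope. A simpler CR1 scalar correction is available behind
`adjustment="cr1"` and its use is logged. Bonferroni correction multiplies
each moderator's raw p by 5 — the number of candidate moderators, held
fixed even though the materials factor contributes two coefficients, so the
correction matches the moderator count rather than the column count.
Constant or collinear moderator columns are dropped with a warning and the
fit proceeds (mirroring how an inestimable moderator must be excluded in
practice). Simulation checks: with all moderator effects zero the raw-p
rejection rate at the 5% level stays within [0.02, 0.09] over 500 synthetic
ensembles of 40 papers, and a planted −0.5 animal effect on the effect-size
difference metric is recovered with median error < 0.15 over 200 ensembles.

## Synthetic ensembles

The generator emulates the statistical structure of a large preclinical
replication project, not any specific assay:

- **Hierarchy**: experiments per paper ~ Poisson(2.17) truncated at ≥ 1;
  effects per experiment from a negative binomial moment-matched to mean
  3.2 / SD 2.4 and clipped to [1, 13]. These produce roughly 7 effects per
  paper, the density seen in practice.
- **Interpretations and reporting**: 14% of effects null (true SMD 0), 26%
  image-only on the original side (stripped to a direction label); 12% of
  effects receive 2–3 internal replications of the replication experiment.
- **True positive effects**: lognormal with median 1 (μ = 0, σ = 1 on the
  log scale) by default — right-skewed, scale-free, and configurable
  (`normal` and degenerate `point` families are also available). The true
  generative distribution of published effects is unknowable; this is a
  stand-in and is labeled as such.
- **Sample sizes**: total n per side from discretized lognormals matched to
  median 8 (original) and 12 (replication) with IQR-matched log-spreads
  (0.57 and 0.75), floored at 4 and split evenly into two arms.
- **Estimates**: each side's estimate is a normal draw around its true
  effect with the Cohen's-d SE evaluated at the true effect and sampled
  group sizes; that same SE is recorded with the estimate. Recording the
  sampling SE (rather than re-deriving it from the noisy estimate) keeps
  the ensemble exactly calibrated, which is what makes the 50% direction
  floor and 95% PI coverage checks sharp. Real data differ: SEs are
  themselves estimated, estimates are non-normal at n = 4, and image-derived
  originals carry unmodeled digitization error. Passing calibration here
  therefore validates the criteria's arithmetic, not the behavior of the
  pipeline under real-data noise.
- **Heterogeneity**: with τ > 0 the replication-side true effect is the
  original's plus a N(0, τ²) pair-level perturbation, so the difference of
  true effects has SD τ — exactly the quantity the pairwise metrics add to
  their variance under the sensitivity analysis.
- **Moderators** are drawn at the experiment level (animal 30%, CRO 50%,
  core facility 30%, materials shared no/yes/not-requested at 20/60/20%,
  clarification quality uniform on 0–5) and have no effect on outcomes
  unless `moderator_effects` plants additive shifts on the replication-side
  true effect — the hook used by the parameter-recovery tests.
- **Publication bias**: `significant_only` selection retains effects whose
  original p < α, leaving the replication side untouched. This reproduces
  the winner's curse direction: selected originals overshoot truth while
  replications remain unbiased, so most replications come out smaller.

One `numpy` Generator seeded from `SimConfig.seed` drives the entire
stream; identical configs are byte-identical on disk.

## Problem sizes and tolerances

Calibration checks use 10,000 pairs (same-direction rate within ±1.5
points of 50%; PI coverage within ±0.6 points of 95%; p_orig uniform by
Kolmogorov–Smirnov at the 1% level). REML recovery uses 500 simulated
20-effect meta-analyses (median relative τ error < 25%). The selection
experiment uses ~10,000 effects with true SMD 0.3 and SE ≈ 0.3, where
significance selection inflates the retained originals' mean by more than
half. These sizes make the binomial/KS tolerances comfortably larger than
Monte-Carlo error while keeping the full suite fast.

## Known limitations

- Conversions to SMD are approximations; hazard-ratio and correlation
  conversions distort tails for large effects.
- The generator does not simulate assay-specific structure (survival
  curves, image pixel data), correlated effects within an experiment, or
  non-normal small-sample estimate distributions.
- The harmonic-mean calibration assumes equal weights across p-values.
- CR2 inference uses t(G−1) degrees of freedom throughout; with very few,
  highly unbalanced clusters a Satterthwaite rule would be more accurate.
- The optional reproduction of a real project's headline numbers requires
  that project's deposited master tables; nothing in the desk-scale
  calibration can substitute for them.
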