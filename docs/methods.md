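# Methods

## Model

The Transcriptomic Index of a sample is the posterior predictive
probability that its sex label is male, under a Bayesian nearest-neighbor
model with a changepoint partition prior.

Given a target x_τ, the training samples of the same cancer type are sorted
by Euclidean distance to the target in the full supplied gene space,
**farthest first** (x_0 most distant). The ordered binary label sequence is
modeled as piecewise-i.i.d. Bernoulli: let k_i be the number of points
sharing the partition of point i among its predecessors, with

    p(k_0 = 0) = 1
    p(k_i = 0        | k_{i−1}) = p_γ        (a breakpoint: a new block starts)
    p(k_i = k_{i−1}+1 | k_{i−1}) = 1 − p_γ    (the block extends)

Within a block the male probability θ has a Beta(α, β) prior, so the
predictive for the next label given weighted male mass m of total mass k in
the current block is (α + m)/(α + β + k). The forward recursion carries
the joint p(k_i, x_0..x_i); the target transition follows the same
changepoint law, and the TI is

    TI = Σ_k p(k_τ = k | labels) · (α + m_k)/(α + β + t_k)

where m_k, t_k are the masses of the k nearest training points. The
implementation renormalizes the joint vector at every step and accumulates
the log normalization constant, so it is exact to floating point for
sequences of at least 10^4 points (verified in tests); a brute-force
enumeration over all 2^τ breakpoint configurations serves as an independent
oracle for τ ≤ 20.

A note on the transition prior: the two verbal conditional definitions
above (breakpoint = p_γ, extension = 1 − p_γ) are what this package
implements throughout, including the target's own transition; the target's
breakpoint indicator shares the same p_γ, which makes the p_γ = 1 limit
return exactly the prior mean and p_γ = 0 the single-block predictive.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α, β | 10, 10 | Beta pseudo-counts for male/female; symmetric prior mean 0.5; the heavy prior shrinks TI toward 0.5 in small neighborhoods |
| p_γ | 0.05 | breakpoint probability per step; smaller values produce larger effective neighborhoods |
| bounds | (0.25, 0.75) | midrange TI zone for pole contrasts; the extreme tails are operationally single-sex in large cohorts |
| FDR threshold | 0.05 | BH level for skew calls and enrichment |

With α = β the model is label-flip antisymmetric: flipping every training
label maps TI → 1 − TI (asserted to 1e−12).

TI is computed separately per cancer type, leave-one-out: the target is
excluded from its own training set. Balanced weighting (w_male = N/(2N_m),
w_female = N/(2N_f), computed from the full type's composition including
the held-out target) enters only the Bernoulli sufficient statistics —
male/total masses become weighted sums — never the changepoint prior, since
the weights exist to balance label evidence, not to reshape geometry.
Distance ties are broken by ascending sample id for reproducibility.
Sex-chromosome genes are not filtered internally; `tindex ti
--exclude-genes` applies a caller-supplied list.

Per-sample **support** is E[k_τ | data], the expected size of the block the
target joins. It is reported alongside TI as the model's native confidence
measure: tight, label-homogeneous neighborhoods yield large support (tests
verify it grows monotonically with cluster tightness).

## Downstream statistics

- **Skew calling.** Per gene and cancer type, OLS of expression on TI with
  an exact two-sided t test on the slope (n − 2 df), BH across genes within
  the cohort. Positive slope at q < 0.05 → male-skewed; negative →
  female-skewed. Constant genes get slope 0, p 1, skew none (the t statistic
  is undefined); a gene fit exactly by TI gets p 0. Cross-cohort claims are
  made only at the gene-list/pathway level; raw TI values are never pooled
  across cancer types.
- **Enrichment.** One-sided (over-representation) Fisher's exact test of a
  query list against each GMT set, sets intersected with the universe
  first. The universe is the genes that entered the association analysis
  for that cohort, so the tested population matches the selection
  population. BH is applied within one query list across sets; male and
  female lists are corrected separately. The Fisher p equals the
  hypergeometric upper tail (asserted to 1e−12 against a tail-sum oracle).
- **Midrange contrasts.** Within a sex stratum and cancer type, samples
  with TI in [0.25, 0.75] are compared to that sex's pole (females below
  0.25, males above 0.75) by per-gene Welch t-tests with BH correction;
  direction "gained"/"lost" from the sign of the midrange-minus-pole mean
  difference. A per-gene location test feeding the same enrichment
  machinery is the minimal procedure consistent with pathway-level
  pole-vs-midrange comparisons; regression-within-stratum is a possible
  alternative we did not adopt.
- **Cohort summaries.** Median TI and the 5/25/75/95% quantiles (linear
  interpolation between order statistics), counts, and IRR as the
  male:female count ratio. Printed epidemiological IRRs need not equal
  count ratios; `tindex report --irr-column` accepts externally supplied
  IRRs, and the IRR-vs-median-TI regression is offered on the linear or
  log2 IRR scale (both are reported because either choice is defensible;
  the count-ratio IRR on the linear scale is the default).

## Synthetic cohorts

The generator emulates the statistical premise the method assumes: a latent
sex-continuum z with z | male ~ N(1, 1) and z | female ~ N(−1, 1) —
separated by two latent SDs but overlapping, as real male/female
transcriptomes are; a planted male module (expression = baseline + 1·z +
N(0,1) noise), a mirrored female module, and a majority of null genes with
baselines drawn once from N(0,1). Defaults: 300 samples, male fraction
0.5, 2000 genes with 100 + 100 planted. These sizes give strong but not
saturated recovery (Spearman(TI, z) ≈ 0.98, planted-gene AUROC ≈ 1.0,
empirical FDR ≈ 0.04 at nominal 0.05) and run in seconds, which is why the
test suite and acceptance script use 10–20 seeds of them. `register_genesets`
emits the planted modules plus eight size-matched decoy sets drawn from the
null genes (decoys never overlap the modules).

What the generator does **not** emulate: negative-binomial count noise,
batch effects, gene–gene correlation beyond the planted modules,
copy-number structure, or multiple cancer types with differing baselines.
Passing recovery tests therefore shows the estimator is correct and
calibrated under the model's own assumptions, not that real cohorts meet
those assumptions.

## Numerical choices and degenerate inputs

- Per-step renormalization with an accumulated log constant instead of raw
  joint products (raw products underflow once τ reaches a few hundred).
- Empty neighbor sequence (a cancer type with one sample) returns the prior
  mean α/(α+β) with a warning, partition mass all on k = 0.
- Distance ties: stable sort, secondary key ascending sample id.
- Quantiles: linear interpolation (numpy default), documented and fixed.
- Expression files: missing values dropped per gene by default or
  row-mean-imputed on request; duplicate gene ids are an error unless
  `dedup="first"`. Expression round-trips exactly (`%.17g` on write, exact
  float parsing on read).
- Sex labels are normalized case-insensitively from {male, m, female, f};
  anything else is an error, never silently dropped — the binary encoding
  is a model assumption that must be explicit. Non-binary designations are
  a documented limitation of v1.

## Limitations

- Binary sex labels only; the TI continuum is inferred *from* the binary
  labels, it does not replace richer sex/gender information.
- Euclidean distance on all supplied genes; no feature selection, no
  alternative metrics, no approximate neighbor indexes.
- The 0.25/0.75 midrange bounds are calibrated for cohorts of hundreds of
  samples; with small n the Beta(10,10) prior shrinks TI toward 0.5 and the
  pole tails can be empty, in which case narrower bounds must be supplied.
- Association is unadjusted OLS (no age/stage covariates, no moderated
  variance estimators).
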