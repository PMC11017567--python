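# tindex — a Transcriptomic Index for sex-biased expression structure

Most sex differences in cancer biology are not dichotomous: male and female
tumor transcriptomes overlap heavily and vary between female- and
male-skewed extremes. `tindex` places each tumor sample on that continuum.
It computes a **Transcriptomic Index (TI)**: the Bayesian posterior
probability that a sample is male, given the observed sexes of its most
similar transcriptomes. TI near 1 means a locally male-enriched
neighborhood ("male pole"), near 0 a female-enriched one. The package is
aimed at computational biologists analyzing bulk or single-cell expression
cohorts with binary sex annotations, who want per-patient positioning along
a sex-skew axis and the genes/pathways that define its poles.

## The model

For a target sample x_τ, the training samples of the same cancer type are
ordered by Euclidean distance in expression space, **farthest first**:
x_0, …, x_{τ−1}, with binary labels (1 = male). A changepoint process
partitions this ordered sequence into blocks: moving toward the target,
each step starts a new block with probability p_γ or extends the current
block with probability 1 − p_γ. Within a block, labels are i.i.d.
Bernoulli(θ) with conjugate prior θ ~ Beta(α, β), so the predictive
probability that the next label is male given m males of k block members is

    (α + m) / (α + β + k).

The TI is the posterior predictive P(x_τ = male | x_0, …, x_{τ−1}),
marginalized over the posterior of the target's block size k_τ — computed
exactly by a forward recursion over the joint p(k_i, x_0..x_i), with
per-step renormalization for numerical stability. Defaults are α = β = 10
and p_γ = 0.05. A weighted mode assigns sex-balancing observation weights
w_male = N/(2N_m), w_female = N/(2N_f) per cancer type so that imbalanced
cohorts contribute equal total label evidence per sex.

Downstream, genes are regressed on TI per cohort (male-skewed: positive
slope at BH FDR < 0.05; female-skewed: negative), skewed gene lists are
tested against GMT gene-set collections with one-sided Fisher's exact
tests, and samples with midrange TI (default 0.25–0.75) are contrasted
against their sex's pole by per-gene Welch t-tests.

## Worked example

```python
import numpy as np
from tindex import (BNNConfig, NeighborSequence, bnn_posterior,
                    SyntheticCohortSpec, simulate_cohort, compute_ti_cohort)

# 10 neighbors, 8 male; with p_gamma = 0 the sequence is one block:
seq = NeighborSequence(np.array([1.]*8 + [0.]*2))
ti, part = bnn_posterior(seq, BNNConfig(p_gamma=0.0))
print(round(ti, 3))          # 0.6   = (10+8)/(20+10), the single-block predictive
print(part.expected_size)    # 10.0  = the whole sequence forms the target's block

# a synthetic cohort with planted sex-skewed modules:
expr, ann, truth = simulate_cohort(SyntheticCohortSpec(seed=1))
results = compute_ti_cohort(expr, ann, BNNConfig(weighting="balanced"))
from scipy import stats
ti_vals = {r.sample: r.ti for r in results}
rho = stats.spearmanr([ti_vals[s] for s in truth.z.index], truth.z).statistic
print(round(rho, 3))         # 0.988 — TI recovers the planted latent continuum
```

The printed `0.6` is the Beta–Bernoulli predictive with 8 of 10 male
neighbors under the symmetric Beta(10,10) prior; `0.988` is the Spearman
correlation between recovered TI and the generator's latent sex-continuum
variable on the default 300-sample, 2000-gene cohort.

Or from the shell:

```
tindex simulate --seed 1 --out-prefix syn
tindex ti --expression syn.expr.tsv --annotations syn.ann.tsv --weighted --out ti.tsv
tindex associate --expression syn.expr.tsv --ti-table ti.tsv
tindex enrich --genes male_skewed.txt --universe universe.txt --gmt syn.sets.gmt
tindex report --ti-table ti.tsv
```

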