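"""Synthetic cohorts with known ground truth for parameter-recovery tests.

Each sample carries a latent sex-continuum value ``z``: males draw
``z ~ N(mu_male, sigma_z)`` and females ``z ~ N(mu_female, sigma_z)`` with
``mu_male > mu_female`` and overlapping supports, emulating the overlap of
male and female phenotypes along a continuous axis.  A planted male module
rises linearly with ``z``, a female module falls with it, and the remaining
(majority) genes are pure noise.  All randomness is seeded so a spec is a
fully reproducible fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tindex.enrichment import GeneSetCollection

__all__ = ["SyntheticCohortSpec", "GroundTruth", "simulate_cohort", "register_genesets"]

MALE_MODULE = "PLANTED_MALE_MODULE"
FEMALE_MODULE = "PLANTED_FEMALE_MODULE"


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    Defaults plant 100-gene male and female modules among 2000 genes in a
    balanced 300-sample cohort, with the latent means two latent SDs apart
    (substantial but overlapping sex separation), a one-SD-per-unit-z
    module effect and unit residual noise.
    """

    n_samples: int = 300
    male_fraction: float = 0.5
    n_genes: int = 2000
    male_module_size: int = 100
    female_module_size: int = 100
    mu_male: float = 1.0
    mu_female: float = -1.0
    sigma_z: float = 1.0
    effect: float = 1.0  # expression shift per unit z, in residual-SD units
    noise_sd: float = 1.0
    cancer_type: str = "SYNTH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.male_module_size + self.female_module_size > self.n_genes:
            raise ValueError("planted modules exceed the number of genes")
        if not (0.0 < self.male_fraction < 1.0):
            raise ValueError(f"male_fraction must be in (0, 1), got {self.male_fraction}")
        if self.sigma_z <= 0:
            raise ValueError("sigma_z must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mu_male <= self.mu_female:
            raise ValueError("mu_male must exceed mu_female")
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 samples and 1 gene")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: per-sample latent z and per-gene skew."""

    z: pd.Series  # latent continuum per sample
    sex: pd.Series  # 'male'/'female' per sample
    gene_skew: pd.Series  # 'male' | 'female' | 'null' per gene
    modules: dict[str, list[str]] = field(default_factory=dict)


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression, annotations, ground truth) for one cohort.

    Expression for a male-module gene g is ``baseline_g + effect*z + eps``,
    for a female-module gene ``baseline_g - effect*z + eps`` and for a null
    gene ``baseline_g + eps`` with ``eps ~ N(0, noise_sd)``; baselines are
    drawn once per gene from N(0, 1).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes

    n_male = int(round(n * spec.male_fraction))
    n_male = min(max(n_male, 1), n - 1)
    sex_arr = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sex_arr)
    samples = [f"S{i:04d}" for i in range(n)]
    genes = [f"G{i:05d}" for i in range(g)]

    mu = np.where(sex_arr == "male", spec.mu_male, spec.mu_female)
    z = rng.normal(mu, spec.sigma_z)

    skew = np.array(["null"] * g, dtype=object)
    skew[: spec.male_module_size] = "male"
    skew[spec.male_module_size : spec.male_module_size + spec.female_module_size] = "female"
    direction = np.where(skew == "male", 1.0, np.where(skew == "female", -1.0, 0.0))

    baseline = rng.normal(0.0, 1.0, size=g)
    noise = rng.normal(0.0, spec.noise_sd, size=(g, n))
    values = baseline[:, None] + spec.effect * direction[:, None] * z[None, :] + noise

    expr = pd.DataFrame(values, index=genes, columns=samples)
    ann = pd.DataFrame(
        {"sex": sex_arr, "cancer_type": spec.cancer_type}, index=pd.Index(samples, name="sample")
    )
    truth = GroundTruth(
        z=pd.Series(z, index=samples, name="z"),
        sex=pd.Series(sex_arr, index=samples, name="sex"),
        gene_skew=pd.Series(skew, index=genes, name="skew"),
        modules={
            MALE_MODULE: genes[: spec.male_module_size],
            FEMALE_MODULE: genes[
                spec.male_module_size : spec.male_module_size + spec.female_module_size
            ],
        },
    )
    return expr, ann, truth


def register_genesets(
    truth: GroundTruth, n_decoys: int = 8, seed: int = 0
) -> GeneSetCollection:
    """Planted modules as gene sets plus size-matched decoys of null genes.

    Each decoy's members are drawn without replacement from the null genes,
    so decoys never overlap the planted modules.  Decoy sizes cycle through
    the planted module sizes.
    """
    rng = np.random.default_rng(seed)
    null_genes = np.array(truth.gene_skew.index[truth.gene_skew == "null"])
    sets: dict[str, set[str]] = {
        name: set(members) for name, members in truth.modules.items() if members
    }
    sizes = [len(m) for m in sets.values()] or [10]
    for i in range(n_decoys):
        size = sizes[i % len(sizes)]
        if size > null_genes.size:
            raise ValueError("not enough null genes to draw a size-matched decoy set")
        sets[f"DECOY_{i:02d}"] = set(rng.choice(null_genes, size=size, replace=False))
    descriptions = {name: "planted module" if name in truth.modules else "decoy" for name in sets}
    return GeneSetCollection(sets, descriptions, source="synthetic")
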