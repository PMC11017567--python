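"""Cohort-level Transcriptomic Index computation and summaries.

TI values are computed separately within each cancer type by leave-one-out:
each sample's training set is every *other* sample of the same type, ordered
by Euclidean distance in expression space.  Balanced weighting makes the
total male and female observation weight equal within each type, so cohorts
with skewed sex composition do not bias the posterior through imbalance
alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from tindex.bnn import BNNConfig, NeighborSequence, bnn_posterior

__all__ = [
    "TIResult",
    "CohortSummary",
    "compute_ti_cohort",
    "balanced_weights",
    "summarize_cohort",
    "irr_ti_regression",
]

logger = logging.getLogger(__name__)

QUANTILES = (0.05, 0.25, 0.75, 0.95)


@dataclass(frozen=True)
class TIResult:
    """Per-sample TI with its neighborhood support.

    ``ti`` near 1 indicates a neighborhood enriched with male samples, near
    0 a female-enriched neighborhood.  ``support`` is the expected size of
    the partition the target joins, E[k_tau | data] — the model's native
    measure of how much local evidence backs the posterior.
    """

    sample: str
    cancer_type: str
    sex: str
    ti: float
    support: float


@dataclass(frozen=True)
class CohortSummary:
    cancer_type: str
    n_male: int
    n_female: int
    irr: float
    median_ti: float
    q05: float
    q25: float
    q75: float
    q95: float


def _validate_inputs(expr: pd.DataFrame, ann: pd.DataFrame) -> None:
    missing = [s for s in expr.columns if s not in ann.index]
    if missing:
        raise ValueError(f"samples missing annotation: {missing}")
    vals = expr.to_numpy()
    if not np.isfinite(vals).all():
        bad = expr.index[~np.isfinite(vals).all(axis=1)].tolist()
        raise ValueError(f"non-finite expression values in genes: {bad[:10]}")
    bad_sex = ann.loc[expr.columns, "sex"][~ann.loc[expr.columns, "sex"].isin(["male", "female"])]
    if len(bad_sex):
        raise ValueError(f"sex labels must be 'male'/'female'; offending samples: {bad_sex.index.tolist()}")


def balanced_weights(ann: pd.DataFrame) -> pd.Series:
    """Sex-balancing observation weights within each cancer type.

    For a type with ``N`` samples, ``N_m`` male and ``N_f`` female,
    ``w_male = N / (2 N_m)`` and ``w_female = N / (2 N_f)``, so the total
    weight of each sex is ``N / 2``.

    Parameters
    ----------
    ann
        Annotation frame indexed by sample id with ``sex`` and
        ``cancer_type`` columns.

    Returns
    -------
    pandas.Series of positive weights indexed like ``ann``.
    """
    weights = pd.Series(np.nan, index=ann.index, dtype=float)
    for ctype, grp in ann.groupby("cancer_type"):
        n = len(grp)
        n_m = int((grp["sex"] == "male").sum())
        n_f = int((grp["sex"] == "female").sum())
        if n_m == 0 or n_f == 0:
            raise ValueError(
                f"cancer type {ctype!r} has zero {'male' if n_m == 0 else 'female'} "
                "samples; balanced weighting is undefined"
            )
        weights.loc[grp.index[grp["sex"] == "male"]] = n / (2.0 * n_m)
        weights.loc[grp.index[grp["sex"] == "female"]] = n / (2.0 * n_f)
    return weights


def compute_ti_cohort(
    expr: pd.DataFrame, ann: pd.DataFrame, config: BNNConfig | None = None
) -> list[TIResult]:
    """Leave-one-out TI for every sample, computed within its cancer type.

    Parameters
    ----------
    expr
        Genes x samples expression matrix (normalized, log scale).
    ann
        Sample annotations indexed by sample id, columns ``sex``
        (male/female) and ``cancer_type``.
    config
        Model hyperparameters; ``config.weighting == "balanced"`` applies
        sex-balancing weights per cancer type.

    Returns
    -------
    list of TIResult, one per sample, in the sorted order of
    (cancer_type, sample id) for reproducibility.
    """
    config = config or BNNConfig()
    _validate_inputs(expr, ann)
    ann = ann.loc[expr.columns]
    if config.weighting == "balanced":
        weights = balanced_weights(ann)
    else:
        weights = pd.Series(1.0, index=ann.index)

    results: list[TIResult] = []
    for ctype in sorted(ann["cancer_type"].unique()):
        samples = sorted(ann.index[ann["cancer_type"] == ctype])
        sub = expr[samples].to_numpy().T  # samples x genes
        labels = (ann.loc[samples, "sex"] == "male").to_numpy(dtype=float)
        w = weights.loc[samples].to_numpy(dtype=float)
        n = len(samples)
        if n < 2:
            warnings.warn(
                f"cancer type {ctype!r} has {n} sample(s); TI falls back to the prior mean",
                stacklevel=2,
            )
            for i, sid in enumerate(samples):
                results.append(
                    TIResult(sid, ctype, ann.loc[sid, "sex"], config.prior_mean, 0.0)
                )
            continue
        dist = squareform(pdist(sub, metric="euclidean"))
        for i, sid in enumerate(samples):
            others = [j for j in range(n) if j != i]
            # farthest first; ties by ascending sample id (samples sorted)
            order = sorted(others, key=lambda j: (-dist[i, j], samples[j]))
            seq = NeighborSequence(labels[order], w[order])
            ti, part = bnn_posterior(seq, config)
            results.append(
                TIResult(sid, ctype, ann.loc[sid, "sex"], ti, part.expected_size)
            )
    return results


def results_frame(results: list[TIResult]) -> pd.DataFrame:
    """Tabulate TIResults (columns sample, cancer_type, sex, ti, support)."""
    return pd.DataFrame(
        [(r.sample, r.cancer_type, r.sex, r.ti, r.support) for r in results],
        columns=["sample", "cancer_type", "sex", "ti", "support"],
    )


def summarize_cohort(results: list[TIResult]) -> list[CohortSummary]:
    """Per-type counts, count-ratio IRR, median TI and 5/25/75/95% quantiles.

    Quantiles use linear interpolation between order statistics (numpy's
    default convention).  IRR is the male:female sample count ratio; it is
    ``inf`` when a type has no female samples.
    """
    df = results_frame(results)
    if df.empty:
        return []
    out = []
    for ctype, grp in df.groupby("cancer_type"):
        n_m = int((grp["sex"] == "male").sum())
        n_f = int((grp["sex"] == "female").sum())
        ti = grp["ti"].to_numpy()
        q = np.quantile(ti, QUANTILES)
        irr = n_m / n_f if n_f > 0 else float("inf")
        out.append(
            CohortSummary(
                str(ctype), n_m, n_f, irr, float(np.median(ti)), *map(float, q)
            )
        )
    return sorted(out, key=lambda s: s.cancer_type)


def summaries_frame(summaries: list[CohortSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.cancer_type, s.n_male, s.n_female, s.irr, s.median_ti, s.q05, s.q25, s.q75, s.q95)
            for s in summaries
        ],
        columns=[
            "cancer_type", "n_male", "n_female", "irr", "median_ti",
            "q05", "q25", "q75", "q95",
        ],
    )


def irr_ti_regression(
    summaries: list[CohortSummary],
    scale: str = "linear",
    external_irr: dict[str, float] | None = None,
) -> tuple[float, float, float, float]:
    """OLS of median TI on (log2-)IRR across cancer types.

    Parameters
    ----------
    summaries
        At least 3 cohort summaries.
    scale
        ``"linear"`` regresses on IRR; ``"log2"`` on log2(IRR).
    external_irr
        Optional mapping cancer_type -> externally supplied IRR (e.g.
        registry incidence rates) overriding the count ratio.

    Returns
    -------
    (slope, intercept, pearson_r, p_value) with a two-sided p for zero slope.
    """
    if len(summaries) < 3:
        raise ValueError(f"need >= 3 cohorts for regression, got {len(summaries)}")
    irr = np.array(
        [
            external_irr.get(s.cancer_type, s.irr) if external_irr else s.irr
            for s in summaries
        ]
    )
    if scale == "log2":
        x = np.log2(irr)
    elif scale == "linear":
        x = irr
    else:
        raise ValueError(f"unknown scale {scale!r}")
    y = np.array([s.median_ti for s in summaries])
    if np.ptp(y) == 0.0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)
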