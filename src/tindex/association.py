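"""Per-gene association with TI, skew calling and midrange-vs-pole contrasts.

A gene is *male-skewed* when its expression rises with TI (positive OLS
slope, BH q below threshold) and *female-skewed* when it falls.  Samples
with midrange TI sit between the all-female and all-male tails of the TI
distribution; contrasting them against their sex's pole reveals which
pole-defining programs are gained or lost along the continuum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationRecord",
    "ContrastRecord",
    "associate_genes",
    "bh_fdr",
    "classify_poles",
    "overlap_test",
    "midrange_contrast",
]


@dataclass(frozen=True)
class AssociationRecord:
    gene: str
    cancer_type: str
    slope: float
    p: float
    q: float
    skew: str  # 'male' | 'female' | 'none'


@dataclass(frozen=True)
class ContrastRecord:
    gene: str
    cancer_type: str
    sex: str
    mean_pole: float
    mean_midrange: float
    difference: float  # midrange - pole
    p: float
    q: float
    direction: str  # 'gained' | 'lost' | 'none'


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_genes(
    expr: pd.DataFrame,
    ti: pd.Series,
    threshold: float = 0.05,
    cancer_type: str = "",
) -> list[AssociationRecord]:
    """OLS of each gene's expression on TI, with BH correction across genes.

    Parameters
    ----------
    expr
        Genes x samples matrix; columns must match ``ti``'s index.
    ti
        Per-sample TI values (not all identical).
    threshold
        FDR level for skew calls (default 0.05).

    Notes
    -----
    Constant genes get slope 0, p 1, skew 'none' by convention (the t
    statistic is undefined there).  Two-sided p-values come from the exact
    t distribution on n - 2 degrees of freedom.
    """
    x = ti.loc[expr.columns].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("TI values are all identical; association undefined")
    y = expr.to_numpy(dtype=float)  # genes x samples

    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = y - y.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    syy = np.einsum("ij,ij->i", yc, yc)

    slope = sxy / sxx
    # residual variance and t statistic for the slope
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = syy - slope * sxy
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    constant = syy == 0.0
    slope[constant] = 0.0
    p[constant] = 1.0
    # exact fit on a non-constant gene: se = 0, |t| = inf -> p = 0
    p = np.where(np.isnan(p) & ~constant, 0.0, p)
    q = bh_fdr(p)

    records = []
    for g, s, pv, qv in zip(expr.index, slope, p, q):
        if qv < threshold and s > 0:
            skew = "male"
        elif qv < threshold and s < 0:
            skew = "female"
        else:
            skew = "none"
        records.append(AssociationRecord(str(g), cancer_type, float(s), float(pv), float(qv), skew))
    return records


def classify_poles(
    records: list[AssociationRecord], threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Partition significant genes into (male-skewed, female-skewed) lists."""
    male = [r.gene for r in records if r.q < threshold and r.slope > 0]
    female = [r.gene for r in records if r.q < threshold and r.slope < 0]
    return male, female


def overlap_test(list_a, list_b, universe_size: int) -> tuple[int, float]:
    """Hypergeometric upper-tail test for the overlap of two gene lists.

    Returns ``(overlap, p)`` where ``p = P[X >= overlap]`` for
    ``X ~ Hypergeom(N=universe_size, K=|A|, n=|B|)``.
    """
    a, b = set(list_a), set(list_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("list larger than universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)


def midrange_contrast(
    expr: pd.DataFrame,
    ti: pd.Series,
    ann: pd.DataFrame,
    sex: str,
    bounds: tuple[float, float] = (0.25, 0.75),
    threshold: float = 0.05,
    cancer_type: str = "",
) -> list[ContrastRecord]:
    """Welch t-test per gene: midrange-TI samples vs their sex's pole.

    The pole group is sex-conditional — females with ``ti < bounds[0]`` or
    males with ``ti > bounds[1]`` — and the midrange group is samples of
    that sex with ``ti`` inside ``[bounds[0], bounds[1]]``.  Direction
    'gained' means higher mean expression in the midrange group than at the
    pole (at BH q < threshold), 'lost' the reverse.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex stratum must be 'male' or 'female', got {sex!r}")
    low, high = bounds
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"invalid bounds {bounds}")
    sel = ann.loc[expr.columns, "sex"] == sex
    samples = expr.columns[sel.to_numpy()]
    t = ti.loc[samples]
    if sex == "female":
        pole = samples[(t < low).to_numpy()]
    else:
        pole = samples[(t > high).to_numpy()]
    mid = samples[((t >= low) & (t <= high)).to_numpy()]
    label = f"{sex} stratum" + (f" of {cancer_type}" if cancer_type else "")
    if len(pole) == 0:
        raise ValueError(f"empty pole group in {label}")
    if len(mid) == 0:
        raise ValueError(f"empty midrange group in {label}")

    yp = expr[pole].to_numpy(dtype=float)
    ym = expr[mid].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = stats.ttest_ind(ym, yp, axis=1, equal_var=False)
    p = np.where(np.isfinite(tt.pvalue), tt.pvalue, 1.0)
    q = bh_fdr(p)
    mean_p = yp.mean(axis=1)
    mean_m = ym.mean(axis=1)

    records = []
    for g, mp, mm, pv, qv in zip(expr.index, mean_p, mean_m, p, q):
        diff = float(mm - mp)
        if qv < threshold and diff > 0:
            direction = "gained"
        elif qv < threshold and diff < 0:
            direction = "lost"
        else:
            direction = "none"
        records.append(
            ContrastRecord(str(g), cancer_type, sex, float(mp), float(mm), diff, float(pv), float(qv), direction)
        )
    return records
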