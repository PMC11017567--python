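"""Readers and writers for the tab-separated formats the pipeline touches.

Expression matrices are genes x samples TSV (first column gene ids, header
row sample ids).  Annotation tables carry sample id, sex and cancer type.
All writers emit a header and sort rows by id so outputs diff cleanly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tindex.association import AssociationRecord, ContrastRecord
from tindex.cohort import CohortSummary, TIResult, results_frame, summaries_frame
from tindex.enrichment import EnrichmentRecord

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "normalize_sex",
    "write_ti_results",
    "read_ti_results",
    "write_summaries",
    "write_associations",
    "write_contrasts",
    "write_enrichment",
    "write_gene_list",
    "read_gene_list",
]

_SEX_ALIASES = {"male": "male", "m": "male", "female": "female", "f": "female"}


def normalize_sex(value: str) -> str:
    """Map {male, m, female, f} (case-insensitive) to 'male'/'female'."""
    key = str(value).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unrecognized sex label {value!r}; expected male/m/female/f")
    return _SEX_ALIASES[key]


def read_expression(
    path,
    transpose: bool = False,
    missing: str = "drop",
    exclude_genes=None,
    dedup: str = "error",
) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    Parameters
    ----------
    transpose
        Set when the file stores samples as rows.
    missing
        ``"drop"`` removes gene rows with any missing value; ``"impute"``
        replaces missing cells with the gene's row mean.
    exclude_genes
        Optional collection of gene ids to remove after parsing (e.g. a
        sex-chromosome gene list).
    dedup
        ``"error"`` rejects duplicate gene ids; ``"first"`` keeps the first
        occurrence.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        if dedup == "first":
            df = df[~df.index.duplicated(keep="first")]
        else:
            raise ValueError(f"duplicate gene ids: {dups[:10]} (use dedup='first' to keep the first)")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids: {df.columns[df.columns.duplicated()].tolist()[:10]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    if df.isna().any().any():
        if missing == "drop":
            df = df.dropna(axis=0, how="any")
        elif missing == "impute":
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    if exclude_genes is not None:
        df = df.drop(index=[g for g in exclude_genes if g in df.index])
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"non-finite expression values remain in {path}")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    expr.sort_index().to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_annotations(path) -> pd.DataFrame:
    """Read a sample annotation TSV (columns: sample, sex, cancer_type[, weight])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "sex", "cancer_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    df["sex"] = df["sex"].map(normalize_sex)
    df = df.set_index("sample")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if "weight" in df.columns:
        df["weight"] = df["weight"].astype(float)
    return df


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.sort_index().to_csv(path, sep="\t", index_label="sample")


def write_ti_results(results: list[TIResult], path) -> None:
    df = results_frame(results).sort_values(["cancer_type", "sample"])
    df.to_csv(path, sep="\t", index=False)


def read_ti_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "cancer_type": str, "sex": str})
    return df


def write_summaries(summaries: list[CohortSummary], path) -> None:
    df = summaries_frame(summaries).sort_values("cancer_type")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_associations(records: list[AssociationRecord], path) -> None:
    df = pd.DataFrame(
        [(r.gene, r.cancer_type, r.slope, r.p, r.q, r.skew) for r in records],
        columns=["gene", "cancer_type", "slope", "p", "q", "skew"],
    ).sort_values(["cancer_type", "gene"])
    df.to_csv(path, sep="\t", index=False)


def write_contrasts(records: list[ContrastRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.gene, r.cancer_type, r.sex, r.mean_pole, r.mean_midrange, r.difference, r.p, r.q, r.direction)
            for r in records
        ],
        columns=[
            "gene", "cancer_type", "sex", "mean_pole", "mean_midrange",
            "difference", "p", "q", "direction",
        ],
    ).sort_values(["cancer_type", "sex", "gene"])
    df.to_csv(path, sep="\t", index=False)


def write_enrichment(records: list[EnrichmentRecord], path) -> None:
    df = pd.DataFrame(
        [(r.set_name, r.query_size, r.set_size, r.overlap, r.p, r.q) for r in records],
        columns=["set_name", "query_size", "set_size", "overlap", "p", "q"],
    ).sort_values("set_name")
    df.to_csv(path, sep="\t", index=False)


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]
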