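"""Gene-set over-representation analysis for skewed and contrast gene lists.

One-sided Fisher's exact test (equivalently, the hypergeometric upper tail)
of a query gene list against each set in a GMT collection, with BH
correction across the tested sets.  The universe is the caller's choice; by
convention it is every gene that entered the association analysis for the
same cohort, so the tested population matches the selection population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from tindex.association import bh_fdr

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "write_gmt",
    "fisher_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional per-set description."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    query_size: int
    set_size: int  # after intersection with the universe
    overlap: int
    p: float
    q: float


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, member genes (tabs).

    Duplicate members within a line are stored once; empty lines are
    skipped; a line with fewer than 3 fields raises with its line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in genes if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (members sorted for diffability)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def fisher_enrichment(
    query,
    universe,
    sets: GeneSetCollection,
) -> tuple[list[EnrichmentRecord], list[str]]:
    """Test each gene set for over-representation in the query list.

    Parameters
    ----------
    query
        Gene list of interest (e.g. male-skewed genes); must be a subset of
        ``universe``.
    universe
        Background gene list (duplicates removed); sets are intersected
        with it before testing and sets with empty intersection skipped.
    sets
        The GMT collection.

    Returns
    -------
    (records, skipped)
        Enrichment records sorted by set name with one-sided Fisher p
        (hypergeometric upper tail) and BH q across the tested sets, plus
        the names of sets skipped for empty universe intersection.
    """
    uni = set(universe)
    q = set(query)
    stray = sorted(q - uni)
    if stray:
        raise ValueError(f"query genes not in universe: {stray[:10]}")
    n_uni = len(uni)
    n_query = len(q)

    names, records_wo_q, skipped = [], [], []
    for name in sorted(sets.sets):
        members = sets.sets[name] & uni
        if not members:
            skipped.append(name)
            continue
        overlap = len(members & q)
        # 2x2 table: (in query / not) x (in set / not), one-sided over-representation
        table = [
            [overlap, n_query - overlap],
            [len(members) - overlap, n_uni - n_query - (len(members) - overlap)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        names.append(name)
        records_wo_q.append((name, n_query, len(members), overlap, float(p)))
    qvals = bh_fdr([r[4] for r in records_wo_q])
    records = [
        EnrichmentRecord(name, nq, ns, ov, p, float(qv))
        for (name, nq, ns, ov, p), qv in zip(records_wo_q, qvals)
    ]
    return records, skipped
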