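"""Homolog hit-table analytics and mutation stability classification.

A :class:`HitTable` holds the deduplicated homology-search hits of one query
toxin. The pipeline applied to a set of tables is: length filtering (hits
shorter than 75% or longer than 150% of the query are discounted), pairwise
and global hit-set overlap, single-linkage family clustering on overlap, and
taxon tallies over the deduplicated union. Separately,
:func:`classify_stability` bins mutations by a symmetric ddG cutoff band
(|ddG| <= 2 kcal/mol is "stable").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

HIT_COLUMNS = ["query_id", "query_len", "hit_id", "hit_len", "taxon"]


@dataclass
class HitTable:
    query_id: str
    query_len: int
    hits: pd.DataFrame  # hit_id, hit_len, taxon

    def __post_init__(self):
        if self.query_len <= 0:
            raise ValueError(f"query {self.query_id!r}: nonpositive query length")
        self.hits = self.hits.drop_duplicates(subset="hit_id").reset_index(drop=True)
        if len(self.hits) and (self.hits.hit_len <= 0).any():
            raise ValueError(f"query {self.query_id!r}: nonpositive hit length")

    def hit_ids(self) -> set[str]:
        return set(self.hits.hit_id)

    def __len__(self) -> int:
        return len(self.hits)


def read_hit_tables(path: str | Path) -> list[HitTable]:
    """Read hit tables from TSV with header (query_id, query_len, hit_id, hit_len, taxon)."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "hit_id": str, "taxon": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tables = []
    for qid, group in df.groupby("query_id", sort=False):
        qlens = group.query_len.unique()
        if len(qlens) != 1:
            raise ValueError(f"{path}: query {qid!r} has inconsistent query_len")
        tables.append(
            HitTable(
                query_id=qid,
                query_len=int(qlens[0]),
                hits=group[["hit_id", "hit_len", "taxon"]].copy(),
            )
        )
    return tables


def write_hit_tables(tables: Iterable[HitTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        for row in t.hits.itertuples():
            rows.append((t.query_id, t.query_len, row.hit_id, row.hit_len, row.taxon))
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_hits_by_length(
    table: HitTable, lower: float = 0.75, upper: float = 1.50
) -> tuple[HitTable, int]:
    """Discount hits shorter than ``lower`` or longer than ``upper`` times
    the query length.

    The bounds are strict: a hit exactly at 75% or 150% of the query length
    is kept. Returns the filtered table and the removed count.
    """
    lo = lower * table.query_len
    hi = upper * table.query_len
    keep = (table.hits.hit_len >= lo) & (table.hits.hit_len <= hi)
    kept = HitTable(table.query_id, table.query_len, table.hits[keep].copy())
    return kept, int((~keep).sum())


@dataclass
class PairOverlap:
    query_a: str
    query_b: str
    shared: int
    union: int
    jaccard: float


@dataclass
class OverlapStats:
    pairs: list[PairOverlap]
    global_intersection: int
    global_union: int
    percent_shared: float  # 100 * |intersection of all| / |union of all|

    def pair(self, a: str, b: str) -> PairOverlap:
        for p in self.pairs:
            if {p.query_a, p.query_b} == {a, b}:
                return p
        raise KeyError((a, b))


def overlap_stats(tables: Sequence[HitTable]) -> OverlapStats:
    """Pairwise and global overlap of the queries' hit-id sets.

    "Percent shared" uses the union of deduplicated hit ids across the whole
    group as the denominator — a stated convention, configurable only in the
    sense that callers can recompute from the counts returned.
    """
    if len(tables) < 2:
        raise ValueError("overlap statistics need at least 2 hit tables")
    sets = {t.query_id: t.hit_ids() for t in tables}
    pairs = []
    for a, b in combinations(sets, 2):
        inter = len(sets[a] & sets[b])
        union = len(sets[a] | sets[b])
        pairs.append(
            PairOverlap(a, b, inter, union, inter / union if union else 0.0)
        )
    all_sets = list(sets.values())
    g_inter = set.intersection(*all_sets)
    g_union = set.union(*all_sets)
    return OverlapStats(
        pairs=pairs,
        global_intersection=len(g_inter),
        global_union=len(g_union),
        percent_shared=100.0 * len(g_inter) / len(g_union) if g_union else 0.0,
    )


@dataclass
class FamilyAssignment:
    clusters: list[list[str]]  # each sorted; clusters ordered by first member
    pair_shared: dict[tuple[str, str], int]
    pair_jaccard: dict[tuple[str, str], float]
    cluster_stats: list[dict] = field(default_factory=list)


def cluster_families(
    tables: Sequence[HitTable],
    min_shared: int = 1,
    min_jaccard: float = 0.0,
) -> FamilyAssignment:
    """Single-linkage clustering of queries by hit-set overlap.

    Queries are linked when their shared-hit count is >= ``min_shared`` and
    Jaccard index >= ``min_jaccard``; families are the connected components.
    The permissive defaults mirror qualitative family grouping, where any
    substantial overlap joins two toxins even when it is a small fraction of
    the union. Clusters are ordered by their smallest member id.
    """
    sets = {t.query_id: t.hit_ids() for t in tables}
    ids = sorted(sets)
    parent = {q: q for q in ids}

    def find(q: str) -> str:
        while parent[q] != q:
            parent[q] = parent[parent[q]]
            q = parent[q]
        return q

    pair_shared: dict[tuple[str, str], int] = {}
    pair_jaccard: dict[tuple[str, str], float] = {}
    for a, b in combinations(ids, 2):
        shared = len(sets[a] & sets[b])
        union = len(sets[a] | sets[b])
        jac = shared / union if union else 0.0
        pair_shared[(a, b)] = shared
        pair_jaccard[(a, b)] = jac
        if shared >= min_shared and jac >= min_jaccard and shared > 0:
            parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for q in ids:
        groups.setdefault(find(q), []).append(q)
    clusters = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    stats = []
    for cluster in clusters:
        members = [sets[q] for q in cluster]
        union = set.union(*members)
        inter = set.intersection(*members)
        stats.append(
            {
                "members": cluster,
                "union_size": len(union),
                "intersection_size": len(inter),
                "percent_shared": 100.0 * len(inter) / len(union) if union else 0.0,
            }
        )
    return FamilyAssignment(
        clusters=clusters,
        pair_shared=pair_shared,
        pair_jaccard=pair_jaccard,
        cluster_stats=stats,
    )


#: default lineage keywords -> taxon group
DEFAULT_TAXON_GROUPS = {
    "fungi": "fungi",
    "ascomycota": "fungi",
    "basidiomycota": "fungi",
    "bacteria": "bacteria",
    "viridiplantae": "plants",
    "streptophyta": "plants",
}


def taxon_summary(
    tables: Sequence[HitTable],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Counts and percentages per taxon group over the deduplicated hit union.

    Lineage strings are matched case-insensitively against the ``groups``
    keyword map (first keyword wins); unmatched or missing lineages fall in
    "unknown". Percentages sum to 100 within rounding.
    """
    groups = groups or DEFAULT_TAXON_GROUPS
    seen: dict[str, str] = {}
    for t in tables:
        for row in t.hits.itertuples():
            if row.hit_id in seen:
                continue
            lineage = (row.taxon or "").lower() if isinstance(row.taxon, str) else ""
            label = "unknown"
            for keyword, group in groups.items():
                if keyword in lineage:
                    label = group
                    break
            seen[row.hit_id] = label
    counts = pd.Series(list(seen.values())).value_counts() if seen else pd.Series(dtype=int)
    total = int(counts.sum())
    out = counts.rename_axis("group").reset_index(name="count")
    out["percent"] = 100.0 * out["count"] / total if total else 0.0
    return out


@dataclass
class StabilityRecord:
    mutation: str
    ddg: float  # kcal/mol, folding
    label: str  # stabilizing | stable | destabilizing


def classify_stability(
    records: pd.DataFrame | Sequence[tuple[str, float]],
    cutoff: float = 2.0,
) -> list[StabilityRecord]:
    """Bin mutations by predicted folding ddG against a symmetric cutoff.

    ddG > cutoff is destabilizing, ddG < -cutoff stabilizing, anything in
    the closed band [-cutoff, cutoff] stable. Every record lands in exactly
    one class.
    """
    if isinstance(records, pd.DataFrame):
        rows = list(records[["mutation", "ddg"]].itertuples(index=True))
        items = [(r.Index, r.mutation, r.ddg) for r in rows]
    else:
        items = [(i, m, d) for i, (m, d) in enumerate(records)]
    out = []
    for idx, mutation, ddg in items:
        try:
            value = float(ddg)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx} ({mutation!r}): non-numeric ddG {ddg!r}") from exc
        if value > cutoff:
            label = "destabilizing"
        elif value < -cutoff:
            label = "stabilizing"
        else:
            label = "stable"
        out.append(StabilityRecord(mutation=str(mutation), ddg=value, label=label))
    return out


def read_ddg_table(path: str | Path) -> pd.DataFrame:
    """Read a mutation ddG table from TSV with header (mutation, ddg)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"mutation", "ddg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
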