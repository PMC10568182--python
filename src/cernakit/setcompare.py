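"""Cross-region Venn accounting, disease-category mapping, top-k class tables.

Answers the bookkeeping questions of a two-region DE study: how many genes
are co-up/co-downregulated in both regions per biotype, how many significant
DEGs fall in each disease category (pain, anxiety, ...) and their multi-way
intersections, and which are the top-k up/down genes within a gene class
(e.g. GPCRs, ion channels) ranked by fold change.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diffexp import DETable


@dataclass
class OverlapReport:
    """Venn / category counts plus the underlying member sets."""

    counts: pd.DataFrame
    members: dict[str, set[str]] = field(default_factory=dict)


def co_expression_overlap(de_a: DETable, de_b: DETable) -> OverlapReport:
    """Per-biotype co-up / co-down Venn partition between two regions.

    For each biotype and each direction: |A∩B| (co-regulated), |A\\B|, |B\\A|.
    The three partition counts sum to |A∪B| by construction.  Empty
    significant sets give zero counts.
    """
    ta, tb = de_a.table, de_b.table
    biotypes = sorted(
        set(ta.get("biotype", pd.Series(dtype=str))) | set(tb.get("biotype", pd.Series(dtype=str)))
    ) or ["all"]
    rows = []
    members: dict[str, set[str]] = {}
    for bt in biotypes:
        bt_arg = None if bt == "all" else bt
        for direction in ("up", "down"):
            a = de_a.significant_ids(direction=direction, biotype=bt_arg)
            b = de_b.significant_ids(direction=direction, biotype=bt_arg)
            key = f"{bt}_{direction}"
            members[f"{key}_co"] = a & b
            rows.append(
                {
                    "biotype": bt,
                    "direction": direction,
                    "co_regulated": len(a & b),
                    f"only_{de_a.region}": len(a - b),
                    f"only_{de_b.region}": len(b - a),
                    "union": len(a | b),
                }
            )
    return OverlapReport(counts=pd.DataFrame(rows), members=members)


def map_to_categories(
    de: DETable,
    categories: dict[str, set[str]],
    tuples: list[tuple[str, ...]] | None = None,
    mrna_only: bool = False,
) -> OverlapReport:
    """Map a region's significant DEGs onto disease-category gene sets.

    Single categories get a count and a percent of the significant DEG total
    (all biotypes by default, mRNA-only switchable); each requested tuple of
    category names gets the count of DEGs in the intersection of those sets.
    Unknown category names raise with the available names listed.
    """
    deg = de.significant_ids(biotype="mRNA" if mrna_only else None)
    requested = list(categories) + [nm for tup in (tuples or []) for nm in tup]
    unknown = sorted(set(requested) - set(categories))
    if unknown:
        raise KeyError(
            f"unknown categories {unknown}; available: {sorted(categories)}"
        )

    rows = []
    members: dict[str, set[str]] = {}
    denom = len(deg)
    for name in sorted(categories):
        hit = deg & set(categories[name])
        members[name] = hit
        rows.append(
            {
                "selection": name,
                "kind": "category",
                "count": len(hit),
                "percent": 100.0 * len(hit) / denom if denom else 0.0,
            }
        )
    for tup in tuples or []:
        inter = deg.copy()
        for nm in tup:
            inter &= set(categories[nm])
        key = "&".join(tup)
        members[key] = inter
        rows.append({"selection": key, "kind": "intersection", "count": len(inter), "percent": float("nan")})
    counts = pd.DataFrame(rows, columns=["selection", "kind", "count", "percent"])
    counts.attrs["denominator"] = denom
    return OverlapReport(counts=counts, members=members)


def top_k_by_class(de: DETable, class_set: set[str], k: int = 15) -> pd.DataFrame:
    """Top-k up- and downregulated significant genes within a gene class.

    Ranked by |log2fc| descending; ties broken by smaller p, then gene_id.
    Fewer than k rows are returned (per direction) when the class is short;
    ``df.attrs['short']`` flags that case.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = de.table[de.table["significant"] & de.table["gene_id"].isin(set(class_set))].copy()
    sig["abs_lfc"] = sig["log2fc"].abs()
    parts = []
    short = False
    for direction in ("up", "down"):
        sub = sig[sig["direction"] == direction].sort_values(
            ["abs_lfc", "p_value", "gene_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        short = short or len(sub) < k
        sub = sub.head(k).drop(columns="abs_lfc")
        sub.insert(0, "rank", range(1, len(sub) + 1))
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True) if parts else sig
    out.attrs["short"] = short
    return out
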