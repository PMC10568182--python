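"""ceRNA (miRNA-sponge) pair calling and tripartite network assembly.

The competing-endogenous-RNA hypothesis: a lncRNA or circRNA that shares
miRNA response elements with an mRNA can sponge those miRNAs and de-repress
the mRNA.  Candidate evidence for a (ceRNA, mRNA) pair, both differentially
expressed in a region:

1. *Shared-miRNA over-representation* — with M = distinct miRNAs in the
   target map, K = miRNAs targeting the ceRNA, n = miRNAs targeting the
   mRNA and k = miRNAs targeting both, the upper-tail hypergeometric
   P(X ≥ k) must be ≤ 0.05.
2. *Expression correlation* — Pearson correlation of the pair's
   log2(RPKM+1) profiles across the region's samples must be ≥ 0.5 with
   p ≤ 0.05.  The profiles are mean-centered within each condition first, so
   the correlation measures sample-level co-expression rather than the
   trivial agreement every pair of concordantly injury-regulated genes shows
   through the group shift (the p-value therefore uses df = n − 3, one
   degree lost to the condition means).
3. *Direction concordance* — the ceRNA and mRNA must be differentially
   expressed in the same direction.

With fewer than 4 samples in the region (the no-replicate regime) the
correlation filter is undefined and passing degrades to criteria 1 + 3,
flagged in the output.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DETable
from .enrichment import hypergeom_tail_vec

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "cerna_id",
    "cerna_biotype",
    "mrna_id",
    "k_shared",
    "K",
    "n",
    "M",
    "shared_mirnas",
    "hypergeom_p",
    "ppc",
    "ppc_p",
    "concordant",
    "passes",
]


def targets_by_gene(targets: pd.DataFrame) -> dict[str, set[str]]:
    """Invert a (mirna_id, target_id) table to gene → {miRNAs targeting it}."""
    out: dict[str, set[str]] = {}
    for m, g in zip(targets["mirna_id"], targets["target_id"]):
        out.setdefault(g, set()).add(m)
    return out


def shared_mirnas(targets: pd.DataFrame, cerna_id: str, mrna_id: str) -> tuple[set[str], int]:
    """miRNAs targeting both genes, and their count (empty set is valid)."""
    by_gene = targets_by_gene(targets)
    shared = by_gene.get(cerna_id, set()) & by_gene.get(mrna_id, set())
    return shared, len(shared)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-based p (df = n − 2).

    Requires length ≥ 3 and non-zero variance in both vectors (zero variance
    leaves r undefined and raises; callers skip such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Pearson r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CeRNANetwork:
    """Passing pairs assembled into a tripartite miRNA–ceRNA–mRNA network."""

    nodes: pd.DataFrame
    edges: pd.DataFrame
    top_cernas: pd.DataFrame
    top_mirnas: pd.DataFrame
    n_pairs: int = 0
    members: dict[str, set[str]] = field(default_factory=dict)


def call_pairs(
    de: DETable,
    expr: pd.DataFrame,
    design: pd.DataFrame,
    region: str,
    targets: pd.DataFrame,
    hyper_alpha: float = 0.05,
    ppc_min: float = 0.5,
    ppc_alpha: float = 0.05,
    log_pseudocount: float = 1.0,
    de_mirnas: set[str] | None = None,
    cerna_biotypes: tuple[str, ...] = ("lncRNA", "circRNA"),
) -> pd.DataFrame:
    """Score every candidate (DE ceRNA, DE mRNA) pair sharing ≥ 1 miRNA.

    Candidates are restricted to genes significant in ``de`` (the region's
    table).  ``de_mirnas``, if given, restricts the mediating miRNAs (and the
    hypergeometric universe) to that set — optional because the upstream
    provenance of miRNA differential expression is typically unspecified.
    Returns one row per candidate with the statistics and pass flags; the
    frame's ``attrs['mode']`` records whether the correlation filter applied.
    """
    if targets.empty:
        raise ValueError("empty miRNA target map")
    if de_mirnas is not None:
        targets = targets[targets["mirna_id"].isin(de_mirnas)]
        if targets.empty:
            raise ValueError("no target-map miRNAs left after DE-miRNA filtering")

    mirnas = sorted(set(targets["mirna_id"]))
    m_index = {m: i for i, m in enumerate(mirnas)}
    M = len(mirnas)
    by_gene = targets_by_gene(targets)

    sig = de.table[de.table["significant"]]
    have_expr = set(expr["gene_id"])
    cer = sig[sig["biotype"].isin(cerna_biotypes) & sig["gene_id"].isin(by_gene)]
    mr = sig[(sig["biotype"] == "mRNA") & sig["gene_id"].isin(by_gene)]
    cer = cer[cer["gene_id"].isin(have_expr)]
    mr = mr[mr["gene_id"].isin(have_expr)]

    sub = design[design["region"] == region]
    sample_cols = sub["sample_id"].tolist()
    missing = [c for c in sample_cols if c not in expr.columns]
    if missing:
        raise ValueError(f"expression matrix missing region samples {missing}")
    ns = len(sample_cols)
    corr_df = ns - 3  # condition means absorb one df beyond the usual two
    degenerate = corr_df < 1
    mode = "hypergeometric-only" if degenerate else "correlation"

    empty = pd.DataFrame(columns=PAIR_COLUMNS)
    empty.attrs.update({"mode": mode, "region": region, "M": M})
    if cer.empty or mr.empty:
        return empty

    def incidence(ids: list[str]) -> np.ndarray:
        mat = np.zeros((len(ids), M), dtype=bool)
        for i, g in enumerate(ids):
            for m in by_gene[g]:
                mat[i, m_index[m]] = True
        return mat

    cer_ids = cer["gene_id"].tolist()
    mr_ids = mr["gene_id"].tolist()
    bc = incidence(cer_ids)
    bm = incidence(mr_ids)
    shared = bc.astype(np.int32) @ bm.T.astype(np.int32)
    ci, mi = np.nonzero(shared >= 1)
    if ci.size == 0:
        return empty

    k = shared[ci, mi]
    K = bc.sum(axis=1)[ci]
    n = bm.sum(axis=1)[mi]
    hyper_p = hypergeom_tail_vec(k, K, n, M)

    # within-condition-centered log2 expression, row-normalized; the matrix
    # product of the two normalized blocks is the full candidate ppc matrix
    genes_needed = list(dict.fromkeys(cer_ids + mr_ids))
    X = np.log2(
        expr.set_index("gene_id").loc[genes_needed, sample_cols].to_numpy(float) + log_pseudocount
    )
    cond = sub["condition"].to_numpy()
    R = X.copy()
    for c in np.unique(cond):
        cols = cond == c
        R[:, cols] -= R[:, cols].mean(axis=1, keepdims=True)
    norm = np.sqrt((R**2).sum(axis=1))
    ok_var = norm > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Rn = np.where(ok_var[:, None], R / np.where(norm == 0, 1.0, norm)[:, None], np.nan)
    row = {g: i for i, g in enumerate(genes_needed)}
    rc = Rn[[row[g] for g in cer_ids]]
    rm = Rn[[row[g] for g in mr_ids]]

    if degenerate:
        ppc = np.full(ci.size, np.nan)
        ppc_p = np.full(ci.size, np.nan)
    else:
        corr = rc @ rm.T
        ppc = np.clip(corr[ci, mi], -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = ppc * np.sqrt(corr_df / np.maximum(1.0 - ppc**2, 1e-15))
            ppc_p = 2.0 * stats.t.sf(np.abs(t), corr_df)
        n_skipped = int(np.isnan(ppc).sum())
        if n_skipped:
            logger.info("skipped %d candidate pairs with zero-variance expression", n_skipped)

    dir_c = cer["direction"].to_numpy()[ci]
    dir_m = mr["direction"].to_numpy()[mi]
    concordant = dir_c == dir_m

    if degenerate:
        passes = (hyper_p <= hyper_alpha) & concordant
    else:
        passes = (
            (hyper_p <= hyper_alpha)
            & concordant
            & np.isfinite(ppc)
            & (ppc >= ppc_min)
            & (ppc_p <= ppc_alpha)
        )

    shared_sets = [
        ";".join(sorted(by_gene[cer_ids[a]] & by_gene[mr_ids[b]])) for a, b in zip(ci, mi)
    ]
    out = pd.DataFrame(
        {
            "cerna_id": np.asarray(cer_ids)[ci],
            "cerna_biotype": cer["biotype"].to_numpy()[ci],
            "mrna_id": np.asarray(mr_ids)[mi],
            "k_shared": k,
            "K": K,
            "n": n,
            "M": M,
            "shared_mirnas": shared_sets,
            "hypergeom_p": hyper_p,
            "ppc": ppc,
            "ppc_p": ppc_p,
            "concordant": concordant,
            "passes": passes,
        }
    ).sort_values(["cerna_id", "mrna_id"], kind="mergesort", ignore_index=True)
    out.attrs.update({"mode": mode, "region": region, "M": M})
    return out


def build_network(
    pairs: pd.DataFrame, top_cerna: int = 10, top_mirna: int = 2
) -> CeRNANetwork:
    """Assemble passing pairs into the tripartite network with degree ranks.

    Degrees: ceRNA = distinct passing mRNA partners; mRNA symmetric; miRNA =
    number of passing pairs whose shared-miRNA evidence contains it.  Top
    lists are ranked by degree descending with ties by the best (smallest)
    hypergeometric p among the node's pairs, then id.  Edge kinds:
    ``cerna-mrna`` (one per passing pair) plus ``mirna-cerna``/``mirna-mrna``
    evidence edges for every shared miRNA.
    """
    passing = pairs[pairs["passes"]] if len(pairs) else pairs
    node_rows: list[dict] = []
    edge_rows: list[dict] = []
    deg: dict[tuple[str, str], int] = {}
    best_p: dict[tuple[str, str], float] = {}

    def bump(kind: str, node: str, p: float) -> None:
        key = (kind, node)
        deg[key] = deg.get(key, 0) + 1
        best_p[key] = min(best_p.get(key, math.inf), p)

    for rec in passing.itertuples(index=False):
        p = float(rec.hypergeom_p)
        bump(rec.cerna_biotype, rec.cerna_id, p)
        bump("mRNA", rec.mrna_id, p)
        edge_rows.append({"source": rec.cerna_id, "target": rec.mrna_id, "kind": "cerna-mrna"})
        for m in str(rec.shared_mirnas).split(";") if rec.shared_mirnas else []:
            bump("miRNA", m, p)
            edge_rows.append({"source": m, "target": rec.cerna_id, "kind": "mirna-cerna"})
            edge_rows.append({"source": m, "target": rec.mrna_id, "kind": "mirna-mrna"})

    for (kind, node), d in deg.items():
        node_rows.append({"node_id": node, "kind": kind, "degree": d, "best_hypergeom_p": best_p[(kind, node)]})
    nodes = pd.DataFrame(node_rows, columns=["node_id", "kind", "degree", "best_hypergeom_p"])
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "kind"]).drop_duplicates(
        ignore_index=True
    )
    if len(nodes):
        nodes = nodes.sort_values(
            ["kind", "degree", "best_hypergeom_p", "node_id"],
            ascending=[True, False, True, True],
            kind="mergesort",
            ignore_index=True,
        )
        edges = edges.sort_values(["kind", "source", "target"], kind="mergesort", ignore_index=True)

    def top(kinds: tuple[str, ...], limit: int) -> pd.DataFrame:
        sub = nodes[nodes["kind"].isin(kinds)].sort_values(
            ["degree", "best_hypergeom_p", "node_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        sub = sub.head(limit).reset_index(drop=True)
        if len(sub):
            sub.insert(0, "rank", range(1, len(sub) + 1))
        return sub

    return CeRNANetwork(
        nodes=nodes,
        edges=edges,
        top_cernas=top(("lncRNA", "circRNA"), top_cerna),
        top_mirnas=top(("miRNA",), top_mirna),
        n_pairs=int(len(passing)),
        members={
            "cernas": set(passing["cerna_id"]) if len(passing) else set(),
            "mrnas": set(passing["mrna_id"]) if len(passing) else set(),
        },
    )
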