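"""Hypergeometric over-representation analysis and BH adjustment.

The upper-tail hypergeometric probability P(X ≥ k) is the common statistic
behind both annotation-term enrichment of a DEG list and the shared-miRNA
sponge test: draw n genes from a universe of M containing K marked ones and
ask how surprising an overlap of k is.  By total probability P(X ≥ 0) = 1.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, M: int) -> float:
    """Upper-tail p-value P(X ≥ k), X ~ Hypergeometric(M, K, n).

    M: universe size, K: marked genes in the universe, n: draw (query) size,
    k: observed overlap.  Requires K ≤ M, n ≤ M, k ≤ min(n, K).
    """
    k, K, n, M = int(k), int(K), int(n), int(M)
    if M < 0:
        raise ValueError("M must be >= 0")
    if not 0 <= K <= M:
        raise ValueError(f"constraint violated: 0 <= K <= M (K={K}, M={M})")
    if not 0 <= n <= M:
        raise ValueError(f"constraint violated: 0 <= n <= M (n={n}, M={M})")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"constraint violated: 0 <= k <= min(n, K) (k={k}, n={n}, K={K})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def hypergeom_tail_vec(k: np.ndarray, K: np.ndarray, n: np.ndarray, M: int) -> np.ndarray:
    """Vectorized :func:`hypergeom_tail` for equal-length arrays (shared M)."""
    k = np.asarray(k, dtype=int)
    K = np.asarray(K, dtype=int)
    n = np.asarray(n, dtype=int)
    if (K > M).any() or (n > M).any() or (k > np.minimum(n, K)).any() or (k < 0).any():
        raise ValueError("hypergeometric constraints violated")
    p = stats.hypergeom.sf(k - 1, M, K, n)
    return np.where(k == 0, 1.0, p)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: set[str] | Iterable[str],
    background: set[str] | Iterable[str],
    sets: Mapping[str, set[str]],
    alpha: float = 0.05,
    top: int = 10,
    descriptions: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided over-representation of ``query`` against each gene set.

    Gene sets and the query are intersected with ``background`` (the universe
    M); query genes outside the background are dropped with a logged count.
    Returns one row per set sorted by p ascending (ties by set name):
    set_name, k, K, n, M, p_value, q_value, neg_log10_p, significant
    (p ≤ alpha), display (the ≤ ``top`` smallest-p rows, chart-ready).
    """
    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    query = set(query)
    dropped = len(query - background)
    if dropped:
        logger.info("dropped %d query genes absent from the background", dropped)
    query &= background

    M, n = len(background), len(query)
    rows = []
    for name in sorted(sets):
        members = set(sets[name]) & background
        K = len(members)
        k = len(members & query)
        p = hypergeom_tail(k, K, n, M)
        rows.append(
            {
                "set_name": name,
                "description": (descriptions or {}).get(name, ""),
                "k": k,
                "K": K,
                "n": n,
                "M": M,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "description", "k", "K", "n", "M", "p_value"]
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["neg_log10_p"] = -np.log10(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "set_name"], kind="mergesort", ignore_index=True)
        out["significant"] = out["p_value"] <= alpha
        out["display"] = np.arange(len(out)) < top
    return out
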