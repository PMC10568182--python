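"""Threshold-defined differential expression calling.

Per region, each gene is tested between injury (CCI) and sham samples:
log2 fold change from pseudocounted RPKM group means, p-value from Welch's
unequal-variance two-sample t-test on log2(RPKM + pseudocount).  A gene is
significant when p ≤ alpha AND |log2FC| ≥ log2(fc_cutoff) — the classic
"p ≤ 0.05 and fold change ≥ 2" joint filter.  BH q-values are reported as an
extra column but take no part in the headline filter.

Conventions for degenerate genes: both groups constant and equal → p = 1;
both constant but different → p = 0 (the Welch limit); fewer than two
replicates in either group → p is missing and the gene is excluded from
significance.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .expression import META_COLS


@dataclass(frozen=True)
class DETable:
    """One region's differential-expression calls with the thresholds used."""

    region: str
    alpha: float
    fc_cutoff: float
    pseudocount: float
    table: pd.DataFrame = field(repr=False)

    def significant_ids(self, direction: str | None = None, biotype: str | None = None) -> set[str]:
        t = self.table[self.table["significant"]]
        if direction is not None:
            t = t[t["direction"] == direction]
        if biotype is not None and "biotype" in t.columns:
            t = t[t["biotype"] == biotype]
        return set(t["gene_id"])

    def summary(self) -> pd.DataFrame:
        """Up/down significant counts per biotype (the headline table shape)."""
        sig = self.table[self.table["significant"]]
        if "biotype" not in sig.columns:
            sig = sig.assign(biotype="all")
        rows = []
        for bt, grp in sig.groupby("biotype", sort=False):
            rows.append(
                {
                    "region": self.region,
                    "biotype": bt,
                    "n_significant": len(grp),
                    "n_up": int((grp["direction"] == "up").sum()),
                    "n_down": int((grp["direction"] == "down").sum()),
                }
            )
        return pd.DataFrame(rows, columns=["region", "biotype", "n_significant", "n_up", "n_down"])


def _welch_log2(case: np.ndarray, ctrl: np.ndarray, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (log2fc, p) over gene rows; NaN p where a group has < 2 reps."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl, dtype=float))
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lfc = np.log2((case.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount))
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        return lfc, np.full(case.shape[0], np.nan)
    la = np.log2(case + pseudocount)
    lb = np.log2(ctrl + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    both_const = (va == 0) & (vb == 0)
    if both_const.any():
        equal = both_const & np.isclose(la[:, 0], lb[:, 0])
        p = np.where(both_const, np.where(equal, 1.0, 0.0), p)
    return lfc, p


def test_gene(
    case_values: np.ndarray, ctrl_values: np.ndarray, pseudocount: float = 1.0
) -> tuple[float, float]:
    """Single-gene (log2 fold change, Welch p) — see module docstring for the
    degenerate-input conventions.  p is NaN when either group has < 2 values."""
    lfc, p = _welch_log2(
        np.asarray(case_values, float)[None, :], np.asarray(ctrl_values, float)[None, :], pseudocount
    )
    return float(lfc[0]), float(p[0])


def call_de(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    region: str,
    alpha: float = 0.05,
    fc_cutoff: float = 2.0,
    pseudocount: float = 1.0,
) -> DETable:
    """Call DE genes for one region of an RPKM matrix.

    ``expr`` is the frame produced by :func:`cernakit.expression.compute_rpkm`
    (gene metadata columns plus one column per sample); ``design`` the sample
    table.  Both conditions must be present in the region.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1")
    sub = design[design["region"] == region]
    case_cols = sub.loc[sub["condition"] == "CCI", "sample_id"].tolist()
    ctrl_cols = sub.loc[sub["condition"] == "sham", "sample_id"].tolist()
    if not case_cols or not ctrl_cols:
        raise ValueError(f"region {region!r} lacks a CCI or sham condition in the design")
    missing = [c for c in case_cols + ctrl_cols if c not in expr.columns]
    if missing:
        raise ValueError(f"expression matrix missing sample columns {missing}")

    case = expr[case_cols].to_numpy(float)
    ctrl = expr[ctrl_cols].to_numpy(float)
    lfc, p = _welch_log2(case, ctrl, pseudocount)

    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])

    log2_cut = math.log2(fc_cutoff)
    significant = ok & (p <= alpha) & (np.abs(lfc) >= log2_cut)
    table = pd.DataFrame(
        {
            "gene_id": expr["gene_id"].to_numpy(),
            "region": region,
            "mean_case": case.mean(axis=1),
            "mean_ctrl": ctrl.mean(axis=1),
            "log2fc": lfc,
            "p_value": p,
            "q_value": q,
            "direction": np.where(lfc > 0, "up", "down"),
            "significant": significant,
        }
    )
    if "biotype" in expr.columns:
        table.insert(1, "biotype", expr["biotype"].to_numpy())
    return DETable(region=region, alpha=alpha, fc_cutoff=fc_cutoff, pseudocount=pseudocount, table=table)
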