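"""Expression normalization (RPKM) and the qPCR 2^-ΔΔCt ratio.

RPKM(g, s) = 1e9 · C(g, s) / (N_s · L_g) with N_s the per-sample column sum
over all genes in the supplied matrix and L_g the gene length in bases.  Using
the column sum as "total mapped reads" makes the computation self-contained
and order-independent; it is applied uniformly to every biotype (length
normalization of miRNA-sized genes is biologically moot but harmless, and the
synthetic generator treats miRNAs like any other gene).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

META_COLS = ("gene_id", "biotype", "length_bp")


def sample_columns(counts: pd.DataFrame) -> list[str]:
    """Sample columns of a count matrix = everything after the metadata columns."""
    return [c for c in counts.columns if c not in META_COLS]


def compute_rpkm(counts: pd.DataFrame, per_biotype: bool = False) -> pd.DataFrame:
    """Reads-per-kilobase-per-million normalization of a count matrix.

    Parameters
    ----------
    counts
        Frame with gene_id, biotype, length_bp and one integer column per
        sample.
    per_biotype
        If True, library sizes N_s are computed within each biotype panel
        instead of globally over all genes (default global).

    Returns a frame with gene_id, biotype, length_bp and RPKM columns in the
    same row and column order.  A sample whose total count is zero is an
    error (its RPKM is undefined).
    """
    samples = sample_columns(counts)
    if not samples:
        raise ValueError("count matrix has no sample columns")
    mat = counts[samples].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts")
    lengths = counts["length_bp"].to_numpy(dtype=float)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1")

    if per_biotype:
        rpkm = np.empty_like(mat)
        for bt, idx in counts.groupby("biotype", sort=False).indices.items():
            sub = mat[idx]
            totals = sub.sum(axis=0)
            zero = np.flatnonzero(totals == 0)
            if zero.size:
                raise ValueError(
                    f"sample {samples[zero[0]]!r} has zero total count in biotype {bt!r}"
                )
            rpkm[idx] = 1e9 * sub / (totals[None, :] * lengths[idx, None])
    else:
        totals = mat.sum(axis=0)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(f"sample {samples[zero[0]]!r} has zero total count")
        rpkm = 1e9 * mat / (totals[None, :] * lengths[:, None])

    out = counts[list(META_COLS)].copy()
    out[samples] = rpkm
    return out


def ddct_ratio(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression ratio by the 2^-ΔΔCt method.

    ΔCt = Ct(target) − Ct(reference housekeeping gene) within each group;
    ΔΔCt = ΔCt(case) − ΔCt(control); the ratio is 2^−ΔΔCt.  A target
    amplifying one cycle earlier in the case group (ΔΔCt = −1) doubles.
    """
    vals = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
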