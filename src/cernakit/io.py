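"""Plain-text readers/writers: TSV tables, GMT gene sets, ground truth.

All writers are deterministic (fixed column order, ``%.12g`` floats, ``\\n``
line endings) so a fixed seed reproduces byte-identical files.
"""
from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .synth import GroundTruth, Triplet

FLOAT_FMT = "%.12g"


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Count matrix TSV: gene_id, biotype, length_bp, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "biotype", "length_bp"):
        if col not in df.columns:
            raise ValueError(f"count matrix missing column {col!r}")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in count matrix")
    return df


def write_gmt(sets: dict[str, set[str]], path: str | os.PathLike, descriptions: dict[str, str] | None = None) -> None:
    """GMT: one line per set — name, description, tab-separated members."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *sorted(sets[name])]) + "\n")


def read_gmt(path: str | os.PathLike) -> tuple[dict[str, set[str]], dict[str, str]]:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            name, desc, *members = parts
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return sets, descriptions


def write_ground_truth(truth: GroundTruth, out_dir: str | os.PathLike) -> None:
    out = Path(out_dir)
    de = pd.DataFrame(
        [
            {"gene_id": g, "region": region, "planted_log2fc": lfc}
            for g, (region, lfc) in sorted(truth.de_genes.items())
        ],
        columns=["gene_id", "region", "planted_log2fc"],
    )
    write_tsv(de, out / "truth_de_genes.tsv")
    trip = pd.DataFrame(
        [
            {"mirna_id": t.mirna_id, "cerna_id": t.cerna_id, "mrna_id": t.mrna_id, "planted_r": t.planted_r}
            for t in truth.triplets
        ],
        columns=["mirna_id", "cerna_id", "mrna_id", "planted_r"],
    )
    write_tsv(trip, out / "truth_triplets.tsv")
    write_gmt(truth.set_membership, out / "truth_gene_sets.gmt")


def read_ground_truth(truth_dir: str | os.PathLike) -> GroundTruth:
    d = Path(truth_dir)
    truth = GroundTruth()
    de = read_tsv(d / "truth_de_genes.tsv")
    for rec in de.itertuples(index=False):
        truth.de_genes[rec.gene_id] = (rec.region, float(rec.planted_log2fc))
    trip = read_tsv(d / "truth_triplets.tsv")
    for rec in trip.itertuples(index=False):
        truth.triplets.append(Triplet(rec.mirna_id, rec.cerna_id, rec.mrna_id, float(rec.planted_r)))
    gmt = d / "truth_gene_sets.gmt"
    if gmt.exists():
        truth.set_membership, _ = read_gmt(gmt)
    return truth
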