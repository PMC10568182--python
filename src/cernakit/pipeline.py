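"""End-to-end orchestration: synth → RPKM → DE → set/enrichment/hub/ceRNA.

A :class:`RunConfig` (flat YAML key-value file, unknown keys rejected) drives
the whole analysis.  ``simulate`` writes the synthetic inputs; ``run``
executes every stage per region and writes deterministic TSV outputs plus a
``manifest.json`` echoing the configuration, the seed, and a sha256 checksum
and row count for every file; ``recover`` scores a finished run against the
planted ground truth (DE sensitivity/FDR, ceRNA recall and null pass rate).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cerna, diffexp, enrichment, io, ppi_hubs, setcompare, synth
from .expression import compute_rpkm

logger = logging.getLogger(__name__)

DISEASE_CATEGORIES = ("pain", "anxiety", "depression", "inflammation", "apoptosis", "immunity")


@dataclass
class RunConfig:
    """All tunables of a pipeline run.  Defaults mirror the two-region,
    two-condition study design (3 pooled samples per group) at a
    scaled-down transcriptome size."""

    seed: int = 0
    regions: tuple[str, ...] = synth.REGIONS
    replicates_per_cell: int = 3
    # synthetic-data shape
    n_mrna: int = 800
    n_lncrna: int = 400
    n_circrna: int = 300
    n_mirna: int = 100
    n_de: int = 200
    de_log2fc: float = 2.0
    de_region: str = "TG"
    dispersion: float = 0.05
    n_triplets: int = 10
    triplet_r: float = 0.8
    mirnas_per_triplet: int = 3
    n_mirna_regulators: int = 100
    targets_per_mirna: int = 20
    n_ppi_edges: int = 4000
    pain_set_size: int = 150
    category_size: int = 120
    category_overlap: int = 25
    # analysis thresholds
    alpha: float = 0.05
    fc_cutoff: float = 2.0
    pseudocount: float = 1.0
    hyper_alpha: float = 0.05
    ppc_min: float = 0.5
    ppc_alpha: float = 0.05
    require_de_mirna: bool = False
    rpkm_per_biotype: bool = False
    top_hubs: int = 50
    top_cerna: int = 10
    top_mirna: int = 2
    top_k_class: int = 15

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1 or not 0 <= self.hyper_alpha <= 1 or not 0 <= self.ppc_alpha <= 1:
            raise ValueError("alpha thresholds must be in [0, 1]")
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")
        if not -1 <= self.ppc_min <= 1:
            raise ValueError("ppc_min must be in [-1, 1]")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for nm in ("top_hubs", "top_cerna", "top_mirna", "top_k_class"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be >= 1")
        unknown = [r for r in self.regions if r not in synth.REGIONS]
        if unknown or self.de_region not in synth.REGIONS:
            raise ValueError(f"unknown region(s) {unknown or [self.de_region]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys {unknown}; known keys: {sorted(known)}")
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _n_rows(path: Path) -> int:
    with open(path) as fh:
        return max(sum(1 for _ in fh) - 1, 0)  # minus header for TSV; GMT has none


def simulate(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write all synthetic inputs; returns the file map."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss_children = [int(s) for s in np.random.SeedSequence(config.seed).generate_state(4) % (2**31)]
    design = synth.generate_design(config.replicates_per_cell, seed=config.seed)
    counts, truth = synth.generate_counts(
        design,
        n_per_biotype={
            "mRNA": config.n_mrna,
            "lncRNA": config.n_lncrna,
            "circRNA": config.n_circrna,
            "miRNA": config.n_mirna,
        },
        n_de=config.n_de,
        de_log2fc=config.de_log2fc,
        dispersion=config.dispersion,
        seed=ss_children[0],
        de_region=config.de_region,
        n_triplets=config.n_triplets,
        triplet_r=config.triplet_r,
        mirnas_per_triplet=config.mirnas_per_triplet,
    )
    targets = synth.generate_target_map(
        counts,
        n_mirna=min(config.n_mirna_regulators, config.n_mirna),
        targets_per_mirna=config.targets_per_mirna,
        triplets=truth.triplets,
        seed=ss_children[1],
    )
    non_mirna = counts.loc[counts["biotype"] != "miRNA", "gene_id"].tolist()
    categories = [("pain", config.pain_set_size)] + [
        (c, config.category_size) for c in DISEASE_CATEGORIES[1:]
    ]
    overlap_spec = {("pain", c): config.category_overlap for c in DISEASE_CATEGORIES[1:]}
    overlap_spec[("pain", "anxiety", "depression")] = max(config.category_overlap // 3, 1)
    overlap_spec[("pain", "apoptosis", "inflammation", "immunity")] = max(
        config.category_overlap // 3, 1
    )
    sets, descriptions = synth.generate_gene_sets(
        non_mirna, categories, overlap_spec, seed=ss_children[2]
    )
    truth.set_membership = sets
    mrna_ids = counts.loc[counts["biotype"] == "mRNA", "gene_id"].tolist()
    ppi = synth.generate_ppi_edges(mrna_ids, config.n_ppi_edges, seed=ss_children[3])

    files = {
        "design": out / "design.tsv",
        "counts": out / "counts.tsv",
        "targets": out / "targets.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "ppi_edges": out / "ppi_edges.tsv",
    }
    io.write_tsv(design, files["design"])
    io.write_tsv(counts, files["counts"])
    io.write_tsv(targets, files["targets"])
    io.write_gmt(sets, files["gene_sets"], descriptions)
    io.write_tsv(ppi, files["ppi_edges"])
    io.write_ground_truth(truth, out)
    return files


def run(
    config: RunConfig,
    out_dir: str | Path,
    inputs: dict[str, str | Path] | None = None,
) -> dict:
    """Execute the full pipeline; returns (and writes) the manifest.

    With ``inputs`` omitted, synthetic inputs are generated under
    ``out_dir/inputs`` first.  Stage failures abort with the stage name.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if inputs is None:
        inputs = simulate(config, out / "inputs")

    stage = "read-inputs"
    try:
        design = io.read_tsv(inputs["design"])
        counts = io.read_counts(inputs["counts"])
        targets = io.read_tsv(inputs["targets"])
        sets, descriptions = io.read_gmt(inputs["gene_sets"])
        ppi = io.read_tsv(inputs["ppi_edges"])

        stage = "rpkm"
        rpkm = compute_rpkm(counts, per_biotype=config.rpkm_per_biotype)
        io.write_tsv(rpkm, out / "rpkm.tsv")

        stage = "diffexp"
        de_tables: dict[str, diffexp.DETable] = {}
        summaries = []
        for region in config.regions:
            de = diffexp.call_de(
                rpkm, design, region,
                alpha=config.alpha, fc_cutoff=config.fc_cutoff, pseudocount=config.pseudocount,
            )
            de_tables[region] = de
            io.write_tsv(de.table, out / f"de_{region}.tsv")
            summaries.append(de.summary())
        io.write_tsv(pd.concat(summaries, ignore_index=True), out / "de_summary.tsv")

        stage = "setcompare"
        if len(config.regions) >= 2:
            a, b = config.regions[0], config.regions[1]
            overlap = setcompare.co_expression_overlap(de_tables[a], de_tables[b])
            io.write_tsv(overlap.counts, out / "coexpression_overlap.tsv")
        tuples = [
            ("pain", "anxiety", "depression"),
            ("pain", "apoptosis", "inflammation", "immunity"),
        ]
        tuples = [t for t in tuples if all(nm in sets for nm in t)]
        for region in config.regions:
            report = setcompare.map_to_categories(de_tables[region], sets, tuples=tuples)
            io.write_tsv(report.counts, out / f"categories_{region}.tsv")
            if "pain" in sets:
                top_tbl = setcompare.top_k_by_class(
                    de_tables[region], sets["pain"], k=config.top_k_class
                )
                io.write_tsv(top_tbl, out / f"top_class_pain_{region}.tsv")

        stage = "enrichment"
        background = set().union(*sets.values()) if sets else set()
        for region in config.regions:
            query = de_tables[region].significant_ids(biotype="mRNA")
            enr = enrichment.enrich(
                query, background, sets, alpha=config.alpha, top=config.top_cerna,
                descriptions=descriptions,
            )
            io.write_tsv(enr, out / f"enrichment_{region}.tsv")

        stage = "ppi_hubs"
        for region in config.regions:
            graph = ppi_hubs.induce_deg_subgraph(ppi, de_tables[region])
            hubs = ppi_hubs.select_hubs(graph, k=config.top_hubs)
            io.write_tsv(hubs, out / f"hubs_{region}.tsv")
            nodes, edges = ppi_hubs.graph_tables(graph)
            io.write_tsv(nodes, out / f"ppi_nodes_{region}.tsv")
            io.write_tsv(edges, out / f"ppi_edges_{region}.tsv")

        stage = "cerna"
        for region in config.regions:
            de_mirnas = (
                de_tables[region].significant_ids(biotype="miRNA")
                if config.require_de_mirna
                else None
            )
            pairs = cerna.call_pairs(
                de_tables[region], rpkm, design, region, targets,
                hyper_alpha=config.hyper_alpha, ppc_min=config.ppc_min,
                ppc_alpha=config.ppc_alpha, log_pseudocount=config.pseudocount,
                de_mirnas=de_mirnas,
            )
            io.write_tsv(pairs, out / f"cerna_pairs_{region}.tsv")
            net = cerna.build_network(pairs, top_cerna=config.top_cerna, top_mirna=config.top_mirna)
            io.write_tsv(net.nodes, out / f"cerna_nodes_{region}.tsv")
            io.write_tsv(net.edges, out / f"cerna_edges_{region}.tsv")
            io.write_tsv(net.top_cernas, out / f"cerna_top_cernas_{region}.tsv")
            io.write_tsv(net.top_mirnas, out / f"cerna_top_mirnas_{region}.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    truth_file = Path(inputs.get("design", ".")).parent / "truth_de_genes.tsv"
    recovery = None
    if truth_file.exists():
        recovery = recover(out, truth_file.parent, config=config)
        with open(out / "recovery.json", "w", newline="\n") as fh:
            json.dump(recovery, fh, indent=2, sort_keys=True)
            fh.write("\n")

    manifest = {
        "package": "cernakit",
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(config).items()},
        "files": {
            p.name: {"rows": _n_rows(p), "sha256": _sha256(p)}
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.suffix in {".tsv", ".gmt"}
        },
    }
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def recover(
    run_dir: str | Path,
    truth_dir: str | Path | None = None,
    config: RunConfig | None = None,
) -> dict:
    """Score a finished run against the planted ground truth.

    Reports, for the planted region: DE sensitivity, empirical FDR among DE
    calls, ceRNA recall over planted (ceRNA, mRNA) pairs, and the pass rate
    among non-planted candidate pairs (false-positive control).
    """
    run_dir = Path(run_dir)
    truth_dir = Path(truth_dir) if truth_dir is not None else run_dir / "inputs"
    truth = io.read_ground_truth(truth_dir)
    if config is None:
        manifest = json.loads((run_dir / "manifest.json").read_text())
        raw = dict(manifest["config"])
        raw["regions"] = tuple(raw["regions"])
        config = RunConfig(**raw)
    region = config.de_region

    de = io.read_tsv(run_dir / f"de_{region}.tsv")
    called = set(de.loc[de["significant"], "gene_id"])
    planted = {g for g, (r, _) in truth.de_genes.items() if r == region}
    sensitivity = len(called & planted) / len(planted) if planted else float("nan")
    fdr = len(called - planted) / len(called) if called else 0.0

    pairs = io.read_tsv(run_dir / f"cerna_pairs_{region}.tsv")
    planted_pairs = {(t.cerna_id, t.mrna_id) for t in truth.triplets}
    if len(pairs):
        key = list(zip(pairs["cerna_id"], pairs["mrna_id"]))
        is_planted = pd.Series([k in planted_pairs for k in key])
        passed = pairs["passes"].astype(bool)
        recall = (
            float((is_planted & passed).sum()) / len(planted_pairs) if planted_pairs else float("nan")
        )
        null_cand = (~is_planted).sum()
        null_pass_rate = float((~is_planted & passed).sum()) / null_cand if null_cand else 0.0
    else:
        recall = 0.0 if planted_pairs else float("nan")
        null_pass_rate = 0.0

    return {
        "region": region,
        "n_planted_de": len(planted),
        "n_called_de": len(called),
        "de_sensitivity": sensitivity,
        "de_fdr": fdr,
        "n_planted_pairs": len(planted_pairs),
        "n_candidate_pairs": int(len(pairs)),
        "cerna_recall": recall,
        "cerna_null_pass_rate": null_pass_rate,
    }
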