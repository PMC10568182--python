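"""Seeded synthetic data with known ground truth.

Emulates the two-region (trigeminal ganglion TG / subnucleus caudalis Sp5C),
two-condition (nerve-injury CCI / sham) bulk RNA-seq design: negative-binomial
counts over four biotypes (mRNA, lncRNA, circRNA, miRNA) with planted
differentially expressed genes and planted miRNA-sponge (ceRNA) triplets whose
ceRNA and mRNA log-expressions are positively correlated and concordantly
regulated.  Also generates the auxiliary inputs the downstream stages consume:
a miRNA→target interaction table, disease-category gene sets (GMT-style), and
a protein–protein interaction edge list.

All randomness flows from a single integer seed fanned out into per-stage
substreams via ``numpy.random.SeedSequence``; fixed seed ⇒ bit-identical
outputs.

Note on miRNAs: miRNA abundances are emitted in the same count matrix and
generated by the same model as the other biotypes.  This is a deliberate
simplification — in practice small RNAs require a separate library protocol,
and the provenance of miRNA differential expression in the motivating study
design is unspecified.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("TG", "Sp5C")
CONDITIONS = ("CCI", "sham")
BIOTYPES = ("mRNA", "lncRNA", "circRNA", "miRNA")

#: default gene-panel sizes: a scaled-down transcriptome with the same
#: biotype structure as a whole-transcriptome run
DEFAULT_N_PER_BIOTYPE = {"mRNA": 800, "lncRNA": 400, "circRNA": 300, "miRNA": 100}


@dataclass(frozen=True)
class Triplet:
    """A planted miRNA-sponge triplet: miRNA targets both the ceRNA and the mRNA."""

    mirna_id: str
    cerna_id: str
    mrna_id: str
    planted_r: float


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring.

    ``de_genes`` maps gene_id → (region, planted log2 fold change);
    ``triplets`` lists planted sponge triplets (their members are also in
    ``de_genes``); ``set_membership`` records the generated gene sets.
    """

    de_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    triplets: list[Triplet] = field(default_factory=list)
    set_membership: dict[str, set[str]] = field(default_factory=dict)

    def validate(self, counts: pd.DataFrame) -> None:
        """Referential integrity against a generated count matrix."""
        genes = set(counts["gene_id"])
        for g, (region, lfc) in self.de_genes.items():
            if g not in genes:
                raise ValueError(f"planted DE gene {g!r} absent from count matrix")
            if region not in REGIONS:
                raise ValueError(f"planted DE region {region!r} unknown")
            if abs(lfc) < 1:
                raise ValueError(f"planted |log2FC| < 1 for {g!r}")
        for t in self.triplets:
            for g in (t.mirna_id, t.cerna_id, t.mrna_id):
                if g not in genes:
                    raise ValueError(f"triplet member {g!r} absent from count matrix")


def generate_design(replicates_per_cell: int, seed: int = 0) -> pd.DataFrame:
    """Sample design table: 2 regions × 2 conditions × ``replicates_per_cell``.

    The layout is fully determined by the replicate count; ``seed`` is part of
    the signature for symmetry with the other generators and recorded by the
    pipeline, but draws nothing.
    """
    if replicates_per_cell < 1:
        raise ValueError("replicates_per_cell must be >= 1")
    rows = [
        {
            "sample_id": f"{region}_{condition}_{r}",
            "region": region,
            "condition": condition,
            "replicate": r,
        }
        for region in REGIONS
        for condition in CONDITIONS
        for r in range(1, replicates_per_cell + 1)
    ]
    return pd.DataFrame(rows)


def _gene_ids(n_per_biotype: dict[str, int]) -> tuple[list[str], list[str]]:
    ids, biotypes = [], []
    for bt in BIOTYPES:
        n = int(n_per_biotype.get(bt, 0))
        if n < 0:
            raise ValueError(f"negative gene count for biotype {bt!r}")
        ids.extend(f"{bt}_{i:05d}" for i in range(1, n + 1))
        biotypes.extend([bt] * n)
    return ids, biotypes


def generate_counts(
    design: pd.DataFrame,
    n_per_biotype: dict[str, int] | None = None,
    n_de: int = 200,
    de_log2fc: float = 2.0,
    dispersion: float = 0.05,
    seed: int = 0,
    de_region: str = "TG",
    n_triplets: int = 0,
    triplet_r: float = 0.8,
    mirnas_per_triplet: int = 3,
    length_range: tuple[int, int] = (200, 10_000),
    baseline_log_mean: float = math.log(200.0),
    baseline_log_sd: float = 1.0,
    bio_log_sd: float = 0.3,
    triplet_log_sd: float = 0.65,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial count matrix with planted DE genes and sponge triplets.

    Model: gene baselines mu_g ~ LogNormal(baseline_log_mean, baseline_log_sd);
    per-sample biological variation multiplies the mean by exp(sd·eps) with
    eps ~ N(0,1); counts ~ NB(mean mu, variance mu + dispersion·mu²).  Planted
    DE genes get their CCI-condition mean in ``de_region`` multiplied by
    2**log2fc (sign alternates up/down).  Planted triplets give the ceRNA and
    mRNA a shared per-sample latent factor sized so the expected Pearson
    correlation of their log-expressions ≈ ``triplet_r`` after counting noise
    (attenuation corrected per pair from the members' actual baselines);
    both members are planted DE in the same direction.  Sponge-pair members
    are drawn from the expressed stratum (baseline clamped to the median) —
    an effective ceRNA must be abundant enough to sequester miRNAs, and
    lowly expressed transcripts are routinely filtered before ceRNA analysis.  Each sponge pair is
    mediated by ``mirnas_per_triplet`` distinct miRNAs (one ground-truth
    triplet record per miRNA): a pair sharing a single miRNA is essentially
    undetectable by the shared-miRNA over-representation test, which is
    powered by multiple shared response elements — as in the biology.

    Returns the count matrix (gene_id, biotype, length_bp, one column per
    sample) and the :class:`GroundTruth`.
    """
    if n_per_biotype is None:
        n_per_biotype = dict(DEFAULT_N_PER_BIOTYPE)
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if de_region not in REGIONS:
        raise ValueError(f"unknown region {de_region!r}")
    if not -1.0 <= triplet_r <= 1.0:
        raise ValueError("triplet_r must be in [-1, 1]")

    gene_ids, biotypes = _gene_ids(n_per_biotype)
    genes = np.asarray(gene_ids)
    bt = np.asarray(biotypes)
    n_genes = len(genes)
    non_mirna = np.flatnonzero(bt != "miRNA")
    mirna_idx = np.flatnonzero(bt == "miRNA")

    if n_de < 0:
        raise ValueError("n_de must be >= 0")
    if n_de + 2 * n_triplets > len(non_mirna):
        raise ValueError(
            f"n_de={n_de} plus {2 * n_triplets} triplet members exceeds the "
            f"{len(non_mirna)} non-miRNA genes available"
        )
    if mirnas_per_triplet < 1:
        raise ValueError("mirnas_per_triplet must be >= 1")
    if n_triplets > 0 and len(mirna_idx) < n_triplets * mirnas_per_triplet:
        raise ValueError("not enough miRNA genes for the requested triplets")

    ss = np.random.SeedSequence(seed)
    r_len, r_base, r_pick, r_noise, r_nb = (np.random.default_rng(c) for c in ss.spawn(5))

    lengths = r_len.integers(length_range[0], length_range[1] + 1, size=n_genes)
    mu = r_base.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)

    # pick triplet members: ceRNAs alternate lncRNA/circRNA so both network
    # flavours are exercised, then mRNA partners and mediating miRNAs
    truth = GroundTruth()
    lnc_pool = list(np.flatnonzero(bt == "lncRNA"))
    circ_pool = list(np.flatnonzero(bt == "circRNA"))
    mrna_pool = list(np.flatnonzero(bt == "mRNA"))
    cer_idx: list[int] = []
    if n_triplets > 0:
        n_lnc = min((n_triplets + 1) // 2, len(lnc_pool))
        n_circ = n_triplets - n_lnc
        if n_circ > len(circ_pool):
            raise ValueError("not enough lncRNA/circRNA genes for the requested triplets")
        cer_idx = list(r_pick.choice(lnc_pool, size=n_lnc, replace=False)) + list(
            r_pick.choice(circ_pool, size=n_circ, replace=False)
        )
    mr_idx = list(r_pick.choice(mrna_pool, size=n_triplets, replace=False)) if n_triplets else []
    mi_idx = (
        list(r_pick.choice(mirna_idx, size=n_triplets * mirnas_per_triplet, replace=False))
        if n_triplets
        else []
    )

    reserved = set(cer_idx) | set(mr_idx)
    de_pool = np.asarray([i for i in non_mirna if i not in reserved])
    de_idx = np.sort(r_pick.choice(de_pool, size=n_de, replace=False)) if n_de else np.asarray([], int)
    de_sign = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    de_sign = r_pick.permutation(de_sign)

    lfc = np.zeros(n_genes)
    lfc[de_idx] = de_sign * de_log2fc
    trip_sign = np.where(r_pick.random(n_triplets) < 0.5, 1.0, -1.0)
    for t in range(n_triplets):
        lfc[cer_idx[t]] = trip_sign[t] * de_log2fc
        lfc[mr_idx[t]] = trip_sign[t] * de_log2fc

    for i in np.flatnonzero(lfc != 0):
        truth.de_genes[genes[i]] = (de_region, float(lfc[i]))
    for t in range(n_triplets):
        for j in range(mirnas_per_triplet):
            truth.triplets.append(
                Triplet(
                    genes[mi_idx[t * mirnas_per_triplet + j]],
                    genes[cer_idx[t]],
                    genes[mr_idx[t]],
                    float(triplet_r),
                )
            )

    samples = design["sample_id"].tolist()
    n_samples = len(samples)
    is_case = (
        (design["region"].to_numpy() == de_region) & (design["condition"].to_numpy() == "CCI")
    )

    # log-scale sample noise; triplet rows get a shared latent factor whose
    # weight is inflated by the analytic attenuation from counting noise so
    # the realized log-expression correlation lands near triplet_r
    eps = r_noise.normal(0.0, 1.0, size=(n_genes, n_samples))
    noise = bio_log_sd * eps
    if n_triplets > 0:
        mu_med = math.exp(baseline_log_mean)
        for i in set(cer_idx) | set(mr_idx):
            mu[i] = max(mu[i], mu_med)
        z = r_noise.normal(0.0, 1.0, size=(n_triplets, n_samples))
        # the sponge factor models condition-independent co-regulation:
        # center it within each (region, condition) cell so it cannot perturb
        # the planted fold changes, then restore unit variance
        cells = (design["region"] + "/" + design["condition"]).to_numpy()
        for cell in np.unique(cells):
            cols = cells == cell
            if cols.sum() > 1:
                zc = z[:, cols]
                zc = zc - zc.mean(axis=1, keepdims=True)
                sd = zc.std(axis=1, ddof=0, keepdims=True)
                z[:, cols] = np.where(sd > 0, zc / sd, zc)
        for t in range(n_triplets):
            mu_gm = math.sqrt(mu[cer_idx[t]] * mu[mr_idx[t]])
            atten = triplet_log_sd**2 / (triplet_log_sd**2 + dispersion + 1.0 / mu_gm)
            rho = float(np.clip(triplet_r / atten, -0.995, 0.995))
            # loading sqrt(|rho|) on the shared factor gives the pair a latent
            # correlation of exactly rho (sign carried by the mRNA member)
            a = math.sqrt(abs(rho))
            w = math.sqrt(1.0 - abs(rho))
            sgn = 1.0 if rho >= 0 else -1.0
            noise[cer_idx[t]] = triplet_log_sd * (a * z[t] + w * eps[cer_idx[t]])
            noise[mr_idx[t]] = triplet_log_sd * (sgn * a * z[t] + w * eps[mr_idx[t]])

    log_mu = np.log(mu)[:, None] + noise
    log_mu = log_mu + (lfc[:, None] * math.log(2.0)) * is_case[None, :]
    mean = np.exp(log_mu)
    size = 1.0 / dispersion
    p = size / (size + mean)
    counts = r_nb.negative_binomial(size, p)

    out = pd.DataFrame({"gene_id": genes, "biotype": bt, "length_bp": lengths})
    out[samples] = pd.DataFrame(counts, columns=samples)
    truth.validate(out)
    return out, truth


def generate_target_map(
    universe: pd.DataFrame,
    n_mirna: int,
    targets_per_mirna: int,
    triplets: list[Triplet] | tuple[Triplet, ...] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """miRNA → target interaction table (mirna_id, target_id, target_biotype).

    ``universe`` is a count matrix (or any frame with gene_id/biotype).  The
    first ``n_mirna`` miRNA-biotype genes act as regulators; each receives
    ``targets_per_mirna`` background targets sampled uniformly without
    replacement from the non-miRNA genes.  Every planted triplet contributes
    its two edges (miRNA→ceRNA, miRNA→mRNA).  Duplicate (miRNA, target) pairs
    are collapsed with a logged warning.
    """
    bt_map = dict(zip(universe["gene_id"], universe["biotype"]))
    mirnas = [g for g, b in bt_map.items() if b == "miRNA"][:n_mirna]
    if len(mirnas) < n_mirna:
        raise ValueError(f"universe holds only {len(mirnas)} miRNAs, {n_mirna} requested")
    pool = np.asarray([g for g, b in bt_map.items() if b != "miRNA"])
    if targets_per_mirna > len(pool):
        raise ValueError("targets_per_mirna exceeds the number of candidate target genes")
    for t in triplets:
        for g in (t.mirna_id, t.cerna_id, t.mrna_id):
            if g not in bt_map:
                raise ValueError(f"triplet member {g!r} not in universe")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows: list[tuple[str, str]] = []
    regulators = list(dict.fromkeys(mirnas + [t.mirna_id for t in triplets]))
    for m in regulators:
        if m in mirnas and targets_per_mirna > 0:
            rows.extend((m, g) for g in rng.choice(pool, size=targets_per_mirna, replace=False))
    for t in triplets:
        rows.append((t.mirna_id, t.cerna_id))
        rows.append((t.mirna_id, t.mrna_id))

    n_raw = len(rows)
    rows = list(dict.fromkeys(rows))
    if len(rows) < n_raw:
        logger.warning("collapsed %d duplicate (miRNA, target) pairs", n_raw - len(rows))
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id"]).sort_values(
        ["mirna_id", "target_id"], kind="mergesort", ignore_index=True
    )
    df["target_biotype"] = df["target_id"].map(bt_map)
    return df


def generate_gene_sets(
    universe: list[str] | np.ndarray,
    categories: list[tuple[str, int]],
    overlap_spec: dict[tuple[str, ...], int] | None = None,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Gene sets with exact sizes and exact specified overlaps.

    ``overlap_spec`` maps a tuple of ≥2 set names to a block size: that many
    fresh genes are shared by exactly those sets.  The pairwise overlap of two
    sets is the sum of blocks containing both; pairs mentioned in no block do
    not overlap.  Fill genes are drawn fresh from the universe so requested
    overlaps are exact.  Returns (sets, descriptions).
    """
    overlap_spec = dict(overlap_spec or {})
    names = [n for n, _ in categories]
    sizes = dict(categories)
    if len(set(names)) != len(names):
        raise ValueError("duplicate category names")
    universe = list(dict.fromkeys(map(str, universe)))

    for key, block in overlap_spec.items():
        key_t = (key,) if isinstance(key, str) else tuple(key)
        if len(key_t) < 2:
            raise ValueError(f"overlap key {key!r} must name at least two sets")
        for nm in key_t:
            if nm not in sizes:
                raise ValueError(f"overlap key {key!r} names unknown set {nm!r}")
        if block < 0:
            raise ValueError(f"negative overlap for {key!r}")
    committed = {nm: 0 for nm in names}
    for key, block in overlap_spec.items():
        for nm in key:
            committed[nm] += block
    for nm in names:
        if sizes[nm] < 0 or sizes[nm] > len(universe):
            raise ValueError(f"set {nm!r} size {sizes[nm]} outside [0, |universe|]")
        if committed[nm] > sizes[nm]:
            raise ValueError(
                f"infeasible overlap_spec: set {nm!r} needs {committed[nm]} shared "
                f"genes but has size {sizes[nm]}"
            )
    fresh_needed = sum(overlap_spec.values()) + sum(sizes[nm] - committed[nm] for nm in names)
    if fresh_needed > len(universe):
        raise ValueError(
            f"infeasible overlap_spec: {fresh_needed} distinct genes required, "
            f"universe has {len(universe)}"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    shuffled = list(rng.permutation(universe))
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        block = shuffled[cursor : cursor + n]
        cursor += n
        return block

    sets: dict[str, set[str]] = {nm: set() for nm in names}
    for key in sorted(overlap_spec, key=lambda k: tuple(k)):
        block = take(overlap_spec[key])
        for nm in key:
            sets[nm].update(block)
    for nm in names:
        sets[nm].update(take(sizes[nm] - len(sets[nm])))
        if sizes[nm] == 0:
            logger.warning("gene set %r generated empty", nm)

    descriptions = {nm: f"synthetic {nm} category (n={sizes[nm]})" for nm in names}
    return sets, descriptions


def generate_ppi_edges(gene_ids: list[str] | np.ndarray, n_edges: int, seed: int = 0) -> pd.DataFrame:
    """Random undirected interaction edge list (gene_a, gene_b), no self-loops
    or duplicate unordered pairs — a stand-in for a STRING-style export."""
    gene_ids = list(dict.fromkeys(map(str, gene_ids)))
    n = len(gene_ids)
    max_edges = n * (n - 1) // 2
    if n_edges < 0 or n_edges > max_edges:
        raise ValueError(f"n_edges must be in [0, {max_edges}]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_edges:
        draw = rng.integers(0, n, size=(max(64, 2 * (n_edges - len(seen))), 2))
        for a, b in draw:
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                if len(seen) == n_edges:
                    break
    pairs = sorted(seen)
    return pd.DataFrame(
        {"gene_a": [gene_ids[a] for a, _ in pairs], "gene_b": [gene_ids[b] for _, b in pairs]}
    )
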