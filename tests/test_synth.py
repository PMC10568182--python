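"""Generator contracts: design arithmetic, determinism, planted effects,
target-map structure, gene-set overlap exactness."""
import numpy as np
import pandas as pd
import pytest

import cernakit as ck


def test_design_arithmetic():
    d = ck.generate_design(3, seed=7)
    assert len(d) == 12
    assert d.groupby(["region", "condition"]).size().eq(3).all()
    assert d["sample_id"].is_unique
    d1 = ck.generate_design(1, seed=0)
    assert len(d1) == 4
    # replicate numbering dense from 1 within each cell
    for _, grp in d.groupby(["region", "condition"]):
        assert sorted(grp["replicate"]) == [1, 2, 3]


def test_design_rejects_nonpositive_replicates():
    with pytest.raises(ValueError):
        ck.generate_design(0)


def test_design_and_counts_deterministic():
    d1 = ck.generate_design(3, seed=7)
    d2 = ck.generate_design(3, seed=7)
    pd.testing.assert_frame_equal(d1, d2)
    kw = dict(
        n_per_biotype={"mRNA": 50, "lncRNA": 20, "circRNA": 10, "miRNA": 20},
        n_de=10,
        n_triplets=2,
        seed=42,
    )
    c1, t1 = ck.generate_counts(d1, **kw)
    c2, t2 = ck.generate_counts(d2, **kw)
    pd.testing.assert_frame_equal(c1, c2)
    assert t1.de_genes == t2.de_genes
    assert t1.triplets == t2.triplets


def test_counts_schema_and_truth_integrity(small_dataset, small_design):
    counts, truth = small_dataset["counts"], small_dataset["truth"]
    samples = small_design["sample_id"].tolist()
    assert list(counts.columns[:3]) == ["gene_id", "biotype", "length_bp"]
    assert list(counts.columns[3:]) == samples
    assert (counts[samples].to_numpy() >= 0).all()
    assert counts["length_bp"].between(200, 10_000).all()
    truth.validate(counts)  # every planted entry resolvable
    assert all(abs(lfc) >= 1 for _, lfc in truth.de_genes.values())


def test_null_generator_log2fc_shrinks_with_replicates():
    panels = {"mRNA": 300, "lncRNA": 0, "circRNA": 0, "miRNA": 0}
    spreads = []
    for reps in (3, 9):
        d = ck.generate_design(reps, seed=1)
        c, _ = ck.generate_counts(d, panels, n_de=0, seed=1)
        de = ck.call_de(ck.compute_rpkm(c), d, "TG")
        spreads.append(de.table["log2fc"].abs().mean())
    assert spreads[1] < spreads[0]


def test_planted_fold_change_realized_within_factor_two():
    # planted log2fc = 2 → group-mean ratio within [2, 8] (factor 2 of 4)
    panels = {"mRNA": 200, "lncRNA": 0, "circRNA": 0, "miRNA": 0}
    for seed in range(5):
        d = ck.generate_design(9, seed=seed)
        c, truth = ck.generate_counts(d, panels, n_de=20, de_log2fc=2.0, seed=seed)
        case = [s for s in c.columns if s.startswith("TG_CCI")]
        ctrl = [s for s in c.columns if s.startswith("TG_sham")]
        sub = c[c["gene_id"].isin(truth.de_genes)]
        ratio = (sub[case].mean(axis=1) + 1) / (sub[ctrl].mean(axis=1) + 1)
        signed = np.where(
            [truth.de_genes[g][1] > 0 for g in sub["gene_id"]], ratio, 1 / ratio
        )
        assert ((signed >= 2) & (signed <= 8)).mean() >= 0.9


def test_null_fraction_near_nominal_level(small_design):
    fracs = []
    for seed in range(5):
        d = ck.generate_design(9, seed=seed)
        c, _ = ck.generate_counts(
            d, {"mRNA": 400, "lncRNA": 0, "circRNA": 0, "miRNA": 0}, n_de=0, seed=seed
        )
        de = ck.call_de(ck.compute_rpkm(c), d, "TG")
        fracs.append(de.table["significant"].mean())
    assert np.median(fracs) < 0.05


def test_target_map_structure(small_dataset):
    counts, truth = small_dataset["counts"], small_dataset["truth"]
    tm = small_dataset["targets"]
    # planted triplets appear as both edges
    pairs = set(zip(tm["mirna_id"], tm["target_id"]))
    for t in truth.triplets:
        assert (t.mirna_id, t.cerna_id) in pairs
        assert (t.mirna_id, t.mrna_id) in pairs
        shared, k = ck.shared_mirnas(tm, t.cerna_id, t.mrna_id)
        assert t.mirna_id in shared and k >= 1
    assert not tm.duplicated(["mirna_id", "target_id"]).any()
    assert (tm["target_biotype"] != "miRNA").all()


def test_target_map_exact_background_size_and_determinism(small_dataset):
    counts = small_dataset["counts"]
    tm1 = ck.generate_target_map(counts, n_mirna=10, targets_per_mirna=5, seed=3)
    tm2 = ck.generate_target_map(counts, n_mirna=10, targets_per_mirna=5, seed=3)
    assert len(tm1) == 50
    pd.testing.assert_frame_equal(tm1, tm2)


def test_target_map_single_triplet_no_background(small_dataset):
    counts, truth = small_dataset["counts"], small_dataset["truth"]
    t = truth.triplets[0]
    tm = ck.generate_target_map(counts, n_mirna=0, targets_per_mirna=0, triplets=[t], seed=0)
    assert len(tm) == 2


def test_gene_sets_exact_sizes_and_overlaps():
    universe = [f"g{i}" for i in range(100)]
    sets, _ = ck.generate_gene_sets(
        universe, [("A", 10), ("B", 10), ("C", 5)], {("A", "B"): 4}, seed=2
    )
    assert len(sets["A"]) == 10 and len(sets["B"]) == 10 and len(sets["C"]) == 5
    assert len(sets["A"] & sets["B"]) == 4
    assert not sets["C"] & (sets["A"] | sets["B"])


def test_gene_sets_multiway_block():
    universe = [f"g{i}" for i in range(60)]
    sets, _ = ck.generate_gene_sets(
        universe, [("A", 12), ("B", 12), ("C", 12)], {("A", "B", "C"): 3, ("A", "B"): 2}, seed=4
    )
    assert len(sets["A"] & sets["B"] & sets["C"]) == 3
    assert len(sets["A"] & sets["B"]) == 5  # triple block + pair block


def test_gene_sets_empty_set_retained_and_infeasible_errors():
    universe = [f"g{i}" for i in range(30)]
    sets, _ = ck.generate_gene_sets(universe, [("E", 0)], seed=1)
    assert sets["E"] == set()
    with pytest.raises(ValueError, match="infeasible"):
        ck.generate_gene_sets(universe, [("A", 10), ("B", 10)], {("A", "B"): 11}, seed=1)
    with pytest.raises(ValueError):
        ck.generate_gene_sets(universe, [("A", 31)], seed=1)


def test_counts_rejects_overfull_de_request(small_design):
    with pytest.raises(ValueError):
        ck.generate_counts(
            small_design, {"mRNA": 10, "lncRNA": 0, "circRNA": 0, "miRNA": 0}, n_de=11
        )


def test_ppi_edges_unique_undirected():
    edges = ck.generate_ppi_edges([f"g{i}" for i in range(30)], 50, seed=9)
    assert len(edges) == 50
    assert (edges["gene_a"] != edges["gene_b"]).all()
    keys = {frozenset(e) for e in zip(edges["gene_a"], edges["gene_b"])}
    assert len(keys) == 50
    with pytest.raises(ValueError):
        ck.generate_ppi_edges(["a", "b"], 2)
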