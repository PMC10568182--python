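"""ceRNA pair calling and network assembly: oracles and threshold logic."""
import numpy as np
import pandas as pd
import pytest

import cernakit as ck
from cernakit.cerna import build_network, call_pairs, pearson_with_p, shared_mirnas
from cernakit.enrichment import hypergeom_tail


def make_targets(pairs):
    df = pd.DataFrame(pairs, columns=["mirna_id", "target_id"])
    df["target_biotype"] = ["lncRNA" if t.startswith("L") else "mRNA" for t in df["target_id"]]
    return df


def test_shared_mirnas_examples():
    tm = make_targets([("miR-1", "L1"), ("miR-1", "M1"), ("miR-2", "L1")])
    shared, k = shared_mirnas(tm, "L1", "M1")
    assert shared == {"miR-1"} and k == 1
    shared, k = shared_mirnas(tm, "L1", "M9")
    assert shared == set() and k == 0


def test_shared_mirnas_matches_brute_force(small_dataset):
    tm = small_dataset["targets"]
    by_gene = {}
    for m, g in zip(tm["mirna_id"], tm["target_id"]):
        by_gene.setdefault(g, set()).add(m)
    genes = sorted(by_gene)[:12]
    for a in genes:
        for b in genes:
            shared, k = shared_mirnas(tm, a, b)
            assert shared == by_gene[a] & by_gene[b]
            assert k == len(shared)


def test_pearson_perfect_and_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    r, p = pearson_with_p(x, 2 * x + 1)
    assert r == pytest.approx(1.0) and p < 1e-8
    r, _ = pearson_with_p(x, -x)
    assert r == pytest.approx(-1.0)
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
    r, p = pearson_with_p(x, y)
    # covariance-formula oracle
    r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(r_oracle, abs=1e-12)


def test_pearson_rejects_zero_variance_and_short():
    with pytest.raises(ValueError):
        pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson_with_p([1.0, 2.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def planted_run():
    design = ck.generate_design(9, seed=21)
    counts, truth = ck.generate_counts(
        design,
        {"mRNA": 300, "lncRNA": 150, "circRNA": 100, "miRNA": 60},
        n_de=150,
        seed=21,
        n_triplets=8,
        triplet_r=0.8,
    )
    targets = ck.generate_target_map(counts, 60, 10, truth.triplets, seed=21)
    rpkm = ck.compute_rpkm(counts)
    de = ck.call_de(rpkm, design, "TG")
    pairs = call_pairs(de, rpkm, design, "TG", targets)
    return design, truth, targets, rpkm, de, pairs


def test_call_pairs_recovers_planted_majority(planted_run):
    _, truth, _, _, _, pairs = planted_run
    planted = {(t.cerna_id, t.mrna_id) for t in truth.triplets}
    passed = {
        (a, b) for a, b, ok in zip(pairs["cerna_id"], pairs["mrna_id"], pairs["passes"]) if ok
    }
    assert len(passed & planted) / len(planted) >= 0.75
    assert pairs.attrs["mode"] == "correlation"


def test_call_pairs_hypergeom_matches_scalar_tail(planted_run):
    _, _, _, _, _, pairs = planted_run
    for rec in pairs.head(50).itertuples(index=False):
        assert rec.hypergeom_p == pytest.approx(
            hypergeom_tail(rec.k_shared, rec.K, rec.n, rec.M), abs=1e-15
        )
        assert rec.k_shared == len(str(rec.shared_mirnas).split(";"))


def test_call_pairs_ppc_matches_residual_pearson(planted_run):
    design, _, _, rpkm, _, pairs = planted_run
    sub = design[design["region"] == "TG"]
    cols = sub["sample_id"].tolist()
    cond = sub["condition"].to_numpy()
    mat = rpkm.set_index("gene_id")
    for rec in pairs.head(10).itertuples(index=False):
        x = np.log2(mat.loc[rec.cerna_id, cols].to_numpy(float) + 1)
        y = np.log2(mat.loc[rec.mrna_id, cols].to_numpy(float) + 1)
        for c in np.unique(cond):
            x[cond == c] -= x[cond == c].mean()
            y[cond == c] -= y[cond == c].mean()
        r_ref, _ = pearson_with_p(x, y)
        assert rec.ppc == pytest.approx(r_ref, abs=1e-10)


def test_discordant_pairs_never_pass(planted_run):
    _, _, _, _, _, pairs = planted_run
    assert not pairs.loc[~pairs["concordant"], "passes"].any()


def test_anticorrelated_planted_pair_never_passes():
    design = ck.generate_design(9, seed=31)
    counts, truth = ck.generate_counts(
        design,
        {"mRNA": 100, "lncRNA": 50, "circRNA": 30, "miRNA": 30},
        n_de=40,
        seed=31,
        n_triplets=4,
        triplet_r=-0.8,
    )
    targets = ck.generate_target_map(counts, 30, 5, truth.triplets, seed=31)
    rpkm = ck.compute_rpkm(counts)
    de = ck.call_de(rpkm, design, "TG")
    pairs = call_pairs(de, rpkm, design, "TG", targets)
    planted = {(t.cerna_id, t.mrna_id) for t in truth.triplets}
    hit = pairs[[(a, b) in planted for a, b in zip(pairs["cerna_id"], pairs["mrna_id"])]]
    assert not hit["passes"].any()
    assert (hit["ppc"] < 0.5).all()


def test_threshold_tightening_is_monotone(planted_run):
    design, _, targets, rpkm, de, base = planted_run
    base_pass = set(zip(*(base.loc[base["passes"], ["cerna_id", "mrna_id"]].T.values)))
    for kw in [
        {"hyper_alpha": 0.01},
        {"ppc_min": 0.7},
        {"ppc_alpha": 0.01},
        {"hyper_alpha": 0.01, "ppc_min": 0.8, "ppc_alpha": 0.001},
    ]:
        tighter = call_pairs(de, rpkm, design, "TG", targets, **kw)
        tp = set(zip(*(tighter.loc[tighter["passes"], ["cerna_id", "mrna_id"]].T.values)))
        assert tp <= base_pass


def test_degenerate_mode_without_replicates():
    design = ck.generate_design(1, seed=41)  # 2 samples per region
    counts, truth = ck.generate_counts(
        design,
        {"mRNA": 100, "lncRNA": 50, "circRNA": 30, "miRNA": 30},
        n_de=40,
        seed=41,
        n_triplets=3,
    )
    targets = ck.generate_target_map(counts, 30, 5, truth.triplets, seed=41)
    rpkm = ck.compute_rpkm(counts)
    de = ck.call_de(rpkm, design, "TG", alpha=1.0)  # p unavailable at n=1 → alpha irrelevant
    # with single replicates p is missing, nothing is significant
    assert not de.table["significant"].any()


def test_empty_target_map_errors(planted_run):
    design, _, _, rpkm, de, _ = planted_run
    with pytest.raises(ValueError):
        call_pairs(de, rpkm, design, "TG", pd.DataFrame(columns=["mirna_id", "target_id"]))


def test_network_single_pair_counts():
    pairs = pd.DataFrame(
        [
            {
                "cerna_id": "L1",
                "cerna_biotype": "lncRNA",
                "mrna_id": "M1",
                "k_shared": 1,
                "K": 1,
                "n": 1,
                "M": 10,
                "shared_mirnas": "miR-1",
                "hypergeom_p": 0.01,
                "ppc": 0.9,
                "ppc_p": 0.001,
                "concordant": True,
                "passes": True,
            }
        ]
    )
    net = build_network(pairs)
    assert len(net.nodes) == 3
    assert (net.nodes["degree"] == 1).all()
    assert net.n_pairs == 1
    kinds = net.edges["kind"].tolist()
    assert sorted(kinds) == ["cerna-mrna", "mirna-cerna", "mirna-mrna"]


def test_network_degree_equals_incidence_oracle(planted_run):
    _, _, _, _, _, pairs = planted_run
    net = build_network(pairs, top_cerna=10, top_mirna=2)
    passing = pairs[pairs["passes"]]
    # side-degree identity
    cer_deg = net.nodes[net.nodes["kind"].isin(["lncRNA", "circRNA"])]["degree"].sum()
    mr_deg = net.nodes[net.nodes["kind"] == "mRNA"]["degree"].sum()
    assert cer_deg == mr_deg == len(passing)
    # incidence-count oracle per node
    for rec in net.nodes.itertuples(index=False):
        if rec.kind == "mRNA":
            assert rec.degree == (passing["mrna_id"] == rec.node_id).sum()
        elif rec.kind in ("lncRNA", "circRNA"):
            assert rec.degree == (passing["cerna_id"] == rec.node_id).sum()
        else:
            assert rec.degree == passing["shared_mirnas"].str.split(";").apply(
                lambda ms: rec.node_id in ms
            ).sum()
    assert len(net.top_mirnas) <= 2 and len(net.top_cernas) <= 10
    if len(net.top_cernas) > 1:
        assert net.top_cernas["degree"].is_monotonic_decreasing


def test_network_invariant_to_pair_order(planted_run):
    _, _, _, _, _, pairs = planted_run
    net1 = build_network(pairs)
    net2 = build_network(pairs.sample(frac=1, random_state=9).reset_index(drop=True))
    pd.testing.assert_frame_equal(net1.nodes, net2.nodes)
    pd.testing.assert_frame_equal(net1.edges, net2.edges)


def test_cerna_degree_four_ranks_first():
    rows = []
    for i in range(4):
        rows.append(
            {
                "cerna_id": "L1",
                "cerna_biotype": "lncRNA",
                "mrna_id": f"M{i}",
                "k_shared": 1,
                "K": 2,
                "n": 2,
                "M": 20,
                "shared_mirnas": "miR-9",
                "hypergeom_p": 0.02,
                "ppc": 0.8,
                "ppc_p": 0.01,
                "concordant": True,
                "passes": True,
            }
        )
    rows.append(dict(rows[0], cerna_id="L2", mrna_id="M9"))
    net = build_network(pd.DataFrame(rows))
    assert net.top_cernas.loc[0, "node_id"] == "L1"
    assert net.top_cernas.loc[0, "degree"] == 4
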