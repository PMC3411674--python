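import math

import pandas as pd
import pytest

from vakgbm import (
    BindingTable,
    build_cognate_network,
    inverse_pairs,
    rank_score,
    select_signature,
)
from vakgbm.markers import MarkerResult


def binding_of(rows):
    return BindingTable(
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n_algorithms"])
    )


def markers_of(rows, top):
    """rows: (feature_id, kind, p, fold). top: {(class, kind): ids}."""
    table = pd.DataFrame(
        [
            {
                "feature_id": fid,
                "kind": kind,
                "stat": math.copysign(1.0, fold),
                "p": p,
                "q": p,
                "fold_regulation": fold,
                "up_in": "VAK-A" if fold > 0 else "VAK-B",
            }
            for fid, kind, p, fold in rows
        ]
    )
    return MarkerResult(table=table, top=top)


class TestRankScore:
    def test_worked_product_for_gene(self):
        # -log10(0.01)=2; 2 * 2 * 5 * 3 = 60
        assert rank_score(0.01, +2.0, 5.0, 3, "gene") == pytest.approx(60.0)

    def test_mirna_sign_is_negative(self):
        assert rank_score(0.01, +2.0, 5.0, 3, "microRNA") == pytest.approx(-60.0)

    def test_unconnected_molecule_scores_zero(self):
        assert rank_score(0.01, 2.0, 5.0, 0, "gene") == 0.0

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            rank_score(0.0, 2.0, 5.0, 3, "gene")

    def test_magnitude_monotone_in_each_factor(self):
        base = abs(rank_score(0.01, 2.0, 5.0, 3, "gene"))
        assert abs(rank_score(0.001, 2.0, 5.0, 3, "gene")) >= base
        assert abs(rank_score(0.01, 3.0, 5.0, 3, "gene")) >= base
        assert abs(rank_score(0.01, 2.0, 6.0, 3, "gene")) >= base
        assert abs(rank_score(0.01, 2.0, 5.0, 4, "gene")) >= base


class TestInversePairs:
    def test_inverse_pair_in_binding_emits_edge(self):
        genes = pd.DataFrame({"feature_id": ["G1"], "fold_regulation": [2.0]})
        mirnas = pd.DataFrame({"feature_id": ["m1"], "fold_regulation": [-2.0]})
        edges = inverse_pairs(genes, mirnas, binding_of([("m1", "G1", 5)]))
        assert edges == [("m1", "G1", 5)]

    def test_concordant_pair_emits_nothing(self):
        genes = pd.DataFrame({"feature_id": ["G1"], "fold_regulation": [2.0]})
        mirnas = pd.DataFrame({"feature_id": ["m1"], "fold_regulation": [2.0]})
        assert inverse_pairs(genes, mirnas, binding_of([("m1", "G1", 5)])) == []

    def test_pair_absent_from_binding_emits_nothing(self):
        genes = pd.DataFrame({"feature_id": ["G1"], "fold_regulation": [2.0]})
        mirnas = pd.DataFrame({"feature_id": ["m1"], "fold_regulation": [-2.0]})
        assert inverse_pairs(genes, mirnas, binding_of([("m1", "G2", 5)])) == []


def planted_markers(n_mir=3, n_gene=9, cls="VAK-A"):
    sign = 1.0 if cls == "VAK-A" else -1.0
    mir_ids = [f"m{cls[-1]}{i}" for i in range(n_mir)]
    gene_ids = [f"G{cls[-1]}{i}" for i in range(n_gene)]
    rows = [(m, "microRNA", 0.001, -sign * 2.0) for m in mir_ids] + [
        (g, "gene", 0.001, sign * 2.0) for g in gene_ids
    ]
    top = {
        (cls, "microRNA"): mir_ids,
        (cls, "gene"): gene_ids,
        ("VAK-A" if cls == "VAK-B" else "VAK-B", "microRNA"): [],
        ("VAK-A" if cls == "VAK-B" else "VAK-B", "gene"): [],
    }
    edges = [(m, g, 5) for m in mir_ids for g in gene_ids]
    return markers_of(rows, top), binding_of(edges), mir_ids, gene_ids


class TestCognateNetwork:
    def test_fully_connected_module_has_all_molecules(self):
        mk, binding, mirs, genes = planted_markers()
        net = build_cognate_network(mk, binding, "VAK-A")
        assert len(net.nodes) == 12
        assert len(net.edges) == 27
        by_id = {n.feature_id: n for n in net.nodes}
        # node degree equals n_targets
        for m in mirs:
            assert by_id[m].n_targets == 9
        for g in genes:
            assert by_id[g].n_targets == 3
        # bipartite: every edge joins a miRNA and a gene
        for m, g, _ in net.edges:
            assert by_id[m].kind == "microRNA" and by_id[g].kind == "gene"

    def test_sign_convention_on_nodes(self):
        mk, binding, _, _ = planted_markers()
        net = build_cognate_network(mk, binding, "VAK-A")
        for node in net.nodes:
            if node.kind == "microRNA":
                assert node.rank_score <= 0
            else:
                assert node.rank_score >= 0

    def test_empty_binding_gives_empty_module(self):
        mk, _, _, _ = planted_markers()
        net = build_cognate_network(mk, binding_of([]), "VAK-A")
        assert net.nodes == [] and net.edges == []

    def test_deleting_edge_never_raises_any_score(self):
        mk, binding, _, _ = planted_markers()
        full = {
            n.feature_id: abs(n.rank_score)
            for n in build_cognate_network(mk, binding, "VAK-A").nodes
        }
        smaller = binding_of(list(binding.pairs.itertuples(index=False))[1:])
        pruned = build_cognate_network(mk, smaller, "VAK-A")
        for node in pruned.nodes:
            assert abs(node.rank_score) <= full[node.feature_id] + 1e-12

    def test_strength_is_mean_over_distinct_partners(self):
        rows = [
            ("m1", "microRNA", 0.01, -2.0),
            ("G1", "gene", 0.01, 2.0),
            ("G2", "gene", 0.01, 2.0),
        ]
        top = {
            ("VAK-A", "microRNA"): ["m1"],
            ("VAK-A", "gene"): ["G1", "G2"],
            ("VAK-B", "microRNA"): [],
            ("VAK-B", "gene"): [],
        }
        mk = markers_of(rows, top)
        net = build_cognate_network(mk, binding_of([("m1", "G1", 4), ("m1", "G2", 8)]), "VAK-A")
        m1 = next(n for n in net.nodes if n.feature_id == "m1")
        assert m1.binding_strength == pytest.approx(6.0)
        assert m1.n_targets == 2
        net_sum = build_cognate_network(
            mk, binding_of([("m1", "G1", 4), ("m1", "G2", 8)]), "VAK-A", strength_mode="sum"
        )
        m1s = next(n for n in net_sum.nodes if n.feature_id == "m1")
        assert m1s.binding_strength == pytest.approx(12.0)


class TestSelectSignature:
    def test_default_sizes_give_25_molecules(self):
        mkA, bindA, _, _ = planted_markers(3, 9, "VAK-A")
        mkB, bindB, _, _ = planted_markers(5, 8, "VAK-B")
        netA = build_cognate_network(mkA, bindA, "VAK-A")
        netB = build_cognate_network(mkB, bindB, "VAK-B")
        set_A, set_B = select_signature(netA, netB)
        assert len(set_A) == 12 and len(set_B) == 13
        assert not set(set_A) & set(set_B)

    def test_zero_size_gives_empty_set(self):
        mkA, bindA, _, _ = planted_markers(3, 9, "VAK-A")
        netA = build_cognate_network(mkA, bindA, "VAK-A")
        set_A, set_B = select_signature(netA, netA, size_A=0, size_B=1)
        assert set_A == [] and len(set_B) == 1

    def test_deficit_reported_when_module_too_small(self):
        mkA, bindA, _, _ = planted_markers(1, 2, "VAK-A")
        netA = build_cognate_network(mkA, bindA, "VAK-A")
        with pytest.raises(ValueError, match="deficit"):
            select_signature(netA, netA, size_A=12, size_B=13)

    def test_boundary_tie_broken_by_fold_then_id(self):
        # two genes with identical rank scores: higher |fold| wins, then lexicographic
        rows = [
            ("m1", "microRNA", 0.01, -2.0),
            ("GA", "gene", 0.01, 2.0),
            ("GB", "gene", 0.01, 2.0),
            ("GC", "gene", 0.1, 4.0),   # tie in |score| with GA/GB? no - distinct p
        ]
        top = {
            ("VAK-A", "microRNA"): ["m1"],
            ("VAK-A", "gene"): ["GA", "GB", "GC"],
            ("VAK-B", "microRNA"): [],
            ("VAK-B", "gene"): [],
        }
        mk = markers_of(rows, top)
        binding = binding_of([("m1", "GA", 5), ("m1", "GB", 5), ("m1", "GC", 5)])
        net = build_cognate_network(mk, binding, "VAK-A")
        # GA and GB tie exactly (same p, fold, strength, degree): id order decides
        module_ids = [n.feature_id for n in net.module if n.kind == "gene"]
        assert module_ids.index("GA") < module_ids.index("GB")
        # determinism: rebuilding gives the same order
        again = build_cognate_network(mk, binding, "VAK-A")
        assert [n.feature_id for n in again.module] == [n.feature_id for n in net.module]
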