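"""Layer inference, hierarchy assembly, summaries, scoring, serialization."""

import numpy as np
import pytest

from pcgrn import (
    Edge,
    GeneCatalog,
    HierarchicalGRN,
    ProcessMap,
    ThresholdConfig,
    build_hierarchical_grn,
    infer_layer,
    score_recovery,
    summarize_grn,
)
from pcgrn.builder import (
    read_graphml,
    read_grn,
    read_sif,
    write_edge_tsv,
    write_graphml,
    write_layers_tsv,
    write_sif,
)
from pcgrn.simulate import (
    generate_planted_network,
    make_gene_catalog,
    simulate_expression,
)

from conftest import matrix_from_array


def small_grn():
    return HierarchicalGRN(
        layers=[{"T1"}, {"M1", "M2"}, {"B1", "B2", "B3", "B4"}],
        edges=[
            Edge("T1", "M1"),
            Edge("T1", "M2"),
            Edge("M1", "B1"),
            Edge("M1", "B2"),
            Edge("M2", "B2"),
            Edge("M2", "B3"),
            Edge("M2", "B4"),
        ],
        unplaced_regulators={"U1"},
    )


class TestInferLayer:
    def test_planted_driver_assigned(self, rng):
        n = 24
        z = rng.normal(size=n)
        x = z + 0.05 * rng.normal(size=n)
        y = z + 0.05 * rng.normal(size=n)
        w = rng.normal(size=n)
        m = matrix_from_array(np.vstack([x, y, z, w]),
                              gene_ids=["A", "B", "Z", "W"])
        assigned, edges = infer_layer(["A", "B"], ["Z", "W"], m)
        assert assigned == {"Z"}
        assert {e.key for e in edges} == {("Z", "A"), ("Z", "B")}
        assert all(e.n_supporting_pairs == 1 for e in edges)

    def test_no_candidates(self, rng):
        base = rng.normal(size=10)
        m = matrix_from_array(
            np.vstack([base, base + 0.01 * rng.normal(size=10)]),
            gene_ids=["A", "B"],
        )
        assert infer_layer(["A", "B"], [], m) == (set(), [])

    def test_uncorrelated_bottom_yields_nothing(self, rng):
        m = matrix_from_array(rng.normal(size=(5, 20)))
        genes = m.gene_ids
        assigned, edges = infer_layer(genes[:4], genes[4:], m)
        assert assigned == set() and edges == []

    def test_single_gene_bottom_warns(self, rng):
        m = matrix_from_array(rng.normal(size=(2, 10)), gene_ids=["A", "Z"])
        with pytest.warns(UserWarning, match="< 2 genes"):
            assigned, edges = infer_layer(["A"], ["Z"], m)
        assert assigned == set() and edges == []

    def test_overlapping_bottom_and_candidates_rejected(self, rng):
        m = matrix_from_array(rng.normal(size=(3, 10)), gene_ids=["A", "B", "C"])
        with pytest.raises(ValueError, match="overlap"):
            infer_layer(["A", "B"], ["B", "C"], m)

    def test_min_pairs_broken_raises_stringency(self, rng):
        n = 24
        z = rng.normal(size=n)
        profiles = [z + 0.05 * rng.normal(size=n) for _ in range(2)]
        m = matrix_from_array(np.vstack(profiles + [z]),
                              gene_ids=["A", "B", "Z"])
        a1, _ = infer_layer(["A", "B"], ["Z"], m, min_pairs_broken=1)
        a2, _ = infer_layer(["A", "B"], ["Z"], m, min_pairs_broken=2)
        assert a1 == {"Z"} and a2 == set()

    def test_candidate_pool_monotonicity(self, rng):
        # enlarging the candidate pool never removes an assigned
        # regulator's edges at the first inferred layer
        n = 24
        z = rng.normal(size=n)
        x = z + 0.05 * rng.normal(size=n)
        y = z + 0.05 * rng.normal(size=n)
        extra = rng.normal(size=n)
        m = matrix_from_array(np.vstack([x, y, z, extra]),
                              gene_ids=["A", "B", "Z", "W"])
        _, edges_small = infer_layer(["A", "B"], ["Z"], m)
        _, edges_big = infer_layer(["A", "B"], ["Z", "W"], m)
        assert {e.key for e in edges_small} <= {e.key for e in edges_big}


class TestBuildHierarchy:
    def test_exactly_recovers_two_layer_planted_network(self):
        # one TF level over structural genes: each TF's children form
        # co-expressed pairs that only their own parent can break, so
        # recovery is exact at modest noise
        net = generate_planted_network(
            layer_sizes=(3, 9), fan_out=3, seed=5, noise_sd=0.05
        )
        m = simulate_expression(net)
        cat = make_gene_catalog(net)
        grn = build_hierarchical_grn(m, cat, cat.structural, n_layers=2)
        rep = score_recovery(grn, net)
        assert rep.membership_accuracy == 1.0
        assert rep.exact_layers
        # every single-parent target's edge is recovered; only a minority
        # parent of a multi-parent target may be diluted below threshold
        indeg = {}
        for e in net.edges:
            indeg[e.target] = indeg.get(e.target, 0) + 1
        single = {(e.regulator, e.target) for e in net.edges if indeg[e.target] == 1}
        assert single <= grn.edge_keys()
        assert rep.edge_recall >= 0.8

    def test_three_layer_build_recovers_tf_layer_over_bottom(self):
        # with two levels of TFs the bottom layer and the TF level directly
        # above it are recovered with high edge recall; the top level is
        # harder (a grandparent whose signal reaches the bottom can be
        # absorbed downward) so only containment is asserted here
        net = generate_planted_network(
            layer_sizes=(2, 4, 12), fan_out=3, seed=2, noise_sd=0.1
        )
        m = simulate_expression(net)
        cat = make_gene_catalog(net)
        grn = build_hierarchical_grn(m, cat, cat.structural)
        rep = score_recovery(grn, net)
        assert set(grn.bottom_layer) == net.layers[-1]
        assert net.layers[1] <= grn.layers[-2]  # planted mid TFs all found
        assert rep.edge_metrics[0]["recall"] >= 0.7

    def test_two_layer_build_stops_after_one_inference(self):
        net = generate_planted_network(layer_sizes=(2, 4, 12), seed=3)
        m = simulate_expression(net)
        cat = make_gene_catalog(net)
        grn = build_hierarchical_grn(m, cat, cat.structural, n_layers=2)
        assert grn.n_layers == 2
        assert grn.bottom_layer == set(cat.structural)

    def test_empty_regulator_pool(self, rng):
        m = matrix_from_array(rng.normal(size=(4, 12)))
        cat = GeneCatalog(role_by_gene={g: "structural" for g in m.gene_ids})
        grn = build_hierarchical_grn(m, cat, m.gene_ids)
        assert grn.n_layers == 1
        assert grn.edges == [] and grn.unplaced_regulators == set()

    def test_regulator_in_bottom_rejected(self, rng):
        m = matrix_from_array(rng.normal(size=(3, 10)), gene_ids=["A", "B", "Z"])
        cat = GeneCatalog(
            role_by_gene={"A": "structural", "B": "structural", "Z": "regulator"}
        )
        with pytest.raises(ValueError, match="Z"):
            build_hierarchical_grn(m, cat, ["A", "B", "Z"])

    def test_built_grn_passes_structural_invariants(self):
        net = generate_planted_network(layer_sizes=(2, 4, 12), seed=2)
        m = simulate_expression(net)
        cat = make_gene_catalog(net)
        grn = build_hierarchical_grn(m, cat, cat.structural)
        grn.validate()  # disjoint layers, adjacent edges, out-degrees
        placed = set().union(*grn.layers)
        assert grn.unplaced_regulators.isdisjoint(placed)

    def test_determinism(self):
        net = generate_planted_network(layer_sizes=(2, 4, 12), seed=4)
        m = simulate_expression(net)
        cat = make_gene_catalog(net)
        g1 = build_hierarchical_grn(m, cat, cat.structural)
        g2 = build_hierarchical_grn(m, cat, cat.structural)
        assert g1.layers == g2.layers
        assert [e.key for e in g1.edges] == [e.key for e in g2.edges]


class TestGrnInvariants:
    def test_disjoint_layers_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            HierarchicalGRN(layers=[{"A"}, {"A", "B"}], edges=[Edge("A", "B")])

    def test_non_adjacent_edge_rejected(self):
        with pytest.raises(ValueError, match="adjacent"):
            HierarchicalGRN(
                layers=[{"T"}, {"M"}, {"B"}],
                edges=[Edge("T", "M"), Edge("M", "B"), Edge("T", "B")],
            )

    def test_dangling_non_bottom_gene_rejected(self):
        with pytest.raises(ValueError, match="without outgoing"):
            HierarchicalGRN(layers=[{"T", "T2"}, {"B"}], edges=[Edge("T", "B")])

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            HierarchicalGRN(
                layers=[{"T"}, {"B"}], edges=[Edge("T", "B"), Edge("T", "B")]
            )


class TestSummaries:
    def test_complete_bipartite_edge_counts(self):
        layers = [{"T"}, {"M1", "M2"}, {"B1", "B2", "B3", "B4"}]
        edges = [Edge("T", m) for m in ("M1", "M2")] + [
            Edge(m, b)
            for m in ("M1", "M2")
            for b in ("B1", "B2", "B3", "B4")
        ]
        s = summarize_grn(HierarchicalGRN(layers=layers, edges=edges))
        assert s.per_layer_counts == [1, 2, 4]
        assert s.edge_counts_between_layers == [2, 8]
        assert s.edge_count_total == 10
        assert s.regulated_targets_by_top_regulator["T"] == {"B1", "B2", "B3", "B4"}

    def test_empty_edges(self):
        s = summarize_grn(HierarchicalGRN(layers=[{"B1", "B2"}], edges=[]))
        assert s.edge_count_total == 0
        assert s.out_degree_by_regulator == {}

    def test_two_hop_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        tops = [f"T{i}" for i in range(3)]
        mids = [f"M{i}" for i in range(5)]
        bots = [f"B{i}" for i in range(10)]
        edges = []
        for t in tops:
            for m in rng.choice(mids, size=3, replace=False):
                edges.append(Edge(t, str(m)))
        for m in mids:
            for b in rng.choice(bots, size=4, replace=False):
                edges.append(Edge(str(m), str(b)))
        grn = HierarchicalGRN(
            layers=[set(tops), set(mids), set(bots)], edges=edges
        )
        s = summarize_grn(grn)
        for t in tops:
            expect = set()
            for e1 in edges:
                if e1.regulator == t:
                    for e2 in edges:
                        if e2.regulator == e1.target:
                            expect.add(e2.target)
            assert s.regulated_targets_by_top_regulator[t] == expect

    def test_per_process_counts(self):
        grn = small_grn()
        pm = ProcessMap(sets={
            "p_all_regulated": {"B1", "B2"},
            "p_partial": {"B1", "Bmissing"},
            "p_outside": {"X1"},
        })
        s = summarize_grn(grn, pm)
        # every bottom gene in small_grn has a parent
        assert s.per_process_counts["p_all_regulated"] == (2, 2)
        assert s.per_process_counts["p_partial"] == (1, 1)
        assert s.per_process_counts["p_outside"] == (0, 0)


class TestScoreRecovery:
    def test_self_comparison_is_perfect(self):
        grn = small_grn()
        rep = score_recovery(grn, grn)
        assert rep.exact_layers and rep.exact_edges
        assert rep.edge_precision == 1.0 and rep.edge_recall == 1.0
        assert rep.membership_accuracy == 1.0

    def test_empty_prediction_has_zero_recall_undefined_precision(self):
        truth = small_grn()
        empty = HierarchicalGRN(
            layers=[set(truth.bottom_layer)], edges=[]
        )
        rep = score_recovery(empty, truth)
        assert rep.edge_recall == 0.0
        assert rep.edge_precision is None

    def test_deleted_edges_reduce_recall_arithmetically(self):
        truth = small_grn()
        pruned_edges = [e for e in truth.edges if e.key not in
                        {("M2", "B3"), ("M2", "B4")}]
        pruned = HierarchicalGRN(
            layers=[set(l) for l in truth.layers], edges=pruned_edges
        )
        rep = score_recovery(pruned, truth)
        assert rep.edge_recall == pytest.approx(1 - 2 / 7)


class TestSerialization:
    def test_edge_tsv_and_layers_round_trip(self, tmp_path):
        grn = small_grn()
        write_edge_tsv(grn, tmp_path / "e.tsv")
        write_layers_tsv(grn, tmp_path / "l.tsv")
        back = read_grn(tmp_path / "e.tsv", tmp_path / "l.tsv")
        assert back.layers == grn.layers
        assert back.edge_keys() == grn.edge_keys()
        assert back.unplaced_regulators == grn.unplaced_regulators

    def test_sif_round_trip(self, tmp_path):
        grn = small_grn()
        write_sif(grn, tmp_path / "g.sif")
        assert read_sif(tmp_path / "g.sif") == grn.edge_keys()

    def test_graphml_round_trip(self, tmp_path):
        grn = small_grn()
        write_graphml(grn, tmp_path / "g.graphml")
        back = read_graphml(tmp_path / "g.graphml")
        assert back.layers == grn.layers
        assert back.edge_keys() == grn.edge_keys()
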