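import networkx as nx
import numpy as np
import pytest

from hepatlas.errors import ValidationError
from hepatlas.differential import call_enhanced
from hepatlas.io_formats import LigandReceptorDB, OrthologyMap, PathwayGraph, TFTargetMap
from hepatlas.crosstalk import (
    ActivePathwayCall,
    apply_orthology,
    build_network,
    call_active_pathways,
    compare_path_lengths,
    select_candidates,
    shortest_path_lex,
)

import _oracles
from conftest import make_matrix


def _pathway(name, edges_with_roles):
    g = nx.DiGraph()
    for u, v, ru, rv in edges_with_roles:
        g.add_node(u, role=ru)
        g.add_node(v, role=rv)
        g.add_edge(u, v)
    return PathwayGraph(name, g)


@pytest.fixture()
def toy_world():
    """One enhanced ligand in KC, receptor detected in HC, one pathway
    R1 -> N1 -> TF1 with target G1."""
    genes = ["L1", "R1", "N1", "TF1", "G1", "filler"]
    vals = np.array(
        [
            [0.0, 0.0, 8.0, 0.0],  # L1 exclusive to KC
            [1.0, 1.0, 1.0, 1.0],  # R1 everywhere
            [1.0, 1.0, 1.0, 1.0],  # N1
            [1.0, 1.0, 1.0, 1.0],  # TF1
            [1.0, 1.0, 1.0, 1.0],  # G1
            [1.0, 1.0, 1.0, 1.0],
        ]
    )
    matrix = make_matrix(vals, genes=genes)
    lr = LigandReceptorDB((("L1", "R1", "toy"),))
    pw = _pathway(
        "pw1",
        [
            ("L1", "R1", "ligand", "receptor"),
            ("R1", "N1", "receptor", "intermediate"),
            ("N1", "TF1", "intermediate", "tf"),
        ],
    )
    tft = TFTargetMap({"TF1": frozenset({"G1"})})
    enhanced = {c: call_enhanced(matrix, c) for c in ("HSC", "KC", "LSEC")}
    return matrix, lr, pw, tft, enhanced


class TestSelectCandidates:
    def test_enhanced_ligand_detected_receptor(self, toy_world):
        matrix, lr, pw, tft, enhanced = toy_world
        cands = select_candidates(lr, matrix, {}, ("HSC", "KC", "LSEC"), "HC", enhanced)
        assert len(cands) == 1
        c = cands[0]
        assert (c.ligand, c.sender, c.receptor, c.evidence) == ("L1", "KC", "R1", "enhanced")

    def test_unsupported_ligand_yields_nothing(self, toy_world):
        matrix, _, pw, tft, enhanced = toy_world
        lr = LigandReceptorDB((("filler", "R1", "toy"),))
        assert select_candidates(lr, matrix, {}, ("KC",), "HC", enhanced) == []

    def test_enhanced_and_secreted_tagged_both_once(self, toy_world):
        matrix, lr, pw, tft, enhanced = toy_world
        cands = select_candidates(
            lr, matrix, {"KC": frozenset({"L1"})}, ("KC",), "HC", enhanced
        )
        assert len(cands) == 1
        assert cands[0].evidence == "both"

    def test_undetected_receptor_excluded_unless_transcribed(self, toy_world):
        matrix, lr, pw, tft, enhanced = toy_world
        m2 = make_matrix(
            np.array([[0.0, 0.0, 8.0, 0.0], [0.0, 1.0, 1.0, 1.0]]),
            genes=["L1", "R1"],
        )
        enhanced2 = {c: call_enhanced(m2, c) for c in ("KC",)}
        assert select_candidates(lr, m2, {}, ("KC",), "HC", enhanced2) == []
        fpkm = make_matrix(np.array([[0.0], [5.0]]), genes=["L1", "R1"],
                           cells=("HC",), unit="fpkm")
        cands = select_candidates(lr, m2, {}, ("KC",), "HC", enhanced2,
                                  transcriptome=fpkm)
        assert len(cands) == 1

    def test_unknown_receiver_rejected(self, toy_world):
        matrix, lr, pw, tft, enhanced = toy_world
        with pytest.raises(ValidationError):
            select_candidates(lr, matrix, {}, ("KC",), "XX", enhanced)


class TestActivePathways:
    def test_fully_enhanced_pathway_small_universe(self):
        universe = [f"g{i}" for i in range(20)]
        pw = _pathway("pw", [
            ("g0", "g1", "receptor", "intermediate"),
            ("g1", "g2", "intermediate", "intermediate"),
            ("g2", "g3", "intermediate", "intermediate"),
            ("g3", "g4", "intermediate", "tf"),
        ])
        calls = call_active_pathways([pw], universe[:5], universe, universe)
        assert calls[0].p == pytest.approx(1 / 15504, rel=1e-9)  # 1/C(20,5)
        assert calls[0].active

    def test_undetected_node_vetoes_activity(self):
        universe = [f"g{i}" for i in range(20)]
        pw = _pathway("pw", [
            ("g0", "g1", "receptor", "intermediate"),
            ("g1", "g2", "intermediate", "tf"),
        ])
        detected = [g for g in universe if g != "g1"]
        calls = call_active_pathways([pw], universe[:5], detected, universe)
        assert calls[0].p < 0.05 and not calls[0].active

    def test_no_enhanced_overlap_inactive(self):
        universe = [f"g{i}" for i in range(20)]
        pw = _pathway("pw", [("g0", "g1", "receptor", "tf")])
        calls = call_active_pathways([pw], universe[10:12], universe, universe)
        assert calls[0].p == pytest.approx(1.0)
        assert not calls[0].active

    def test_pathway_outside_universe_reported_inactive(self):
        pw = _pathway("pw", [("x", "y", "receptor", "tf")])
        calls = call_active_pathways([pw], ["g1"], ["g1", "g2"], ["g1", "g2"])
        assert calls[0].p == 1.0 and not calls[0].all_detected and not calls[0].active


class TestBuildNetwork:
    def test_single_chain_network(self, toy_world):
        matrix, lr, pw, tft, enhanced = toy_world
        cands = select_candidates(lr, matrix, {}, ("KC",), "HC", enhanced)
        calls = [ActivePathwayCall("pw1", 0.001, 3, 4, True, True)]
        net = build_network(cands, calls, [pw], {"TF1"}, tft,
                           receiver_detected=matrix.detected("HC"))
        assert len(net.receptor_tf_edges) == 1
        e = net.receptor_tf_edges[0]
        assert (e.receptor, e.tf, e.pathway, e.length) == ("R1", "TF1", "pw1", 2)
        assert e.path == ("R1", "N1", "TF1")
        assert net.tf_targets["TF1"] == frozenset({"G1"})
        assert len(net.candidates) == 1

    def test_inactive_pathway_contributes_no_edges(self, toy_world):
        matrix, lr, pw, tft, enhanced = toy_world
        cands = select_candidates(lr, matrix, {}, ("KC",), "HC", enhanced)
        calls = [ActivePathwayCall("pw1", 0.5, 1, 4, True, False)]
        net = build_network(cands, calls, [pw], {"TF1"}, tft)
        assert net.is_empty()
        assert net.candidates == ()

    def test_shortest_of_two_routes_recorded(self):
        pw = _pathway("pw", [
            ("R1", "A", "receptor", "intermediate"),
            ("A", "TF1", "intermediate", "tf"),
            ("R1", "B", "receptor", "intermediate"),
            ("B", "C", "intermediate", "intermediate"),
            ("C", "D", "intermediate", "intermediate"),
            ("D", "TF1", "intermediate", "tf"),
        ])
        matrix = make_matrix(np.ones((6, 4)), genes=["R1", "A", "B", "C", "D", "TF1"])
        from hepatlas.crosstalk import CandidateInteraction
        cands = [CandidateInteraction("L", "KC", "R1", "HC", "enhanced")]
        calls = [ActivePathwayCall("pw", 0.001, 2, 6, True, True)]
        net = build_network(cands, calls, [pw], set(), TFTargetMap({"TF1": frozenset({"X"})}))
        assert net.receptor_tf_edges[0].length == 2

    def test_lexicographic_witness_among_equal_lengths(self):
        pw = _pathway("pw", [
            ("R1", "B", "receptor", "intermediate"),
            ("B", "TF1", "intermediate", "tf"),
            ("R1", "A", "receptor", "intermediate"),
            ("A", "TF1", "intermediate", "tf"),
        ])
        path = shortest_path_lex(pw.graph, "R1", "TF1")
        assert path == ["R1", "A", "TF1"]

    def test_removing_active_pathway_never_adds_edges(self, cohort_noiseless):
        co = cohort_noiseless
        m0 = co.expectation_matrix()
        enhanced = {c: call_enhanced(m0, c) for c in co.config.cell_types}
        cands = select_candidates(co.lr_db, m0, co.secretomes, co.config.senders,
                                  "HC", enhanced)
        det = m0.detected()
        union = set().union(*(e.genes for e in enhanced.values()))
        calls = call_active_pathways(co.pathways, union, det, det)
        net_full = build_network(cands, calls, co.pathways,
                                 co.truth.specific_tfs["HC"], co.tf_targets)
        dropped = [c for c in calls if c.name != sorted(co.truth.active_pathways)[0]]
        net_less = build_network(cands, dropped, co.pathways,
                                 co.truth.specific_tfs["HC"], co.tf_targets)
        full_edges = {(e.receptor, e.tf) for e in net_full.receptor_tf_edges}
        less_edges = {(e.receptor, e.tf) for e in net_less.receptor_tf_edges}
        assert less_edges <= full_edges
        assert len(less_edges) < len(full_edges)


class TestComparePathLengths:
    def _net(self, lengths_spec, lengths_other):
        from hepatlas.crosstalk import CrosstalkNetwork, ReceptorTFEdge
        edges = []
        for i, L in enumerate(lengths_spec):
            edges.append(ReceptorTFEdge(f"R{i}", "TFS", "pw", L, (), True))
        for i, L in enumerate(lengths_other):
            edges.append(ReceptorTFEdge(f"Q{i}", "TFN", "pw", L, (), False))
        return CrosstalkNetwork((), tuple(edges), {})

    def test_equal_lengths_give_p_one(self):
        net = self._net([2, 2, 2], [2, 2, 2])
        comp = compare_path_lengths(net, {"TFS"}, mode="all")
        assert comp.mean_specific == comp.mean_reference == 2.0
        assert comp.mwu.p == 1.0

    def test_shorter_specific_paths(self):
        net = self._net([2, 2, 2], [4, 4, 4])
        comp = compare_path_lengths(net, {"TFS"}, mode="all")
        assert comp.mean_specific == 2.0
        assert comp.mean_reference == pytest.approx(3.0)  # overlapping groups
        comp2 = compare_path_lengths(net, {"TFS"}, mode="nonspecific")
        assert comp2.mean_reference == 4.0
        # tie-corrected p agrees with full labeling enumeration
        p_enum = _oracles.mwu_exact_two_sided([2, 2, 2], [4, 4, 4])
        assert abs(comp2.mwu.p - p_enum) < 0.08

    def test_empty_group_rejected(self):
        net = self._net([2], [3])
        with pytest.raises(ValidationError):
            compare_path_lengths(net, {"OTHER"}, mode="all")


class TestOrthology:
    def test_mapping_drops_unmapped_and_unions_collisions(self):
        tft = TFTargetMap(
            {
                "TfA": frozenset({"t1", "t2", "t_unmapped"}),
                "TfB": frozenset({"t3"}),
                "TfUnmapped": frozenset({"t1"}),
            }
        )
        orth = OrthologyMap(
            {"TfA": "TFH", "TfB": "TFH", "t1": "T1", "t2": "T2", "t3": "T3"}
        )
        mapped = apply_orthology(tft, orth)
        assert set(mapped.targets) == {"TFH"}
        assert mapped.targets["TFH"] == frozenset({"T1", "T2", "T3"})


class TestPathLengthOracle:
    def test_every_recorded_length_matches_bfs_oracle(self, cohort_noiseless):
        co = cohort_noiseless
        m0 = co.expectation_matrix()
        enhanced = {c: call_enhanced(m0, c) for c in co.config.cell_types}
        cands = select_candidates(co.lr_db, m0, co.secretomes, co.config.senders,
                                  "HC", enhanced)
        det = m0.detected()
        union = set().union(*(e.genes for e in enhanced.values()))
        calls = call_active_pathways(co.pathways, union, det, det)
        net = build_network(cands, calls, co.pathways,
                           co.truth.specific_tfs["HC"], co.tf_targets)
        by_name = {pw.name: pw.graph for pw in co.pathways}
        assert net.receptor_tf_edges
        for e in net.receptor_tf_edges:
            assert e.length == _oracles.bfs_path_length(
                by_name[e.pathway], e.receptor, e.tf
            )
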