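"""Topology roles, CPT colouring, abridgement, Cytoscape export."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cytobn as cb
from cytobn.scoring import DagModel


def roles(dag, **kw):
    table = cb.classify_topology(dag, **kw)
    return dict(zip(table["node"], table["role"]))


class TestClassifyTopology:
    def test_collider_roots_and_terminal(self):
        dag = DagModel(("A", "B", "C"), {"C": ("A", "B")})
        assert roles(dag) == {"A": "parent", "B": "parent", "C": "terminal"}

    def test_isolated_node_is_orphan(self):
        dag = DagModel(("A", "B", "C", "D"), {"C": ("A", "B")})
        assert roles(dag)["D"] == "orphan"

    def test_star_node_is_hub(self):
        # 2 in + 2 out satisfies both hub clauses
        dag = DagModel(
            ("A", "B", "H", "X", "Y"), {"H": ("A", "B"), "X": ("H",), "Y": ("H",)}
        )
        assert roles(dag)["H"] == "hub"

    def test_degree_three_hub(self):
        dag = DagModel(("A", "H", "X", "Y"), {"H": ("A",), "X": ("H",), "Y": ("H",)})
        assert roles(dag)["H"] == "hub"
        assert roles(dag, hub_min_degree=4)["H"] == "internal"

    def test_chain_middle_is_internal(self):
        dag = DagModel(("A", "B", "C"), {"B": ("A",), "C": ("B",)})
        assert roles(dag)["B"] == "internal"

    @given(st.integers(0, 2**6 - 1))
    @settings(max_examples=64, deadline=None)
    def test_role_partition_and_degree_invariants(self, mask):
        # every subset of the 6 name-ordered pairs over 4 nodes is a DAG
        nodes = ("A", "B", "C", "D")
        pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1 :]]
        parents = {v: set() for v in nodes}
        for bit, (u, v) in enumerate(pairs):
            if mask >> bit & 1:
                parents[v].add(u)
        dag = DagModel(nodes, {v: tuple(ps) for v, ps in parents.items()})
        table = cb.classify_topology(dag)
        assert len(table) == len(nodes)  # exactly one role per node
        for r in table.itertuples():
            if r.role == "orphan":
                assert r.in_degree == 0 and r.out_degree == 0
            elif r.role == "terminal":
                assert r.out_degree == 0 and r.in_degree >= 1
            elif r.role == "parent":
                assert r.in_degree == 0 and r.out_degree >= 1
            else:
                assert r.in_degree >= 1 and r.out_degree >= 1


class TestColourNodes:
    def test_degenerate_high_cpt_green_full_intensity(self):
        dag = DagModel(("A",), {})
        colours = cb.colour_nodes({"A": np.array([[0.0, 0.0, 1.0]])}, dag)
        row = colours.iloc[0]
        assert (row["colour"], row["intensity"]) == ("green", 1.0)

    def test_uniform_cpt_white_zero_intensity(self):
        dag = DagModel(("A",), {})
        colours = cb.colour_nodes({"A": np.full((1, 3), 1 / 3)}, dag)
        row = colours.iloc[0]
        assert (row["colour"], row["intensity"]) == ("white", 0.0)

    def test_modal_low_intensity_rule(self):
        dag = DagModel(("A",), {})
        colours = cb.colour_nodes({"A": np.array([[0.6, 0.25, 0.15]])}, dag)
        row = colours.iloc[0]
        assert row["colour"] == "red"
        assert row["intensity"] == pytest.approx((0.6 - 1 / 3) / (2 / 3))

    def test_parent_modal_state_selects_row(self):
        dag = DagModel(("A", "B"), {"B": ("A",)})
        cpts = {
            "A": np.array([[0.0, 0.0, 1.0]]),  # A modal state: high (row 2 of B's CPT)
            "B": np.array([[1.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3], [0.0, 0.0, 1.0]]),
        }
        colours = cb.colour_nodes(cpts, dag).set_index("node")
        assert colours.loc["B", "colour"] == "green"

    def test_missing_cpt_rejected(self):
        dag = DagModel(("A", "B"), {})
        with pytest.raises(ValueError, match="missing CPTs"):
            cb.colour_nodes({"A": np.full((1, 3), 1 / 3)}, dag)

    def test_intensity_zero_iff_white(self, demo_discrete):
        model = cb.tabu_search(demo_discrete, seed=0)
        colours = cb.colour_nodes(cb.fit_cpts(model, demo_discrete), model)
        for r in colours.itertuples():
            assert 0.0 <= r.intensity <= 1.0
            assert (r.intensity == 0.0) == (r.colour == "white")


class TestAbridgeAndRelearn:
    def test_empty_exclusion_matches_full_run(self, demo_model):
        panel = cb.generate_panel(demo_model, 120, seed=31)
        cfg = cb.LearnConfig(n_bootstrap=10, seed=5)
        full = cb.run_pipeline(panel, config=cfg)
        noop = cb.abridge_and_relearn(panel, [], config=cfg)
        pd.testing.assert_frame_equal(full.consensus.edges, noop.consensus.edges)

    def test_presets_encode_cross_species_panels(self):
        from cytobn.reference import (
            MOUSE_ABRIDGE_EXCLUSIONS,
            MOUSE_ANALYTES,
            RAT_ABRIDGE_EXCLUSIONS,
            RAT_ANALYTES,
        )

        assert set(RAT_ABRIDGE_EXCLUSIONS) == set(RAT_ANALYTES) - set(MOUSE_ANALYTES)
        assert set(MOUSE_ABRIDGE_EXCLUSIONS) == set(MOUSE_ANALYTES) - set(RAT_ANALYTES)
        shared_from_rat = set(RAT_ANALYTES) - set(RAT_ABRIDGE_EXCLUSIONS)
        shared_from_mouse = set(MOUSE_ANALYTES) - set(MOUSE_ABRIDGE_EXCLUSIONS)
        assert shared_from_rat == shared_from_mouse

    def test_excluding_everything_rejected(self, demo_model):
        panel = cb.generate_panel(demo_model, 30, seed=1)
        with pytest.raises(ValueError, match="every analyte"):
            cb.abridge_and_relearn(panel, panel.analytes)

    def test_unknown_exclusion_rejected(self, demo_model):
        panel = cb.generate_panel(demo_model, 30, seed=1)
        with pytest.raises(ValueError, match="not in panel"):
            cb.abridge_and_relearn(panel, ["nonesuch"])

    def test_removing_hub_keeps_dag_acyclic(self, demo_model):
        import networkx as nx

        panel = cb.generate_panel(demo_model, 300, seed=33)
        cfg = cb.LearnConfig(n_bootstrap=5, seed=2)
        res = cb.abridge_and_relearn(panel, ["IL-10"], config=cfg)
        assert "IL-10" not in res.dag.nodes
        assert nx.is_directed_acyclic_graph(res.dag.to_digraph())


@pytest.fixture(scope="module")
def result(demo_model):
    panel = cb.generate_panel(demo_model, 200, seed=41)
    return cb.run_pipeline(panel, config=cb.LearnConfig(n_bootstrap=10, seed=3))


class TestExport:

    def test_sif_lines_sorted_and_complete(self, result, tmp_path):
        paths = cb.export_network(
            result.consensus, result.topology, result.colours, tmp_path / "net", "sif"
        )
        sif = (tmp_path / "net.sif").read_text().splitlines()
        assert len(sif) == len(result.consensus.edges)
        assert sif == sorted(sif)
        assert all(len(l.split("\t")) == 3 for l in sif)

    def test_sif_roundtrip(self, result, tmp_path):
        cb.export_network(
            result.consensus, result.topology, result.colours, tmp_path / "net", "sif"
        )
        edges, nodes = cb.read_network(tmp_path / "net", "sif")
        expected = result.consensus.edges.sort_values(["parent", "child"]).reset_index(drop=True)
        assert [(r.parent, r.child) for r in edges.itertuples()] == [
            (r.parent, r.child) for r in expected.itertuples()
        ]
        assert np.allclose(edges["confidence"], expected["confidence"], atol=1e-6)
        assert list(edges["tier"]) == list(expected["tier"])
        merged = result.topology.merge(result.colours, on="node")
        assert list(nodes["role"]) == list(merged.sort_values("node")["role"])

    def test_graphml_roundtrip(self, result, tmp_path):
        cb.export_network(
            result.consensus, result.topology, result.colours, tmp_path / "net", "graphml"
        )
        edges, nodes = cb.read_network(tmp_path / "net", "graphml")
        assert {(r.parent, r.child) for r in edges.itertuples()} == set(
            result.consensus.point.edges()
        )
        assert set(nodes["node"]) == set(result.dag.nodes)
        assert np.allclose(
            sorted(edges["confidence"]), sorted(result.consensus.edges["confidence"])
        )

    def test_unknown_format_rejected(self, result, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            cb.export_network(
                result.consensus, result.topology, result.colours, tmp_path / "x", "dot"
            )
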