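"""Generator correctness: ancestral sampling, emission, moment calibration."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cytobn as cb
from cytobn.synthetic import (
    diagonal_cpt,
    uniform_cpt,
    _emission_from_moments,
)
from conftest import make_copy_model


def single_node_model(cpt_row, seed=0):
    return cb.GroundTruthModel(
        nodes=("A",),
        parents={"A": ()},
        cpts={"A": np.array([cpt_row])},
        emission={"A": np.column_stack([np.log([1.0, 2.0, 4.0]), np.zeros(3)])},
        zero_rate={"A": 0.0},
        seed=seed,
    )


class TestSampleStates:
    def test_degenerate_cpt_all_low(self):
        model = single_node_model([1.0, 0.0, 0.0])
        states = cb.sample_states(model, 5)
        assert (states["A"] == 0).all()

    def test_deterministic_copy_edge(self, copy_states):
        assert (copy_states["A"] == copy_states["B"]).all()

    def test_chain_conditional_frequencies_match_cpt(self):
        strength = 0.9
        em = np.column_stack([np.log([5.0, 20.0, 80.0]), np.full(3, 0.2)])
        model = cb.GroundTruthModel(
            nodes=("A", "B", "C"),
            parents={"A": (), "B": ("A",), "C": ("B",)},
            cpts={
                "A": uniform_cpt(0),
                "B": diagonal_cpt(1, strength),
                "C": diagonal_cpt(1, strength),
            },
            emission={v: em for v in "ABC"},
            zero_rate={v: 0.0 for v in "ABC"},
            seed=11,
        )
        states = cb.sample_states(model, 10_000)
        for a in range(3):
            sub = states.loc[states["A"] == a, "B"]
            for b in range(3):
                target = strength if b == a else (1 - strength) / 2
                assert abs((sub == b).mean() - target) < 0.02

    def test_fixed_seed_bit_identical(self):
        model = cb.ground_truth_demo(seed=5)
        p1 = cb.generate_panel(model, 50, seed=9)
        p2 = cb.generate_panel(model, 50, seed=9)
        pd.testing.assert_frame_equal(p1.values, p2.values)

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            cb.GroundTruthModel(
                nodes=("A", "B"),
                parents={"A": ("B",), "B": ("A",)},
                cpts={"A": diagonal_cpt(1), "B": diagonal_cpt(1)},
                emission={v: np.column_stack([np.log([1, 2, 4]), np.zeros(3)]) for v in "AB"},
            )

    def test_bad_cpt_row_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            single_node_model([0.5, 0.2, 0.2])


class TestEmission:
    def test_zero_scale_emission_is_exact(self):
        model = single_node_model([0.0, 0.0, 1.0])
        states = cb.sample_states(model, 10)
        panel = cb.states_to_concentrations(states, model)
        assert np.allclose(panel.values["A"], 4.0)

    def test_zero_rate_one_column_undetectable(self):
        model = single_node_model([0.0, 1.0, 0.0])
        model.zero_rate["A"] = 1.0
        states = cb.sample_states(model, 20)
        panel = cb.states_to_concentrations(states, model)
        assert (panel.values["A"] == 0.0).all()

    def test_unknown_state_rejected(self):
        model = single_node_model([1.0, 0.0, 0.0])
        bad = pd.DataFrame({"A": [0, 1, 3]})
        with pytest.raises(ValueError, match="states must be coded"):
            cb.states_to_concentrations(bad, model)

    def test_concentrations_non_negative(self, demo_panel):
        assert (demo_panel.values.to_numpy() >= 0).all()


class TestCalibration:
    def test_moment_match_mean_and_sd(self):
        spec = cb.PanelSpec(
            analytes=("X",), n_subjects=20, target_moments={"X": (100.0, 10.0)}
        )
        model = cb.calibrate_to_moments(spec, seed=2)
        panel = cb.generate_panel(model, 10_000, seed=2)
        x = panel.values["X"]
        assert abs(x.mean() - 100.0) / 100.0 < 0.10
        implied_sd = 10.0 * np.sqrt(20)  # ~44.7
        assert abs(x.std(ddof=1) - implied_sd) / implied_sd < 0.15

    def test_zero_sem_degenerate_at_mean(self):
        spec = cb.PanelSpec(
            analytes=("X",), n_subjects=20, target_moments={"X": (42.0, 0.0)}
        )
        model = cb.calibrate_to_moments(spec)
        panel = cb.generate_panel(model, 50, seed=0)
        assert np.allclose(panel.values["X"], 42.0)

    def test_rat_seminal_kc_scale(self):
        # KC in rat seminal fluid: 229.24 +/- 24.48 pg/ml
        spec = cb.PanelSpec(
            analytes=("KC",), n_subjects=20, target_moments={"KC": (229.24, 24.48)}
        )
        model = cb.calibrate_to_moments(spec, seed=3)
        panel = cb.generate_panel(model, 5000, seed=3)
        x = panel.values["KC"]
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - 229.24) < 3 * se

    def test_serum_leptin_heavy_right_tail(self):
        # serum leptin: 9498.56 +/- 791.89 pg/ml, strongly right-skewed
        spec = cb.PanelSpec(
            analytes=("Leptin",),
            n_subjects=20,
            target_moments={"Leptin": (9498.56, 791.89)},
        )
        model = cb.calibrate_to_moments(spec, seed=4)
        panel = cb.generate_panel(model, 10_000, seed=4)
        x = panel.values["Leptin"]
        assert (x > 0).all()
        assert abs(x.mean() - 9498.56) / 9498.56 < 0.10
        assert sps.skew(x) > 0.5

    def test_zero_mean_encoded_as_undetectable(self):
        spec = cb.PanelSpec(
            analytes=("VEGF",), n_subjects=20, target_moments={"VEGF": (0.0, 0.0)}
        )
        model = cb.calibrate_to_moments(spec)
        assert model.zero_rate["VEGF"] == 1.0
        panel = cb.generate_panel(model, 30, seed=1)
        assert (panel.values["VEGF"] == 0.0).all()

    def test_negative_mean_with_sem_rejected(self):
        spec = cb.PanelSpec(
            analytes=("X",), n_subjects=20, target_moments={"X": (-1.0, 2.0)}
        )
        with pytest.raises(ValueError, match="non-positive mean"):
            cb.calibrate_to_moments(spec)

    def test_emission_locations_increase_with_state(self):
        em = _emission_from_moments(100.0, 44.7)
        assert np.all(np.diff(em[:, 0]) > 0)


class TestStructuralSanity:
    def test_independent_nodes_have_no_rank_correlation(self):
        analytes = tuple("ABCDEFGH")
        spec = cb.PanelSpec(
            analytes=analytes,
            n_subjects=20,
            target_moments={a: (50.0, 5.0) for a in analytes},
        )
        model = cb.calibrate_to_moments(spec, seed=6)
        panel = cb.generate_panel(model, 10_000, seed=6)
        rho = panel.values.corr(method="spearman").to_numpy()
        off = rho[~np.eye(len(analytes), dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_chain_adjacent_mi_exceeds_nonadjacent(self):
        em = np.column_stack([np.log([5.0, 20.0, 80.0]), np.full(3, 0.2)])
        model = cb.GroundTruthModel(
            nodes=("A", "B", "C"),
            parents={"A": (), "B": ("A",), "C": ("B",)},
            cpts={"A": uniform_cpt(0), "B": diagonal_cpt(1, 0.8), "C": diagonal_cpt(1, 0.8)},
            emission={v: em for v in "ABC"},
            zero_rate={v: 0.0 for v in "ABC"},
            seed=8,
        )
        panel = cb.generate_panel(model, 10_000, seed=8)
        dp = cb.discretize_panel(panel)

        def mi(u, v):
            joint = pd.crosstab(dp.states[u], dp.states[v]).to_numpy() / dp.n_subjects
            pu, pv = joint.sum(1), joint.sum(0)
            nz = joint > 0
            return (joint[nz] * np.log(joint[nz] / np.outer(pu, pv)[nz])).sum()

        assert mi("A", "B") > mi("A", "C")
        assert mi("B", "C") > mi("A", "C")

    def test_n_subjects_minimum(self):
        with pytest.raises(ValueError, match="n_subjects"):
            cb.PanelSpec(analytes=("A",), n_subjects=2)

    def test_duplicate_analytes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            cb.PanelSpec(analytes=("A", "A"))

    def test_edge_list_roundtrip(self, tmp_path, demo_model):
        path = tmp_path / "truth.tsv"
        cb.synthetic.write_edge_list(demo_model.edges(), path)
        lines = [tuple(l.split("\t")) for l in path.read_text().splitlines()]
        assert lines == demo_model.edges()


def test_skeleton_f1_values():
    truth = [("A", "B"), ("B", "C")]
    assert cb.skeleton_f1(truth, [("B", "A"), ("C", "B")]) == 1.0
    assert cb.skeleton_f1(truth, []) == 0.0
    assert cb.skeleton_f1(truth, [("A", "B")]) == pytest.approx(2 / 3)
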