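"""Comb construction, regime evaluation, interventions and padding."""

import itertools

import numpy as np
import pytest

from causalcomb import (
    ADMGSpec,
    BranchProbabilityTable,
    CausalModel,
    CycleError,
    DAGSpec,
    InterventionRegime,
    ModelValidationError,
    ProcessMatrix,
    basis_state,
    build_admg_layout,
    build_comb,
    do_distribution,
    make_coarse_grained_observation,
    make_identity_instrument,
    make_perfect_observation,
    marginalize,
    pad_mechanisms,
    parameter_count,
    regime_probabilities,
    state,
)
from causalcomb.io import random_model, random_separable_instrument

from conftest import brute_force_regime_table


class TestDAGSpec:
    def test_nodes_reordered_topologically(self):
        dag = DAGSpec(("Y", "X"), frozenset({("X", "Y")}), {"X": 2, "Y": 2})
        assert dag.nodes == ("X", "Y")

    def test_cycle_reported_with_members(self):
        with pytest.raises(CycleError, match="X"):
            DAGSpec(("X", "Y"), frozenset({("X", "Y"), ("Y", "X")}), {"X": 2, "Y": 2})

    def test_unknown_edge_endpoint_rejected(self):
        with pytest.raises(ModelValidationError, match="Z"):
            DAGSpec(("X",), frozenset({("X", "Z")}), {"X": 2})

    def test_parent_order_follows_node_order(self, five_node_dag):
        assert five_node_dag.parents("D") == ("B", "C")


class TestBuildComb:
    def test_two_node_chain_layout(self, two_node_dag):
        layout = build_comb(two_node_dag)
        assert layout["X"].inputs == ()
        assert set(layout["X"].fanout) == {"Y", "X"}
        assert layout["Y"].inputs == ("X",)
        assert layout["Y"].fanout == ("Y",)

    def test_five_node_fanouts(self, five_node_dag):
        layout = build_comb(five_node_dag)
        fanout_sizes = {w.node: len(w.fanout) for w in layout.wiring}
        assert fanout_sizes == {"A": 3, "B": 2, "C": 3, "D": 1, "E": 1}

    def test_single_node_layout(self):
        dag = DAGSpec(("X",), frozenset(), {"X": 3})
        layout = build_comb(dag)
        assert layout["X"].inputs == ()
        assert layout["X"].fanout == ("X",)

    def test_latent_locus_has_no_gap_output(self):
        dag = DAGSpec(
            ("A", "B"), frozenset({("A", "B")}), {"A": 2, "B": 2}, latent={"A"}
        )
        layout = build_comb(dag)
        assert layout["A"].latent
        assert layout["A"].fanout == ("B",)


class TestRegimeProbabilities:
    def test_perfect_observation_chain_table(self, two_node_model):
        table = regime_probabilities(
            two_node_model, InterventionRegime.perfect_observation(two_node_model.dag)
        )
        assert table[("1", "1")] == pytest.approx(0.48)
        assert table[("1", "2")] == pytest.approx(0.32)
        assert table[("2", "1")] == pytest.approx(0.06)
        assert table[("2", "2")] == pytest.approx(0.14)

    def test_noisy_instrument_table(self, two_node_model, noisy_instrument):
        table = regime_probabilities(
            two_node_model,
            {"X": noisy_instrument, "Y": make_perfect_observation(2)},
        )
        assert table[("psi.phi", "1")] == pytest.approx(0.396)
        assert table[("psi.phi", "2")] == pytest.approx(0.264)
        assert table[("psi'.phi'", "1")] == pytest.approx(0.102)
        assert table[("psi'.phi'", "2")] == pytest.approx(0.238)

    def test_identity_regime_gives_single_certain_entry(self, five_node_dag):
        model = random_model(five_node_dag, seed=3)
        table = regime_probabilities(
            model, InterventionRegime.identity(five_node_dag)
        )
        assert len(table.probabilities) == 1
        assert table.total() == pytest.approx(1.0)

    def test_instrument_on_latent_locus_refused(self):
        dag = DAGSpec(
            ("A", "B"), frozenset({("A", "B")}), {"A": 2, "B": 2}, latent={"A"}
        )
        model = random_model(dag, seed=0)
        regime = {
            "A": make_perfect_observation(2),
            "B": make_perfect_observation(2),
        }
        with pytest.raises(ModelValidationError):
            regime_probabilities(model, regime)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_enumeration(self, seed):
        """The frontier contraction agrees with full wire enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        nodes = tuple(f"X{i}" for i in range(n))
        edges = {
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.6
        }
        latent = {nodes[0]} if rng.random() < 0.3 and n > 2 else set()
        dag = DAGSpec(nodes, frozenset(edges), {x: 2 for x in nodes}, latent)
        model = random_model(dag, seed=seed + 50)
        assignment = {}
        for node in dag.observable:
            kind = rng.integers(0, 3)
            if kind == 0:
                assignment[node] = make_perfect_observation(2)
            elif kind == 1:
                assignment[node] = random_separable_instrument(
                    2, seed=int(rng.integers(0, 2**31))
                )
            else:
                assignment[node] = make_coarse_grained_observation(2, [[0, 1]])
        regime = InterventionRegime(assignment)
        fast = regime_probabilities(model, regime)
        slow = brute_force_regime_table(model, regime)
        for combo, p in slow.probabilities.items():
            assert fast[combo] == pytest.approx(p, abs=1e-12)

    def test_perfect_observation_equals_markov_factorization(self, five_node_dag):
        model = random_model(five_node_dag, seed=11)
        table = regime_probabilities(
            model, InterventionRegime.perfect_observation(five_node_dag)
        )
        for combo, p in table.probabilities.items():
            values = {n: int(lbl) - 1 for n, lbl in zip(five_node_dag.nodes, combo)}
            expected = 1.0
            for n in five_node_dag.nodes:
                col = 0
                for parent in five_node_dag.parents(n):
                    col = col * 2 + values[parent]
                expected *= model.mechanism(n).entries[values[n], col]
            assert p == pytest.approx(expected, abs=1e-12)

    def test_tables_sum_to_one(self, five_node_dag):
        model = random_model(five_node_dag, seed=21)
        regime = InterventionRegime(
            {
                n: random_separable_instrument(2, seed=i)
                if i % 2
                else make_coarse_grained_observation(2, [[0], [1]])
                for i, n in enumerate(five_node_dag.nodes)
            }
        )
        table = regime_probabilities(model, regime)
        assert table.total() == pytest.approx(1.0, abs=1e-12)


class TestMarginalize:
    def test_noisy_table_marginal_over_downstream(self, two_node_model, noisy_instrument):
        table = regime_probabilities(
            two_node_model,
            {"X": noisy_instrument, "Y": make_perfect_observation(2)},
        )
        marg = marginalize(table, ["X"])
        assert marg[("psi.phi",)] == pytest.approx(0.66)
        assert marg[("psi'.phi'",)] == pytest.approx(0.34)

    def test_keeping_all_loci_is_identity(self, two_node_model):
        table = regime_probabilities(
            two_node_model, InterventionRegime.perfect_observation(two_node_model.dag)
        )
        again = marginalize(table, table.loci)
        assert again.probabilities == pytest.approx(table.probabilities)

    def test_matches_double_sum_on_three_locus_table(self):
        rng = np.random.default_rng(5)
        labels = {"A": ("1", "2"), "B": ("1", "2", "3"), "C": ("1", "2")}
        combos = list(itertools.product(*labels.values()))
        p = rng.dirichlet(np.ones(len(combos)))
        table = BranchProbabilityTable(
            ("A", "B", "C"), labels, dict(zip(combos, p))
        )
        marg = marginalize(table, ["B"])
        for b_lbl in labels["B"]:
            direct = sum(
                table[(a, b_lbl, c)] for a in labels["A"] for c in labels["C"]
            )
            assert marg[(b_lbl,)] == pytest.approx(direct)

    def test_unknown_locus_rejected(self, two_node_model):
        table = regime_probabilities(
            two_node_model, InterventionRegime.perfect_observation(two_node_model.dag)
        )
        with pytest.raises(KeyError):
            marginalize(table, ["Z"])


class TestDoDistribution:
    def test_surgical_intervention_on_chain(self, two_node_model):
        dist = do_distribution(two_node_model, {"X": basis_state(2, 1)}, "Y")
        assert dist.entries[:, 0] == pytest.approx([0.3, 0.7])

    def test_do_on_non_ancestor_leaves_query_unchanged(self, five_node_dag):
        model = random_model(five_node_dag, seed=13)
        baseline = do_distribution(model, {}, "B")
        intervened = do_distribution(model, {"E": basis_state(2, 0)}, "B")
        assert intervened.entries == pytest.approx(baseline.entries, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_truncated_factorization(self, seed):
        """do() agrees with the enumerate-and-replace-the-factor oracle."""
        rng = np.random.default_rng(seed + 100)
        nodes = ("A", "B", "C", "D")
        edges = frozenset({("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")})
        dag = DAGSpec(nodes, edges, {n: 2 for n in nodes})
        model = random_model(dag, seed=seed)
        do_node, do_value, query = "A", 1, "D"
        dist = do_distribution(model, {do_node: basis_state(2, do_value)}, query)
        expected = np.zeros(2)
        for values in itertools.product(range(2), repeat=4):
            assign = dict(zip(nodes, values))
            if assign[do_node] != do_value:
                continue
            w = 1.0
            for n in nodes:
                if n == do_node:
                    continue  # the do-factor is replaced by the point mass
                col = 0
                for p in dag.parents(n):
                    col = col * 2 + assign[p]
                w *= model.mechanism(n).entries[assign[n], col]
            expected[assign[query]] += w
        assert dist.entries[:, 0] == pytest.approx(expected, abs=1e-12)


class TestPadMechanisms:
    def test_fully_connected_model_unchanged(self):
        dag = DAGSpec(
            ("A", "B", "C"),
            frozenset({("A", "B"), ("A", "C"), ("B", "C")}),
            {"A": 2, "B": 2, "C": 2},
        )
        model = random_model(dag, seed=4)
        padded = pad_mechanisms(model)
        for n in dag.nodes:
            assert np.allclose(
                padded.mechanism(n).entries, model.mechanism(n).entries
            )

    def test_chain_terminal_mechanism_becomes_constant_in_root(self):
        dag = DAGSpec(
            ("X", "Y", "Z"),
            frozenset({("X", "Y"), ("Y", "Z")}),
            {"X": 2, "Y": 2, "Z": 2},
        )
        model = random_model(dag, seed=6)
        padded = pad_mechanisms(model)
        z = padded.mechanism("Z")
        assert z.dom == (2, 2)
        # columns (x, y) with x varying, y fixed, must coincide
        assert np.allclose(z.entries[:, 0], z.entries[:, 2])
        assert np.allclose(z.entries[:, 1], z.entries[:, 3])

    @pytest.mark.parametrize("seed", range(3))
    def test_padding_preserves_regime_tables(self, seed):
        rng = np.random.default_rng(seed + 40)
        nodes = tuple(f"X{i}" for i in range(4))
        edges = {
            (nodes[i], nodes[j])
            for i in range(4)
            for j in range(i + 1, 4)
            if rng.random() < 0.5
        }
        dag = DAGSpec(nodes, frozenset(edges), {n: 2 for n in nodes})
        model = random_model(dag, seed=seed)
        padded = pad_mechanisms(model)
        for r in range(3):
            regime = InterventionRegime(
                {
                    n: random_separable_instrument(2, seed=100 * seed + 10 * r + i)
                    for i, n in enumerate(nodes)
                }
            )
            t1 = regime_probabilities(model, regime)
            t2 = regime_probabilities(padded, regime)
            for combo, p in t1.probabilities.items():
                assert t2[combo] == pytest.approx(p, abs=1e-12)


class TestLatentClosure:
    def test_identity_closure_equals_marginalized_markov_table(self, five_node_dag):
        model = random_model(five_node_dag, seed=17)
        full = regime_probabilities(
            model, InterventionRegime.perfect_observation(five_node_dag)
        )
        latent_dag = DAGSpec(
            five_node_dag.nodes,
            five_node_dag.edges,
            five_node_dag.cardinalities,
            latent={"A"},
        )
        latent_model = CausalModel(latent_dag, model.mechanisms)
        closed = regime_probabilities(
            latent_model, InterventionRegime.perfect_observation(latent_dag)
        )
        marg = marginalize(full, ("B", "C", "D", "E"))
        for combo, p in marg.probabilities.items():
            assert closed[combo] == pytest.approx(p, abs=1e-12)


class TestConfoundingWitness:
    def test_two_interpretations_same_observations_different_do(self):
        """A latent common cause makes do-effects underdetermined by observation."""
        dag = DAGSpec(
            ("L", "X", "Y"),
            frozenset({("L", "X"), ("L", "Y"), ("X", "Y")}),
            {"L": 2, "X": 2, "Y": 2},
            latent={"L"},
        )
        copy_mech = ProcessMatrix(np.eye(2), dom=(2,), cod=(2,))
        # Y reads X and ignores L
        y_from_x = ProcessMatrix(
            np.array([[1.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0, 1.0]]),
            dom=(2, 2),
            cod=(2,),
        )
        # Y reads L and ignores X
        y_from_l = ProcessMatrix(
            np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]]),
            dom=(2, 2),
            cod=(2,),
        )
        uniform = state([0.5, 0.5])
        model_causal = CausalModel(
            dag, {"L": uniform, "X": copy_mech, "Y": y_from_x}
        )
        model_confounded = CausalModel(
            dag, {"L": uniform, "X": copy_mech, "Y": y_from_l}
        )
        obs = InterventionRegime.perfect_observation(dag)
        t1 = regime_probabilities(model_causal, obs)
        t2 = regime_probabilities(model_confounded, obs)
        for combo, p in t1.probabilities.items():
            assert t2[combo] == pytest.approx(p, abs=1e-12)
        d1 = do_distribution(model_causal, {"X": basis_state(2, 0)}, "Y")
        d2 = do_distribution(model_confounded, {"X": basis_state(2, 0)}, "Y")
        assert np.abs(d1.entries - d2.entries).max() > 0.4


class TestADMGLayout:
    def test_no_bidirected_edges_reduces_to_dag_comb(self, five_node_dag):
        admg = ADMGSpec(
            five_node_dag.nodes,
            five_node_dag.edges,
            frozenset(),
            five_node_dag.cardinalities,
        )
        layout = build_admg_layout(admg)
        reference = build_comb(five_node_dag)
        assert layout == reference

    def test_bidirected_edge_becomes_two_output_latent_source(self):
        admg = ADMGSpec(
            ("B", "C", "D", "E"),
            frozenset({("B", "D"), ("C", "D"), ("C", "E")}),
            frozenset({("B", "C")}),
            {n: 2 for n in "BCDE"},
        )
        layout = build_admg_layout(admg)
        assert "B~C" in layout.dag.latent
        assert set(layout.dag.children("B~C")) == {"B", "C"}
        assert layout.dag.card("B~C") == 4

    def test_latent_root_margin_expressible_in_admg_layout(self, five_node_dag):
        """Marginalizing the root of the fork matches a bidirected-edge model."""
        latent_dag = DAGSpec(
            five_node_dag.nodes,
            five_node_dag.edges,
            five_node_dag.cardinalities,
            latent={"A"},
        )
        model = random_model(latent_dag, seed=23)
        admg = ADMGSpec(
            ("B", "C", "D", "E"),
            frozenset({("B", "D"), ("C", "D"), ("C", "E")}),
            frozenset({("B", "C")}),
            {n: 2 for n in "BCDE"},
        )
        layout = build_admg_layout(admg, latent_cardinalities={("B", "C"): 2})
        interp = CausalModel(
            layout.dag,
            {
                "B~C": model.mechanism("A"),
                "B": model.mechanism("B"),
                "C": model.mechanism("C"),
                "D": model.mechanism("D"),
                "E": model.mechanism("E"),
            },
        )
        t_dag = regime_probabilities(
            model, InterventionRegime.perfect_observation(latent_dag)
        )
        t_admg = regime_probabilities(
            interp, InterventionRegime.perfect_observation(layout.dag)
        )
        for combo, p in t_dag.probabilities.items():
            assert t_admg[combo] == pytest.approx(p, abs=1e-12)


class TestTableValidation:
    def test_missing_branch_combination_rejected(self):
        with pytest.raises(ModelValidationError, match="missing"):
            BranchProbabilityTable(
                ("X",), {"X": ("1", "2")}, {("1",): 1.0}
            )

    def test_non_unit_total_rejected(self):
        with pytest.raises(ModelValidationError, match="sums to"):
            BranchProbabilityTable(
                ("X",), {"X": ("1", "2")}, {("1",): 0.4, ("2",): 0.4}
            )


def test_parameter_count_of_fork_collider_graph(five_node_dag):
    dag10 = DAGSpec(
        five_node_dag.nodes,
        five_node_dag.edges,
        {n: 10 for n in five_node_dag.nodes},
    )
    assert parameter_count(dag10) == 1310
    assert parameter_count(five_node_dag) == 2 + 4 + 4 + 8 + 4
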