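"""Shared fixtures: worked-example models and the brute-force comb oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from causalcomb import (
    BranchProbabilityTable,
    CausalModel,
    DAGSpec,
    InterventionRegime,
    ProcessMatrix,
    basis_state,
    effect,
    make_perfect_observation,
    make_separable,
    state,
)


@pytest.fixture
def two_node_dag() -> DAGSpec:
    return DAGSpec(("X", "Y"), frozenset({("X", "Y")}), {"X": 2, "Y": 2})


@pytest.fixture
def two_node_model(two_node_dag) -> CausalModel:
    """Binary chain X→Y with x=[0.8,0.2] and y=[[0.6,0.3],[0.4,0.7]]."""
    return CausalModel(
        two_node_dag,
        {
            "X": state([0.8, 0.2]),
            "Y": ProcessMatrix([[0.6, 0.3], [0.4, 0.7]], dom=(2,), cod=(2,)),
        },
    )


@pytest.fixture
def noisy_instrument():
    """Disturbing probe: fuzzy effects [0.8,0.1]/[0.2,0.9] feeding pure states."""
    return make_separable(
        [
            (effect([0.8, 0.1]), basis_state(2, 0)),
            (effect([0.2, 0.9]), basis_state(2, 1)),
        ],
        labels=["psi.phi", "psi'.phi'"],
    )


@pytest.fixture
def randomizing_instrument():
    """MIC probe whose first branch totally randomizes the fed-forward value."""
    return make_separable(
        [
            (effect([0.8, 0.9]), state([0.5, 0.5])),
            (effect([0.2, 0.1]), state([0.9, 0.1])),
        ],
        labels=["psi.phi", "psi'.phi'"],
    )


@pytest.fixture
def bit_flip_instrument():
    """Truthful report with 10% chance of flipping the fed-forward bit."""
    return make_separable(
        [
            (effect([1.0, 0.0]), state([0.9, 0.1])),
            (effect([0.0, 1.0]), state([0.1, 0.9])),
        ],
        labels=["1", "2"],
    )


@pytest.fixture
def five_node_dag() -> DAGSpec:
    """The fork/collider graph A→B, A→C, B→D, C→D, C→E."""
    return DAGSpec(
        ("A", "B", "C", "D", "E"),
        frozenset({("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("C", "E")}),
        {n: 2 for n in "ABCDE"},
    )


def brute_force_regime_table(
    model: CausalModel, regime: InterventionRegime
) -> BranchProbabilityTable:
    """Exhaustive-enumeration oracle for the comb contraction.

    For each combination of instrument branches, sums over every joint
    assignment of pre-gap and post-gap values of every node the product of
    mechanism entries and branch-matrix entries along the wiring (latent
    gaps force post = pre).  Exponential, only for tiny fixtures.
    """
    dag = model.dag
    nodes = dag.nodes
    loci = dag.observable
    cards = {n: dag.card(n) for n in nodes}
    label_sets = [regime.assignment[n].labels for n in loci]
    probs: dict[tuple[str, ...], float] = {}
    for combo in itertools.product(*label_sets):
        branch = {
            n: regime.assignment[n].branch(lbl).entries
            for n, lbl in zip(loci, combo)
        }
        total = 0.0
        value_ranges = [range(cards[n]) for n in nodes] * 2
        for assign in itertools.product(*value_ranges):
            pre = dict(zip(nodes, assign[: len(nodes)]))
            post = dict(zip(nodes, assign[len(nodes):]))
            w = 1.0
            for n in nodes:
                parents = dag.parents(n)
                col = 0
                for p in parents:
                    col = col * cards[p] + post[p]
                w *= model.mechanism(n).entries[pre[n], col]
                if n in dag.latent:
                    w *= 1.0 if post[n] == pre[n] else 0.0
                else:
                    w *= branch[n][post[n], pre[n]]
                if w == 0.0:
                    break
            total += w
        probs[combo] = total
    labels = {n: regime.assignment[n].labels for n in loci}
    return BranchProbabilityTable(loci, labels, probs)
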