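"""Comb-shaped causal models over DAGs and their branch statistics.

A causal model here is a DAG plus one column-stochastic mechanism per node.
Semantically it is a *comb*: a second-order process with one gap (an
input-output wire pair, the *intervention locus*) per observable node.  The
mechanism of a node feeds the bottom of its gap; whatever an instrument
branch plugged into the gap feeds forward is copied to the node's children.
Latent nodes have their gap closed with an identity wire at construction
time, so nothing can be plugged there.

Evaluating a local intervention regime — one instrument per observable
locus — produces the joint probability of every combination of instrument
branches.  The evaluator contracts the comb node by node in topological
order, carrying a joint weight tensor over the realized branches and the
"live" wires still needed downstream; cost is exponential only in the
frontier width, which is small for the desk-scale graphs this package
targets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .instruments import Instrument, make_discard_prepare, make_identity_instrument, make_perfect_observation
from .matrices import (
    DEFAULT_TOL,
    ProcessMatrix,
    WireTypeError,
    is_normalized,
    normalization_defect,
)

__all__ = [
    "DAGSpec",
    "ADMGSpec",
    "CausalModel",
    "InterventionRegime",
    "BranchProbabilityTable",
    "CausalStructureLayout",
    "CycleError",
    "ModelValidationError",
    "build_comb",
    "build_admg_layout",
    "regime_probabilities",
    "marginalize",
    "do_distribution",
    "pad_mechanisms",
    "parameter_count",
]


class CycleError(ValueError):
    """Raised when a supposed DAG contains a directed cycle."""


class ModelValidationError(ValueError):
    """Raised when mechanisms or regimes do not fit the declared graph."""


@dataclass(frozen=True)
class DAGSpec:
    """A DAG with per-node cardinalities and an optional set of latent nodes.

    The node list is reordered into a topological order on construction, so
    downstream code may rely on ``nodes`` being topologically sorted.
    Parent order (hence mechanism input order) is the order in which the
    parents appear in ``nodes``.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    cardinalities: Mapping[str, int]
    latent: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        nodes = tuple(str(n) for n in self.nodes)
        if len(set(nodes)) != len(nodes):
            raise ModelValidationError(f"duplicate node names in {nodes}")
        edges = frozenset((str(p), str(c)) for p, c in self.edges)
        for p, c in edges:
            for endpoint in (p, c):
                if endpoint not in nodes:
                    raise ModelValidationError(f"edge endpoint {endpoint!r} is not a declared node")
        latent = frozenset(str(n) for n in self.latent)
        for n in latent:
            if n not in nodes:
                raise ModelValidationError(f"latent node {n!r} is not a declared node")
        cards = {n: int(self.cardinalities[n]) for n in nodes}
        for n, c in cards.items():
            if c < 1:
                raise ModelValidationError(f"cardinality of {n!r} must be >= 1, got {c}")
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        try:
            # stable: keeps the declared order wherever it is already valid
            topo = tuple(nx.lexicographical_topological_sort(g, key=lambda n: nodes.index(n)))
        except nx.NetworkXUnfeasible:
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise CycleError(f"graph has a directed cycle: {' -> '.join(cycle + cycle[:1])}")
        object.__setattr__(self, "nodes", topo)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "cardinalities", cards)
        object.__setattr__(self, "latent", latent)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if (n, node) in self.edges)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if (node, n) in self.edges)

    @property
    def observable(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.latent)

    def card(self, node: str) -> int:
        return self.cardinalities[node]


@dataclass(frozen=True)
class ADMGSpec:
    """Acyclic directed mixed graph: directed edges plus bidirected edges."""

    nodes: tuple[str, ...]
    directed: frozenset[tuple[str, str]]
    bidirected: frozenset[tuple[str, str]]
    cardinalities: Mapping[str, int]


@dataclass(frozen=True)
class LocusWiring:
    """Wiring of one node in the comb layout."""

    node: str
    inputs: tuple[str, ...]  # parents feeding the mechanism, in order
    fanout: tuple[str, ...]  # destinations of the copy after the gap: children + locus
    latent: bool


@dataclass(frozen=True)
class CausalStructureLayout:
    """Evaluation plan for the comb of a DAG: per-node wiring in topo order."""

    dag: DAGSpec
    wiring: tuple[LocusWiring, ...]

    def __getitem__(self, node: str) -> LocusWiring:
        for w in self.wiring:
            if w.node == node:
                return w
        raise KeyError(node)


def build_comb(dag: DAGSpec) -> CausalStructureLayout:
    """Lay out the comb for a DAG.

    For each node: the mechanism reads the node's parents, its output enters
    the locus gap, and the value fed forward out of the gap is copied to the
    node's children.  Latent loci are closed with an identity, so their
    mechanism output is copied straight to the children.
    """
    wiring = []
    for node in dag.nodes:
        fanout = dag.children(node)
        if node not in dag.latent:
            fanout = fanout + (node,)  # the locus output of the overall comb
        wiring.append(
            LocusWiring(
                node=node,
                inputs=dag.parents(node),
                fanout=fanout,
                latent=node in dag.latent,
            )
        )
    return CausalStructureLayout(dag=dag, wiring=tuple(wiring))


def build_admg_layout(
    admg: ADMGSpec,
    latent_cardinalities: Mapping[tuple[str, str], int] | None = None,
) -> CausalStructureLayout:
    """Comb layout for an ADMG: one latent source per bidirected edge.

    Each bidirected edge u<->v becomes a synthetic latent root "u~v" feeding
    both endpoints.  Its cardinality defaults to |u|·|v|, which is enough for
    the endpoint mechanisms to emulate an arbitrary joint latent state by
    composing with coordinate projections.  The returned layout is evaluable
    by :func:`regime_probabilities` once latent-state interpretations (the
    mechanisms of the synthetic roots) are supplied in a
    :class:`CausalModel`.
    """
    nodes = list(admg.nodes)
    edges = set(admg.directed)
    cards = dict(admg.cardinalities)
    latent: set[str] = set()
    for u, v in sorted(admg.bidirected):
        name = f"{u}~{v}"
        if name in cards:
            raise ModelValidationError(f"latent name {name!r} collides with a node")
        card = None
        if latent_cardinalities is not None:
            card = latent_cardinalities.get((u, v), latent_cardinalities.get((v, u)))
        if card is None:
            card = cards[u] * cards[v]
        nodes.insert(0, name)
        cards[name] = card
        latent.add(name)
        edges.add((name, u))
        edges.add((name, v))
    dag = DAGSpec(tuple(nodes), frozenset(edges), cards, frozenset(latent))
    return build_comb(dag)


@dataclass(frozen=True)
class CausalModel:
    """A DAG plus one normalized mechanism matrix per node."""

    dag: DAGSpec
    mechanisms: Mapping[str, ProcessMatrix]
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        mechs = dict(self.mechanisms)
        for node in self.dag.nodes:
            if node not in mechs:
                raise ModelValidationError(f"no mechanism for node {node!r}")
            mech = mechs[node]
            want_dom = tuple(self.dag.card(p) for p in self.dag.parents(node))
            want_cod = (self.dag.card(node),)
            if mech.dom != want_dom or mech.cod != want_cod:
                raise ModelValidationError(
                    f"mechanism for {node!r} has type {mech.dom}->{mech.cod}, "
                    f"expected {want_dom}->{want_cod}"
                )
            if not is_normalized(mech, self.tol):
                raise ModelValidationError(
                    f"mechanism for {node!r} is not column-stochastic "
                    f"(worst column defect {normalization_defect(mech):.3g})"
                )
        object.__setattr__(self, "mechanisms", mechs)

    @property
    def is_strictly_positive(self) -> bool:
        return all(m.entries.min() > 0 for m in self.mechanisms.values())

    def mechanism(self, node: str) -> ProcessMatrix:
        return self.mechanisms[node]


@dataclass(frozen=True)
class InterventionRegime:
    """One instrument per observable locus; no cross-locus adaptivity."""

    assignment: Mapping[str, Instrument]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    @classmethod
    def perfect_observation(cls, dag: DAGSpec) -> "InterventionRegime":
        return cls({n: make_perfect_observation(dag.card(n)) for n in dag.observable})

    @classmethod
    def identity(cls, dag: DAGSpec) -> "InterventionRegime":
        return cls({n: make_identity_instrument(dag.card(n)) for n in dag.observable})

    def validate(self, dag: DAGSpec) -> None:
        assigned = set(self.assignment)
        expected = set(dag.observable)
        if assigned - expected & dag.latent:
            raise ModelValidationError(
                f"instruments assigned to latent loci: {sorted(assigned & dag.latent)}"
            )
        if assigned != expected:
            missing = expected - assigned
            extra = assigned - expected
            raise ModelValidationError(
                f"regime must cover exactly the observable loci; "
                f"missing {sorted(missing)}, extra {sorted(extra)}"
            )
        for node, ins in self.assignment.items():
            want = (dag.card(node),)
            if ins.dom != want or ins.cod != want:
                raise WireTypeError(
                    f"instrument at {node!r} has type {ins.dom}->{ins.cod}, "
                    f"expected {want}->{want}"
                )


@dataclass(frozen=True)
class BranchProbabilityTable:
    """Joint probabilities over one branch label per observable locus."""

    loci: tuple[str, ...]
    branch_labels: Mapping[str, tuple[str, ...]]
    probabilities: Mapping[tuple[str, ...], float]
    tol: float = 1e-6

    def __post_init__(self) -> None:
        labels = {n: tuple(v) for n, v in self.branch_labels.items()}
        probs = {tuple(k): float(v) for k, v in self.probabilities.items()}
        object.__setattr__(self, "branch_labels", labels)
        object.__setattr__(self, "probabilities", probs)
        if set(labels) != set(self.loci):
            raise ModelValidationError("branch_labels must name exactly the loci")
        expected = set(itertools.product(*(labels[n] for n in self.loci)))
        if set(probs) != expected:
            missing = expected - set(probs)
            extra = set(probs) - expected
            raise ModelValidationError(
                f"table keys must cover every branch combination exactly once; "
                f"{len(missing)} missing (e.g. {sorted(missing)[:3]}), {len(extra)} extra"
            )
        for k, v in probs.items():
            if v < -self.tol:
                raise ModelValidationError(f"negative probability {v} at {k}")
        total = sum(probs.values())
        if abs(total - 1.0) > self.tol:
            raise ModelValidationError(f"table sums to {total}, not 1")

    def __getitem__(self, key: Sequence[str]) -> float:
        return self.probabilities[tuple(key)]

    def total(self) -> float:
        return sum(self.probabilities.values())

    def marginalize(self, keep: Sequence[str]) -> "BranchProbabilityTable":
        return marginalize(self, keep)


def marginalize(
    table: BranchProbabilityTable, keep: Sequence[str]
) -> BranchProbabilityTable:
    """Sum the table over the branch labels of the discarded loci."""
    keep = tuple(keep)
    for n in keep:
        if n not in table.loci:
            raise KeyError(f"unknown locus {n!r}; table has {table.loci}")
    pos = [table.loci.index(n) for n in keep]
    out: dict[tuple[str, ...], float] = {}
    for combo, p in table.probabilities.items():
        key = tuple(combo[i] for i in pos)
        out[key] = out.get(key, 0.0) + p
    labels = {n: table.branch_labels[n] for n in keep}
    return BranchProbabilityTable(keep, labels, out, tol=table.tol)


# -- the contraction evaluator --------------------------------------------

def _contract_branch_tensor(
    model: CausalModel, instruments: Mapping[str, Instrument]
) -> np.ndarray:
    """Joint branch-probability tensor, one axis per observable locus.

    Carries a weight tensor whose axes are the already-realized branch
    choices plus the live post-gap wires; each node multiplies in its
    mechanism, applies the instrument branch stack (or the identity closure
    for a latent locus), and wires that no later mechanism reads are summed
    out immediately.
    """
    dag = model.dag
    consumers = {n: len(dag.children(n)) for n in dag.nodes}

    next_id = itertools.count()
    weight = np.ones(())
    w_ids: list[int] = []
    wire_id: dict[str, int] = {}
    branch_ids: dict[str, int] = {}

    def sum_out(axis_id: int) -> None:
        nonlocal weight
        pos = w_ids.index(axis_id)
        weight = weight.sum(axis=pos)
        del w_ids[pos]

    for node in dag.nodes:
        parents = dag.parents(node)
        pcards = tuple(dag.card(p) for p in parents)
        mech = model.mechanism(node).entries.reshape((dag.card(node),) + pcards)
        pre = next(next_id)
        pids = [wire_id[p] for p in parents]
        weight = np.einsum(weight, w_ids, mech, [pre] + pids, w_ids + [pre])
        w_ids.append(pre)
        for p in parents:
            consumers[p] -= 1
            if consumers[p] == 0:
                sum_out(wire_id[p])
        if node in dag.latent:
            wire_id[node] = pre  # gap closed with identity: post = pre
        else:
            tensor = instruments[node].as_tensor()  # (branches, out, in)
            b_id, post = next(next_id), next(next_id)
            out_ids = [i for i in w_ids if i != pre] + [b_id, post]
            weight = np.einsum(weight, w_ids, tensor, [b_id, post, pre], out_ids)
            w_ids[:] = out_ids
            branch_ids[node] = b_id
            wire_id[node] = post
        if consumers[node] == 0 and wire_id[node] in w_ids:
            sum_out(wire_id[node])

    order = [branch_ids[n] for n in dag.observable]
    assert sorted(w_ids) == sorted(order)
    return np.einsum(weight, w_ids, order)


def regime_probabilities(
    model: CausalModel, regime: InterventionRegime | Mapping[str, Instrument]
) -> BranchProbabilityTable:
    """Joint probability of every branch combination under a regime.

    Each entry is the scalar obtained by plugging one branch of each locus's
    instrument into its gap (and identities into latent gaps) and contracting
    the comb; the entries over all combinations sum to 1.
    """
    if not isinstance(regime, InterventionRegime):
        regime = InterventionRegime(regime)
    regime.validate(model.dag)
    tensor = _contract_branch_tensor(model, regime.assignment)
    loci = model.dag.observable
    labels = {n: regime.assignment[n].labels for n in loci}
    probs = {
        tuple(labels[n][i] for n, i in zip(loci, idx)): float(tensor[idx])
        for idx in np.ndindex(tensor.shape)
    }
    return BranchProbabilityTable(loci, labels, probs)


def do_distribution(
    model: CausalModel,
    do_assignments: Mapping[str, ProcessMatrix],
    query: str,
) -> ProcessMatrix:
    """Marginal of ``query`` when the do-loci are discard-and-prepared.

    Each do-locus receives a single-branch instrument that throws away the
    incoming value and emits the given normalized state; every other locus is
    left untouched (identity instrument) and the query locus is read out with
    perfect passive observation.  Returns the probability column over the
    query variable's values, i.e. P(query | do(...)).
    """
    if query in do_assignments:
        raise ModelValidationError(f"query {query!r} is among the do-loci")
    if query not in model.dag.observable:
        raise ModelValidationError(f"query {query!r} is not an observable locus")
    assignment: dict[str, Instrument] = {}
    for node in model.dag.observable:
        if node in do_assignments:
            prepared = do_assignments[node]
            if prepared.cod != (model.dag.card(node),):
                raise WireTypeError(
                    f"do-state at {node!r} has cod {prepared.cod}, "
                    f"expected {(model.dag.card(node),)}"
                )
            assignment[node] = make_discard_prepare(prepared)
        elif node == query:
            assignment[node] = make_perfect_observation(model.dag.card(node))
        else:
            assignment[node] = make_identity_instrument(model.dag.card(node))
    table = regime_probabilities(model, InterventionRegime(assignment))
    marg = table.marginalize([query])
    card = model.dag.card(query)
    vec = np.array([[marg[(str(i + 1),)]] for i in range(card)])
    return ProcessMatrix(vec, dom=(), cod=(card,))


def pad_mechanisms(model: CausalModel) -> CausalModel:
    """Give every mechanism all topological predecessors as inputs.

    The padded mechanism acts as the original on the true parents and
    discards the rest, so the padded and original models generate identical
    regime tables.  This is the canonical fully-connected form on which the
    identification algorithm operates.
    """
    dag = model.dag
    order = dag.nodes
    edges = {(order[i], order[j]) for i in range(len(order)) for j in range(i + 1, len(order))}
    padded_dag = DAGSpec(order, frozenset(edges), dag.cardinalities, dag.latent)
    mechanisms = {}
    for j, node in enumerate(order):
        preds = order[:j]
        true_parents = dag.parents(node)
        shape = [dag.card(node)] + [dag.card(p) if p in true_parents else 1 for p in preds]
        mech = model.mechanism(node).entries.reshape(shape)
        full = np.broadcast_to(mech, [dag.card(node)] + [dag.card(p) for p in preds])
        flat = full.reshape(dag.card(node), -1)
        mechanisms[node] = ProcessMatrix(
            flat.copy(), dom=tuple(dag.card(p) for p in preds), cod=(dag.card(node),)
        )
    return CausalModel(padded_dag, mechanisms, tol=model.tol)


def parameter_count(dag: DAGSpec) -> int:
    """Number of entries in the conditional-probability matrices of a DAG.

    Each node contributes |X|·∏|parents| numbers; a five-node fork/collider
    graph at cardinality 10 per node needs 1310 numbers instead of the
    100000 of an unconstrained joint distribution.
    """
    return sum(
        dag.card(n) * math.prod(dag.card(p) for p in dag.parents(n)) for n in dag.nodes
    )
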