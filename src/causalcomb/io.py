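"""File formats and seeded fixture generators.

Models, graphs and instruments travel as JSON documents; branch-probability
tables travel as TSV with one header row (locus names plus ``probability``)
so they open directly in a spreadsheet.  Matrices are serialized as nested
arrays in the package's column-stochastic orientation: row = output value,
column = mixed-radix joint input index with the first input most
significant.  Probabilities round-trip at full ``repr`` precision.

The generators produce seeded random DAGs, strictly positive models and
noisy separable instruments — the synthetic study material used throughout
the test-suite and the acceptance benchmarks.
"""

from __future__ import annotations

import itertools
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instruments import (
    Instrument,
    make_coarse_grained_observation,
    make_discard_prepare,
    make_identity_instrument,
    make_perfect_observation,
    make_separable,
)
from .matrices import ProcessMatrix, effect, state
from .models import (
    BranchProbabilityTable,
    CausalModel,
    DAGSpec,
    ModelValidationError,
)

__all__ = [
    "MODEL_SCHEMA",
    "read_model",
    "write_model",
    "read_graph",
    "write_graph",
    "read_table",
    "write_table",
    "instrument_from_spec",
    "instrument_to_spec",
    "random_dag",
    "random_model",
    "random_separable_instrument",
]

MODEL_SCHEMA = "causalcomb/model-v1"
INSTRUMENT_SCHEMA = "causalcomb/instrument-v1"


class DocumentError(ValueError):
    """Raised when a document fails schema or stochasticity validation."""


# -- graphs and models ----------------------------------------------------

def _graph_from_doc(doc: Mapping) -> DAGSpec:
    for key in ("nodes", "cardinalities"):
        if key not in doc:
            raise DocumentError(f"document missing required field {key!r}")
    return DAGSpec(
        nodes=tuple(doc["nodes"]),
        edges=frozenset((p, c) for p, c in doc.get("edges", [])),
        cardinalities=dict(doc["cardinalities"]),
        latent=frozenset(doc.get("latent", [])),
    )


def _graph_to_doc(dag: DAGSpec) -> dict:
    return {
        "nodes": list(dag.nodes),
        "edges": sorted([p, c] for p, c in dag.edges),
        "cardinalities": dict(dag.cardinalities),
        "latent": sorted(dag.latent),
    }


def read_graph(path: str | Path) -> DAGSpec:
    with open(path) as fh:
        return _graph_from_doc(json.load(fh))


def write_graph(dag: DAGSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_graph_to_doc(dag), fh, indent=1)
        fh.write("\n")


def read_model(path: str | Path, tol: float = 1e-9) -> CausalModel:
    """Load a model document, validating stochasticity column by column."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != MODEL_SCHEMA:
        raise DocumentError(
            f"unrecognized schema {doc.get('schema')!r}; expected {MODEL_SCHEMA!r}"
        )
    dag = _graph_from_doc(doc)
    mechanisms = {}
    for node in dag.nodes:
        if node not in doc.get("mechanisms", {}):
            raise DocumentError(f"no mechanism for node {node!r}")
        arr = np.asarray(doc["mechanisms"][node], dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(-1, 1)
        colsums = arr.sum(axis=0)
        bad = np.flatnonzero(np.abs(colsums - 1.0) > tol)
        if bad.size:
            raise DocumentError(
                f"mechanism for node {node!r} is not column-stochastic: "
                f"column {bad[0]} sums to {colsums[bad[0]]!r}"
            )
        dom = tuple(dag.card(p) for p in dag.parents(node))
        mechanisms[node] = ProcessMatrix(arr, dom=dom, cod=(dag.card(node),))
    return CausalModel(dag, mechanisms)


def write_model(model: CausalModel, path: str | Path) -> None:
    doc = _graph_to_doc(model.dag)
    doc["schema"] = MODEL_SCHEMA
    doc["orientation"] = (
        "rows = child value; columns = mixed-radix joint parent index, "
        "first parent most significant; columns sum to 1"
    )
    doc["mechanisms"] = {
        node: model.mechanism(node).entries.tolist() for node in model.dag.nodes
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# -- tables ---------------------------------------------------------------

def write_table(table: BranchProbabilityTable, path: str | Path) -> None:
    rows = []
    for combo in itertools.product(*(table.branch_labels[n] for n in table.loci)):
        rows.append(list(combo) + [repr(table.probabilities[combo])])
    frame = pd.DataFrame(rows, columns=list(table.loci) + ["probability"])
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, tol: float = 1e-6) -> BranchProbabilityTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "probability" not in frame.columns:
        raise DocumentError("table file has no 'probability' column")
    loci = tuple(c for c in frame.columns if c != "probability")
    if not loci:
        raise DocumentError("table file names no loci")
    labels: dict[str, list[str]] = {n: [] for n in loci}
    probs: dict[tuple[str, ...], float] = {}
    for _, row in frame.iterrows():
        combo = tuple(str(row[n]) for n in loci)
        if combo in probs:
            raise DocumentError(f"duplicate branch combination {combo}")
        probs[combo] = float(row["probability"])
        for n, lbl in zip(loci, combo):
            if lbl not in labels[n]:
                labels[n].append(lbl)
    try:
        return BranchProbabilityTable(
            loci, {n: tuple(v) for n, v in labels.items()}, probs, tol=tol
        )
    except ModelValidationError as exc:
        raise DocumentError(str(exc)) from exc


# -- instruments ----------------------------------------------------------

def instrument_from_spec(spec: Mapping, cardinality: int) -> Instrument:
    """Build an instrument from a JSON-style description.

    Supported kinds: ``perfect_observation``, ``identity``,
    ``discard_prepare`` (fields: state, optional label), ``separable``
    (field branches: list of {label?, effect, state}), ``coarse_grained``
    (field blocks: list of lists of 1-based values), ``branches``
    (field branches: list of {label, matrix}).
    """
    kind = spec.get("kind")
    if kind == "perfect_observation":
        return make_perfect_observation(cardinality)
    if kind == "identity":
        return make_identity_instrument(cardinality)
    if kind == "discard_prepare":
        st = state(spec["state"])
        return make_discard_prepare(st, label=spec.get("label", "prepare"))
    if kind == "separable":
        pairs, labels = [], []
        for i, br in enumerate(spec["branches"]):
            pairs.append((effect(br["effect"]), state(br["state"])))
            labels.append(str(br.get("label", f"b{i + 1}")))
        return make_separable(pairs, labels)
    if kind == "coarse_grained":
        blocks = [[int(v) - 1 for v in blk] for blk in spec["blocks"]]
        return make_coarse_grained_observation(cardinality, blocks)
    if kind == "branches":
        branches = tuple(
            (
                str(br["label"]),
                ProcessMatrix(
                    np.asarray(br["matrix"], dtype=float),
                    dom=(cardinality,),
                    cod=(cardinality,),
                ),
            )
            for br in spec["branches"]
        )
        return Instrument(branches)
    raise DocumentError(f"unknown instrument kind {kind!r}")


def instrument_to_spec(instrument: Instrument) -> dict:
    return {
        "schema": INSTRUMENT_SCHEMA,
        "kind": "branches",
        "branches": [
            {"label": lbl, "matrix": mat.entries.tolist()}
            for lbl, mat in instrument.branches
        ],
    }


# -- seeded generators ----------------------------------------------------

def random_dag(
    n_nodes: int,
    seed: int = 0,
    max_cardinality: int = 3,
    edge_probability: float = 0.5,
) -> DAGSpec:
    """A random DAG on nodes X1..Xn with random per-node cardinalities."""
    rng = np.random.default_rng(seed)
    nodes = tuple(f"X{i + 1}" for i in range(n_nodes))
    edges = {
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_probability
    }
    cards = {n: int(rng.integers(2, max_cardinality + 1)) for n in nodes}
    return DAGSpec(nodes, frozenset(edges), cards)


def random_model(dag: DAGSpec, seed: int = 0, min_entry: float = 0.05) -> CausalModel:
    """A strictly positive random model: Dirichlet columns floored at min_entry.

    Each mechanism column is drawn from a flat Dirichlet and then mixed
    toward the floor, ``col ← min_entry + (1 − card·min_entry)·col``, which
    keeps columns stochastic while bounding every entry into
    ``[min_entry, 1 − (card−1)·min_entry]``.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    mechanisms = {}
    for node in dag.nodes:
        card = dag.card(node)
        if min_entry * card >= 1.0:
            raise ValueError(
                f"min_entry {min_entry} infeasible for cardinality {card}"
            )
        n_cols = math.prod(dag.card(p) for p in dag.parents(node))
        cols = rng.dirichlet(np.ones(card), size=n_cols).T  # (card, n_cols)
        cols = min_entry + (1.0 - card * min_entry) * cols
        mechanisms[node] = ProcessMatrix(
            cols, dom=tuple(dag.card(p) for p in dag.parents(node)), cod=(card,)
        )
    return CausalModel(dag, mechanisms)


def random_separable_instrument(
    cardinality: int,
    seed: int = 0,
    effect_noise: float = 0.2,
    state_noise: float = 0.2,
) -> Instrument:
    """A noisy, disturbing — but marginally informationally complete — probe.

    Effects are the rows of a perturbed identity (each branch is a fuzzy
    "has value i" predicate), and states are basis states mixed toward the
    uniform distribution; both families stay linearly independent, so the
    separable criterion certifies marginal informational completeness.
    """
    rng = np.random.default_rng(seed)
    eps = rng.uniform(0.05, effect_noise)
    delta = rng.uniform(0.05, state_noise)
    eff = (1.0 - eps) * np.eye(cardinality) + eps / cardinality
    pairs, labels = [], []
    for i in range(cardinality):
        phi = effect(eff[i])
        psi_vec = (1.0 - delta) * np.eye(cardinality)[i] + delta / cardinality
        pairs.append((phi, state(psi_vec)))
        labels.append(str(i + 1))
    return make_separable(pairs, labels)
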