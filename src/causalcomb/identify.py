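"""Identification of comb models from accessible branch statistics.

Given a DAG and, for each locus, an *accessible set* of instruments, the
joint branch-probability tables of all accessible regimes determine a
Markovian model completely — provided every accessible set is marginally
informationally complete.  The reconstruction is constructive: a double
induction that recovers the mechanisms node by node in topological order.
For each target node, the state arriving at its locus under every fixed
combination of earlier branches is first read off by linear-inversion
tomography (later loci marginalize away because instrument branch sums are
stochastic); then, working forward through the earlier loci, known basis
probes are plugged into already-identified structure until the target
mechanism itself is isolated, in its padded form with every topological
predecessor as an input.

All inversions are solved by least squares with explicit rank checks, so
informationally incomplete accessible sets fail loudly with a diagnostic
naming the offending locus, and finite-sample tables degrade gracefully
into reported residuals rather than silent error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .instruments import (
    CompletenessVerdict,
    Instrument,
    is_marginally_informationally_complete,
)
from .matrices import DEFAULT_TOL, ProcessMatrix, joint_index
from .models import (
    BranchProbabilityTable,
    CausalModel,
    DAGSpec,
    InterventionRegime,
    ModelValidationError,
    marginalize,
    regime_probabilities,
)

__all__ = [
    "AccessibleData",
    "IdentifiedModel",
    "InformationalIncompletenessError",
    "TableInconsistencyError",
    "tomography_solve",
    "identify_markovian",
    "identify_latent_root",
    "predict_counterfactual",
]


class InformationalIncompletenessError(ValueError):
    """A tomography system did not have full rank."""

    def __init__(self, message: str, rank_found: int, rank_required: int):
        super().__init__(message)
        self.rank_found = rank_found
        self.rank_required = rank_required


class TableInconsistencyError(ValueError):
    """Accessible tables are mutually inconsistent beyond tolerance."""


RegimeKey = tuple[int, ...]


@dataclass
class AccessibleData:
    """Accessible sets of instruments plus their regime tables.

    Tables may be given up front (one per regime, keyed by the tuple of
    instrument indices, one per observable locus in topological order) or
    produced on demand by an oracle callable; oracle queries are cached.
    """

    dag: DAGSpec
    accessible_sets: Mapping[str, Sequence[Instrument]]
    tables: Mapping[RegimeKey, BranchProbabilityTable] | None = None
    oracle: Callable[[RegimeKey], BranchProbabilityTable] | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.tables is None and self.oracle is None:
            raise ModelValidationError("provide tables or an oracle")
        self.accessible_sets = {n: list(v) for n, v in self.accessible_sets.items()}
        for node in self.dag.observable:
            if node not in self.accessible_sets or not self.accessible_sets[node]:
                raise ModelValidationError(f"no accessible instruments at locus {node!r}")
            want = (self.dag.card(node),)
            for ins in self.accessible_sets[node]:
                if ins.dom != want or ins.cod != want:
                    raise ModelValidationError(
                        f"accessible instrument at {node!r} has type "
                        f"{ins.dom}->{ins.cod}, expected {want}->{want}"
                    )
        if self.tables is not None:
            self.tables = {tuple(k): v for k, v in self.tables.items()}

    @classmethod
    def from_model(
        cls,
        model: CausalModel,
        accessible_sets: Mapping[str, Sequence[Instrument]],
        n_trials: int | None = None,
        seed: int = 0,
    ) -> "AccessibleData":
        """Forward-simulate tables on demand from a known model.

        With ``n_trials`` set, each table is replaced by empirical branch
        frequencies from a multinomial sample of that size, emulating
        finite-trial data collection.
        """
        sets = {n: list(v) for n, v in accessible_sets.items()}
        loci = model.dag.observable
        rng = np.random.default_rng(seed)

        def oracle(key: RegimeKey) -> BranchProbabilityTable:
            regime = InterventionRegime(
                {node: sets[node][i] for node, i in zip(loci, key)}
            )
            table = regime_probabilities(model, regime)
            if n_trials is None:
                return table
            combos = list(table.probabilities)
            probs = np.array([table.probabilities[c] for c in combos])
            counts = rng.multinomial(n_trials, probs / probs.sum())
            freqs = {c: counts[i] / n_trials for i, c in enumerate(combos)}
            return BranchProbabilityTable(table.loci, table.branch_labels, freqs)

        return cls(dag=model.dag, accessible_sets=sets, oracle=oracle)

    def table_for(self, key: RegimeKey) -> BranchProbabilityTable:
        key = tuple(key)
        if self.tables is not None and key in self.tables:
            return self.tables[key]
        if key not in self._cache:
            if self.oracle is None:
                raise KeyError(f"no table for regime {key} and no oracle")
            self._cache[key] = self.oracle(key)
        return self._cache[key]


@dataclass(frozen=True)
class IdentifiedModel:
    """A recovered padded model with per-node reconstruction diagnostics."""

    model: CausalModel
    residuals: Mapping[str, float]
    condition_numbers: Mapping[str, float]
    mic_verdicts: Mapping[str, CompletenessVerdict]

    def worst_residual(self) -> float:
        return max(self.residuals.values(), default=0.0)

    def redundant_inputs(self, tol: float = 1e-8) -> dict[str, tuple[str, ...]]:
        """Report padded inputs on which a recovered mechanism is constant.

        Inputs that the declared DAG never had as parents should show up
        here when recovery is exact; the padding is reported, never removed.
        """
        out: dict[str, tuple[str, ...]] = {}
        dag = self.model.dag
        for j, node in enumerate(dag.nodes):
            preds = dag.nodes[:j]
            mech = self.model.mechanism(node)
            shape = (dag.card(node),) + tuple(dag.card(p) for p in preds)
            tensor = mech.entries.reshape(shape)
            const = []
            for axis, p in enumerate(preds, start=1):
                spread = tensor.max(axis=axis) - tensor.min(axis=axis)
                if spread.max(initial=0.0) <= tol:
                    const.append(p)
            out[node] = tuple(const)
        return out


def tomography_solve(
    probe_matrix: np.ndarray,
    measurements: np.ndarray,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, float, float]:
    """Least-squares linear inversion with an explicit rank check.

    Rows of ``probe_matrix`` are the known probe vectors (effects or
    states), ``measurements`` the corresponding pairing numbers.  Returns
    the solution, the worst-case residual and the condition number of the
    probe system.  Raises if the probes do not span the unknown's space.
    """
    probe = np.asarray(probe_matrix, dtype=float)
    meas = np.asarray(measurements, dtype=float)
    if probe.ndim != 2:
        raise ValueError("probe matrix must be 2-D")
    s = np.linalg.svd(probe, compute_uv=False)
    required = probe.shape[1]
    rank = int((s > tol * (s[0] if s.size else 0.0)).sum())
    if rank < required:
        raise InformationalIncompletenessError(
            f"probe system has rank {rank}, needs {required}: "
            f"the probes are not informationally complete",
            rank_found=rank,
            rank_required=required,
        )
    solution, *_ = np.linalg.lstsq(probe, meas, rcond=None)
    residual = float(np.abs(probe @ solution - meas).max())
    cond = float(s[0] / s[rank - 1]) if s.size else 1.0
    return solution, residual, cond


def _clip_tiny_negatives(arr: np.ndarray, tol: float) -> np.ndarray:
    out = arr.copy()
    mask = (out < 0) & (out > -max(tol, 1e-7))
    out[mask] = 0.0
    return out


def identify_markovian(
    data: AccessibleData,
    tol: float = DEFAULT_TOL,
    n_random: int = 20,
    seed: int = 0,
) -> IdentifiedModel:
    """Reconstruct every mechanism of a Markovian model from its tables.

    Outer induction over the nodes in topological order; for node ``n`` an
    inner induction eliminates the earlier loci one at a time.  The base
    step reads off, for each combination of branches at loci before ``n``,
    the state arriving at locus ``n`` by tomography against the accessible
    effects there (later loci are marginalized away).  Each inner step plugs
    standard basis probes into the already-identified earlier mechanisms:
    strict positivity guarantees the realized probe states have full
    support, so the accessible branches turn them into an informationally
    complete family and one more locus can be inverted away.  The recovered
    model is in padded form (every topological predecessor is an input).
    """
    dag = data.dag
    if dag.latent:
        raise ModelValidationError(
            f"identify_markovian requires a Markovian model; latent loci: {sorted(dag.latent)}"
        )
    order = dag.observable
    m = len(order)
    cards = [dag.card(n) for n in order]

    mic_verdicts = {
        node: is_marginally_informationally_complete(
            data.accessible_sets[node], tol=tol, n_random=n_random, seed=seed
        )
        for node in order
    }

    # branch pools: the union of branches over the accessible set per locus,
    # each remembering the instrument it came from (needed to pick regimes)
    pools: list[list[tuple[int, str, np.ndarray]]] = []
    for node in order:
        pool = []
        for i_idx, ins in enumerate(data.accessible_sets[node]):
            for lbl, mat in ins.branches:
                pool.append((i_idx, lbl, mat.entries))
        pools.append(pool)

    marg_cache: dict = {}

    def measured(entries: tuple[tuple[int, str], ...]) -> float:
        """P(branches at loci 0..n realized), later loci marginalized."""
        n = len(entries)
        key = tuple(e[0] for e in entries) + (0,) * (m - n)
        cache_key = (key, n)
        if cache_key not in marg_cache:
            marg_cache[cache_key] = marginalize(data.table_for(key), order[:n])
        return marg_cache[cache_key][tuple(e[1] for e in entries)]

    mechanisms: dict[str, ProcessMatrix] = {}
    residuals: dict[str, float] = {}
    conditions: dict[str, float] = {}

    for n_idx, node in enumerate(order):
        c_n = cards[n_idx]
        worst_res, worst_cond = 0.0, 1.0

        # tomography system at the target locus: effects d∘ϕ_n
        effect_rows = np.asarray([mat.sum(axis=0) for _, _, mat in pools[n_idx]])

        # base: states on the target for every combination of earlier branches
        stage: dict[tuple, np.ndarray] = {}
        for combo in itertools.product(*pools[:n_idx]):
            combo_key = tuple((i, lbl) for i, lbl, _ in combo)
            try:
                q = np.array(
                    [measured(combo_key + ((i, lbl),)) for i, lbl, _ in pools[n_idx]]
                )
                sol, res, cond = tomography_solve(effect_rows, q, tol)
            except InformationalIncompletenessError as exc:
                raise InformationalIncompletenessError(
                    f"locus {node!r}: accessible effects are not informationally "
                    f"complete ({exc})",
                    exc.rank_found,
                    exc.rank_required,
                ) from exc
            stage[combo_key] = sol.reshape(c_n, 1)
            worst_res = max(worst_res, res)
            worst_cond = max(worst_cond, cond)

        # inner induction: eliminate loci 0..n_idx-1 in order using the
        # mechanisms already identified there
        for k0 in range(n_idx):
            c_k = cards[k0]
            in_dim = int(np.prod(cards[:k0])) if k0 else 1
            mech_k = mechanisms[order[k0]].entries  # (c_k, in_dim), padded
            # realized probe states per basis input: rows are ϕ_k∘x_k∘ε
            probe_rows = []
            for v in range(in_dim):
                s_v = mech_k[:, v]
                probe_rows.append(np.asarray([mat @ s_v for _, _, mat in pools[k0]]))
            new_stage: dict[tuple, np.ndarray] = {}
            tail_pools = pools[k0 + 1 : n_idx]
            for combo in itertools.product(*tail_pools):
                combo_key = tuple((i, lbl) for i, lbl, _ in combo)
                mat_out = np.empty((c_n, in_dim * c_k))
                for v in range(in_dim):
                    data_rows = np.asarray(
                        [
                            stage[((i, lbl),) + combo_key][:, v]
                            for i, lbl, _ in pools[k0]
                        ]
                    )
                    try:
                        coeff, res, cond = tomography_solve(
                            probe_rows[v], data_rows, tol
                        )
                    except InformationalIncompletenessError as exc:
                        raise InformationalIncompletenessError(
                            f"locus {order[k0]!r}: realized probe states are not "
                            f"informationally complete (rank {exc.rank_found} of "
                            f"{exc.rank_required}); the accessible set is not "
                            f"marginally informationally complete or the model "
                            f"violates strict positivity",
                            exc.rank_found,
                            exc.rank_required,
                        ) from exc
                    worst_res = max(worst_res, res)
                    worst_cond = max(worst_cond, cond)
                    for w in range(c_k):
                        mat_out[:, v * c_k + w] = coeff[w]
                new_stage[combo_key] = mat_out
            stage = new_stage

        mech = _clip_tiny_negatives(stage[()], tol)
        dom = tuple(cards[:n_idx])
        mechanisms[node] = ProcessMatrix(mech, dom=dom, cod=(c_n,))
        residuals[node] = max(
            worst_res, float(np.abs(mech.sum(axis=0) - 1.0).max())
        )
        conditions[node] = worst_cond

    edges = {
        (order[i], order[j]) for i in range(m) for j in range(i + 1, m)
    }
    padded_dag = DAGSpec(order, frozenset(edges), dag.cardinalities, frozenset())
    # mechanisms are only approximately stochastic under noisy tables;
    # validate at a tolerance matching the observed residuals
    model_tol = max(DEFAULT_TOL, 10.0 * max(residuals.values(), default=0.0))
    model = CausalModel(padded_dag, mechanisms, tol=model_tol)
    return IdentifiedModel(model, residuals, conditions, mic_verdicts)


def identify_latent_root(
    table: BranchProbabilityTable,
) -> tuple[ProcessMatrix, ProcessMatrix]:
    """Recover the margin of a fork/collider model whose root is latent.

    ``table`` must be the perfect-passive-observation table over the four
    observable loci (B, C, D, E) of a strictly positive model on the graph
    A→B, A→C, B→D, C→D, C→E with A latent.  Individual mechanisms are not
    identifiable, but the comb margin is: the joint state on B⊗C (read off
    by marginalizing D and E) and the channel B⊗C→D⊗E whose entries are
    accessible probabilities divided by the already-known state entries.
    Together with discards these reproduce every table entry.
    """
    if len(table.loci) != 4:
        raise ModelValidationError(
            f"expected a table over 4 loci (B, C, D, E), got {table.loci}"
        )
    b, c, d, e = table.loci
    cb, cc = len(table.branch_labels[b]), len(table.branch_labels[c])
    cd, ce = len(table.branch_labels[d]), len(table.branch_labels[e])
    sigma = np.zeros((cb * cc, 1))
    marg = marginalize(table, (b, c))
    for i, lb in enumerate(table.branch_labels[b]):
        for j, lc in enumerate(table.branch_labels[c]):
            sigma[joint_index((i, j), (cb, cc)), 0] = marg[(lb, lc)]
    if sigma.min() <= 0.0:
        raise ModelValidationError(
            "zero marginal probability on (B, C): strict positivity violated"
        )
    channel = np.zeros((cd * ce, cb * cc))
    for (lb, lc, ld, le), p in table.probabilities.items():
        i = table.branch_labels[b].index(lb)
        j = table.branch_labels[c].index(lc)
        k = table.branch_labels[d].index(ld)
        l = table.branch_labels[e].index(le)
        col = joint_index((i, j), (cb, cc))
        channel[joint_index((k, l), (cd, ce)), col] = p / sigma[col, 0]
    state = ProcessMatrix(sigma, dom=(), cod=(cb, cc))
    chan = ProcessMatrix(channel, dom=(cb, cc), cod=(cd, ce))
    return state, chan


def predict_counterfactual(
    identified: IdentifiedModel,
    regime: InterventionRegime | Mapping[str, Instrument],
) -> BranchProbabilityTable:
    """Branch table of the recovered model under any (possibly unseen) regime."""
    return regime_probabilities(identified.model, regime)
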