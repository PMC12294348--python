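"""Instruments: branchy probes of a variable at an intervention locus.

An instrument of type A→A′ is a finite labelled set of non-negative branch
matrices whose sum is a stochastic map.  Applying the instrument to a system
realizes exactly one branch, which is reported to the agent; the branch also
determines what is fed forward.  Special cases cover the whole observational
spectrum: perfect passive observation, noisy/disturbing separable probes,
coarse-grained non-disturbing observations, discard-and-prepare (surgical
"do") interventions, and the trivial identity instrument.

The module also decides *informational completeness* (do a set of states or
effects span the space, so that pairing numbers determine any unknown
partner?) and *marginal informational completeness* of instrument sets — the
condition under which Markovian comb models are identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrices import (
    DEFAULT_TOL,
    ProcessMatrix,
    WireTypeError,
    basis_effect,
    basis_state,
    discard,
    identity,
    is_normalized,
    normalization_defect,
    uniform_state,
)

__all__ = [
    "Instrument",
    "InstrumentError",
    "CompletenessVerdict",
    "make_perfect_observation",
    "make_identity_instrument",
    "make_discard_prepare",
    "make_separable",
    "make_coarse_grained_observation",
    "branch_probability",
    "is_informationally_complete",
    "is_marginally_informationally_complete",
]


class InstrumentError(ValueError):
    """Raised when a set of branches fails the instrument axioms."""


@dataclass(frozen=True)
class Instrument:
    """A finite set of labelled branches summing to a normalized map."""

    branches: tuple[tuple[str, ProcessMatrix], ...]
    tol: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if not self.branches:
            raise InstrumentError("an instrument needs at least one branch")
        branches = tuple((str(lbl), mat) for lbl, mat in self.branches)
        object.__setattr__(self, "branches", branches)
        labels = [lbl for lbl, _ in branches]
        if len(set(labels)) != len(labels):
            raise InstrumentError(f"branch labels not unique: {labels}")
        first = branches[0][1]
        for lbl, mat in branches:
            if mat.dom != first.dom or mat.cod != first.cod:
                raise InstrumentError(
                    f"branch {lbl!r} has type {mat.dom}->{mat.cod}, "
                    f"expected {first.dom}->{first.cod}"
                )
        total = sum(mat.entries for _, mat in branches)
        defect = float(np.abs(total.sum(axis=0) - 1.0).max())
        if defect > self.tol:
            raise InstrumentError(
                f"branch sum is not a normalized map (worst column defect {defect:.3g})"
            )

    @property
    def dom(self) -> tuple[int, ...]:
        return self.branches[0][1].dom

    @property
    def cod(self) -> tuple[int, ...]:
        return self.branches[0][1].cod

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.branches)

    def branch(self, label: str) -> ProcessMatrix:
        for lbl, mat in self.branches:
            if lbl == label:
                return mat
        raise KeyError(f"no branch labelled {label!r}; have {list(self.labels)}")

    def branch_sum(self) -> ProcessMatrix:
        total = sum(mat.entries for _, mat in self.branches)
        return ProcessMatrix(total, dom=self.dom, cod=self.cod)

    def as_tensor(self) -> np.ndarray:
        """Stack of branch matrices, shape (n_branches, out_dim, in_dim)."""
        return np.stack([mat.entries for _, mat in self.branches])

    def __len__(self) -> int:
        return len(self.branches)


# -- constructors ---------------------------------------------------------

def make_perfect_observation(cardinality: int) -> Instrument:
    """Perfect passive observation: branch i reports value i and feeds it on.

    Branch labels are the 1-based value labels "1".."|A|".
    """
    branches = tuple(
        (str(i + 1), basis_state(cardinality, i) @ basis_effect(cardinality, i))
        for i in range(cardinality)
    )
    return Instrument(branches)


def make_identity_instrument(cardinality: int) -> Instrument:
    """Single-branch instrument that lets the system pass untouched."""
    return Instrument((("id", identity(cardinality)),))


def make_discard_prepare(state: ProcessMatrix, label: str = "prepare") -> Instrument:
    """Discard the incoming system and emit a fixed normalized state.

    With a pure state this is an atomic "do" intervention.
    """
    if not state.is_state:
        raise InstrumentError(f"expected a state, got dom {state.dom}")
    if not is_normalized(state):
        raise InstrumentError(
            f"prepared state not normalized (defect {normalization_defect(state):.3g})"
        )
    card = state.entries.shape[0]
    return Instrument(((label, state @ discard(card)),))


def make_separable(
    pairs: Sequence[tuple[ProcessMatrix, ProcessMatrix]],
    labels: Sequence[str] | None = None,
    tol: float = DEFAULT_TOL,
) -> Instrument:
    """Instrument whose branches are ψ∘ϕ for an (effect ϕ, state ψ) pair each.

    Given normalized states, the sum condition holds iff the effects sum to
    the discard effect; this is validated explicitly for a clearer error.
    """
    effect_sum = None
    branches = []
    for idx, (phi, psi) in enumerate(pairs):
        if not phi.is_effect:
            raise InstrumentError(f"pair {idx}: first element must be an effect")
        if not psi.is_state:
            raise InstrumentError(f"pair {idx}: second element must be a state")
        if not is_normalized(psi, tol):
            raise InstrumentError(
                f"pair {idx}: state not normalized "
                f"(defect {normalization_defect(psi):.3g})"
            )
        effect_sum = phi.entries if effect_sum is None else effect_sum + phi.entries
        lbl = labels[idx] if labels is not None else f"b{idx + 1}"
        branches.append((lbl, psi @ phi))
    assert effect_sum is not None
    defect = float(np.abs(effect_sum - 1.0).max())
    if defect > tol:
        raise InstrumentError(
            f"effects do not sum to the discard effect (worst defect {defect:.3g})"
        )
    return Instrument(tuple(branches))


def make_coarse_grained_observation(
    cardinality: int, blocks: Sequence[Sequence[int]]
) -> Instrument:
    """Non-disturbing but coarse-grained observation.

    Each block of values yields one branch: the sum of the perfect-observation
    branches for the values in the block.  The observer learns only which
    block the value fell in; the value itself passes through undisturbed.
    Branches for blocks of size > 1 are non-separable.
    """
    seen = sorted(v for blk in blocks for v in blk)
    if seen != list(range(cardinality)):
        raise InstrumentError(
            f"blocks {blocks} are not a partition of 0..{cardinality - 1}"
        )
    branches = []
    for blk in blocks:
        mat = np.zeros((cardinality, cardinality))
        for v in blk:
            mat[v, v] = 1.0
        lbl = "|".join(str(v + 1) for v in blk)
        branches.append((lbl, ProcessMatrix(mat, (cardinality,), (cardinality,))))
    return Instrument(tuple(branches))


# -- probabilities --------------------------------------------------------

def branch_probability(
    instrument: Instrument, input_state: ProcessMatrix, label: str
) -> float:
    """Probability of realizing a branch on a given normalized input state."""
    if not is_normalized(input_state):
        raise InstrumentError("input state must be normalized")
    if input_state.cod != instrument.dom:
        raise WireTypeError(
            f"state on {input_state.cod} fed to instrument with dom {instrument.dom}"
        )
    out = instrument.branch(label) @ input_state
    d = discard(out.entries.shape[0]) if out.cod != () else None
    return (d @ out).scalar if d is not None else out.scalar


# -- informational completeness -------------------------------------------

@dataclass(frozen=True)
class CompletenessVerdict:
    """Outcome of a completeness decision.

    ``complete`` and ``incomplete`` come from exact rank criteria;
    ``probably_complete`` only from the randomized certificate used for
    non-separable branch sets, where a universally quantified condition is
    checked on sampled full-support states.
    """

    status: str  # "complete" | "incomplete" | "probably_complete"
    rank_found: int
    rank_required: int
    witness: ProcessMatrix | None = None

    def __post_init__(self) -> None:
        if self.status not in ("complete", "incomplete", "probably_complete"):
            raise ValueError(f"unknown status {self.status!r}")

    def __bool__(self) -> bool:
        return self.status != "incomplete"


def _numerical_rank(mat: np.ndarray, tol: float) -> tuple[int, np.ndarray | None]:
    """Rank with relative singular-value threshold, plus a null vector if any."""
    if mat.size == 0:
        return 0, None
    u, s, vt = np.linalg.svd(mat)
    cutoff = tol * (s[0] if s.size else 0.0)
    rank = int((s > cutoff).sum())
    null = vt[rank] if rank < vt.shape[0] else None
    return rank, null


def is_informationally_complete(
    vectors: Sequence[ProcessMatrix | np.ndarray],
    cardinality: int,
    tol: float = DEFAULT_TOL,
) -> CompletenessVerdict:
    """Do these states (or effects) span the |A|-dimensional space?

    A set of effects is informationally complete for A exactly when pairing
    numbers determine any state — i.e. the stacked vectors have full rank
    |A|; dually for states.  The witness on failure is a direction invisible
    to every vector in the set.
    """
    rows = []
    for v in vectors:
        arr = v.entries if isinstance(v, ProcessMatrix) else np.asarray(v, float)
        flat = arr.reshape(-1)
        if flat.shape[0] != cardinality:
            raise WireTypeError(
                f"vector of length {flat.shape[0]} for cardinality {cardinality}"
            )
        rows.append(flat)
    rank, null = _numerical_rank(np.asarray(rows), tol)
    if rank >= cardinality:
        return CompletenessVerdict("complete", rank, cardinality)
    witness = None
    if null is not None:
        witness = ProcessMatrix(np.abs(null).reshape(-1, 1), (), (cardinality,))
    return CompletenessVerdict("incomplete", rank, cardinality, witness)


def _separable_factors(
    mat: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """If the branch has numerical rank 1, return (state, effect) factors."""
    u, s, vt = np.linalg.svd(mat)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros(mat.shape[0]), np.zeros(mat.shape[1])
    if s.size > 1 and s[1] > tol * s[0]:
        return None
    psi, phi = u[:, 0] * s[0], vt[0]
    # both factors of a non-negative rank-1 matrix can be flipped together
    if psi.sum() < 0:
        psi, phi = -psi, -phi
    return psi, phi


def is_marginally_informationally_complete(
    instruments: Sequence[Instrument],
    tol: float = DEFAULT_TOL,
    n_random: int = 20,
    seed: int = 0,
) -> CompletenessVerdict:
    """Decide marginal informational completeness of an instrument set.

    The set of all branches (the union over the instruments) must satisfy:

    1. the effects obtained by discarding each branch's output are
       informationally complete for the input type — checked exactly;
    2. for every full-support input state ρ, the output states branch∘ρ are
       informationally complete for the output type.

    When every branch is ∘-separable (numerical rank 1), condition 2 reduces
    exactly to informational completeness of the state factors ψ, and the
    verdict is definitive.  Otherwise condition 2 is certified by testing the
    uniform state plus ``n_random`` Dirichlet-sampled full-support states:
    any failure is a definite ``incomplete`` (with the failing ρ as witness);
    uniform success yields ``probably_complete``.
    """
    if not instruments:
        raise InstrumentError("need at least one instrument")
    dom, cod = instruments[0].dom, instruments[0].cod
    for ins in instruments[1:]:
        if ins.dom != dom or ins.cod != cod:
            raise WireTypeError(
                f"instruments of mixed types: {ins.dom}->{ins.cod} vs {dom}->{cod}"
            )
    in_card = int(np.prod(dom)) if dom else 1
    out_card = int(np.prod(cod)) if cod else 1
    mats = [mat.entries for ins in instruments for _, mat in ins.branches]

    # condition 1: effect side, exact
    effect_rows = np.asarray([m.sum(axis=0) for m in mats])
    rank1, null1 = _numerical_rank(effect_rows, tol)
    if rank1 < in_card:
        witness = None
        if null1 is not None:
            witness = ProcessMatrix(np.abs(null1).reshape(-1, 1), (), dom)
        return CompletenessVerdict("incomplete", rank1, in_card, witness)

    # condition 2: state side
    factors = [_separable_factors(m, tol) for m in mats]
    if all(f is not None for f in factors):
        states = np.asarray([f[0] for f in factors])  # type: ignore[index]
        rank2, _ = _numerical_rank(states, tol)
        if rank2 < out_card:
            return CompletenessVerdict("incomplete", rank2, out_card)
        return CompletenessVerdict("complete", min(rank1, rank2), max(in_card, out_card))

    # randomized certificate for non-separable branch sets
    rng = np.random.default_rng(seed)
    probes = [np.full(in_card, 1.0 / in_card)]
    probes.extend(rng.dirichlet(np.ones(in_card)) for _ in range(n_random))
    worst_rank = out_card
    for rho in probes:
        if rho.min() <= 0:  # resample degenerate draws toward full support
            rho = (rho + 1e-6) / (1.0 + in_card * 1e-6)
        out_states = np.asarray([m @ rho for m in mats])
        rank2, _ = _numerical_rank(out_states, tol)
        if rank2 < out_card:
            return CompletenessVerdict(
                "incomplete",
                rank2,
                out_card,
                ProcessMatrix(rho.reshape(-1, 1), (), dom),
            )
        worst_rank = min(worst_rank, rank2)
    return CompletenessVerdict("probably_complete", worst_rank, out_card)
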