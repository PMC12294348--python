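"""Typed non-negative matrices: the concrete process theory of finite probability.

Every state, effect, channel and scalar in this package is a
:class:`ProcessMatrix`: a matrix of non-negative reals together with typed
input wires (``dom``) and output wires (``cod``).  A wire type is just the
cardinality of the random variable carried on that wire.  Sequential
composition is matrix multiplication, parallel composition is the Kronecker
product, and the copy/discard/swap family gives the familiar probabilistic
wiring primitives.

Orientation convention (used everywhere in the package):

* states are column vectors (``dom = ()``), effects are row vectors
  (``cod = ()``), scalars are 1x1;
* a stochastic channel is column-stochastic, ``M[i, j] = P(out=i | in=j)``;
* a joint index over a wire list ``(A, B, ...)`` is mixed-radix with the
  FIRST wire most significant (row-major), matching ``numpy.kron`` ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProcessMatrix",
    "WireTypeError",
    "seq_compose",
    "par_compose",
    "identity",
    "discard",
    "copy_map",
    "basis_state",
    "basis_effect",
    "uniform_state",
    "state",
    "effect",
    "swap",
    "is_normalized",
    "normalization_defect",
    "joint_index",
    "split_index",
    "DEFAULT_TOL",
]

DEFAULT_TOL = 1e-9


class WireTypeError(ValueError):
    """Raised when wire lists of two processes do not match for composition."""


def _dim(wires: Sequence[int]) -> int:
    return int(math.prod(wires)) if wires else 1


def _check_wires(wires: Iterable[int]) -> tuple[int, ...]:
    out = tuple(int(w) for w in wires)
    for w in out:
        if w < 1:
            raise ValueError(f"wire cardinality must be >= 1, got {w}")
    return out


@dataclass(frozen=True)
class ProcessMatrix:
    """A process: non-negative matrix with typed input and output wire lists.

    Parameters
    ----------
    entries:
        2-D array with ``prod(cod)`` rows and ``prod(dom)`` columns.
    dom:
        Ordered cardinalities of the input wires; ``()`` is the unit type.
    cod:
        Ordered cardinalities of the output wires.
    """

    entries: np.ndarray
    dom: tuple[int, ...] = ()
    cod: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=float)
        if arr.ndim == 1:  # tolerate flat vectors for states/effects
            arr = arr.reshape(-1, 1) if self.dom == () else arr.reshape(1, -1)
        object.__setattr__(self, "entries", arr)
        object.__setattr__(self, "dom", _check_wires(self.dom))
        object.__setattr__(self, "cod", _check_wires(self.cod))
        expected = (_dim(self.cod), _dim(self.dom))
        if arr.shape != expected:
            raise WireTypeError(
                f"matrix shape {arr.shape} does not match wires: "
                f"cod {self.cod} x dom {self.dom} requires {expected}"
            )
        if arr.size and arr.min() < -1e-12:
            raise ValueError(f"negative entry {arr.min():g} in process matrix")

    # -- predicates ------------------------------------------------------
    @property
    def is_state(self) -> bool:
        return self.dom == ()

    @property
    def is_effect(self) -> bool:
        return self.cod == ()

    @property
    def is_scalar(self) -> bool:
        return self.dom == () and self.cod == ()

    @property
    def scalar(self) -> float:
        if not self.is_scalar:
            raise WireTypeError(f"not a scalar: dom={self.dom}, cod={self.cod}")
        return float(self.entries[0, 0])

    # -- composition sugar ----------------------------------------------
    def __matmul__(self, other: "ProcessMatrix") -> "ProcessMatrix":
        """``g @ f`` is the sequential composite g∘f (f happens first)."""
        return seq_compose(self, other)

    def tensor(self, other: "ProcessMatrix") -> "ProcessMatrix":
        return par_compose(self, other)

    def transpose(self) -> "ProcessMatrix":
        return ProcessMatrix(self.entries.T, dom=self.cod, cod=self.dom)

    def __add__(self, other: "ProcessMatrix") -> "ProcessMatrix":
        if self.dom != other.dom or self.cod != other.cod:
            raise WireTypeError(
                f"cannot add processes of different types: "
                f"{other.dom}->{other.cod} vs {self.dom}->{self.cod}"
            )
        return ProcessMatrix(self.entries + other.entries, self.dom, self.cod)

    def scale(self, factor: float) -> "ProcessMatrix":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return ProcessMatrix(self.entries * factor, self.dom, self.cod)

    def isclose(self, other: "ProcessMatrix", tol: float = 1e-12) -> bool:
        return (
            self.dom == other.dom
            and self.cod == other.cod
            and bool(np.allclose(self.entries, other.entries, atol=tol, rtol=0.0))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProcessMatrix({self.dom} -> {self.cod})\n{self.entries}"


# -- index helpers --------------------------------------------------------

def joint_index(values: Sequence[int], wires: Sequence[int]) -> int:
    """Mixed-radix joint index of per-wire values, first wire most significant."""
    if len(values) != len(wires):
        raise ValueError(f"{len(values)} values for {len(wires)} wires")
    idx = 0
    for v, w in zip(values, wires):
        if not 0 <= v < w:
            raise IndexError(f"value {v} out of range for cardinality {w}")
        idx = idx * w + v
    return idx


def split_index(index: int, wires: Sequence[int]) -> tuple[int, ...]:
    """Inverse of :func:`joint_index`."""
    if not 0 <= index < _dim(wires):
        raise IndexError(f"joint index {index} out of range for wires {wires}")
    out = []
    for w in reversed(wires):
        out.append(index % w)
        index //= w
    return tuple(reversed(out))


# -- operations -----------------------------------------------------------

def seq_compose(second: ProcessMatrix, first: ProcessMatrix) -> ProcessMatrix:
    """Sequential composite ``second ∘ first`` (matrix product)."""
    if first.cod != second.dom:
        raise WireTypeError(
            f"cannot compose: first has cod {first.cod}, second has dom {second.dom}"
        )
    return ProcessMatrix(second.entries @ first.entries, dom=first.dom, cod=second.cod)


def par_compose(left: ProcessMatrix, right: ProcessMatrix) -> ProcessMatrix:
    """Parallel composite (Kronecker product); left wires come first."""
    return ProcessMatrix(
        np.kron(left.entries, right.entries),
        dom=left.dom + right.dom,
        cod=left.cod + right.cod,
    )


def identity(wires: int | Sequence[int]) -> ProcessMatrix:
    ws = (wires,) if isinstance(wires, int) else tuple(wires)
    ws = _check_wires(ws)
    d = _dim(ws)
    return ProcessMatrix(np.eye(d), dom=ws, cod=ws)


def discard(cardinality: int) -> ProcessMatrix:
    """The all-ones row effect; discards a system of the given cardinality."""
    return ProcessMatrix(np.ones((1, cardinality)), dom=(cardinality,), cod=())


def copy_map(cardinality: int, n_outputs: int = 2) -> ProcessMatrix:
    """Copy a wire onto ``n_outputs`` wires.

    Sends basis state i to the n-fold product i⊗…⊗i; one output is the
    identity, zero outputs the discard effect.
    """
    if n_outputs < 0:
        raise ValueError("n_outputs must be >= 0")
    if n_outputs == 0:
        return discard(cardinality)
    rows = cardinality**n_outputs
    mat = np.zeros((rows, cardinality))
    for i in range(cardinality):
        mat[joint_index((i,) * n_outputs, (cardinality,) * n_outputs), i] = 1.0
    return ProcessMatrix(mat, dom=(cardinality,), cod=(cardinality,) * n_outputs)


def basis_state(cardinality: int, index: int) -> ProcessMatrix:
    """Pure state: column vector with 1 in position ``index`` (0-based)."""
    if not 0 <= index < cardinality:
        raise IndexError(f"basis index {index} out of range for cardinality {cardinality}")
    vec = np.zeros((cardinality, 1))
    vec[index, 0] = 1.0
    return ProcessMatrix(vec, dom=(), cod=(cardinality,))


def basis_effect(cardinality: int, index: int) -> ProcessMatrix:
    """Transpose of :func:`basis_state`: the 'is in configuration i' effect."""
    return basis_state(cardinality, index).transpose()


def uniform_state(cardinality: int) -> ProcessMatrix:
    return ProcessMatrix(np.full((cardinality, 1), 1.0 / cardinality), dom=(), cod=(cardinality,))


def state(values: Sequence[float], wires: int | Sequence[int] | None = None) -> ProcessMatrix:
    """Convenience constructor for a state from a flat probability vector."""
    vec = np.asarray(values, dtype=float).reshape(-1, 1)
    if wires is None:
        wires = (vec.shape[0],)
    elif isinstance(wires, int):
        wires = (wires,)
    return ProcessMatrix(vec, dom=(), cod=tuple(wires))


def effect(values: Sequence[float], wires: int | Sequence[int] | None = None) -> ProcessMatrix:
    """Convenience constructor for an effect from a flat vector."""
    vec = np.asarray(values, dtype=float).reshape(1, -1)
    if wires is None:
        wires = (vec.shape[1],)
    elif isinstance(wires, int):
        wires = (wires,)
    return ProcessMatrix(vec, dom=tuple(wires), cod=())


def swap(a: int, b: int) -> ProcessMatrix:
    """The wire-crossing permutation A⊗B → B⊗A."""
    mat = np.zeros((a * b, a * b))
    for i in range(a):
        for j in range(b):
            mat[joint_index((j, i), (b, a)), joint_index((i, j), (a, b))] = 1.0
    return ProcessMatrix(mat, dom=(a, b), cod=(b, a))


def normalization_defect(f: ProcessMatrix) -> float:
    """Largest absolute deviation of a column sum from 1."""
    if f.entries.shape[1] == 0:
        return 0.0
    return float(np.abs(f.entries.sum(axis=0) - 1.0).max())


def is_normalized(f: ProcessMatrix, tol: float = DEFAULT_TOL) -> bool:
    """True iff discarding the output is the same as discarding the input.

    Concretely: every column of the matrix sums to 1 within ``tol``
    (stochastic channels, probability-vector states, the scalar 1).
    """
    return normalization_defect(f) <= tol
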