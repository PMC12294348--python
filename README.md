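# causalcomb

Causal identification when the data do not come from clean observations.

The standard inputs to a causal identification problem are a directed
acyclic graph of causal hypotheses and the joint distribution of the
variables under *perfect passive observation*. Real data-collection
procedures are rarely that kind: a probe may be noisy (it sometimes reports
the wrong value), disturbing (it changes the value it feeds forward), or
coarse-grained (it reports only which block of values occurred).
`causalcomb` represents a causal model as a **comb** — a second-order
stochastic process with one input–output gap (*intervention locus*) per
variable — and every probing procedure as an **instrument**: a finite set of
non-negative branch matrices whose sum is a stochastic map. Plugging one
branch per locus into the comb and contracting gives the joint probability
of that combination of outcomes; perfect observation, surgical `do`
interventions, and arbitrary noisy/disturbing/coarse probes are all just
instruments.

The package is aimed at researchers in causal inference and epidemiological
modelling who want to simulate, diagnose, and invert such generalized
observation schemes on discrete graphical models.

## The model and the main result

For a DAG `G` with nodes `X_1 … X_m` (topologically ordered), a model
assigns each node a column-stochastic mechanism
`x_i : P(X_i = x | parents)`. Under perfect passive observation the comb
reproduces the usual Markov factorization

```
P(X_1, …, X_m) = ∏_i P(X_i | pa(X_i)),
```

but the comb also assigns probabilities to any other *local intervention
regime* (one instrument per locus). A set of instruments on a locus is
**marginally informationally complete (MIC)** when (i) the effects
`d∘ϕ` obtained by discarding each branch's output span the input space, and
(ii) for every full-support input `ρ`, the output states `ϕ∘ρ` span the
output space. The central identifiability fact implemented here: *a
Markovian, strictly positive model is uniquely determined by the branch
tables of its accessible regimes whenever the accessible set at every locus
is MIC* — even when no regime produces a Markov-factorizing distribution.
`identify_markovian` is a constructive double induction that recovers every
mechanism by repeated linear-inversion tomography, with rank diagnostics
naming the offending locus when an accessible set is not informative enough.

Also included: interventional (`do`) distributions via discard-and-prepare
instruments, a non-identifiability witness for latent confounding, margin
recovery for a fork/collider graph with a latent root, and ADMG layouts in
which bidirected edges become latent two-output sources.

## Worked example

The binary chain `X → Y` with `x = [0.8, 0.2]` and
`y = [[0.6, 0.3], [0.4, 0.7]]`, probed at `X` by a disturbing instrument
whose branches are `ψ∘ϕ` with fuzzy effects `ϕ = [0.8, 0.1]`,
`ϕ′ = [0.2, 0.9]` and pure prepared states:

```python
from causalcomb import *

dag = DAGSpec(("X", "Y"), frozenset({("X", "Y")}), {"X": 2, "Y": 2})
model = CausalModel(dag, {
    "X": state([0.8, 0.2]),
    "Y": ProcessMatrix([[0.6, 0.3], [0.4, 0.7]], dom=(2,), cod=(2,)),
})
noisy = make_separable(
    [(effect([0.8, 0.1]), basis_state(2, 0)),
     (effect([0.2, 0.9]), basis_state(2, 1))],
    labels=["psi.phi", "psi'.phi'"])

table = regime_probabilities(model, {"X": noisy, "Y": make_perfect_observation(2)})
print(table.probabilities)
# {('psi.phi', '1'): 0.396, ('psi.phi', '2'): 0.264,
#  ("psi'.phi'", '1'): 0.102, ("psi'.phi'", '2'): 0.238}

data = AccessibleData.from_model(model,
    {"X": [noisy], "Y": [make_perfect_observation(2)]})
result = identify_markovian(data)
print(result.model.mechanism("X").entries.ravel())   # [0.8 0.2]
print(result.model.mechanism("Y").entries)           # [[0.6 0.3]
                                                     #  [0.4 0.7]]
print(do_distribution(model, {"X": basis_state(2, 1)}, "Y").entries.ravel())
# [0.3 0.7]
```

Reading: the branch table is *not* Markov for the graph (the probe disturbs
`X`), yet because the lone noisy instrument is MIC its statistics pin down
both mechanisms exactly — including the interventional probability
`P(Y=1 | do(X=2)) = 0.06 / (0.06 + 0.14) = 0.3` that perfect observations
would have yielded.

A command-line interface mirrors the library:
`causalcomb simulate`, `causalcomb identify`, `causalcomb check-mic`,
`causalcomb do`, `causalcomb random-model` (see `--help` of each). Models
and instruments are JSON documents; branch tables are TSV. No
bioinformatics wire formats apply to this package.

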