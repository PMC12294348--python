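# Methods

## The process-matrix substrate

All computation happens in the category of non-negative real matrices with
typed wires (`causalcomb.matrices`). A wire type is the cardinality of the
variable it carries; sequential composition is matrix multiplication,
parallel composition the Kronecker product. States are columns, effects
rows, and a channel is column-stochastic with `M[i, j] = P(out=i | in=j)`.
Joint indices over a wire list are mixed-radix with the **first wire most
significant** (row-major), which is exactly `numpy.kron`'s ordering; helper
converters `joint_index`/`split_index` enforce it. Indices are 0-based in
memory; file formats and CLI output use 1-based value labels, converted at
the I/O boundary. "Normalized" means every column sums to 1 within an
absolute tolerance of 1e-9 per column; validation errors report the worst
column. Multi-wire processes are stored flattened (a single matrix plus
wire metadata) — no tensor-rank storage is needed at the problem sizes this
package targets.

## Combs and regime evaluation

A model is a DAG plus one normalized mechanism per node. Its comb has one
gap per observable node: the mechanism output enters the gap from below,
and the value the instrument branch feeds forward is copied to the node's
children. Latent gaps are closed with an identity wire at layout time, and
the API refuses instruments on latent loci. This wiring — children see the
*post*-instrument value — is what makes disturbing probes genuinely
disturbing: the downstream mechanisms react to whatever the instrument fed
forward, and with perfect passive observation (branch `i` = report `i`,
feed `i` forward) the table collapses to the usual Markov factorization.

`regime_probabilities` contracts the comb node by node in topological
order, carrying a joint weight tensor over the already-realized branch
outcomes and the "live" post-gap wires still read by later mechanisms. A
wire axis is summed out as soon as its last consumer has been processed.
The cost is exponential in the branch axes and the frontier width; that is
accepted deliberately, since the package targets desk-scale graphs (a
handful of nodes, cardinalities of a few), and an exhaustive enumeration
oracle in the test-suite certifies the contraction to 1e-12.

`do_distribution` is defined through the comb: a discard-and-prepare
instrument at each do-locus, identity elsewhere, perfect observation at the
query. For mixed prepared states this means the realized value after the
preparation is *not* observed — the comb semantics, which we adopt
uniformly rather than grafting on a post-preparation observation.

ADMG layouts realize each bidirected edge as one synthetic latent root
(`"u~v"`) copied to both endpoints, with default cardinality `|u|·|v|` so
that the endpoint mechanisms can emulate an arbitrary joint latent state by
composing with coordinate projections. Only construction and evaluation are
provided; no completeness semantics for bidirected-edge interpretations is
claimed.

## Instruments and completeness

An instrument is a labelled set of non-negative branch matrices summing to
a stochastic map. The separable constructor checks the equivalent, sharper
condition (states normalized, effects summing to the discard effect) so
that failures say which half is wrong.

Informational completeness of a set of states or effects is a numerical
rank decision: singular values below `tol × σ_max` count as zero, with
`tol = 1e-9` by default. Marginal informational completeness is decided in
two steps:

1. **Effect side (exact).** The effects obtained by discarding each
   branch's output are stacked and ranked against the input cardinality.
2. **State side.** If every branch has numerical rank 1 it is
   ∘-separable; a rank-1 factorization recovers the state factor up to the
   (irrelevant) scaling freedom, and the exact criterion ranks the state
   factors against the output cardinality. Otherwise the universally
   quantified condition ("for *every* full-support input, the output states
   span") is not decidable by sampling, so the module tests the uniform
   state plus `n_random = 20` symmetric-Dirichlet draws (seeded): any
   failure is a definite `incomplete` with the failing input as witness;
   uniform success returns the honest three-valued verdict
   `probably_complete` rather than overclaiming.

One typing wrinkle is resolved explicitly: the full-support probe state in
the state-side condition lives on the branch *input* type, and the spanned
set `{branch∘ρ}` on the *output* type — the convention the identification
algorithm actually relies on.

## Identification

`tomography_solve` is least squares with an explicit relative-rank check;
it reports the residual and condition number of every solve, so
over-complete probe sets are handled without subset selection and
finite-sample tables degrade into reported residuals instead of silent
error.

`identify_markovian` implements the constructive double induction:

* **Outer loop** over nodes in topological order; the output is the
  *padded* model in which every node's mechanism takes all topological
  predecessors as inputs (acting as the original on true parents and
  discarding the rest). Padding is equivalent — `pad_mechanisms` and the
  original model produce identical tables — and removes all ordering
  ambiguity. A post-pass (`IdentifiedModel.redundant_inputs`) reports
  inputs on which a recovered mechanism is constant; it never un-pads
  silently.
* **Base step**: for each combination of accessible branches at the
  earlier loci, the state arriving at the target locus is reconstructed
  from the probabilities of the target's accessible branches, with all
  later loci marginalized (branch sums are stochastic, so discarding
  "falls through" them). The regime used for a given branch combination
  fixes instrument index 0 at every later locus; marginalized tables are
  cached per regime.
* **Inner steps** eliminate the earlier loci one at a time. Standard basis
  states are plugged into the inputs of the already-known composite —
  basis states are copied exactly by copy maps, so this is pure
  computation, not a new experiment. Strict positivity guarantees the
  realized probe states `ϕ_k ∘ x_k ∘ ε` have full support; the accessible
  branches then turn them into a spanning family and one least-squares
  solve per basis column removes the locus.

MIC verdicts for each accessible set are computed up front and recorded on
the result, but identification is not hard-blocked on `probably_complete`
(or even `incomplete`) verdicts: the algorithm's own rank checks catch any
real deficiency and raise `InformationalIncompletenessError` naming the
locus, which is both a sharper and a more trustworthy diagnostic. Recovered
entries in `(-1e-7, 0)` are clipped to zero before the stochasticity check;
the model's validation tolerance is widened to ten times the worst observed
residual so that finite-sample reconstructions remain representable, with
the residual itself reported.

The tables the algorithm consumes are assumed mutually consistent (they
are, when produced by a model); with noisy tables the least-squares
residuals quantify the misfit — the package makes no attempt to decide
which table is "wrong". Empirically (exercised in the test-suite),
recovery error under multinomial sampling noise at `n` trials scales as
`n^{-1/2}`.

`identify_latent_root` covers the one latent case with a closed-form
answer implemented here: the five-node fork/collider graph (`A→B`, `A→C`,
`B→D`, `C→D`, `C→E`) with `A` latent. The individual mechanisms are not
identifiable, but the comb margin is: the joint state on `B⊗C` is the
table's upstream marginal, and the channel `B⊗C → D⊗E` divides each table
entry by that marginal — raising a strict-positivity error on any zero
marginal.

## Synthetic study material

`random_dag`, `random_model` and `random_separable_instrument` generate the
seeded fixtures used throughout the tests and benchmarks.

* Random models draw each mechanism column from a flat Dirichlet and mix it
  toward an entry floor (`min_entry = 0.05` by default):
  `col ← min_entry + (1 − card·min_entry)·col`. This keeps columns
  stochastic, makes every model strictly positive by construction, and
  bounds the conditioning of the tomography systems away from degeneracy
  — mirroring the strict-positivity assumption under which identifiability
  holds at all.
* Random probes perturb perfect observation: effects are rows of
  `(1−ε)·I + ε/card` and prepared states are basis states mixed toward
  uniform, with `ε, δ` drawn from `[0.05, 0.2]`. Both families stay
  linearly independent, so every generated probe is MIC by the separable
  criterion — these are the "realistically imperfect" instruments of the
  benchmark conditions.
* The recovery benchmark uses 100 models on random DAGs of 2–5 nodes with
  cardinalities 2–3 (edge probability 0.5), accessible sets drawn from
  {perfect observation}, {noisy probe}, {noisy probe, perfect
  observation}, and exact (infinite-trial) tables; recovery is required to
  max-abs error below 1e-8.

What the generator does **not** emulate: sampling noise is available but
off by default (tables are exact probabilities); there are no continuous
or high-cardinality variables, no model misspecification (the identifying
graph is always the generating graph), and no adaptive instrument choice.
Passing tests therefore demonstrate correctness of the algebra and the
identification algorithm under the stated assumptions — not robustness to
misspecified graphs or small samples beyond the explicit noise-scaling
check.

## Numerical choices and limitations

* Rank threshold `1e-9` (relative), normalization tolerance `1e-9` per
  column, table sum tolerance `1e-6` (tables may come from files at lower
  precision); probabilities serialize at full `repr` precision.
* Degenerate inputs: cardinality-1 wires, empty wire lists (the unit
  type), single-node graphs, and copy maps with zero outputs (= discard)
  are all first-class and covered by tests.
* The evaluator and identifier are exponential in the number of loci and
  branches; five nodes at cardinality 3 with two instruments per locus run
  in well under a second, but the design makes no attempt at larger-scale
  inference.
* Identification for general latent structures or ADMGs is out of scope;
  the confounded comb is used only as a non-identifiability witness (two
  interpretations, identical observational tables, different
  do-distributions).
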