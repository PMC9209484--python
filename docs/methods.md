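# Methods

`netfate` identifies cell-fate reprogramming targets on a static signed
biological network. It combines three ingredients: a steady-state
estimator (signal flow analysis) that turns any initial expression
state into a fixed-point attractor; feedback vertex set (FVS) control,
which singles out the node set whose permanent override is sufficient
to steer a nonlinear networked system between its attractors; and a
screening-plus-filtering stage that decides which concrete override
combination actually lands in the desired region of the attractor
landscape.

## Signal flow analysis

The network state is a vector of per-node log-scale activities x. It is
updated synchronously:

    x_i(t+1) = α Σ_j W_ij x_j(t) + (1 − α) b_i,
    W_ij = sign(j→i) / sqrt(D_out(j) · D_in(i)),

where b is the initial activity (typically a normalized expression
sample) and sign(j→i) is +1 for activation, −1 for inhibition. The
degree normalization divides a regulator's influence among its targets
and dilutes it among competing regulators. α ∈ [0, 1) weighs topology
against the persistence of the initial state; the default 0.9 favours
topology. Iteration stops when the **max-norm** of the state change
falls below the tolerance (default 1e−6; the norm is our choice — the
strictest elementwise criterion consistent with fixed-point semantics),
or at `max_iterations` (default 1000) with an explicit non-convergence
flag; non-convergence is never silent.

Because the map is affine, a converged run equals the solution of
(I − αW) x = (1 − α) b whenever the spectral radius of αW is below one.
This closed form is deliberately *not* used as the implementation — the
iterative propagation is the method — but it serves as an independent
oracle in the test suite and acceptance script.

Overridden nodes (perturbations, gain/loss-of-function mutations, drug
treatments) hold a fixed value p for all t. They ignore incoming flow
but still feed p to their neighbours: the defining property of an
override is that the *overridden node* is unaffected, not that it goes
silent. The override magnitudes come from the undesired-phenotype
expression extrema of the node,

    p_up   = max(normexp) + 2.5·max(normexp),
    p_down = min(normexp) − 2.5·min(normexp),

and fall back to ±2.5 when no expression data exists (purely in-silico
runs). On log-scale data a negative minimum makes p_down land *above*
the minimum; the formula is applied verbatim and a warning is emitted
rather than silently correcting it.

Inputs are treated as already log-scale and are never re-logged: the
in-silico convention of seeding nodes with raw 0/1 activities is
common, and double-logging would corrupt it.

Attractor comparisons are qualitative, analogous to a log fold-change:
the per-node difference's sign gives up/down, with a 1e−9 equality
guard for float noise; magnitudes are reported but are not effect
sizes.

## Feedback vertex set search

An FVS is a node set intersecting every directed cycle (self-loops are
cycles of length 1; since a node bearing one can never join an acyclic
subgraph it is a forced FVS member and is flagged in results). Minimum
FVS is NP-hard, so the search is a simulated-annealing local search in
the style of the classic SA-FVSP family: the state is the *complement*
— an acyclic induced subgraph kept as an explicit topological order —
and a move picks an outside node and inserts it just after its last
ordered in-neighbour ("left") or just before its first ordered
out-neighbour ("right"), evicting the neighbours that contradict the
position. The energy is the FVS size; uphill moves are accepted with
Metropolis probability. Defaults: initial temperature 0.6, geometric
cooling ×0.99, 50·|V| moves per level, stop at a 1e−3 temperature
floor or after 50 levels without improvement. All draws come from a
single seeded generator.

The returned set is made inclusion-minimal by a deterministic greedy
pruning pass in network node order. Minimum *size* is certified only
against the exhaustive enumerator (guarded to ≤ 20 nodes), which is
also the exact branch of `enumerate_fvs` for graphs of ≤ 14 nodes.
Above that bound, enumeration collects distinct minimum-size sets over
randomized restarts until 25 consecutive restarts add nothing new —
a saturation heuristic that cannot certify exhaustiveness, and says so.

Control nodes are the chosen FVS minus any node already pinned by a
mutation or treatment (its override would be redundant); when several
minimal FVSes exist they are equivalent for controllability and the
lexicographically first is used by default (`fvs_index` selects
another).

## Landscape estimation and phenotype association

Experimental samples alone under-sample the attractor landscape, so
`n_random` (default 100,000) extra initial states are drawn per node
uniformly within the [min, max] of its values across the supplied
phenotypes' samples, pooled. Pooling is our reading of an ambiguous
convention; a stratified per-phenotype mode is available behind a flag,
and the sampling distribution is recorded in the k-selection report.
Every initial state yields exactly one attractor (the estimator has no
basins to merge them), hence attractors = samples + n_random.

Attractors are partitioned with k-means (10 seeded initializations per
k; k from 2 to 10 by default). Two optima are computed: the elbow of
the within-cluster-sum-of-squares curve, located at the maximum
discrete second difference, and the argmax of the mean silhouette
(estimated on a seeded subsample of 5,000 attractors when the landscape
is larger, for tractability). If the optima agree and that k keeps the
undesired- and desired-derived experimental attractors in different
clusters, it is chosen; otherwise the smallest candidate that separates
them wins; if none does, the run stops with a separation error advising
network or marker revision — a co-clustered landscape cannot support
the downstream filters.

A marker-consistency report then checks each internal-marker node: the
sign of (desired − undesired) attractor values must match the expected
direction, and with replicates the two value ranges must not overlap —
an overlapping marker cannot separate the phenotypes and is flagged
unreliable.

## Perturbation screening

Each control node is assigned overexpress / knock out / leave
unchanged, giving 3^n schemes, generated as a ternary counter over the
node order (deterministic, lexicographic, all-unchanged first) so that
checkpointing and resumption are stable. A cap at 16 control nodes
(3^16 ≈ 43 M) must be explicitly overridden. Scheme ids such as
`Nanog:up|Klf4:unchanged` are a bijection with assignments.

For every scheme × undesired replicate, the system is initialized at
that replicate's expression vector and propagated with the scheme's
overrides pinned on top of any mutation/treatment baseline. Override
magnitudes use pooled undesired-sample extrema, shared across
replicates. All cells are propagated as one masked matrix batch, so
execution order cannot influence any result; non-convergence is logged
per cell, never fatal.

## Filtering criteria

**Criterion 1.** Gaussian Naive Bayes, a linear-kernel SVM and a Random
Forest are trained on the full landscape (features = entire attractor
vectors, labels = k-means clusters; library-default hyperparameters
with fixed seeds; the linear kernel is chosen so coefficient-based
importance is well defined). Training is a full fit with training
accuracy reported — the filters need the landscape's own partition, not
generalization to held-out data. A screened attractor passes when at
least 2 of 3 classifiers place it in a desired-phenotype cluster; a
scheme passes overall only if it passes on every replicate. Feature
importances (RF impurity, SVM |coefficients|, NB seeded permutation
importance with 10 repeats — NB has no native ranking) are reported as
top-⌈10%⌉ lists per classifier plus a cross-classifier recurrence
summary.

**Criterion 2.** Among criterion-1 survivors, at least 90% (the
`threshold`) of the internal-marker nodes must land in the expected
range, evaluated per replicate and independently within each marker
group when groups (e.g. apoptosis / proliferation / signalling panels)
are defined. A marker's direction is taken from a literature annotation
or inferred from the sign of desired-vs-undesired attractor values;
markers with identical values in both phenotypes are unresolvable and
are excluded from the denominator with a warning (a deliberate choice —
counting them as failures would punish uninformative markers twice).
With replicate ranges, `strict` mode requires the value beyond the
desired-range boundary nearer the undesired side (up: > min of desired
values; down: < max), the natural generalization of the single-value
rule "must exceed the desired value"; `relaxed` only requires moving
beyond the undesired extremum. For non-overlapping marker ranges strict
implies relaxed, and raising the threshold can only remove survivors.
A marker that is itself overridden by the scheme is evaluated at its
pinned value and flagged. The criteria are deterministic filters, not
hypothesis tests; no multiple-testing correction is applied or needed.

Survivors are ranked smallest-intervention-first (perturbed-node count,
then scheme id), with a recurrence table of node:action assignments
across survivors.

## Synthetic study generator

The generator emulates a study's inputs, not any real dataset. Networks
plant vertex-disjoint directed cycles (the only cycles, so the minimum
FVS size equals the cycle count — certified against the exhaustive
enumerator at build time for ≤ 16 nodes), hang marker nodes off the
cycles as pure readouts (one signed edge each, never a scaffold
target), and wire the remaining nodes as random acyclic scaffolding
respecting a topological order over cycle blocks. Expression gives
cycle nodes and up-markers ≈ 1.0 in the undesired phenotype and
1.0 + effect in the desired one (down-markers mirror this), with
N(0, jitter) replicate noise; defaults: effect 2.0, jitter 0.05,
3 replicates per phenotype — separation a scientist would call a clear
but realistic two-condition design. The planted reprogramming scheme is
"every control node up", which provably raises all positive cycles and
pushes the markers past the desired ranges.

Noise injection adds N(0, sd) to every nonzero value, with sd the
absolute noise level (0.01–0.50 emulating 1–50% noise on unit-scale
data); zero-valued nodes stay untouched and level 0 is the exact
identity.

What passing tests on these fixtures show — and what they do not: they
demonstrate that the machinery is correct (fixed points match the
linear solve, the FVS is truly minimal, the filters behave
monotonically, a scheme that provably works is found and the null
scheme rejected, robustly under noise). They do not show that any real
network's curation is adequate, that real expression noise is Gaussian,
or that real landscapes are as cleanly separable as the planted ones.

## Problem sizes and determinism

The bundled tests and the acceptance script run at desk scale, chosen
as the smallest sizes at which each property is meaningfully exercised:
the standard 14-node fixture with 300 random initial states for full
pipeline runs (20 seeds; 100 noise trials at levels 0.1–0.2 reusing the
fixed network's FVS, since expression noise cannot change the graph),
100 random graphs ≤ 30 nodes for the linear-solve oracle, 200 random
digraphs ≤ 12 nodes for annealing-vs-exact agreement, and one
paper-scale landscape (36 nodes, 100,006 attractors) for the count
contract. Every stochastic stage — sampling, k-means, annealing,
classifiers, permutation importance — draws from explicitly passed
seeds, and two runs with identical configuration produce byte-identical
outputs; the file pipeline checkpoints steps by content hash of inputs
and configuration, so a resumed run re-executes exactly the stale
steps.

## Known limitations

* Only fixed-point attractors are estimated; limit cycles are out of
  scope (the tolerance-based stopping rule cannot represent them).
* Updates are synchronous and deterministic; asynchronous/stochastic
  schemes and time-delayed perturbations are not modelled.
* The linear propagation cannot express cooperative (AND-like) logic;
  a target whose effect depends on such logic may be missed.
* The saturation heuristic for FVS enumeration on large graphs cannot
  certify that all minimal FVSes were found.
* Landscape separability depends on network fidelity; the separation
  error is a diagnosis, not a cure.
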