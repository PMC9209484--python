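# netfate

Identification of cell-fate reprogramming targets on static signed
biological networks.

Cell-fate reprogramming asks which genes or proteins must be
permanently overexpressed or knocked out to drive a cell from an
undesired phenotype (a primed stem-cell state, a therapy-resistant
tumour state) to a desired one. For most systems of interest no
parameterized dynamical model exists — only a curated signed network
(activation/inhibition edges) and some normalized expression data.
`netfate` works from exactly those inputs. It is aimed at systems
biologists who have a network and phenotype-labelled expression samples
and want a ranked, biologically filtered list of intervention
combinations to test.

## Method

Three results from network dynamics and control theory are combined:

1. **Signal flow analysis (SFA).** Node activities are propagated
   synchronously, x_i(t+1) = α Σ_j W_ij x_j(t) + (1−α) b_i with
   degree-normalized signed weights W_ij = sign(j→i)/√(D_out(j)·D_in(i)),
   until the change drops below 10⁻⁶. Each initial state b (an
   expression sample, or a random state drawn within the observed
   expression ranges) yields one fixed-point attractor. k-means over
   the resulting attractor cloud, with elbow/silhouette selection of k,
   gives an estimated attractor landscape whose clusters are associated
   with the undesired and desired phenotypes.
2. **Feedback vertex set (FVS) control.** A minimal node set
   intersecting all directed cycles is found by simulated annealing
   (exhaustively on small graphs). Overriding the states of an FVS is
   sufficient to steer a nonlinear networked system into any of its
   attractors, so these are the only nodes that need screening.
3. **Screening and filtering.** All 3^n overexpress/knockout/unchanged
   combinations on the n control nodes are simulated from the undesired
   phenotype's expression state, with overrides pinned to
   p_up = 3.5·max(normexp) or p_down = −1.5·min(normexp). A scheme
   survives if (criterion 1) at least 2 of 3 classifiers — Naive Bayes,
   linear SVM, Random Forest, trained on the landscape — place its
   attractor in the desired cluster on every replicate, and
   (criterion 2) at least 90% of the user's internal-marker nodes land
   in the desired phenotype's attractor value range.

Full details, parameter defaults and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

The package ships a synthetic study generator, so the whole pipeline
runs without any download. The standard fixture is a 14-node network
with two planted cycles (the certified minimum FVS has one node per
cycle), four marker readouts and 3 + 3 replicate expression samples
separated by 2.0 log units on markers and cycle nodes:

```python
import netfate as nf

fx = nf.make_fixture()                      # network + expression + markers
res = nf.run_study(fx.network, fx.expression, fx.markers,
                   n_random=300, seed=0)
print(res.counts)
print(res.ranked.to_string(index=False))
```

prints

```
{'attractors': 306, 'non_converged': 0, 'k': 2, 'n_fvs': 6,
 'n_control_nodes': 2, 'schemes': 9, 'criterion1_survivors': 3,
 'criterion2_survivors_per_replicate': {'undesired_r0': 1,
 'undesired_r1': 1, 'undesired_r2': 1}, 'survivors': 1}
      scheme_id  n_perturbed
C0N0:up|C1N0:up            2
```

Reading: 6 expression samples plus 300 random initial states gave 306
attractors, clustered at k = 2 with the two phenotypes in different
clusters. The network has 6 equivalent minimal FVSes of size 2; the
first is used, giving 3² = 9 perturbation schemes. Three schemes pass
the classifier vote, and exactly one — overexpressing one node of each
cycle — passes the marker filter on all replicates. That is the planted
reprogramming scheme, and the do-nothing scheme is correctly rejected.

The same run works from the shell:

```sh
netfate fixtures make --out study/ --seed 0
netfate run --network study/network.tsv --expression study/expression.tsv \
            --phenotypes study/phenotypes.tsv --markers study/markers.tsv \
            --out study/results --n-random 300 --seed 0
```

Outputs are TSVs (attractor tables, cluster assignments, FVS list,
scheme manifest, per-criterion pass lists, ranked survivors) plus JSON
reports; steps are checkpointed by input hash and resume cleanly.

Real studies substitute their own `network.tsv` (three tab-separated
columns: source, sign, target, with signs 1/-1, +/-, or
activate/inhibit), a node × sample expression TSV, a sample→phenotype
map, a marker list, and optionally a mutation table
(gene `<TAB>` gain_of_function/loss_of_function).

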