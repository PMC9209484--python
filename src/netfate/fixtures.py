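"""Synthetic study generator: networks, expression and noise.

These fixtures emulate the inputs a reprogramming study needs — a
signed network with a *known* minimum feedback vertex set, a
two-phenotype expression table whose marker nodes separate by a chosen
effect size, and noise-injected replicate initial states — so that the
whole pipeline builds and tests without downloading any real dataset.

Design of the planted network:

* vertex-disjoint directed cycles of the requested lengths are the only
  cycles, so the minimum FVS size equals the number of planted cycles
  (one node per cycle breaks everything);
* marker nodes hang off the cycles as pure readouts (a positive edge
  from a cycle node, or a negative edge for ``down`` markers) and never
  receive scaffold edges, so overriding any node of a cycle provably
  moves its markers;
* remaining nodes form random acyclic scaffolding that respects a
  global topological order over the cycle-contracted graph, which
  cannot create new cycles.

The *planted reprogramming scheme* is therefore "every control node
up": it raises all positive cycles, drives up-markers past the desired
range and down-markers below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fvs import brute_force_min_fvs
from .landscape import ExpressionTable, InitialStateBatch
from .network import SignedDigraph, write_network

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_network",
    "make_expression",
    "make_fixture",
    "inject_noise",
    "write_fixture",
    "STANDARD_SPEC",
]

#: noise levels used in the robustness study (absolute SDs on unit-scale data)
NOISE_LEVELS = (0.0, 0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    effect_size is the desired-vs-undesired marker separation in log
    units (default 2.0); jitter is the within-phenotype replicate SD
    (default 0.05, small against the effect so marker checks are
    unambiguous).
    """

    n_nodes: int = 14
    cycle_lengths: tuple[int, ...] = (3, 2)
    cycle_signs: tuple[int, ...] | None = None  # per-cycle edge sign, default all +1
    markers_per_cycle: int = 2
    down_markers: int = 1  # how many of the markers read a cycle negatively
    effect_size: float = 2.0
    replicates: int = 3
    jitter: float = 0.05
    scaffold_edge_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.replicates < 1:
            raise ValueError("counts must be positive")
        if self.jitter < 0 or self.effect_size < 0:
            raise ValueError("jitter and effect_size must be >= 0")
        if any(l < 1 for l in self.cycle_lengths):
            raise ValueError("cycle lengths must be >= 1")
        needed = sum(self.cycle_lengths) + len(self.cycle_lengths) * self.markers_per_cycle
        if needed > self.n_nodes:
            raise ValueError(
                f"spec infeasible: cycles+markers need {needed} nodes, "
                f"only {self.n_nodes} available"
            )


#: the default study conditions used throughout the test-bench
STANDARD_SPEC = FixtureSpec()


@dataclass
class Fixture:
    """A complete synthetic study."""

    spec: FixtureSpec
    network: SignedDigraph
    expression: ExpressionTable
    markers: list[tuple[str, str]]  # (node, expected desired-vs-undesired direction)
    cycles: list[list[str]]
    min_fvs_size: int
    certified: bool  # min FVS size checked against brute force at build time
    planted_scheme_symbols: dict[str, str] = field(default_factory=dict)

    @property
    def marker_nodes(self) -> list[str]:
        return [m for m, _ in self.markers]


def make_network(spec: FixtureSpec) -> tuple[SignedDigraph, dict]:
    """Build the planted-cycle network; see the module docstring.

    Returns the graph and a metadata dict (cycles, markers with their
    driving sign, certified minimum FVS size).  Bitwise reproducible
    under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    g = SignedDigraph()
    signs = spec.cycle_signs or tuple(1 for _ in spec.cycle_lengths)
    if len(signs) != len(spec.cycle_lengths):
        raise ValueError("cycle_signs length must match cycle_lengths")

    cycles: list[list[str]] = []
    for ci, length in enumerate(spec.cycle_lengths):
        names = [f"C{ci}N{j}" for j in range(length)]
        cycles.append(names)
        for j, src in enumerate(names):
            g.add_edge(src, names[(j + 1) % length], signs[ci])

    # markers hang off the cycles as pure readouts; a negatively-read
    # marker is expected "down" in the desired (cycle-high) phenotype
    markers: list[tuple[str, str]] = []
    marker_edges: list[tuple[str, str, int]] = []
    n_markers = len(cycles) * spec.markers_per_cycle
    down_left = spec.down_markers
    mi = 0
    for cyc in cycles:
        for k in range(spec.markers_per_cycle):
            name = f"M{mi}"
            sign = -1 if down_left > 0 else 1
            down_left = max(down_left - 1, 0)
            marker_edges.append((cyc[k % len(cyc)], name, sign))
            markers.append((name, "up" if sign > 0 else "down"))
            mi += 1
    for driver, name, sign in marker_edges:
        g.add_edge(driver, name, sign)

    n_scaffold = spec.n_nodes - sum(spec.cycle_lengths) - n_markers
    scaffold = [f"S{j}" for j in range(n_scaffold)]
    for s in scaffold:
        g.add_node(s)
    # topological order over super-nodes: cycle blocks first, then scaffold
    order: list[list[str]] = [list(c) for c in cycles] + [[s] for s in scaffold]
    for i, blk_i in enumerate(order):
        for j in range(i + 1, len(order)):
            blk_j = order[j]
            if rng.random() < spec.scaffold_edge_prob:
                src = blk_i[rng.integers(len(blk_i))]
                tgt = blk_j[rng.integers(len(blk_j))]
                if tgt.startswith("M") or g.has_edge(src, tgt):
                    continue  # markers stay pure readouts
                g.add_edge(src, tgt, 1 if rng.random() < 0.7 else -1)
    # an edge-list file cannot represent isolated nodes: tether any
    # orphan scaffold node from the first cycle (still acyclic: cycle
    # blocks precede scaffold in the block order)
    deg = {n: 0 for n in g.nodes}
    for s, t, _ in g.edges:
        deg[s] += 1
        deg[t] += 1
    anchor = cycles[0][-1] if cycles else None
    for s in scaffold:
        if deg[s] == 0:
            if anchor is None:
                anchor = s
                continue
            g.add_edge(anchor, s, 1)

    min_size = len([c for c in cycles if len(c) > 0])
    certified = False
    if g.n_nodes <= 16:
        family = brute_force_min_fvs(g)
        exact = len(family[0]) if family else 0
        if exact != min_size:
            raise AssertionError(
                f"planted minimum FVS size {min_size} != brute force {exact}"
            )
        certified = True
    meta = {
        "cycles": cycles,
        "markers": markers,
        "min_fvs_size": min_size,
        "certified": certified,
    }
    return g, meta


def make_expression(
    g: SignedDigraph,
    spec: FixtureSpec,
    meta: dict,
) -> tuple[ExpressionTable, list[tuple[str, str]]]:
    """Two-phenotype replicate expression with planted marker separation.

    Cycle nodes and ``up`` markers sit near 1.0 in the undesired
    phenotype and near 1.0 + effect_size in the desired one; ``down``
    markers move the opposite way; scaffold nodes are phenotype-neutral.
    Replicates add N(0, jitter) noise.  Expected marker directions are
    returned alongside.
    """
    rng = np.random.default_rng(spec.seed + 1)
    markers: list[tuple[str, str]] = meta["markers"]
    direction = dict(markers)
    cycle_nodes = {n for cyc in meta["cycles"] for n in cyc}

    base = {n: 1.0 for n in g.nodes}
    desired_shift = {}
    for n in g.nodes:
        if n in cycle_nodes:
            desired_shift[n] = spec.effect_size
        elif n in direction:
            desired_shift[n] = spec.effect_size if direction[n] == "up" else -spec.effect_size
        else:
            desired_shift[n] = 0.0

    cols = {}
    phenotype = {}
    for r in range(spec.replicates):
        name = f"undesired_r{r}"
        cols[name] = [base[n] + rng.normal(0, spec.jitter) for n in g.nodes]
        phenotype[name] = "undesired"
    for r in range(spec.replicates):
        name = f"desired_r{r}"
        cols[name] = [
            base[n] + desired_shift[n] + rng.normal(0, spec.jitter) for n in g.nodes
        ]
        phenotype[name] = "desired"
    table = ExpressionTable(pd.DataFrame(cols, index=g.nodes), phenotype)
    return table, markers


def make_fixture(spec: FixtureSpec = STANDARD_SPEC) -> Fixture:
    """Network + expression + markers + the planted scheme, in one call."""
    g, meta = make_network(spec)
    expr, markers = make_expression(g, spec, meta)
    return Fixture(
        spec=spec,
        network=g,
        expression=expr,
        markers=markers,
        cycles=meta["cycles"],
        min_fvs_size=meta["min_fvs_size"],
        certified=meta["certified"],
        planted_scheme_symbols={cyc[0]: "up" for cyc in meta["cycles"]},
    )


def inject_noise(
    states: InitialStateBatch | ExpressionTable,
    fraction: float,
    seed: int,
):
    """Perturb each nonzero value with N(value, fraction) noise.

    ``fraction`` is an absolute standard deviation on unit-scale data
    (levels 0.01-0.50 emulate 1%-50% noise).  Zero-valued nodes are left
    untouched and fraction 0 is the exact identity.  Returns the same
    container type as the input.
    """
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if isinstance(states, ExpressionTable):
        values = states.values
    else:
        values = states.values
    if fraction == 0:
        noisy = values.copy()
    else:
        rng = np.random.default_rng(seed)
        arr = values.to_numpy(dtype=float).copy()
        nz = arr != 0
        arr[nz] = arr[nz] + rng.normal(0.0, fraction, size=int(nz.sum()))
        noisy = pd.DataFrame(arr, index=values.index, columns=values.columns)
    if isinstance(states, ExpressionTable):
        return ExpressionTable(noisy, dict(states.phenotype))
    return InitialStateBatch(noisy, list(states.labels), states.provenance)


def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Emit the exact file formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "expression": out / "expression.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "markers": out / "markers.tsv",
    }
    write_network(fixture.network, paths["network"])
    fixture.expression.values.to_csv(paths["expression"], sep="\t")
    with paths["phenotypes"].open("w") as fh:
        for sample, pheno in fixture.expression.phenotype.items():
            fh.write(f"{sample}\t{pheno}\n")
    with paths["markers"].open("w") as fh:
        for node, direction in fixture.markers:
            fh.write(f"{node}\t{direction}\n")
    return paths
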