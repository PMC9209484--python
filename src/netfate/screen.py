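"""Combinatorial perturbation screening on FVS control nodes.

Every control node can be overexpressed (``up``), knocked out
(``down``) or left alone (``unchanged``); the screen enumerates all 3^n
assignments in deterministic ternary-counter order and computes, for
each scheme and each undesired-phenotype replicate, the attractor
reached when the scheme's overrides are pinned on top of the replicate's
expression-derived initial state.  Override magnitudes come from the
undesired-phenotype expression extrema (up: max + 2.5*max; down:
min - 2.5*min), shared across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import ExpressionTable
from .network import SignedDigraph
from .sfa import OverrideSet, SfaConfig, _propagate_core, override_value, weight_matrix

__all__ = [
    "SYMBOLS",
    "PerturbationScheme",
    "MutationProfile",
    "SchemeCapError",
    "ScreenResult",
    "iter_schemes",
    "generate_schemes",
    "scheme_count",
    "parse_scheme_id",
    "resolve_overrides",
    "run_screen",
]

logger = logging.getLogger(__name__)

#: assignment symbols in counter order; first scheme is all-unchanged
SYMBOLS: tuple[str, ...] = ("unchanged", "up", "down")

DEFAULT_SCHEME_CAP = 16


class SchemeCapError(ValueError):
    """Refused to enumerate 3^n schemes beyond the configured cap."""


@dataclass(frozen=True)
class PerturbationScheme:
    """One assignment of a symbol to every control node."""

    assignment: tuple[tuple[str, str], ...]  # ((node, symbol), ...) in node order

    @property
    def id(self) -> str:
        return "|".join(f"{n}:{s}" for n, s in self.assignment)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.assignment)

    @property
    def n_perturbed(self) -> int:
        return sum(1 for _, s in self.assignment if s != "unchanged")

    @property
    def is_identity(self) -> bool:
        return self.n_perturbed == 0

    def symbol(self, node: str) -> str:
        for n, s in self.assignment:
            if n == node:
                return s
        raise KeyError(node)


def parse_scheme_id(scheme_id: str) -> PerturbationScheme:
    """Inverse of :attr:`PerturbationScheme.id` (bijection contract)."""
    pairs = []
    for token in scheme_id.split("|"):
        node, _, symbol = token.rpartition(":")
        if symbol not in SYMBOLS or not node:
            raise ValueError(f"malformed scheme id token {token!r}")
        pairs.append((node, symbol))
    return PerturbationScheme(tuple(pairs))


def scheme_count(n_control: int) -> int:
    return 3 ** n_control


def iter_schemes(control_nodes: Sequence[str]) -> Iterator[PerturbationScheme]:
    """Yield all 3^n schemes as a ternary counter over the node order.

    The most significant digit is the first control node, so schemes are
    produced in deterministic lexicographic order with the all-unchanged
    scheme first (stable for checkpoint/resume).
    """
    if not control_nodes:
        raise ValueError("control node list is empty")
    n = len(control_nodes)
    nodes = tuple(control_nodes)
    digits = [0] * n
    while True:
        yield PerturbationScheme(tuple(zip(nodes, (SYMBOLS[d] for d in digits))))
        i = n - 1
        while i >= 0 and digits[i] == 2:
            digits[i] = 0
            i -= 1
        if i < 0:
            return
        digits[i] += 1


def generate_schemes(
    control_nodes: Sequence[str],
    cap: int = DEFAULT_SCHEME_CAP,
    allow_large: bool = False,
) -> list[PerturbationScheme]:
    """Materialize all 3^n schemes (see :func:`iter_schemes`).

    Refuses beyond ``cap`` control nodes unless ``allow_large`` is set,
    to protect desk-scale users from accidentally requesting 3^17+.
    """
    n = len(control_nodes)
    if n > cap and not allow_large:
        raise SchemeCapError(
            f"{n} control nodes would generate {scheme_count(n):,} schemes "
            f"(cap {cap}); pass allow_large=True to proceed"
        )
    return list(iter_schemes(control_nodes))


@dataclass(frozen=True)
class MutationProfile:
    """Functional mutation annotations translated to permanent overrides."""

    entries: Mapping[str, str] = field(default_factory=dict)  # gene -> gain_of_function | loss_of_function

    def __post_init__(self) -> None:
        bad = {g: m for g, m in self.entries.items()
               if m not in ("gain_of_function", "loss_of_function")}
        if bad:
            raise ValueError(f"unknown mutation classes: {bad}")

    def validate(self, g: SignedDigraph) -> None:
        unknown = [n for n in self.entries if n not in g]
        if unknown:
            raise KeyError(f"mutated genes not in network: {unknown}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries)


def _direction_for(symbol: str) -> str:
    return {"up": "up", "down": "down",
            "gain_of_function": "up", "loss_of_function": "down",
            "overexpress": "up", "knockout": "down"}[symbol]


def resolve_overrides(
    scheme: PerturbationScheme | None,
    expr: ExpressionTable | pd.DataFrame | None,
    mutations: MutationProfile | None = None,
    treatments: Mapping[str, str] | None = None,
    fallback: bool = False,
) -> OverrideSet:
    """Merge mutation, treatment and scheme overrides into one set.

    Mutation and treatment overrides apply first, then the scheme's
    assignments; ``unchanged`` nodes are absent from the result.  The
    up/down magnitudes come from :func:`netfate.sfa.override_value` on
    the undesired-phenotype expression of each node (``fallback`` allows
    data-free ±2.5 overrides).  A scheme reassigning a mutation-pinned
    node is an error (unreachable when the control set excluded fixed
    nodes upstream; kept as a defensive check).
    """
    if isinstance(expr, ExpressionTable):
        undesired = expr.values[expr.samples_for("undesired")]
    else:
        undesired = expr

    def node_values(node: str) -> list[float]:
        if undesired is None or node not in getattr(undesired, "index", ()):
            return []
        return list(undesired.loc[node].to_numpy(dtype=float).ravel())

    entries: dict[str, float] = {}
    sources: dict[str, str] = {}
    if mutations is not None:
        for gene, cls in mutations.entries.items():
            entries[gene] = override_value(node_values(gene), _direction_for(cls), fallback)
            sources[gene] = "mutation"
    if treatments:
        for node, action in treatments.items():
            entries[node] = override_value(node_values(node), _direction_for(action), fallback)
            sources[node] = "treatment"
    if scheme is not None:
        for node, symbol in scheme.assignment:
            if symbol == "unchanged":
                continue
            if sources.get(node) == "mutation":
                raise ValueError(
                    f"scheme perturbs {node}, already pinned by a mutation; "
                    "exclude fixed nodes from the control set"
                )
            entries[node] = override_value(node_values(node), _direction_for(symbol), fallback)
            sources[node] = "perturbation"
    return OverrideSet(entries, sources)


@dataclass
class ScreenResult:
    """Attractor per (replicate, scheme), with convergence bookkeeping."""

    attractors: pd.DataFrame  # MultiIndex (replicate, scheme_id) x nodes
    converged: pd.Series
    iterations: pd.Series
    scheme_ids: list[str]
    replicates: list[str]

    @property
    def n_cells(self) -> int:
        return len(self.attractors)

    def values_for(self, replicate: str, scheme_id: str) -> pd.Series:
        return self.attractors.loc[(replicate, scheme_id)]

    def manifest(self) -> pd.DataFrame:
        schemes = [parse_scheme_id(s) for s in self.scheme_ids]
        return pd.DataFrame(
            {
                "scheme_id": self.scheme_ids,
                "n_perturbed": [s.n_perturbed for s in schemes],
            }
        )


def run_screen(
    g: SignedDigraph,
    schemes: Iterable[PerturbationScheme],
    replicate_states: pd.DataFrame,
    expr: ExpressionTable | pd.DataFrame | None,
    cfg: SfaConfig | None = None,
    mutations: MutationProfile | None = None,
    treatments: Mapping[str, str] | None = None,
    fallback: bool = False,
    chunk_cols: int = 8192,
) -> ScreenResult:
    """Compute one attractor per (replicate, scheme).

    ``replicate_states`` is nodes x replicates: each column is the
    undesired-phenotype initial state of one replicate.  All replicates
    of a scheme and many schemes are propagated together as one masked
    batch, so execution order cannot affect any cell.  Non-convergence
    is recorded per cell, never fatal.
    """
    cfg = cfg or SfaConfig()
    if mutations is not None:
        mutations.validate(g)
    schemes = list(schemes)
    replicate_states = replicate_states.reindex(g.nodes)
    if replicate_states.isna().any().any():
        raise ValueError("replicate states missing values for some network nodes")
    reps = list(replicate_states.columns)
    n = g.n_nodes
    n_reps = len(reps)
    W = weight_matrix(g)
    base = replicate_states.to_numpy(dtype=float)

    # Pre-resolve per-node up/down magnitudes once (pooled undesired extrema).
    override_sets = [
        resolve_overrides(s, expr, mutations, treatments, fallback) for s in schemes
    ]
    idx_of = {node: g.index(node) for node in g.nodes}

    total = len(schemes) * n_reps
    X_out = np.empty((n, total))
    conv_out = np.empty(total, dtype=bool)
    iters_out = np.empty(total, dtype=int)

    step = max(1, chunk_cols // max(n_reps, 1))
    for start in range(0, len(schemes), step):
        block = slice(start, min(start + step, len(schemes)))
        n_block = block.stop - block.start
        m = n_block * n_reps
        B = np.tile(base, n_block)
        mask = np.zeros((n, m), dtype=bool)
        P = np.zeros((n, m))
        for bi, ov in enumerate(override_sets[block]):
            cols = slice(bi * n_reps, (bi + 1) * n_reps)
            for node, val in ov.entries.items():
                mask[idx_of[node], cols] = True
                P[idx_of[node], cols] = val
        X, conv, iters, _ = _propagate_core(W, B, mask, P, cfg)
        cols = slice(block.start * n_reps, block.stop * n_reps)
        X_out[:, cols] = X
        conv_out[cols] = conv
        iters_out[cols] = iters

    scheme_ids = [s.id for s in schemes]
    index = pd.MultiIndex.from_tuples(
        [(r, sid) for sid in scheme_ids for r in reps],
        names=["replicate", "scheme_id"],
    )
    attractors = pd.DataFrame(X_out.T, index=index, columns=g.nodes)
    converged = pd.Series(conv_out, index=index, name="converged")
    iterations = pd.Series(iters_out, index=index, name="iterations")
    n_fail = int((~converged).sum())
    if n_fail:
        logger.warning("%d screen cell(s) did not converge", n_fail)
    return ScreenResult(attractors, converged, iterations, scheme_ids, reps)
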