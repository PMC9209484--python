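"""Signal flow analysis: fixed-point attractor estimation on signed networks.

The state of every node is propagated synchronously,

    x_i(t+1) = alpha * sum_j W_ij x_j(t) + (1 - alpha) * b_i,

where ``b_i`` is the node's (log-scale) initial activity and the edge
weight ``W_ij = sign(j->i) / sqrt(D_out(j) * D_in(i))`` normalizes the
influence a regulator exerts by how many targets it has and how many
regulators its target integrates.  ``alpha`` (default 0.9) weighs network
topology against the persistence of the initial state.  Iteration stops
when the largest elementwise change falls below ``tolerance`` (default
1e-6); every initial state then yields one fixed-point attractor.

Nodes may be *overridden* — pinned to a fixed value ``p_i`` for all t —
to model permanent overexpression/knockout (perturbations, mutations,
drug treatments).  An overridden node ignores incoming flow but still
feeds its pinned value to its neighbours.

Input values are taken as already log-scale; they are never re-logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import SignedDigraph, degrees

__all__ = [
    "SfaConfig",
    "InitialState",
    "OverrideSet",
    "Attractor",
    "DivergenceError",
    "weight_matrix",
    "propagate",
    "propagate_many",
    "compare_attractors",
    "override_value",
]

#: multiplier in the override equations: up = max + 2.5*max, down = min - 2.5*min
OVERRIDE_FACTOR = 2.5
#: override magnitude used when no expression data exists for the node
OVERRIDE_FALLBACK = 2.5


class DivergenceError(RuntimeError):
    """Propagation produced a non-finite state."""


@dataclass(frozen=True)
class SfaConfig:
    """Propagation hyperparameters.

    alpha : weight on the network term, in [0, 1).  0.9 by default,
        favouring topology over the initial activity.
    tolerance : convergence threshold on the max elementwise change.
    max_iterations : hard cap; non-convergence is flagged, never silent.
    """

    alpha: float = 0.9
    tolerance: float = 1e-6
    max_iterations: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class InitialState:
    """Per-node log-scale activities b_i seeding one simulation."""

    values: Mapping[str, float]
    label: str = ""
    provenance: str = "experimental"  # experimental | random | in_silico

    def vector(self, g: SignedDigraph) -> np.ndarray:
        missing = [n for n in g.nodes if n not in self.values]
        if missing:
            raise KeyError(f"initial state lacks values for nodes: {missing[:5]}")
        v = np.array([float(self.values[n]) for n in g.nodes])
        if not np.all(np.isfinite(v)):
            raise ValueError("initial state contains non-finite values")
        return v


@dataclass(frozen=True)
class OverrideSet:
    """Nodes pinned to fixed values p_i, unaffected by incoming flow."""

    entries: Mapping[str, float] = field(default_factory=dict)
    sources: Mapping[str, str] = field(default_factory=dict)  # perturbation | mutation | treatment

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self, g: SignedDigraph) -> None:
        unknown = [n for n in self.entries if n not in g]
        if unknown:
            raise KeyError(f"override names unknown nodes: {unknown}")
        bad = [n for n, v in self.entries.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite override values for: {bad}")

    def merged_with(self, other: "OverrideSet") -> "OverrideSet":
        entries = dict(self.entries)
        sources = dict(self.sources)
        entries.update(other.entries)
        sources.update(other.sources)
        return OverrideSet(entries, sources)


@dataclass(frozen=True)
class Attractor:
    """Converged (or capped) steady state of one propagation run."""

    values: Mapping[str, float]
    converged: bool
    iterations: int
    residual: float
    initial_label: str = ""
    overrides: OverrideSet = field(default_factory=OverrideSet)

    def vector(self, g: SignedDigraph) -> np.ndarray:
        return np.array([self.values[n] for n in g.nodes])


def weight_matrix(g: SignedDigraph) -> np.ndarray:
    """Degree-normalized signed influence matrix, indexed ``W[target, source]``.

    ``W[i, j] = sign(j->i) / sqrt(D_out(j) * D_in(i))`` for each edge
    j->i, zero elsewhere.
    """
    if g.n_nodes == 0:
        raise ValueError("graph is empty")
    deg = degrees(g)
    n = g.n_nodes
    W = np.zeros((n, n))
    for s, t, sign in g.edges:
        j, i = g.index(s), g.index(t)
        W[i, j] = sign / np.sqrt(deg[s][1] * deg[t][0])
    return W


def _propagate_core(
    W: np.ndarray,
    B: np.ndarray,
    mask: np.ndarray,
    P: np.ndarray,
    cfg: SfaConfig,
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Vectorized synchronous propagation for a batch of initial states.

    Parameters
    ----------
    W : (n, n) weight matrix.
    B : (n, m) initial states, one column per run.
    mask : (n, m) boolean, True where a node is overridden in that column.
    P : (n, m) override values (only read where mask is True).

    Returns ``(X, converged_per_column, iterations, final_residual)``.
    """
    alpha, tol = cfg.alpha, cfg.tolerance
    X = np.where(mask, P, B)
    persist = (1.0 - alpha) * B
    residual_cols = np.full(B.shape[1], np.inf)
    for it in range(1, cfg.max_iterations + 1):
        X_next = alpha * (W @ X) + persist
        X_next = np.where(mask, P, X_next)
        if not np.all(np.isfinite(X_next)):
            raise DivergenceError(f"non-finite state at iteration {it}")
        delta = np.abs(X_next - X)
        residual_cols = delta.max(axis=0) if delta.size else np.zeros(B.shape[1])
        X = X_next
        if residual_cols.size == 0 or residual_cols.max() < tol:
            return X, np.ones(B.shape[1], dtype=bool), it, float(residual_cols.max(initial=0.0))
    return X, residual_cols < tol, cfg.max_iterations, float(residual_cols.max(initial=0.0))


def propagate(
    g: SignedDigraph,
    init: InitialState,
    overrides: OverrideSet | None = None,
    cfg: SfaConfig | None = None,
) -> Attractor:
    """Run SFA from one initial state and return its attractor.

    Overridden nodes hold their pinned value exactly, from t=0 onward.
    Deterministic: identical inputs give bitwise-identical outputs.
    """
    cfg = cfg or SfaConfig()
    overrides = overrides or OverrideSet()
    overrides.validate(g)
    b = init.vector(g)[:, None]
    n = g.n_nodes
    mask = np.zeros((n, 1), dtype=bool)
    P = np.zeros((n, 1))
    for node, val in overrides.entries.items():
        mask[g.index(node), 0] = True
        P[g.index(node), 0] = val
    W = weight_matrix(g)
    X, conv, iters, residual = _propagate_core(W, b, mask, P, cfg)
    values = {node: float(X[i, 0]) for i, node in enumerate(g.nodes)}
    return Attractor(
        values=values,
        converged=bool(conv[0]),
        iterations=iters,
        residual=residual,
        initial_label=init.label,
        overrides=overrides,
    )


def propagate_many(
    g: SignedDigraph,
    B: np.ndarray,
    overrides: OverrideSet | None = None,
    cfg: SfaConfig | None = None,
    W: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Propagate a batch of initial-state columns under one override set.

    Returns ``(X_star, converged_mask, iterations)`` where ``X_star`` is
    (n_nodes, n_states).  Used for landscape estimation where thousands
    of states share the same (possibly empty) baseline override.
    """
    cfg = cfg or SfaConfig()
    overrides = overrides or OverrideSet()
    overrides.validate(g)
    if W is None:
        W = weight_matrix(g)
    n, m = B.shape
    mask = np.zeros((n, 1), dtype=bool)
    P = np.zeros((n, 1))
    for node, val in overrides.entries.items():
        mask[g.index(node), 0] = True
        P[g.index(node), 0] = val
    mask_b = np.broadcast_to(mask, (n, m))
    P_b = np.broadcast_to(P, (n, m))
    X, conv, iters, _ = _propagate_core(W, B, mask_b, P_b, cfg)
    return X, conv, iters


def compare_attractors(
    a: Attractor,
    b: Attractor,
    equality_tolerance: float = 1e-9,
) -> dict[str, tuple[str, float]]:
    """Per-node qualitative comparison, analogous to a log fold-change.

    Returns ``node -> (direction, difference)`` with direction ``up`` if
    a - b > tol, ``down`` if < -tol, else ``unchanged``.  The magnitude
    is reported but is not a quantitative effect size.
    """
    if set(a.values) != set(b.values):
        raise KeyError("attractors cover different node sets")
    out: dict[str, tuple[str, float]] = {}
    for node in a.values:
        d = a.values[node] - b.values[node]
        if d > equality_tolerance:
            direction = "up"
        elif d < -equality_tolerance:
            direction = "down"
        else:
            direction = "unchanged"
        out[node] = (direction, d)
    return out


def override_value(
    expr: Sequence[float] | Iterable[float],
    direction: str,
    fallback: bool = False,
) -> float:
    """Fixed override value for an up- or downregulated node.

    With expression data across the undesired-phenotype samples:

        up   -> max(normexp) + 2.5 * max(normexp)
        down -> min(normexp) - 2.5 * min(normexp)

    Without data (``fallback=True``): up -> +2.5, down -> -2.5.

    On log-scale data with negative minima the down formula can land
    *above* the observed minimum; this is reported as a warning rather
    than silently corrected.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    values = np.asarray(list(expr), dtype=float)
    if values.size == 0:
        if fallback:
            return OVERRIDE_FALLBACK if direction == "up" else -OVERRIDE_FALLBACK
        raise ValueError("no expression values supplied and fallback disabled")
    if direction == "up":
        mx = float(values.max())
        return mx + OVERRIDE_FACTOR * mx
    mn = float(values.min())
    p = mn - OVERRIDE_FACTOR * mn
    if p > mn:
        warnings.warn(
            f"downregulation override {p:.4g} exceeds the observed minimum "
            f"{mn:.4g} (negative log-scale minimum); applied verbatim",
            RuntimeWarning,
            stacklevel=2,
        )
    return p
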