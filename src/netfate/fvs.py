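"""Minimal feedback vertex set (FVS) search.

An FVS is a node set whose removal leaves the directed graph acyclic;
overriding the states of a minimal FVS is sufficient to steer a
nonlinear networked system into any of its attractors.  Finding a
minimum FVS is NP-hard, so the workhorse here is a simulated-annealing
local search (SA-FVSP family): the algorithm maintains the *complement*
— an acyclic induced subgraph kept in topological order — and tries to
grow it by inserting one node at a time, evicting whichever ordered
nodes the insertion contradicts, with Metropolis acceptance of uphill
moves.  An exhaustive enumerator serves as the exact oracle on small
graphs.

Nodes bearing self-loops can never join an acyclic subgraph; they are
forced FVS members and flagged as such.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .network import SignedDigraph, find_cycles_exists

__all__ = [
    "SaSchedule",
    "FvsResult",
    "is_fvs",
    "brute_force_min_fvs",
    "sa_min_fvs",
    "enumerate_fvs",
    "exclude_fixed_nodes",
]

logger = logging.getLogger(__name__)

BRUTE_FORCE_NODE_LIMIT = 20


@dataclass(frozen=True)
class SaSchedule:
    """Annealing schedule for the FVS local search.

    moves_per_level defaults to 50 * |V| when left as None.  The search
    stops at the temperature floor or after ``stagnation_levels``
    consecutive levels without improving the best solution.
    """

    initial_temperature: float = 0.6
    cooling_factor: float = 0.99
    moves_per_level: int | None = None
    stagnation_levels: int = 50
    temperature_floor: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.initial_temperature <= 0 or self.temperature_floor <= 0:
            raise ValueError("temperatures must be positive")
        if self.stagnation_levels < 1:
            raise ValueError("stagnation_levels must be >= 1")
        if self.moves_per_level is not None and self.moves_per_level < 1:
            raise ValueError("moves_per_level must be >= 1")


@dataclass(frozen=True)
class FvsResult:
    members: frozenset[str]
    size: int
    verified_minimal: bool
    search_seed: int
    restarts_used: int = 1
    self_loop_members: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# validity checks
# ---------------------------------------------------------------------------

def is_fvs(g: SignedDigraph, candidate: set[str] | frozenset[str]) -> bool:
    """True iff removing ``candidate`` leaves the graph acyclic."""
    return not find_cycles_exists(g, candidate)


def _adjacency(g: SignedDigraph) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    out: dict[str, set[str]] = {n: set() for n in g.nodes}
    inn: dict[str, set[str]] = {n: set() for n in g.nodes}
    for s, t, _ in g.edges:
        if s == t:
            continue  # self-loops handled as forced members
        out[s].add(t)
        inn[t].add(s)
    return out, inn


def _acyclic_without(
    nodes: list[str],
    out: dict[str, set[str]],
    inn: dict[str, set[str]],
    removed: set[str] | frozenset[str],
) -> bool:
    """Kahn's algorithm on the induced subgraph (self-loops pre-removed)."""
    indeg = {}
    for n in nodes:
        if n in removed:
            continue
        indeg[n] = sum(1 for p in inn[n] if p not in removed)
    queue = [n for n, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for m in out[n]:
            if m in indeg:
                indeg[m] -= 1
                if indeg[m] == 0:
                    queue.append(m)
    return seen == len(indeg)


# ---------------------------------------------------------------------------
# exact enumeration (oracle for small graphs)
# ---------------------------------------------------------------------------

def brute_force_min_fvs(
    g: SignedDigraph,
    size_cap: int | None = None,
) -> list[frozenset[str]]:
    """All minimum-size FVSes by exhaustive subset enumeration.

    Guarded to graphs of at most 20 nodes.  Nodes with self-loops are in
    every FVS and are fixed upfront to prune the search.
    """
    if g.n_nodes > BRUTE_FORCE_NODE_LIMIT:
        raise ValueError(
            f"brute-force enumeration refused for {g.n_nodes} nodes "
            f"(limit {BRUTE_FORCE_NODE_LIMIT}); use sa_min_fvs/enumerate_fvs"
        )
    forced = set(g.self_loop_nodes())
    out, inn = _adjacency(g)
    free = [n for n in g.nodes if n not in forced]
    cap = size_cap if size_cap is not None else g.n_nodes
    for extra in range(0, max(cap - len(forced), 0) + 1):
        found = [
            frozenset(forced | set(comb))
            for comb in combinations(free, extra)
            if _acyclic_without(g.nodes, out, inn, forced | set(comb))
        ]
        if found:
            return found
    return []


# ---------------------------------------------------------------------------
# simulated annealing (SA-FVSP style)
# ---------------------------------------------------------------------------

class _OrderedAcyclicSet:
    """Acyclic induced subgraph maintained as an explicit topological order."""

    def __init__(self) -> None:
        self.order: list[str] = []
        self.pos: dict[str, int] = {}

    def __contains__(self, n: str) -> bool:
        return n in self.pos

    def __len__(self) -> int:
        return len(self.order)

    def _reindex(self) -> None:
        self.pos = {n: i for i, n in enumerate(self.order)}

    def insert(self, node: str, position: int, evicted: set[str]) -> None:
        kept = [n for n in self.order[:position] if n not in evicted]
        tail = [n for n in self.order[position:] if n not in evicted]
        self.order = kept + [node] + tail
        self._reindex()

    def snapshot(self) -> list[str]:
        return list(self.order)


def _sa_search(
    g: SignedDigraph,
    schedule: SaSchedule,
    rng: np.random.Generator,
) -> set[str]:
    """One annealing run; returns the FVS (complement of the best order)."""
    forced = set(g.self_loop_nodes())
    candidates = [n for n in g.nodes if n not in forced]
    if not candidates:
        return set(forced)
    out, inn = _adjacency(g)

    state = _OrderedAcyclicSet()
    best: list[str] = []
    temperature = schedule.initial_temperature
    moves = schedule.moves_per_level or 50 * g.n_nodes
    stagnant = 0
    n_cand = len(candidates)

    while temperature > schedule.temperature_floor:
        improved = False
        for _ in range(moves):
            outside = [n for n in candidates if n not in state]
            if not outside:
                break
            v = outside[rng.integers(len(outside))]
            left = bool(rng.integers(2))
            pos_map = state.pos
            if left:
                # insert just after the last in-neighbour already ordered
                preds = [pos_map[u] for u in inn[v] if u in pos_map]
                position = (max(preds) + 1) if preds else 0
                conflicts = {u for u in out[v] if u in pos_map and pos_map[u] < position}
            else:
                # insert just before the first out-neighbour already ordered
                succs = [pos_map[u] for u in out[v] if u in pos_map]
                position = min(succs) if succs else len(state)
                conflicts = {u for u in inn[v] if u in pos_map and pos_map[u] >= position}
            delta = len(conflicts) - 1  # energy = |FVS| = n - |ordered set|
            if delta <= 0 or rng.random() < math.exp(-delta / temperature):
                state.insert(v, position, conflicts)
                if len(state) > len(best):
                    best = state.snapshot()
                    improved = True
                    if len(best) == n_cand:
                        return forced | (set(candidates) - set(best))
        stagnant = 0 if improved else stagnant + 1
        if stagnant >= schedule.stagnation_levels:
            break
        temperature *= schedule.cooling_factor
    return forced | (set(candidates) - set(best))


def _greedy_minimize(
    g: SignedDigraph,
    members: set[str],
    out: dict[str, set[str]],
    inn: dict[str, set[str]],
    forced: set[str],
) -> set[str]:
    """Deterministic inclusion-minimality pass in network node order."""
    result = set(members)
    for v in g.nodes:
        if v in result and v not in forced:
            trial = result - {v}
            if _acyclic_without(g.nodes, out, inn, trial):
                result = trial
    return result


def sa_min_fvs(
    g: SignedDigraph,
    schedule: SaSchedule | None = None,
    seed: int | None = None,
) -> FvsResult:
    """Near-minimum FVS by simulated annealing plus greedy minimization.

    Always returns a valid, inclusion-minimal FVS; minimum *size* is
    certified only against the brute-force oracle on small graphs.
    """
    if g.n_nodes == 0:
        raise ValueError("graph is empty")
    schedule = schedule or SaSchedule()
    actual_seed = schedule.seed if seed is None else seed
    rng = np.random.default_rng(actual_seed)
    forced = set(g.self_loop_nodes())
    out, inn = _adjacency(g)
    members = _sa_search(g, schedule, rng)
    members = _greedy_minimize(g, members, out, inn, forced)
    assert is_fvs(g, members)
    return FvsResult(
        members=frozenset(members),
        size=len(members),
        verified_minimal=True,
        search_seed=actual_seed,
        self_loop_members=frozenset(forced),
    )


def enumerate_fvs(
    g: SignedDigraph,
    schedule: SaSchedule | None = None,
    max_restarts: int = 200,
    saturation_rounds: int = 25,
    brute_force_limit: int = 14,
) -> list[frozenset[str]]:
    """Distinct minimum-size FVSes.

    Exact enumeration when the graph is within brute-force bounds;
    otherwise randomized SA restarts are collected until
    ``saturation_rounds`` consecutive restarts add nothing new.  The
    heuristic branch cannot certify exhaustiveness.
    """
    if g.n_nodes <= brute_force_limit:
        found = brute_force_min_fvs(g)
        return sorted(found, key=lambda s: sorted(s))
    schedule = schedule or SaSchedule()
    collected: set[frozenset[str]] = set()
    best_size = g.n_nodes + 1
    stagnant = 0
    for restart in range(max_restarts):
        res = sa_min_fvs(g, schedule, seed=schedule.seed + restart)
        if res.size < best_size:
            best_size = res.size
            collected = {res.members}
            stagnant = 0
        elif res.size == best_size and res.members not in collected:
            collected.add(res.members)
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= saturation_rounds:
            break
    return sorted(collected, key=lambda s: sorted(s))


def exclude_fixed_nodes(
    fvs_members: frozenset[str] | set[str],
    fixed: set[str] | frozenset[str],
) -> list[str]:
    """Control-node set after dropping nodes already pinned by mutations
    or treatments (their override would be redundant)."""
    control = [n for n in sorted(fvs_members) if n not in fixed]
    dropped = sorted(set(fvs_members) & set(fixed))
    if dropped:
        logger.info(
            "excluded %d already-fixed node(s) from the control set: %s",
            len(dropped), ", ".join(dropped),
        )
    if not control:
        logger.warning("all FVS members are fixed; control set is empty")
    return control
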