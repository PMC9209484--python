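"""Signed directed networks: the substrate of every computation in netfate.

A regulatory or signalling network is stored as a :class:`SignedDigraph`:
an ordered node set plus a list of ``(source, target, sign)`` edges with
sign +1 (activation) or -1 (inhibition).  Node order is fixed at first
appearance so that matrices built from the graph are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "SignedDigraph",
    "NetworkFormatError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "degrees",
    "find_cycles_exists",
]


class NetworkFormatError(ValueError):
    """A record in a network file could not be parsed."""


class NetworkValidationError(ValueError):
    """The parsed edge list violates a structural invariant."""


#: accepted sign tokens (case-insensitive) -> canonical sign
SIGN_TOKENS: Mapping[str, int] = {
    "1": 1,
    "+1": 1,
    "+": 1,
    "activate": 1,
    "-1": -1,
    "-": -1,
    "inhibit": -1,
}


def normalize_sign(token: str | int) -> int:
    """Map a heterogeneous sign encoding onto ±1."""
    if isinstance(token, int):
        if token in (1, -1):
            return token
        raise NetworkFormatError(f"sign must be +1 or -1, got {token!r}")
    key = token.strip().lower()
    try:
        return SIGN_TOKENS[key]
    except KeyError:
        raise NetworkFormatError(f"unrecognized sign token {token!r}") from None


@dataclass
class SignedDigraph:
    """Directed graph with ±1 edge signs and a stable node order.

    Invariants enforced at construction:

    * no duplicate ``(source, target)`` pairs — in particular, parallel
      edges of opposite sign are rejected;
    * every edge endpoint belongs to the node set;
    * node order is insertion order of first appearance.
    """

    nodes: list[str] = field(default_factory=list)
    edges: list[tuple[str, str, int]] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _pair_sign: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self._index or self._pair_sign:
            return
        nodes, edges = self.nodes, self.edges
        self.nodes, self.edges = [], []
        for n in nodes:
            self.add_node(n)
        for s, t, sign in edges:
            self.add_edge(s, t, sign)

    # -- construction ---------------------------------------------------
    def add_node(self, name: str) -> None:
        if name not in self._index:
            self._index[name] = len(self.nodes)
            self.nodes.append(name)

    def add_edge(self, source: str, target: str, sign: int | str) -> None:
        sign = normalize_sign(sign)
        pair = (source, target)
        if pair in self._pair_sign:
            if self._pair_sign[pair] != sign:
                raise NetworkValidationError(
                    f"contradictory duplicate edge {source}->{target}: "
                    "both activation and inhibition supplied"
                )
            raise NetworkValidationError(
                f"duplicate edge {source}->{target}"
            )
        self.add_node(source)
        self.add_node(target)
        self._pair_sign[pair] = sign
        self.edges.append((source, target, sign))

    # -- queries ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, node: str) -> int:
        """Stable integer position of ``node`` (first-appearance order)."""
        return self._index[node]

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self._pair_sign

    def sign(self, source: str, target: str) -> int:
        return self._pair_sign[(source, target)]

    def out_neighbors(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {n: set() for n in self.nodes}
        for s, t, _ in self.edges:
            out[s].add(t)
        return out

    def in_neighbors(self) -> dict[str, set[str]]:
        inn: dict[str, set[str]] = {n: set() for n in self.nodes}
        for s, t, _ in self.edges:
            inn[t].add(s)
        return inn

    def self_loop_nodes(self) -> list[str]:
        """Nodes bearing a self-loop (length-1 cycles; forced FVS members)."""
        return [n for n in self.nodes if (n, n) in self._pair_sign]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.edges:
            g.add_edge(s, t, sign=sign)
        return g


def read_network(path: str | Path, dialect: str = "sif_sign") -> SignedDigraph:
    """Read a 3-column signed edge list (``source<TAB>sign<TAB>target``).

    Parameters
    ----------
    path
        Tab-separated file, one edge per line; lines starting with ``#``
        are ignored.  Sign tokens: 1, -1, +, -, activate, inhibit
        (case-insensitive).
    dialect
        ``sif_sign`` — middle column is the sign (SIF-style);
        ``three_column`` — columns are source, target, sign.

    Raises
    ------
    NetworkFormatError
        Malformed record (with its line number) or unknown sign token.
    NetworkValidationError
        Empty file, or duplicate/contradictory edges.
    """
    if dialect not in ("sif_sign", "three_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    g = SignedDigraph()
    n_records = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields_ = line.split("\t")
            if len(fields_) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields_)}"
                )
            if dialect == "sif_sign":
                source, sign_tok, target = fields_
            else:
                source, target, sign_tok = fields_
            try:
                g.add_edge(source.strip(), target.strip(), sign_tok)
            except NetworkFormatError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: {exc}") from None
            n_records += 1
    if n_records == 0:
        raise NetworkValidationError(f"{path}: no edge records found")
    return g


def write_network(g: SignedDigraph, path: str | Path) -> None:
    """Write the canonical 3-column form; signs emitted as 1/-1."""
    path = Path(path)
    with path.open("w") as fh:
        for s, t, sign in g.edges:
            fh.write(f"{s}\t{sign}\t{t}\n")


def degrees(g: SignedDigraph) -> dict[str, tuple[int, int]]:
    """Per-node ``(in_degree, out_degree)``.

    A self-loop counts toward both degrees of the looping node, so edge
    conservation Σ in = Σ out = |E| holds.
    """
    ind = {n: 0 for n in g.nodes}
    outd = {n: 0 for n in g.nodes}
    for s, t, _ in g.edges:
        outd[s] += 1
        ind[t] += 1
    return {n: (ind[n], outd[n]) for n in g.nodes}


def find_cycles_exists(g: SignedDigraph, removed: Iterable[str] = ()) -> bool:
    """True iff the graph minus ``removed`` still contains a directed cycle.

    Self-loops count as cycles of length 1.
    """
    removed = set(removed)
    unknown = removed - set(g.nodes)
    if unknown:
        raise KeyError(f"unknown nodes in removal set: {sorted(unknown)}")
    sub = g.to_networkx()
    sub.remove_nodes_from(removed)
    return not nx.is_directed_acyclic_graph(sub)


def subgraph(g: SignedDigraph, keep: Sequence[str]) -> SignedDigraph:
    """Induced subgraph on ``keep``, preserving relative node order."""
    keep_set = set(keep)
    out = SignedDigraph()
    for n in g.nodes:
        if n in keep_set:
            out.add_node(n)
    for s, t, sign in g.edges:
        if s in keep_set and t in keep_set:
            out.add_edge(s, t, sign)
    return out
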