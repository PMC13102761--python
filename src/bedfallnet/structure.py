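"""Score-based structure learning: DAG container, steepest-ascent hill
climbing under a maximum-in-degree constraint, and CPDAG conversion.

Search starts from the empty graph and repeatedly applies the best single-edge
move (add, delete, or reverse) whose score improvement exceeds ``epsilon``,
stopping at a local optimum. Candidate moves are enumerated in a fixed order
— operation (add, delete, reverse), then ordered node pairs sorted
lexicographically — and the first move attaining the maximal improvement wins,
so results are fully deterministic. Because BIC is score-equivalent, the
direction of an edge inside a Markov-equivalence class is an artifact of this
enumeration order; ``to_cpdag`` exposes which directions are actually
compelled by the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, Tuple

import networkx as nx

from bedfallnet.data import IncidentMatrix
from bedfallnet.scoring import bic_local

Edge = Tuple[str, str]


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph over factor codes."""

    nodes: tuple[str, ...]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a directed cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(v for u, v in self.edges if u == node))

    def in_degree(self, node: str) -> int:
        return sum(1 for _, v in self.edges if v == node)

    def out_degree(self, node: str) -> int:
        return sum(1 for u, _ in self.edges if u == node)

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.to_networkx()))
        return order

    @classmethod
    def empty(cls, nodes: Iterable[str]) -> "Dag":
        return cls(tuple(nodes), frozenset())


@dataclass(frozen=True)
class SearchConfig:
    """Hill-climbing settings.

    max_parents
        In-degree cap applied during search; 3 keeps structures sparse on
        ~100-record datasets.
    epsilon
        Minimum score improvement to accept a move; > 0 prevents wandering
        among score-equivalent structures.
    """

    max_parents: int = 3
    score: str = "bic"
    epsilon: float = 1e-9
    tie_break: str = "lexicographic"

    def __post_init__(self) -> None:
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.score != "bic":
            raise ValueError(f"unsupported score {self.score!r}")


class _SearchState:
    """Mutable adjacency + memoised local scores used inside hill climbing."""

    def __init__(self, matrix: IncidentMatrix, nodes: tuple[str, ...]):
        self.matrix = matrix
        self.nodes = nodes
        self.parents: Dict[str, frozenset[str]] = {v: frozenset() for v in nodes}
        self._cache: Dict[tuple[str, frozenset[str]], float] = {}

    def local(self, child: str, parents: FrozenSet[str]) -> float:
        key = (child, parents)
        if key not in self._cache:
            self._cache[key] = bic_local(self.matrix, child, tuple(sorted(parents)))
        return self._cache[key]

    def has_edge(self, u: str, v: str) -> bool:
        return u in self.parents[v]

    def creates_cycle(self, u: str, v: str) -> bool:
        """Would adding u -> v create a cycle? True iff v reaches u."""
        stack, seen = [v], {v}
        while stack:
            w = stack.pop()
            if w == u:
                return True
            for child in self.nodes:
                if w in self.parents[child] and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return False


def hill_climb(matrix: IncidentMatrix, config: SearchConfig = SearchConfig()) -> Dag:
    """Steepest-ascent hill climbing from the empty graph under BIC.

    Deterministic given matrix and config: every iteration scores all legal
    add/delete/reverse moves, applies the first move attaining the maximal
    improvement if that improvement exceeds ``config.epsilon``, and stops
    otherwise.
    """
    if matrix.n == 0:
        raise ValueError("cannot learn structure from an empty matrix")
    nodes = matrix.column_codes
    state = _SearchState(matrix, nodes)

    while True:
        best_delta = config.epsilon
        best_move = None

        # adds
        for u in nodes:
            for v in nodes:
                if u == v or state.has_edge(u, v):
                    continue
                if len(state.parents[v]) >= config.max_parents:
                    continue
                if state.creates_cycle(u, v):
                    continue
                delta = state.local(v, state.parents[v] | {u}) - state.local(v, state.parents[v])
                if delta > best_delta:
                    best_delta, best_move = delta, ("add", u, v)
        # deletes
        for u in nodes:
            for v in nodes:
                if not state.has_edge(u, v):
                    continue
                delta = state.local(v, state.parents[v] - {u}) - state.local(v, state.parents[v])
                if delta > best_delta:
                    best_delta, best_move = delta, ("delete", u, v)
        # reversals (u -> v becomes v -> u)
        for u in nodes:
            for v in nodes:
                if not state.has_edge(u, v):
                    continue
                if len(state.parents[u]) >= config.max_parents:
                    continue
                # removing u->v first, then adding v->u: cycle iff u still reaches v
                state.parents[v] = state.parents[v] - {u}
                cycle = state.creates_cycle(v, u)
                new_pv = state.parents[v]
                state.parents[v] = new_pv | {u}
                if cycle:
                    continue
                delta = (
                    state.local(v, new_pv)
                    - state.local(v, state.parents[v])
                    + state.local(u, state.parents[u] | {v})
                    - state.local(u, state.parents[u])
                )
                if delta > best_delta:
                    best_delta, best_move = delta, ("reverse", u, v)

        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            state.parents[v] = state.parents[v] | {u}
        elif op == "delete":
            state.parents[v] = state.parents[v] - {u}
        else:
            state.parents[v] = state.parents[v] - {u}
            state.parents[u] = state.parents[u] | {v}

    edges = frozenset((u, v) for v in nodes for u in state.parents[v])
    return Dag(nodes, edges)


def to_cpdag(dag: Dag) -> nx.DiGraph:
    """Skeleton plus compelled edge directions (the Markov-equivalence class).

    Returns a directed graph in which a compelled edge u -> v appears only as
    (u, v) while a reversible edge appears as both (u, v) and (v, u).
    V-structures (colliders with non-adjacent parents) are directed first;
    Meek's orientation rules are then applied to closure.
    """
    directed: set[Edge] = set()
    undirected: set[frozenset[str]] = {frozenset(e) for e in dag.edges}

    adjacent = {v: set() for v in dag.nodes}
    for u, v in dag.edges:
        adjacent[u].add(v)
        adjacent[v].add(u)

    # v-structures: u -> w <- v with u, v non-adjacent
    for w in dag.nodes:
        pa = dag.parents(w)
        for i, u in enumerate(pa):
            for v in pa[i + 1:]:
                if v not in adjacent[u]:
                    for parent in (u, v):
                        directed.add((parent, w))
                        undirected.discard(frozenset((parent, w)))

    def has_directed(a: str, b: str) -> bool:
        return (a, b) in directed

    def is_undirected(a: str, b: str) -> bool:
        return frozenset((a, b)) in undirected

    def orient(a: str, b: str) -> None:
        undirected.discard(frozenset((a, b)))
        directed.add((a, b))

    # Meek rules to closure
    changed = True
    while changed:
        changed = False
        for pair in list(undirected):
            a, b = sorted(pair)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, z not adjacent to y  =>  x -> y
                if any(
                    has_directed(z, x) and y not in adjacent[z]
                    for z in adjacent[x] - {y}
                ):
                    orient(x, y)
                    changed = True
                    break
                # R2: directed path x -> z -> y  =>  x -> y
                if any(
                    has_directed(x, z) and has_directed(z, y)
                    for z in adjacent[x] & adjacent[y]
                ):
                    orient(x, y)
                    changed = True
                    break
                # R3: x - z1 -> y, x - z2 -> y, z1/z2 non-adjacent  =>  x -> y
                zs = [
                    z
                    for z in adjacent[x] & adjacent[y]
                    if is_undirected(x, z) and has_directed(z, y)
                ]
                if any(
                    z2 not in adjacent[z1]
                    for i, z1 in enumerate(zs)
                    for z2 in zs[i + 1:]
                ):
                    orient(x, y)
                    changed = True
                    break
            else:
                continue

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(directed)
    for pair in undirected:
        a, b = tuple(pair)
        g.add_edge(a, b)
        g.add_edge(b, a)
    return g
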