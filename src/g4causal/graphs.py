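"""Partially directed graphs, d-separation, and Markov-equivalence machinery.

The structure-learning output of a constraint-based algorithm is a partially
directed acyclic graph (PDAG): compelled edges are directed, edges whose
orientation is not identified by the data remain undirected.  This module
provides the :class:`PDAG` container, the d-separation criterion used as an
exact conditional-independence oracle, Meek's orientation rules, and the
DAG -> CPDAG conversion that serves as an independent reference for the
learner.
"""

from __future__ import annotations

import logging
from collections import deque
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class CycleError(ValueError):
    """Raised when a graph required to be acyclic contains a directed cycle."""


class PDAG:
    """A partially directed graph with disjoint directed and undirected edges.

    Nodes are strings.  A pair of nodes carries at most one edge, which is
    either directed or undirected; the directed subgraph must stay acyclic.
    """

    def __init__(self, nodes: Iterable[str],
                 directed: Iterable[Edge] = (),
                 undirected: Iterable[Iterable[str]] = ()):
        self.nodes: tuple[str, ...] = tuple(dict.fromkeys(nodes))
        self._dir: set[Edge] = set()
        self._und: set[frozenset] = set()
        for a, b in directed:
            self.add_directed(a, b)
        for pair in undirected:
            a, b = tuple(pair)
            self.add_undirected(a, b)

    # -- construction -----------------------------------------------------

    def add_directed(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if a not in self.nodes or b not in self.nodes:
            raise ValueError(f"unknown node in edge {a!r}->{b!r}")
        key = frozenset((a, b))
        self._und.discard(key)
        self._dir.discard((b, a))
        self._dir.add((a, b))

    def add_undirected(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if a not in self.nodes or b not in self.nodes:
            raise ValueError(f"unknown node in edge {a!r}-{b!r}")
        self._dir.discard((a, b))
        self._dir.discard((b, a))
        self._und.add(frozenset((a, b)))

    def remove_edge(self, a: str, b: str) -> None:
        self._dir.discard((a, b))
        self._dir.discard((b, a))
        self._und.discard(frozenset((a, b)))

    def orient(self, a: str, b: str) -> None:
        """Turn the a-b adjacency (however represented) into a->b."""
        if not self.adjacent(a, b):
            raise ValueError(f"{a!r} and {b!r} are not adjacent")
        self.add_directed(a, b)

    def copy(self) -> "PDAG":
        return PDAG(self.nodes, self._dir, self._und)

    # -- queries -----------------------------------------------------------

    @property
    def directed_edges(self) -> frozenset:
        return frozenset(self._dir)

    @property
    def undirected_edges(self) -> frozenset:
        return frozenset(self._und)

    def skeleton_edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self._dir) | frozenset(self._und)

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.skeleton_edges()

    def has_directed(self, a: str, b: str) -> bool:
        return (a, b) in self._dir

    def has_undirected(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._und

    def neighbors(self, a: str) -> set[str]:
        """All nodes adjacent to ``a`` regardless of orientation."""
        out = {y for x, y in self._dir if x == a}
        out |= {x for x, y in self._dir if y == a}
        for pair in self._und:
            if a in pair:
                out |= pair - {a}
        return out

    def parents(self, a: str) -> set[str]:
        return {x for x, y in self._dir if y == a}

    def children(self, a: str) -> set[str]:
        return {y for x, y in self._dir if x == a}

    def undirected_neighbors(self, a: str) -> set[str]:
        out: set[str] = set()
        for pair in self._und:
            if a in pair:
                out |= pair - {a}
        return out

    def is_dag(self) -> bool:
        """True if every edge is directed and the graph is acyclic."""
        return not self._und and self.directed_part_acyclic()

    def directed_part_acyclic(self) -> bool:
        try:
            self.topological_order()
            return True
        except CycleError:
            return False

    def topological_order(self) -> list[str]:
        """Topological order of the directed subgraph (Kahn's algorithm)."""
        indeg = {v: 0 for v in self.nodes}
        for _, y in self._dir:
            indeg[y] += 1
        queue = deque(sorted(v for v in self.nodes if indeg[v] == 0))
        order = []
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in sorted(self.children(v)):
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if len(order) != len(self.nodes):
            raise CycleError("directed subgraph contains a cycle")
        return order

    def validate(self) -> None:
        if not self.directed_part_acyclic():
            raise CycleError("directed subgraph contains a cycle")

    def __eq__(self, other) -> bool:
        if not isinstance(other, PDAG):
            return NotImplemented
        return (set(self.nodes) == set(other.nodes)
                and self._dir == other._dir and self._und == other._und)

    def __hash__(self):
        return hash((frozenset(self.nodes), frozenset(self._dir),
                     frozenset(self._und)))

    def __repr__(self) -> str:
        d = ", ".join(f"{a}->{b}" for a, b in sorted(self._dir))
        u = ", ".join("-".join(sorted(p)) for p in
                      sorted(self._und, key=lambda p: sorted(p)))
        return f"PDAG(nodes={list(self.nodes)}, directed=[{d}], undirected=[{u}])"

    # -- ancestors (on the directed subgraph) ------------------------------

    def ancestors(self, targets: Iterable[str]) -> set[str]:
        """Nodes with a directed path into any target, including the targets."""
        seen = set(targets)
        stack = list(seen)
        while stack:
            v = stack.pop()
            for p in self.parents(v):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    # -- serialization -----------------------------------------------------

    def to_adjacency_frame(self) -> pd.DataFrame:
        """Adjacency matrix: 0 no edge, 1 directed row->col, 2 undirected."""
        n = len(self.nodes)
        mat = np.zeros((n, n), dtype=int)
        idx = {v: i for i, v in enumerate(self.nodes)}
        for a, b in self._dir:
            mat[idx[a], idx[b]] = 1
        for pair in self._und:
            a, b = tuple(pair)
            mat[idx[a], idx[b]] = 2
            mat[idx[b], idx[a]] = 2
        return pd.DataFrame(mat, index=list(self.nodes), columns=list(self.nodes))

    @classmethod
    def from_adjacency_frame(cls, frame: pd.DataFrame) -> "PDAG":
        nodes = [str(c) for c in frame.columns]
        g = cls(nodes)
        mat = frame.to_numpy()
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                if mat[i, j] == 1:
                    g.add_directed(a, b)
                elif mat[i, j] == 2 and i < j:
                    g.add_undirected(a, b)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(a, b, "directed") for a, b in sorted(self._dir)]
        rows += [(a, b, "undirected") for a, b in
                 sorted(tuple(sorted(p)) for p in self._und)]
        return pd.DataFrame(rows, columns=["source", "target", "kind"])

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for a, b in sorted(self._dir):
            lines.append(f'  "{a}" -> "{b}";')
        for a, b in sorted(tuple(sorted(p)) for p in self._und):
            lines.append(f'  "{a}" -> "{b}" [dir=none];')
        lines.append("}")
        return "\n".join(lines)


def dag_from_edges(nodes: Iterable[str], edges: Iterable[Edge]) -> PDAG:
    """Build a fully directed PDAG and check acyclicity."""
    edges = list(edges)
    seen = set(map(tuple, edges))
    if any((b, a) in seen for a, b in seen):
        raise CycleError("edge set contains a 2-cycle")
    g = PDAG(nodes, directed=edges)
    if not g.is_dag():
        raise CycleError("edge set contains a directed cycle")
    return g


# ---------------------------------------------------------------------------
# d-separation
# ---------------------------------------------------------------------------

def d_separated(dag: PDAG, a: Iterable[str] | str, b: Iterable[str] | str,
                s: Iterable[str] = ()) -> bool:
    """Decide whether node sets A and B are d-separated by S in a DAG.

    A path is blocked by S if it contains a chain (->Z->) or fork (<-Z->)
    with Z in S, or a collider (->Z<-) with neither Z nor any descendant of
    Z in S.  A and B are d-separated iff every path between them is blocked.

    Implemented as the linear-time reachability ("Bayes ball") algorithm:
    a breadth-first search over (node, direction-of-arrival) states.
    """
    a_set = {a} if isinstance(a, str) else set(a)
    b_set = {b} if isinstance(b, str) else set(b)
    s_set = set(s)
    if dag.undirected_edges:
        raise ValueError("d-separation requires a fully directed graph")
    if not dag.directed_part_acyclic():
        raise CycleError("d-separation requires an acyclic graph")
    if a_set & b_set or a_set & s_set or b_set & s_set:
        raise ValueError("A, B and S must be disjoint")

    # A collider is open iff it is in S or has a descendant in S, i.e. iff it
    # is an ancestor of S.
    an_s = dag.ancestors(s_set) if s_set else set()

    # States: (node, came_from_child?) where came_from_child means the walk
    # arrived along an edge pointing at the node's child (i.e. we are moving
    # "up", against edge direction is False/True bookkeeping below).
    # Encode direction as "up" (arrived from a child, traversing edge
    # backwards) or "down" (arrived from a parent, traversing forwards).
    visited: set[tuple[str, str]] = set()
    queue: deque[tuple[str, str]] = deque()
    for x in a_set:
        queue.append((x, "up"))  # leaving the source may go anywhere
    while queue:
        node, direction = queue.popleft()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node in b_set and node not in s_set:
            return False
        if direction == "up" and node not in s_set:
            # can go up to parents and down to children
            for p in dag.parents(node):
                queue.append((p, "up"))
            for c in dag.children(node):
                queue.append((c, "down"))
        elif direction == "down":
            if node not in s_set:
                # chain: continue down through children
                for c in dag.children(node):
                    queue.append((c, "down"))
            if node in an_s:
                # open collider: bounce back up to parents
                for p in dag.parents(node):
                    queue.append((p, "up"))
    return True


# ---------------------------------------------------------------------------
# Meek orientation rules
# ---------------------------------------------------------------------------

def apply_meek_rules(g: PDAG) -> PDAG:
    """Apply Meek's orientation rules R1-R4 to a fixed point (in place).

    R1: a->b, b-c, a and c non-adjacent        => b->c
    R2: a->c, c->b, a-b                        => a->b
    R3: a-b, a-c, a-d, c->b, d->b, c,d non-adj => a->b
    R4: a-b, a adj d, d->c, c->b, d,b non-adj  => a->b
    """
    changed = True
    while changed:
        changed = False
        for pair in sorted(g.undirected_edges, key=lambda p: sorted(p)):
            x, y = sorted(pair)
            for a, b in ((x, y), (y, x)):
                if _meek_fires(g, a, b):
                    g.orient(a, b)
                    changed = True
                    break
    g.validate()
    return g


def _meek_fires(g: PDAG, a: str, b: str) -> bool:
    """Would some Meek rule orient the undirected a-b edge as a->b?"""
    # R1: c->a, a-b, c not adjacent to b  => a->b
    for c in g.parents(a):
        if not g.adjacent(c, b):
            return True
    # R2: a->c->b and a-b  => a->b
    for c in g.children(a):
        if g.has_directed(c, b):
            return True
    # R3: a-c, a-d, c->b, d->b, c,d non-adjacent  => a->b
    cands = [c for c in g.undirected_neighbors(a) if g.has_directed(c, b)]
    for c, d in combinations(sorted(cands), 2):
        if not g.adjacent(c, d):
            return True
    # R4: a adjacent d, d->c, c->b, d,b non-adjacent  => a->b
    for c in g.parents(b):
        if c == a:
            continue
        for d in g.parents(c):
            if d != b and g.adjacent(a, d) and not g.adjacent(d, b):
                return True
    return False


# ---------------------------------------------------------------------------
# DAG -> CPDAG
# ---------------------------------------------------------------------------

def dag_to_cpdag(dag: PDAG) -> PDAG:
    """Completed partially directed graph of a DAG's equivalence class.

    Labels every edge compelled or reversible with Chickering's
    transformational characterization, then emits compelled edges directed
    and reversible edges undirected.  Two DAGs are Markov equivalent iff
    they share a skeleton and v-structures; the CPDAG is the canonical
    representative of that class.
    """
    if not dag.is_dag():
        raise CycleError("input must be a fully directed acyclic graph")
    order = dag.topological_order()
    rank = {v: i for i, v in enumerate(order)}

    # Total order on edges: sort by (rank of head, -rank of tail) — i.e. take
    # the lowest-ordered head y with unordered incident edges, then the
    # highest-ordered tail x with x->y unordered.
    edges = sorted(dag.directed_edges, key=lambda e: (rank[e[1]], -rank[e[0]]))

    label: dict[Edge, str] = {}
    for x, y in edges:
        if (x, y) in label:
            continue
        resolved = False
        for w in sorted(dag.parents(x), key=rank.get):
            if label.get((w, x)) != "compelled":
                continue
            if not dag.has_directed(w, y):
                # w -> x compelled and w not a parent of y: every edge into y
                # is compelled.
                for z in dag.parents(y):
                    label[(z, y)] = "compelled"
                resolved = True
                break
            label[(w, y)] = "compelled"
        if resolved:
            continue
        # A v-structure witness z -> y with z not a parent of x (and z != x)
        # compels x -> y and all unlabeled edges into y.
        if any(z != x and not dag.has_directed(z, x) for z in dag.parents(y)):
            for z in dag.parents(y):
                label.setdefault((z, y), "compelled")
        else:
            for z in dag.parents(y):
                label.setdefault((z, y), "reversible")

    out = PDAG(dag.nodes)
    for x, y in dag.directed_edges:
        if label[(x, y)] == "compelled":
            out.add_directed(x, y)
        else:
            out.add_undirected(x, y)
    return out


# ---------------------------------------------------------------------------
# Enumeration helpers (small-graph oracles and simulators lean on these)
# ---------------------------------------------------------------------------

def all_dags(nodes: Sequence[str]) -> list[PDAG]:
    """Enumerate every labelled DAG on the given nodes.

    Each unordered pair independently carries no edge or one of the two
    orientations; the 3^(n choose 2) digraphs are filtered for acyclicity.
    Practical for n <= 4 (543 DAGs) or 5 (29281).
    """
    pairs = list(combinations(nodes, 2))
    out = []
    for choice in np.ndindex(*(3,) * len(pairs)):
        edges = []
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                edges.append((a, b))
            elif c == 2:
                edges.append((b, a))
        g = PDAG(nodes, directed=edges)
        if g.directed_part_acyclic():
            out.append(g)
    return out


def random_dag(nodes: Sequence[str], edge_prob: float,
               rng: np.random.Generator) -> PDAG:
    """Random DAG: random node order, each forward pair kept with edge_prob."""
    perm = list(nodes)
    rng.shuffle(perm)
    edges = [(perm[i], perm[j])
             for i in range(len(perm)) for j in range(i + 1, len(perm))
             if rng.random() < edge_prob]
    return PDAG(nodes, directed=edges)


def v_structures(g: PDAG) -> set[tuple[str, str, str]]:
    """Ordered colliders (x, z, y) with x->z<-y, x,y non-adjacent, x < y."""
    out = set()
    for z in g.nodes:
        for x, y in combinations(sorted(g.parents(z)), 2):
            if not g.adjacent(x, y):
                out.add((x, z, y))
    return out
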