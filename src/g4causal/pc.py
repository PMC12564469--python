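"""Order-independent PC structure learning (PC-stable).

Constraint-based causal discovery: start from the complete undirected graph,
delete edges whose endpoints test conditionally independent given some
subset of their neighbourhood, orient v-structures from the recorded
separating sets, and close under Meek's rules.  The "stable" variant
freezes every node's adjacency set at the start of each level, so the
skeleton does not depend on the order in which edges are visited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import pandas as pd

from .citest import CITestConfig, PermutationCITest
from .graphs import PDAG, apply_meek_rules

logger = logging.getLogger(__name__)

#: a CI test maps (x, y, conditioning set) to a p-value in (0, 1].
CITest = Callable[[str, str, Sequence[str]], float]


@dataclass
class SeparatingSets:
    """Separating set found for each removed adjacency.

    Maps the unordered pair {x, y} to the conditioning set S that rendered
    them independent during skeleton estimation.
    """

    sets: dict[frozenset, frozenset] = field(default_factory=dict)

    def record(self, x: str, y: str, s: Sequence[str]) -> None:
        self.sets[frozenset((x, y))] = frozenset(s)

    def get(self, x: str, y: str) -> frozenset | None:
        return self.sets.get(frozenset((x, y)))

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.sets


def pc_stable(data: pd.DataFrame | Sequence[str],
              ci_test: CITest | None = None,
              config: CITestConfig | None = None,
              max_cond_size: int | None = None,
              ) -> tuple[PDAG, SeparatingSets]:
    """Learn a partially directed graph with the order-independent PC algorithm.

    Parameters
    ----------
    data
        Discrete observational table (one column per variable; a ``stratum``
        column, if present, is not treated as a variable), or, when an
        external ``ci_test`` is supplied, just the list of variable names.
    ci_test
        Callable ``(x, y, s) -> p``.  Defaults to a
        :class:`~g4causal.citest.PermutationCITest` built from ``data``.
    config
        CI-test configuration (alpha, permutation count, seed).
    max_cond_size
        Cap on the conditioning-set size; default |V| - 2 (unrestricted).

    Returns
    -------
    (PDAG, SeparatingSets)
        The estimated CPDAG-like graph and the separating sets used for
        v-structure orientation.

    Notes
    -----
    Nodes, pairs and candidate subsets are always enumerated in sorted-name
    order and the default CI test derives a per-test RNG stream keyed on the
    variable names, so the result is invariant to the column order of
    ``data``.
    """
    config = config or CITestConfig()
    if isinstance(data, pd.DataFrame):
        nodes = sorted(c for c in data.columns if c != "stratum")
        if len(data) == 0:
            raise ValueError("empty data")
    else:
        nodes = sorted(data)
        if ci_test is None:
            raise ValueError("a ci_test is required when data is a node list")
    if len(nodes) < 3:
        raise ValueError("structure learning needs at least 3 variables")

    decide = _decision_fn(data, ci_test, config)
    max_cond = len(nodes) - 2 if max_cond_size is None else max_cond_size

    skeleton, sepsets = _learn_skeleton(nodes, decide, max_cond)
    g = _orient_v_structures(skeleton, sepsets)
    apply_meek_rules(g)
    g.validate()
    return g, sepsets


def _decision_fn(data, ci_test: CITest | None, config: CITestConfig):
    """Wrap either an external p-value test or the built-in permutation test
    into an independence decision with a sepset-recording signature."""
    if ci_test is None:
        perm = PermutationCITest(data, config)
        return perm.independent
    alpha = config.alpha

    def decide(x: str, y: str, s: Sequence[str]) -> bool:
        return ci_test(x, y, s) > alpha

    return decide


def _learn_skeleton(nodes: Sequence[str], independent, max_cond: int,
                    ) -> tuple[PDAG, SeparatingSets]:
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets = SeparatingSets()
    level = 0
    while level <= max_cond:
        # freeze adjacency sets for this level: removals within the level do
        # not shrink the candidate conditioning pools (PC-stable)
        frozen = {v: frozenset(adj[v]) for v in nodes}
        if all(len(frozen[v]) - 1 < level for v in nodes):
            break
        for x, y in combinations(nodes, 2):
            if y not in adj[x]:
                continue
            removed = False
            for a, b in ((x, y), (y, x)):
                pool = sorted(frozen[a] - {b})
                if len(pool) < level:
                    continue
                for s in combinations(pool, level):
                    if independent(a, b, list(s)):
                        adj[x].discard(y)
                        adj[y].discard(x)
                        sepsets.record(x, y, s)
                        logger.debug("removed %s-%s | %s", x, y, s)
                        removed = True
                        break
                if removed:
                    break
        level += 1
    g = PDAG(nodes)
    for x, y in combinations(nodes, 2):
        if y in adj[x]:
            g.add_undirected(x, y)
    return g, sepsets


def _orient_v_structures(skeleton: PDAG, sepsets: SeparatingSets) -> PDAG:
    """Orient x -> z <- y for every unshielded triple with z outside sep(x,y).

    If two v-structures claim opposite orientations for one adjacency, the
    edge is left undirected and the conflict logged: with a consistent CI
    oracle this cannot happen, and under sampling noise an undirected edge
    is the conservative representation.
    """
    g = skeleton.copy()
    claims: dict[tuple[str, str], int] = {}
    for z in g.nodes:
        for x, y in combinations(sorted(g.neighbors(z)), 2):
            if g.adjacent(x, y):
                continue
            sep = sepsets.get(x, y)
            if sep is not None and z not in sep:
                claims[(x, z)] = claims.get((x, z), 0) + 1
                claims[(y, z)] = claims.get((y, z), 0) + 1
    for (a, b) in sorted(claims):
        if (b, a) in claims:
            if a < b:
                logger.warning(
                    "conflicting v-structure orientations on %s-%s; "
                    "leaving undirected", a, b)
            continue
        g.orient(a, b)
    return g
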