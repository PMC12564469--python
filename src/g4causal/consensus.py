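"""Bootstrap consensus networks and robustness measurement.

One *trial* draws several stratified sample sets, learns a candidate
network from each, and condenses them into an *average model*: the graph of
adjacencies supported by at least N of the candidates, each adjacency
oriented by the majority of the candidates that contain it.  Repeating the
trial many times yields (a) robustness statistics — each candidate's
*accuracy* (fraction of its edges present in the consensus) and the
consensus's *coverage* (average fraction of consensus edges a candidate
recovers), summarized across the N grid by an area under the
coverage-vs-accuracy curve — and (b) the *common network*: the adjacencies
shared by every trial's average model, annotated with empirical direction
frequencies that a final resolution step collapses to majority directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .citest import CITestConfig
from .graphs import PDAG
from .pc import pc_stable
from .prep import SamplingConfig, stratified_sample

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# consensus constructions
# ---------------------------------------------------------------------------

def average_model(candidates: Sequence[PDAG], n_agree: int) -> PDAG:
    """Consensus of candidate networks: adjacencies agreed by >= n_agree.

    Each retained adjacency is oriented by majority among the candidates
    containing it: a direction is adopted only when held by a strict
    majority of those candidates (an undirected occurrence supports
    neither direction but still counts in the denominator); otherwise the
    edge stays undirected.  This keeps one noisily oriented candidate from
    out-voting many undirected ones.
    """
    if not candidates:
        raise ValueError("no candidate networks")
    if not 1 <= n_agree <= len(candidates):
        raise ValueError("n_agree must be in [1, number of candidates]")
    nodes = candidates[0].nodes
    support: dict[frozenset, int] = {}
    direction: dict[tuple, int] = {}
    for g in candidates:
        for pair in g.skeleton_edges():
            support[pair] = support.get(pair, 0) + 1
        for a, b in g.directed_edges:
            direction[(a, b)] = direction.get((a, b), 0) + 1
    out = PDAG(nodes)
    for pair, cnt in support.items():
        if cnt < n_agree:
            continue
        a, b = sorted(pair)
        fwd, rev = direction.get((a, b), 0), direction.get((b, a), 0)
        if 2 * fwd > cnt:
            out.add_directed(a, b)
        elif 2 * rev > cnt:
            out.add_directed(b, a)
        else:
            out.add_undirected(a, b)
    if not out.directed_part_acyclic():
        # majority orientations of independently learned candidates can
        # disagree into a cycle; fall back to the conservative representation
        logger.warning("average model majority orientations form a cycle; "
                       "reverting cycle edges to undirected")
        _break_cycles(out)
    return out


def _break_cycles(g: PDAG) -> None:
    while not g.directed_part_acyclic():
        # undirect the lexicographically first edge on some cycle
        for a, b in sorted(g.directed_edges):
            if b in g.ancestors([a]):  # b has a directed path back to a
                g.add_undirected(a, b)
                break


def accuracy_coverage(candidates: Sequence[PDAG], consensus: PDAG,
                      directed_match: bool = False,
                      ) -> tuple[float, float]:
    """Mean accuracy and coverage of candidates against a consensus network.

    Per candidate c: accuracy = |E_c ∩ E_cons| / |E_c| (1 if c has no
    edges); coverage = |E_c ∩ E_cons| / |E_cons| (1 if the consensus is
    empty); both averaged over candidates.  Edges are compared as
    adjacencies by default; ``directed_match`` compares (direction-aware)
    edge identity, treating an undirected edge as matching only undirected.
    """
    if not candidates:
        raise ValueError("no candidate networks")

    def edge_set(g: PDAG):
        if directed_match:
            return frozenset(g.directed_edges) | frozenset(g.undirected_edges)
        return g.skeleton_edges()

    cons = edge_set(consensus)
    accs, covs = [], []
    for c in candidates:
        ec = edge_set(c)
        inter = len(ec & cons)
        accs.append(inter / len(ec) if ec else 1.0)
        covs.append(inter / len(cons) if cons else 1.0)
    return float(np.mean(accs)), float(np.mean(covs))


def robustness_auc(points: Sequence[tuple[float, float]]) -> float:
    """Area under the coverage-vs-accuracy curve, normalized to [0, 1].

    Points (accuracy, coverage) are sorted by accuracy; the trapezoidal
    integral of coverage over accuracy is divided by the spanned accuracy
    range, so a constant coverage of 1 scores 1 regardless of span.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    pts = sorted((float(a), float(c)) for a, c in points)
    acc = np.array([p[0] for p in pts])
    cov = np.array([p[1] for p in pts])
    span = acc[-1] - acc[0]
    if span <= 0:
        raise ValueError("degenerate curve: all points at one accuracy")
    return float(np.trapezoid(cov, acc) / span)


@dataclass
class ConsensusNetwork:
    """A consensus PDAG with per-adjacency empirical direction frequencies.

    ``direction_freq[(a, b)]`` is the fraction of contributing models that
    orient the a-b adjacency as a->b; models leaving it undirected split
    their weight evenly, so an adjacency undirected everywhere carries 0.5.
    """

    graph: PDAG
    direction_freq: dict[tuple, float] = field(default_factory=dict)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        for pair in sorted(self.graph.skeleton_edges(), key=lambda p: sorted(p)):
            a, b = sorted(pair)
            rows.append((a, b, self.direction_freq.get((a, b), 0.5)))
        return pd.DataFrame(rows, columns=["source", "target",
                                           "direction_frequency"])


def common_network(models: Sequence[PDAG]) -> ConsensusNetwork:
    """Adjacencies shared by *all* models, with direction frequencies.

    The skeleton is the intersection of every model's skeleton; each
    retained adjacency's a->b frequency is the fraction of models directing
    it a->b plus half the fraction leaving it undirected.
    """
    if not models:
        raise ValueError("no models")
    skeleton = set(models[0].skeleton_edges())
    for g in models[1:]:
        skeleton &= g.skeleton_edges()
    net = ConsensusNetwork(PDAG(models[0].nodes))
    m = len(models)
    for pair in skeleton:
        a, b = sorted(pair)
        fwd = sum(1.0 if g.has_directed(a, b) else
                  0.5 if g.has_undirected(a, b) else 0.0 for g in models)
        freq = fwd / m
        net.direction_freq[(a, b)] = freq
        if freq > 0.5:
            net.graph.add_directed(a, b)
        elif freq < 0.5:
            net.graph.add_directed(b, a)
        else:
            net.graph.add_undirected(a, b)
    return net


def resolve_directions(net: ConsensusNetwork,
                       protected_sinkless_nodes: Iterable[str] = ("Stability",),
                       ) -> PDAG:
    """Collapse direction frequencies to a final partially directed graph.

    Each adjacency keeps its majority direction; an exact 50/50 split stays
    undirected.  Any edge that would point *into* a protected node (by
    default the G4 stability node, a sequence-intrinsic property that
    nothing in the system can causally set) is conservatively undirected.
    """
    protected = set(protected_sinkless_nodes)
    out = PDAG(net.graph.nodes)
    for pair in net.graph.skeleton_edges():
        a, b = sorted(pair)
        freq = net.direction_freq.get((a, b), 0.5)
        if freq > 0.5:
            head, tail = b, a
        elif freq < 0.5:
            head, tail = a, b
        else:
            out.add_undirected(a, b)
            continue
        if head in protected:
            out.add_undirected(a, b)
        else:
            out.add_directed(tail, head)
    if not out.directed_part_acyclic():
        logger.warning("resolved directions form a cycle; undirecting")
        _break_cycles(out)
    return out


def select_n(points_by_n: Mapping[int, tuple[float, float]]) -> int:
    """Pick the consensus threshold N closest to the upper-right corner.

    Given per-N (accuracy, coverage), returns the N minimizing Euclidean
    distance to (1, 1); ties go to the smaller N.
    """
    if not points_by_n:
        raise ValueError("no points")
    return min(points_by_n,
               key=lambda n: ((1 - points_by_n[n][0]) ** 2
                              + (1 - points_by_n[n][1]) ** 2, n))


# ---------------------------------------------------------------------------
# the bootstrap trial loop
# ---------------------------------------------------------------------------

@dataclass
class RobustnessRecord:
    """Long-format robustness summary across trials.

    One row per (strategy, k, N): mean and standard deviation of accuracy
    and coverage over trials, plus the per-(strategy, k) AUC across the N
    grid (repeated on each of its rows).
    """

    frame: pd.DataFrame

    def auc(self, strategy: str, k: float) -> float:
        sel = self.frame[(self.frame.strategy == strategy)
                         & (self.frame.k == k)]
        if sel.empty:
            raise KeyError((strategy, k))
        return float(sel.auc.iloc[0])


def run_trials(table: pd.DataFrame, sampling: SamplingConfig,
               ci_config: CITestConfig | None = None,
               n_sample_sets: int = 10, n_trials: int = 50,
               n_grid: Sequence[int] | None = None,
               master_seed: int = 0,
               directed_match: bool = False,
               ) -> tuple[RobustnessRecord, dict[int, list[PDAG]]]:
    """Run the full bootstrap: trials x sample sets x structure learning.

    Each trial draws ``n_sample_sets`` stratified samples (seeds derived
    from ``master_seed`` via a spawned SeedSequence, one per (trial, set)),
    learns one candidate network per sample, and builds the average model
    for every N in ``n_grid``.  Accuracy/coverage are scored against the
    same trial's average model at the evaluated N.

    Returns the robustness record and, per N, the list of per-trial average
    models (the input to :func:`common_network`).
    """
    ci_config = ci_config or CITestConfig()
    if n_grid is None:
        n_grid = list(range(1, n_sample_sets + 1))
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(n_trials * n_sample_sets * 2).reshape(
        n_trials, n_sample_sets, 2) % (2 ** 31)

    rows = []
    models_by_n: dict[int, list[PDAG]] = {n: [] for n in n_grid}
    for t in range(n_trials):
        candidates = []
        for j in range(n_sample_sets):
            samp_cfg = SamplingConfig(strategy=sampling.strategy,
                                      k=sampling.k,
                                      seed=int(seeds[t, j, 0]),
                                      replace=sampling.replace)
            sample = stratified_sample(table, samp_cfg)
            cfg = CITestConfig(alpha=ci_config.alpha,
                               n_permutations=ci_config.n_permutations,
                               seed=int(seeds[t, j, 1]))
            g, _ = pc_stable(sample, config=cfg)
            candidates.append(g)
        for n in n_grid:
            avg = average_model(candidates, n)
            models_by_n[n].append(avg)
            acc, cov = accuracy_coverage(candidates, avg,
                                         directed_match=directed_match)
            rows.append((sampling.strategy, sampling.k, n, t, acc, cov))
        logger.info("trial %d/%d done", t + 1, n_trials)

    per_trial = pd.DataFrame(
        rows, columns=["strategy", "k", "N", "trial", "accuracy", "coverage"])
    agg = (per_trial.groupby(["strategy", "k", "N"], as_index=False)
           .agg(acc_mean=("accuracy", "mean"), acc_sd=("accuracy", "std"),
                cov_mean=("coverage", "mean"), cov_sd=("coverage", "std")))
    agg[["acc_sd", "cov_sd"]] = agg[["acc_sd", "cov_sd"]].fillna(0.0)
    try:
        auc = robustness_auc(list(zip(agg.acc_mean, agg.cov_mean)))
    except ValueError:
        auc = float("nan")
    agg["auc"] = auc
    return RobustnessRecord(agg), models_by_n


def plot_robustness(record: RobustnessRecord, path=None):
    """Coverage-vs-accuracy curve with sd bars, one line per (strategy, k)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for (strat, k), grp in record.frame.groupby(["strategy", "k"]):
        grp = grp.sort_values("N")
        ax.errorbar(grp.acc_mean, grp.cov_mean, xerr=grp.acc_sd,
                    yerr=grp.cov_sd, marker="o", capsize=2,
                    label=f"{strat} k={k:g} (AUC={grp.auc.iloc[0]:.3f})")
    ax.set_xlabel("accuracy")
    ax.set_ylabel("coverage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
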