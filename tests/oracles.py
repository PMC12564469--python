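"""Independent brute-force oracles used by the test suite.

Every oracle here recomputes a quantity by the most literal method
available — per-base scans, all-pairs loops, exhaustive path enumeration,
equivalence-class enumeration — deliberately sharing no code with the
implementations it checks.
"""

from itertools import combinations, product

import numpy as np
import pandas as pd

from g4causal.graphs import PDAG


# ---------------------------------------------------------------------------
# d-separation via exhaustive path enumeration
# ---------------------------------------------------------------------------

def dsep_by_paths(dag: PDAG, a: str, b: str, s) -> bool:
    """Enumerate every simple path between a and b in the skeleton and test
    the blocking rule node by node."""
    s = set(s)
    adj = {v: set() for v in dag.nodes}
    for x, y in dag.directed_edges:
        adj[x].add(y)
        adj[y].add(x)

    descendants = {}
    for v in dag.nodes:
        seen, stack = set(), [v]
        while stack:
            u = stack.pop()
            for w in dag.children(u):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        descendants[v] = seen

    def blocked(path):
        for i in range(1, len(path) - 1):
            prev, z, nxt = path[i - 1], path[i], path[i + 1]
            into_z_left = dag.has_directed(prev, z)
            into_z_right = dag.has_directed(nxt, z)
            if into_z_left and into_z_right:  # collider
                if z not in s and not (descendants[z] & s):
                    continue_open = False
                else:
                    continue_open = True
            else:  # chain or fork
                continue_open = z not in s
            if not continue_open:
                return True
        return False

    def paths(frm, to, seen):
        if frm == to:
            yield [to]
            return
        for nxt in adj[frm]:
            if nxt not in seen:
                for rest in paths(nxt, to, seen | {nxt}):
                    yield [frm] + rest

    return all(blocked(p) for p in paths(a, b, {a}))


# ---------------------------------------------------------------------------
# CPDAG by brute-force enumeration of the Markov equivalence class
# ---------------------------------------------------------------------------

def cpdag_by_enumeration(dag: PDAG) -> PDAG:
    """Union of all orientations over DAGs with the same skeleton and
    v-structures: an edge is undirected iff both directions occur."""
    from g4causal.graphs import v_structures

    skel = sorted(tuple(sorted(p)) for p in dag.skeleton_edges())
    target_v = v_structures(dag)
    seen_dirs: set = set()
    for choice in product([0, 1], repeat=len(skel)):
        edges = [(a, b) if c == 0 else (b, a)
                 for (a, b), c in zip(skel, choice)]
        cand = PDAG(dag.nodes, directed=edges)
        if not cand.directed_part_acyclic():
            continue
        if v_structures(cand) != target_v:
            continue
        seen_dirs |= set(edges)
    out = PDAG(dag.nodes)
    for a, b in skel:
        fwd, rev = (a, b) in seen_dirs, (b, a) in seen_dirs
        if fwd and rev:
            out.add_undirected(a, b)
        elif fwd:
            out.add_directed(a, b)
        else:
            out.add_directed(b, a)
    return out


# ---------------------------------------------------------------------------
# per-base / all-pairs genomic oracles
# ---------------------------------------------------------------------------

def per_base_values(track: pd.DataFrame, chrom: str, strand=None):
    """Position -> value map by literally painting every segment."""
    out = {}
    for row in track.itertuples():
        if row.chrom != chrom:
            continue
        if strand is not None and row.strand != strand:
            continue
        for pos in range(row.start, row.end):
            out[pos] = row.value
    return out


def paint_stranded(track):
    """(chrom, strand) -> per-base value map, painted once per track."""
    out = {}
    for chrom in track.chrom.unique():
        for strand in ("+", "-"):
            out[(chrom, strand)] = per_base_values(track, chrom, strand)
    return out


def paint_unstranded(track):
    return {chrom: per_base_values(track, chrom)
            for chrom in track.chrom.unique()}


def oracle_stability(pg4, mm_track, painted=None):
    mid = (pg4.start + pg4.end) // 2
    if painted is None:
        vals = per_base_values(mm_track, pg4.chrom, pg4.strand)
    else:
        vals = painted.get((pg4.chrom, pg4.strand), {})
    window = [vals[p] for p in range(mid - 75, mid + 75) if p in vals]
    return max(window) if window else np.nan


def oracle_phylop(pg4, phylop_track, painted=None):
    mid = (pg4.start + pg4.end) // 2
    if painted is None:
        vals = per_base_values(phylop_track, pg4.chrom)
    else:
        vals = painted.get(pg4.chrom, {})
    window = [vals[p] for p in range(mid - 25, mid + 25) if p in vals]
    return float(np.mean(window)) if window else np.nan


def paint_coverage(fragments):
    """chrom -> per-base fragment count, painted once."""
    out = {}
    for f in fragments.itertuples():
        chrom = out.setdefault(f.chrom, {})
        for pos in range(f.start, f.end):
            chrom[pos] = chrom.get(pos, 0) + 1
    return out


def oracle_atac_painted(region, coverage, mean_depth):
    vals = coverage.get(region.chrom, {})
    total = sum(vals.get(p, 0) for p in range(region.start, region.end))
    return total / (region.end - region.start) / mean_depth


def oracle_overlap_filter(regions, pg4s):
    keep = []
    for r in regions.itertuples():
        hit = any(p.chrom == r.chrom and p.start < r.end and r.start < p.end
                  for p in pg4s.itertuples())
        keep.append(hit)
    return regions.loc[keep]


def oracle_region_assign(region, pg4s, values):
    mid = (region.start + region.end) // 2
    best_key, best_val = None, np.nan
    for p, v in zip(pg4s.itertuples(), values):
        if p.chrom != region.chrom or p.end <= region.start \
                or region.end <= p.start or pd.isna(v):
            continue
        pmid = (p.start + p.end) // 2
        key = (abs(pmid - mid), p.start, 0 if p.strand == "+" else 1)
        if best_key is None or key < best_key:
            best_key, best_val = key, float(v)
    return best_val


def oracle_chrom_state(region, segmentation):
    mid = (region.start + region.end) // 2
    for seg in segmentation.itertuples():
        if seg.chrom == region.chrom and seg.start <= mid < seg.end:
            return str(seg.state)
    return np.nan


def oracle_atac(region, fragments, mean_depth):
    per_pos = 0
    for pos in range(region.start, region.end):
        for f in fragments.itertuples():
            if f.chrom == region.chrom and f.start <= pos < f.end:
                per_pos += 1
    return per_pos / (region.end - region.start) / mean_depth


def oracle_tf_metrics(region, tf_peaks, recruitment="total"):
    occ = {}
    for p in tf_peaks.itertuples():
        if p.chrom == region.chrom and p.start < region.end \
                and region.start < p.end:
            occ[p.tf] = occ.get(p.tf, 0) + 1
    rec = sum(occ.values()) if recruitment == "total" else len(occ)
    return occ, rec


# ---------------------------------------------------------------------------
# misc numeric oracles
# ---------------------------------------------------------------------------

def riemann_auc(points, n_grid=200001):
    """Fine-grid Riemann integral of the piecewise-linear coverage curve,
    normalized by the spanned accuracy range."""
    pts = sorted(points)
    acc = np.array([p[0] for p in pts])
    cov = np.array([p[1] for p in pts])
    grid = np.linspace(acc[0], acc[-1], n_grid)
    vals = np.interp(grid, acc, cov)
    return float(np.mean(vals))


def rank_then_pearson(x, y):
    """Spearman rho by definition: mid-ranks then Pearson correlation."""
    def midrank(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midrank(np.asarray(x, float)), midrank(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
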