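"""Synthetic data with a known ground truth.

Two generators live here:

* :func:`simulate_observations` draws discretized region-by-metric tables
  by ancestral sampling from a user-specified DAG with categorical
  conditional probability tables (:class:`GroundTruthSpec`), in named
  strata standing in for cell lines.  The shipped default topology,
  :func:`default_spec`, is the six-node stability network
  (Stability -> {ChromState, nTFs, eG4s}, phyloP -> {ChromState, nTFs},
  ATACSig -> {ChromState, nTFs}, ChromState -> nTFs), so every stage of the
  learning pipeline can be scored against a recoverable answer.

* :func:`make_genome_fixture` builds a toy genome — eG4 regions, pG4 loci,
  strand-specific MM% and phyloP tracks, a chromatin-state segmentation,
  ATAC fragments, TF peaks and TSSs — exercising every signal-mapping rule,
  including pG4-free decoy regions for the containment filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .graphs import CycleError, dag_from_edges

#: the three cell lines whose eG4 region counts set the default stratum sizes
DEFAULT_STRATUM_SIZES: dict[str, int] = {
    "K562": 7639, "HepG2": 21996, "HEK293T": 8986}

BINARY = ("High", "Low")

#: Roadmap-style 18-state chromatin vocabulary
STATE_VOCAB_18 = (
    "TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk", "ZNF/Rpts", "Het",
    "TssBiv", "EnhBiv", "ReprPC", "ReprPCWk", "Quies")

#: collapsed 8-level "state group" vocabulary used by the default simulator
#: (full 18 levels make child CPT strata too sparse to be informative)
STATE_GROUPS_8 = ("Quies", "ReprPC", "Het", "Biv", "Tx", "Enh",
                  "TssFlnk", "TssA")


# ---------------------------------------------------------------------------
# ground-truth DAG + CPTs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthSpec:
    """A DAG with categorical CPTs driving the observational simulator.

    nodes / edges
        Variable names and directed (parent, child) pairs; must be acyclic.
    levels
        Category labels per node, in CPT column order.
    cpts
        Per node: an array of shape ``(*parent level counts, n_levels)``
        whose trailing axis sums to one; parent axes follow
        ``parent_order[node]``, the node's parents sorted by name.
    strata
        Stratum names (cell-line stand-ins).
    root_overrides
        Optional per-stratum replacement distributions for root nodes,
        ``{stratum: {node: probability vector}}``.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    levels: Mapping[str, tuple[str, ...]]
    cpts: Mapping[str, np.ndarray]
    strata: tuple[str, ...] = tuple(DEFAULT_STRATUM_SIZES)
    root_overrides: Mapping[str, Mapping[str, Sequence[float]]] = \
        field(default_factory=dict)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == node))

    def validate(self) -> None:
        graph = dag_from_edges(self.nodes, self.edges)  # raises on cycle
        del graph
        for node in self.nodes:
            parents = self.parents(node)
            cpt = np.asarray(self.cpts[node], dtype=float)
            want = tuple(len(self.levels[p]) for p in parents) + (
                len(self.levels[node]),)
            if cpt.shape != want:
                raise ValueError(
                    f"CPT for {node!r} has shape {cpt.shape}, expected "
                    f"{want} from parents {parents}")
            sums = cpt.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {node!r} do not sum to 1")
            if (cpt < 0).any():
                raise ValueError(f"CPT for {node!r} has negative entries")
        for stratum, over in self.root_overrides.items():
            if stratum not in self.strata:
                raise ValueError(f"override for unknown stratum {stratum!r}")
            for node, vec in over.items():
                if self.parents(node):
                    raise ValueError(
                        f"override target {node!r} is not a root node")
                v = np.asarray(vec, dtype=float)
                if v.shape != (len(self.levels[node]),) or \
                        not np.isclose(v.sum(), 1.0, atol=1e-9):
                    raise ValueError(f"bad override vector for {node!r}")

    def topological_order(self) -> list[str]:
        return dag_from_edges(self.nodes, self.edges).topological_order()

    def marginals(self) -> dict[str, np.ndarray]:
        """Exact marginal distribution of every node, by enumeration.

        Sums the joint probability over all level configurations; meant as
        an oracle at the shipped problem size (feasible up to ~10 nodes).
        Ignores stratum overrides (i.e. the base CPTs).
        """
        order = self.topological_order()
        sizes = [len(self.levels[n]) for n in order]
        idx = {n: i for i, n in enumerate(order)}
        out = {n: np.zeros(len(self.levels[n])) for n in order}
        for combo in product(*(range(s) for s in sizes)):
            p = 1.0
            for n in order:
                parents = self.parents(n)
                key = tuple(combo[idx[q]] for q in parents)
                p *= float(np.asarray(self.cpts[n])[key + (combo[idx[n]],)])
            for n in order:
                out[n][combo[idx[n]]] += p
        return out

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "nodes": {n: list(self.levels[n]) for n in self.nodes},
            "edges": [list(e) for e in self.edges],
            "cpts": {n: np.asarray(self.cpts[n]).tolist()
                     for n in self.nodes},
            "strata": list(self.strata),
            "root_overrides": {s: {n: list(map(float, v))
                                   for n, v in over.items()}
                               for s, over in self.root_overrides.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GroundTruthSpec":
        doc = yaml.safe_load(text)
        nodes = tuple(doc["nodes"])
        spec = cls(
            nodes=nodes,
            edges=tuple((a, b) for a, b in doc["edges"]),
            levels={n: tuple(doc["nodes"][n]) for n in nodes},
            cpts={n: np.asarray(doc["cpts"][n], dtype=float) for n in nodes},
            strata=tuple(doc.get("strata", list(DEFAULT_STRATUM_SIZES))),
            root_overrides=doc.get("root_overrides", {}),
        )
        spec.validate()
        return spec


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def default_spec(effect_strength: float = 2.0,
                 state_tilt: float = 2.0,
                 n_state_levels: int = 8) -> GroundTruthSpec:
    """The shipped six-node stability network with detectable effects.

    Roots (Stability, phyloP, ATACSig) are Bernoulli(0.5).  Each binary
    child's probability of High is logistic in a centered parent score
    (+1/2 per High binary parent, -1/2 per Low; the chromatin-state parent
    contributes its level's rank scaled to [-1/2, 1/2]) times
    ``effect_strength``.  ChromState is a categorical over
    ``n_state_levels`` collapsed state groups whose mass tilts
    geometrically (``state_tilt``) toward active groups as more parents are
    High.  Defaults were chosen so that every edge is comfortably
    detectable at the shipped sample sizes (thousands of rows per stratum).
    """
    if n_state_levels == 8:
        state_levels = STATE_GROUPS_8
    else:
        state_levels = tuple(f"S{i + 1}" for i in range(n_state_levels))
    nodes = ("Stability", "phyloP", "ATACSig", "ChromState", "eG4s", "nTFs")
    edges = (("Stability", "ChromState"), ("Stability", "nTFs"),
             ("Stability", "eG4s"), ("phyloP", "ChromState"),
             ("phyloP", "nTFs"), ("ATACSig", "ChromState"),
             ("ATACSig", "nTFs"), ("ChromState", "nTFs"))
    levels = {n: BINARY for n in nodes}
    levels["ChromState"] = state_levels

    root = np.array([0.5, 0.5])

    def binary_child_cpt(parents: Sequence[str]) -> np.ndarray:
        shape = tuple(len(levels[p]) for p in parents)
        cpt = np.zeros(shape + (2,))
        for key in np.ndindex(*shape):
            score = 0.0
            for p, k in zip(parents, key):
                if levels[p] == BINARY:
                    # level order is ("High", "Low")
                    score += 0.5 if k == 0 else -0.5
                else:
                    L = len(levels[p])
                    score += k / (L - 1) - 0.5
            p_high = _sigmoid(effect_strength * score)
            cpt[key] = (p_high, 1.0 - p_high)
        return cpt

    def state_cpt(parents: Sequence[str]) -> np.ndarray:
        shape = tuple(len(levels[p]) for p in parents)
        L = len(state_levels)
        scores = np.arange(L) / (L - 1) - 0.5  # activity rank in [-1/2, 1/2]
        cpt = np.zeros(shape + (L,))
        for key in np.ndindex(*shape):
            n_high = sum(1 for k in key if k == 0)
            w = np.exp(state_tilt * (n_high - len(parents) / 2) * scores)
            cpt[key] = w / w.sum()
        return cpt

    cpts = {
        "Stability": root.copy(), "phyloP": root.copy(),
        "ATACSig": root.copy(),
        "ChromState": state_cpt(("ATACSig", "Stability", "phyloP")),
        "eG4s": binary_child_cpt(("Stability",)),
        "nTFs": binary_child_cpt(("ATACSig", "ChromState", "Stability",
                                  "phyloP")),
    }
    spec = GroundTruthSpec(nodes=nodes, edges=edges, levels=levels, cpts=cpts)
    spec.validate()
    return spec


def simulate_observations(spec: GroundTruthSpec,
                          n_per_stratum: int | Mapping[str, int],
                          seed: int) -> pd.DataFrame:
    """Ancestral sampling of a discrete observational table.

    Draws ``n_per_stratum`` rows (an int, or a per-stratum mapping) for
    each stratum in topological node order, indexing each node's CPT by its
    sampled parent levels; root nodes honour per-stratum overrides.  The
    same seed always reproduces the identical table.
    """
    spec.validate()
    if isinstance(n_per_stratum, int):
        if n_per_stratum < 0:
            raise ValueError("n_per_stratum must be >= 0")
        sizes = {s: n_per_stratum for s in spec.strata}
    else:
        sizes = {s: int(n_per_stratum[s]) for s in spec.strata}
        if any(v < 0 for v in sizes.values()):
            raise ValueError("n_per_stratum must be >= 0")
    rng = np.random.default_rng(seed)
    order = spec.topological_order()
    frames = []
    for stratum in spec.strata:
        n = sizes[stratum]
        codes: dict[str, np.ndarray] = {}
        for node in order:
            parents = spec.parents(node)
            cpt = np.asarray(spec.cpts[node], dtype=float)
            if not parents:
                vec = np.asarray(
                    spec.root_overrides.get(stratum, {}).get(node, cpt),
                    dtype=float)
                probs = np.broadcast_to(vec, (n, len(vec)))
            else:
                key = tuple(codes[p] for p in parents)
                probs = cpt[key]
            u = rng.random(n)
            codes[node] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        frame = pd.DataFrame({
            node: pd.Categorical.from_codes(
                codes[node].astype(int), categories=list(spec.levels[node]))
            .astype(str)
            for node in spec.nodes})
        frame["stratum"] = stratum
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=[*spec.nodes, "stratum"])
    return pd.concat(frames, ignore_index=True)


def default_dataset(seed: int,
                    sizes: Mapping[str, int] | int | None = None,
                    spec: GroundTruthSpec | None = None) -> pd.DataFrame:
    """Convenience: the shipped network sampled at the study's stratum sizes."""
    spec = spec or default_spec()
    if sizes is None:
        sizes = DEFAULT_STRATUM_SIZES
    return simulate_observations(spec, sizes, seed)


# ---------------------------------------------------------------------------
# toy genome fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    """Size/shape knobs for the toy genome (all coordinates in bp)."""

    n_chroms: int = 2
    chrom_len: int = 12000
    n_regions: int = 8              # eG4 regions guaranteed to contain a pG4
    n_decoys: int = 2               # regions containing no pG4 at all
    region_len: tuple[int, int] = (150, 400)
    pg4_per_region: tuple[int, int] = (1, 2)
    pg4_len: tuple[int, int] = (20, 40)
    n_extra_pg4: int = 6            # pG4s outside any region
    mm_segment_len: tuple[int, int] = (10, 60)
    mm_gap_len: tuple[int, int] = (0, 80)
    phylop_segment_len: tuple[int, int] = (20, 120)
    phylop_gap_len: tuple[int, int] = (0, 60)
    seg_len: tuple[int, int] = (300, 1500)
    n_atac_fragments: int = 80
    fragment_len: tuple[int, int] = (80, 200)
    tf_names: tuple[str, ...] = ("SP1", "SP2", "YY1", "TARDBP", "CTCF",
                                 "FOXA1")
    peaks_per_tf: int = 6
    peak_len: tuple[int, int] = (60, 200)
    n_tss: int = 10
    stratum: str = "K562"


@dataclass
class GenomeFixture:
    """All tracks of the toy genome, 0-based half-open coordinates."""

    chrom_sizes: dict[str, int]
    pg4s: pd.DataFrame          # chrom start end strand
    mm_track: pd.DataFrame      # chrom start end strand value (MM%, [0,100])
    phylop_track: pd.DataFrame  # chrom start end value
    segmentation: pd.DataFrame  # chrom start end state
    atac_fragments: pd.DataFrame  # chrom start end
    tf_peaks: pd.DataFrame      # chrom start end tf
    regions: pd.DataFrame       # region_id chrom start end eg4_signal stratum
    tss: pd.DataFrame           # chrom pos gene_id strand

    def validate(self) -> None:
        for name, df in [("pg4s", self.pg4s), ("mm_track", self.mm_track),
                         ("phylop_track", self.phylop_track),
                         ("segmentation", self.segmentation),
                         ("atac_fragments", self.atac_fragments),
                         ("tf_peaks", self.tf_peaks),
                         ("regions", self.regions)]:
            if len(df) == 0:
                continue
            if not (df.start < df.end).all():
                raise ValueError(f"{name}: empty or inverted interval")
            for chrom, grp in df.groupby("chrom"):
                size = self.chrom_sizes[chrom]
                if (grp.start < 0).any() or (grp.end > size).any():
                    raise ValueError(f"{name}: interval outside {chrom}")
        if len(self.mm_track) and not self.mm_track.value.between(0, 100).all():
            raise ValueError("MM% outside [0, 100]")
        for key, df in [(("chrom", "strand"), self.mm_track),
                        (("chrom",), self.phylop_track),
                        (("chrom",), self.segmentation)]:
            for _, grp in df.groupby(list(key)):
                g = grp.sort_values("start")
                if (g.start.to_numpy()[1:] < g.end.to_numpy()[:-1]).any():
                    raise ValueError("overlapping track segments")
        if len(self.tss):
            for chrom, grp in self.tss.groupby("chrom"):
                if (grp.pos < 0).any() or \
                        (grp.pos >= self.chrom_sizes[chrom]).any():
                    raise ValueError("TSS outside chromosome")


def _rand_len(rng, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def make_genome_fixture(seed: int,
                        config: FixtureConfig | None = None) -> GenomeFixture:
    """Generate a toy genome fixture (deterministic for a given seed).

    Regions are laid out on an evenly spaced grid per chromosome so that
    true regions, decoys and planted pG4s never collide; random pG4s, MM%
    and phyloP segments, a full-cover chromatin segmentation, ATAC
    fragments, TF peaks and TSSs fill in around them.
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: cfg.chrom_len for c in chroms}

    n_slots_total = cfg.n_regions + cfg.n_decoys
    per_chrom = int(np.ceil(n_slots_total / cfg.n_chroms))
    slot = cfg.chrom_len // max(per_chrom, 1)
    if slot <= cfg.region_len[1] + 2 * 80:
        raise ValueError("chromosomes too small for the requested regions")

    regions, decoy_flags, pg4_rows = [], [], []
    slot_of = []  # (chrom, slot_start, slot_end) per region, for decoy checks
    idx = 0
    for kind in ["real"] * cfg.n_regions + ["decoy"] * cfg.n_decoys:
        chrom = chroms[idx % cfg.n_chroms]
        s_idx = idx // cfg.n_chroms
        lo, hi = s_idx * slot, (s_idx + 1) * slot
        length = _rand_len(rng, cfg.region_len)
        start = int(rng.integers(lo + 80, hi - length - 80))
        regions.append((chrom, start, start + length))
        decoy_flags.append(kind == "decoy")
        slot_of.append((chrom, lo, hi))
        if kind == "real":
            for _ in range(_rand_len(rng, cfg.pg4_per_region)):
                plen = min(_rand_len(rng, cfg.pg4_len), length)
                pstart = int(rng.integers(start, start + length - plen + 1))
                strand = rng.choice(["+", "-"])
                pg4_rows.append((chrom, pstart, pstart + plen, strand))
        idx += 1

    decoy_iv = [(c, s, e) for (c, s, e), d in zip(regions, decoy_flags) if d]

    def hits_decoy(chrom, s, e):
        return any(c == chrom and s < de and ds < e for c, ds, de in decoy_iv)

    for _ in range(cfg.n_extra_pg4):
        for _try in range(50):
            chrom = chroms[int(rng.integers(cfg.n_chroms))]
            plen = _rand_len(rng, cfg.pg4_len)
            pstart = int(rng.integers(0, cfg.chrom_len - plen))
            if not hits_decoy(chrom, pstart, pstart + plen):
                pg4_rows.append((chrom, pstart, pstart + plen,
                                 rng.choice(["+", "-"])))
                break

    pg4s = pd.DataFrame(pg4_rows, columns=["chrom", "start", "end", "strand"])

    def step_track(seg_len, gap_len, value_fn, stranded=False):
        rows = []
        strands = ["+", "-"] if stranded else [None]
        for chrom in chroms:
            for strand in strands:
                pos = int(rng.integers(0, gap_len[1] + 1))
                while pos < cfg.chrom_len:
                    length = _rand_len(rng, seg_len)
                    end = min(pos + length, cfg.chrom_len)
                    row = [chrom, pos, end]
                    if stranded:
                        row.append(strand)
                    row.append(value_fn())
                    rows.append(tuple(row))
                    pos = end + _rand_len(rng, gap_len)
        cols = ["chrom", "start", "end"] + (["strand"] if stranded else []) \
            + ["value"]
        return pd.DataFrame(rows, columns=cols)

    mm_track = step_track(cfg.mm_segment_len, cfg.mm_gap_len,
                          lambda: float(np.round(rng.uniform(0, 100), 2)),
                          stranded=True)
    phylop_track = step_track(cfg.phylop_segment_len, cfg.phylop_gap_len,
                              lambda: float(np.round(rng.normal(1.0, 2.0), 3)))

    seg_rows = []
    for chrom in chroms:
        pos = 0
        while pos < cfg.chrom_len:
            end = min(pos + _rand_len(rng, cfg.seg_len), cfg.chrom_len)
            seg_rows.append((chrom, pos, end,
                             str(rng.choice(STATE_VOCAB_18))))
            pos = end
    segmentation = pd.DataFrame(seg_rows,
                                columns=["chrom", "start", "end", "state"])

    frag_rows = []
    for _ in range(cfg.n_atac_fragments):
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        flen = _rand_len(rng, cfg.fragment_len)
        fstart = int(rng.integers(0, cfg.chrom_len - flen))
        frag_rows.append((chrom, fstart, fstart + flen))
    atac_fragments = pd.DataFrame(frag_rows,
                                  columns=["chrom", "start", "end"])

    peak_rows = []
    for tf in cfg.tf_names:
        for _ in range(cfg.peaks_per_tf):
            chrom = chroms[int(rng.integers(cfg.n_chroms))]
            plen = _rand_len(rng, cfg.peak_len)
            pstart = int(rng.integers(0, cfg.chrom_len - plen))
            peak_rows.append((chrom, pstart, pstart + plen, tf))
    tf_peaks = pd.DataFrame(peak_rows,
                            columns=["chrom", "start", "end", "tf"])

    region_df = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    region_df.insert(0, "region_id",
                     [f"eG4_{i:03d}" for i in range(len(region_df))])
    region_df["eg4_signal"] = np.round(rng.exponential(50.0,
                                                       len(region_df)), 3)
    region_df["stratum"] = cfg.stratum
    region_df["is_decoy"] = decoy_flags

    tss_rows = []
    for i in range(cfg.n_tss):
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        pos = int(rng.integers(0, cfg.chrom_len))
        tss_rows.append((chrom, pos, f"gene_{i:03d}",
                         str(rng.choice(["+", "-"]))))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "gene_id",
                                          "strand"])

    fx = GenomeFixture(chrom_sizes=chrom_sizes, pg4s=pg4s, mm_track=mm_track,
                       phylop_track=phylop_track, segmentation=segmentation,
                       atac_fragments=atac_fragments, tf_peaks=tf_peaks,
                       regions=region_df, tss=tss)
    fx.validate()
    return fx
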