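"""Attach stability, conservation, chromatin and TF signals to eG4 regions.

Coordinates are 0-based half-open throughout; the midpoint of [s, e) is
floor((s + e) / 2).  Mapping rules:

* regions are kept only if they overlap at least one predicted G4 motif
  (pG4) on either strand;
* a pG4's thermostability is the maximum same-strand MM% inside the 150 bp
  window centred on its midpoint, and its conservation the mean phyloP over
  the 50 bp window (strand-agnostic);
* per-pG4 values transfer to a region from the overlapping pG4 whose
  midpoint lies closest to the region midpoint;
* the chromatin state of a region is the label of the segment containing
  its midpoint;
* ATAC intensity is mean per-base fragment coverage over the region divided
  by the genome-wide mean sequencing depth;
* per-TF occupancy counts overlapping peaks of that TF, and recruitment
  totals the hits (or, in "distinct" mode, the number of TFs with a hit).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STABILITY_WINDOW = 150
PHYLOP_WINDOW = 50


def midpoint(start: int, end: int) -> int:
    """Midpoint of a 0-based half-open interval: floor((start + end) / 2)."""
    return (int(start) + int(end)) // 2


def _window(mid: int, width: int) -> tuple[int, int]:
    half = width // 2
    return mid - half, mid + half


class ValueTrack:
    """Interval-valued track with per-base window queries.

    Built from a bedGraph-like frame (chrom, start, end, value, optionally
    strand).  Segments must not overlap within one (chrom, strand) so that
    per-base values are well defined.
    """

    def __init__(self, frame: pd.DataFrame, stranded: bool = False):
        self.stranded = stranded
        self._trees: dict = {}
        keys = ["chrom", "strand"] if stranded else "chrom"
        if len(frame):
            for key, grp in frame.groupby(keys):
                key = tuple(key) if stranded else key
                tree = IntervalTree()
                for row in grp.itertuples():
                    tree[row.start:row.end] = float(row.value)
                self._trees[key] = tree

    def _overlaps(self, chrom: str, lo: int, hi: int, strand=None):
        key = (chrom, strand) if self.stranded else chrom
        tree = self._trees.get(key)
        if tree is None or hi <= lo:
            return []
        return [(max(iv.begin, lo), min(iv.end, hi), iv.data)
                for iv in tree.overlap(lo, hi)]

    def window_max(self, chrom: str, lo: int, hi: int,
                   strand=None) -> float:
        """Max per-base value over [lo, hi); NaN if nothing covered."""
        hits = self._overlaps(chrom, lo, hi, strand)
        return max((v for *_, v in hits), default=np.nan)

    def window_mean(self, chrom: str, lo: int, hi: int,
                    strand=None) -> float:
        """Coverage-weighted mean over covered bases of [lo, hi); NaN if none."""
        hits = self._overlaps(chrom, lo, hi, strand)
        if not hits:
            return np.nan
        weights = [(e - s) for s, e, _ in hits]
        return float(np.average([v for *_, v in hits], weights=weights))


def _interval_tree(frame: pd.DataFrame, payload: str | None = None) -> dict:
    trees: dict[str, IntervalTree] = {}
    for row in frame.itertuples():
        tree = trees.setdefault(row.chrom, IntervalTree())
        data = getattr(row, payload) if payload else row.Index
        tree[row.start:row.end] = data
    return trees


# ---------------------------------------------------------------------------
# per-operation mapping rules
# ---------------------------------------------------------------------------

def filter_regions_with_pg4(regions: pd.DataFrame,
                            pg4s: pd.DataFrame) -> pd.DataFrame:
    """Keep regions overlapping >= 1 pG4 locus (any strand, >= 1 bp).

    Order is preserved; empty inputs yield an empty result.
    """
    if len(regions) == 0 or len(pg4s) == 0:
        return regions.iloc[0:0].copy()
    trees = _interval_tree(pg4s)
    keep = [bool(trees.get(r.chrom) and trees[r.chrom].overlap(r.start, r.end))
            for r in regions.itertuples()]
    return regions.loc[keep].copy()


def stability_of_pg4(pg4, mm_track: ValueTrack) -> float:
    """Max same-strand MM% in the 150 bp window centred on the pG4 midpoint.

    ``pg4`` is any object with chrom/start/end/strand attributes.  NaN when
    no same-strand segment touches the window.
    """
    lo, hi = _window(midpoint(pg4.start, pg4.end), STABILITY_WINDOW)
    return mm_track.window_max(pg4.chrom, lo, hi, strand=pg4.strand)


def phylop_of_pg4(pg4, phylop_track: ValueTrack) -> float:
    """Mean phyloP over covered bases of the 50 bp window on the midpoint."""
    lo, hi = _window(midpoint(pg4.start, pg4.end), PHYLOP_WINDOW)
    return phylop_track.window_mean(pg4.chrom, lo, hi)


def assign_region_value(region, pg4s_with_values: pd.DataFrame,
                        value_column: str = "value") -> float:
    """Region value from the overlapping pG4 nearest the region midpoint.

    Candidates are pG4 rows (chrom/start/end/strand plus ``value_column``)
    overlapping the region and carrying a non-missing value.  Ties on
    midpoint distance break to the lower start coordinate, then '+' strand.
    Returns NaN when no candidate qualifies.
    """
    mid = midpoint(region.start, region.end)
    best = None
    for p in pg4s_with_values.itertuples():
        if p.chrom != region.chrom or p.end <= region.start \
                or region.end <= p.start:
            continue
        v = getattr(p, value_column)
        if pd.isna(v):
            continue
        key = (abs(midpoint(p.start, p.end) - mid), p.start,
               0 if p.strand == "+" else 1)
        if best is None or key < best[0]:
            best = (key, float(v))
    return np.nan if best is None else best[1]


def chrom_state_of_region(region, segmentation: pd.DataFrame) -> str | float:
    """Chromatin-state label of the segment containing the region midpoint.

    Half-open segments mean a midpoint at a boundary b of [a,b)[b,c) gets
    the right-hand label.  NaN when the midpoint is unsegmented; a
    segmentation with overlapping segments is rejected.
    """
    _check_disjoint(segmentation)
    mid = midpoint(region.start, region.end)
    hit = segmentation[(segmentation.chrom == region.chrom)
                       & (segmentation.start <= mid)
                       & (mid < segmentation.end)]
    if hit.empty:
        return np.nan
    return str(hit.state.iloc[0])


def _check_disjoint(segmentation: pd.DataFrame) -> None:
    for _, grp in segmentation.groupby("chrom"):
        g = grp.sort_values("start")
        if (g.start.to_numpy()[1:] < g.end.to_numpy()[:-1]).any():
            raise ValueError("segmentation contains overlapping segments")


def atac_intensity(region, fragments: pd.DataFrame,
                   mean_depth: float) -> float:
    """Depth-normalized mean fragment coverage over the region.

    (sum of per-base fragment coverage / region length) / mean_depth.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    length = region.end - region.start
    cover = 0
    for f in fragments.itertuples():
        if f.chrom != region.chrom:
            continue
        cover += max(0, min(f.end, region.end) - max(f.start, region.start))
    return cover / length / mean_depth


def mean_sequencing_depth(fragments: pd.DataFrame,
                          chrom_sizes: Mapping[str, int]) -> float:
    """Genome-wide mean per-base fragment coverage (the default denominator)."""
    genome = sum(chrom_sizes.values())
    if genome <= 0:
        raise ValueError("empty genome")
    total = int((fragments.end - fragments.start).sum()) if len(fragments) \
        else 0
    return total / genome


def tf_metrics(region, tf_peaks: pd.DataFrame,
               recruitment: str = "total") -> tuple[dict[str, int], int]:
    """Per-TF occupancy and the recruitment count of a region.

    occupancy[tf] = number of that TF's peaks overlapping the region.
    Recruitment is the total number of hits (default) or, in ``"distinct"``
    mode, the number of TFs with at least one hit.
    """
    if recruitment not in ("total", "distinct"):
        raise ValueError("recruitment must be 'total' or 'distinct'")
    occ: dict[str, int] = {}
    for p in tf_peaks.itertuples():
        if p.chrom != region.chrom or p.end <= region.start \
                or region.end <= p.start:
            continue
        occ[p.tf] = occ.get(p.tf, 0) + 1
    rec = sum(occ.values()) if recruitment == "total" else len(occ)
    return occ, rec


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def build_region_table(fixture, recruitment: str = "total",
                       mean_depth: float | None = None,
                       occupancy_tfs: Iterable[str] | None = None,
                       ) -> pd.DataFrame:
    """One row per pG4-containing region with every mapped metric.

    ``fixture`` is a :class:`~g4causal.synthetic.GenomeFixture` or any
    object exposing the same frames.  Missing values propagate as NaN and
    are not imputed.  ``mean_depth`` defaults to the genome-wide mean
    fragment coverage.
    """
    regions = filter_regions_with_pg4(fixture.regions, fixture.pg4s)
    logger.info("pG4 filter kept %d/%d regions",
                len(regions), len(fixture.regions))
    mm = ValueTrack(fixture.mm_track, stranded=True)
    pp = ValueTrack(fixture.phylop_track)
    _check_disjoint(fixture.segmentation)
    if mean_depth is None:
        mean_depth = mean_sequencing_depth(fixture.atac_fragments,
                                           fixture.chrom_sizes)
    pg4s = fixture.pg4s.copy()
    pg4s["stability"] = [stability_of_pg4(p, mm) for p in pg4s.itertuples()]
    pg4s["phylop"] = [phylop_of_pg4(p, pp) for p in pg4s.itertuples()]

    tfs = tuple(occupancy_tfs) if occupancy_tfs is not None else \
        tuple(sorted(fixture.tf_peaks.tf.unique())) if len(fixture.tf_peaks) \
        else ()

    rows = []
    for r in regions.itertuples():
        occ, rec = tf_metrics(r, fixture.tf_peaks, recruitment=recruitment)
        row = {
            "region_id": getattr(r, "region_id", r.Index),
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "stability": assign_region_value(r, pg4s, "stability"),
            "eg4_signal": r.eg4_signal,
            "atac": atac_intensity(r, fixture.atac_fragments, mean_depth),
            "phylop": assign_region_value(r, pg4s, "phylop"),
            "chrom_state": chrom_state_of_region(r, fixture.segmentation),
            "tf_recruitment": rec,
            "stratum": getattr(r, "stratum", "NA"),
        }
        for tf in tfs:
            row[f"occ_{tf}"] = occ.get(tf, 0)
        rows.append(row)
    columns = ["region_id", "chrom", "start", "end", "stability",
               "eg4_signal", "atac", "phylop", "chrom_state",
               "tf_recruitment", "stratum"] + [f"occ_{tf}" for tf in tfs]
    return pd.DataFrame(rows, columns=columns)
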