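"""Correlation, per-state summaries, and TSS-proximal gene assignment.

The association layer answers the descriptive questions around the causal
analysis: how the mapped metrics co-vary (Spearman, since the metrics live
on incomparable scales), how stability and the other signals distribute
across chromatin states, and which genes sit immediately downstream of a
TSS-proximal eG4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import midpoint
from .prep import HIGH, LOW, STABILITY_CUTOFF
from .synthetic import STATE_VOCAB_18

logger = logging.getLogger(__name__)

DEFAULT_METRICS = ("stability", "eg4_signal", "atac", "phylop",
                   "tf_recruitment")


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman results: rho, p-value and pair sample size."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n: pd.DataFrame


def spearman_matrix(table: pd.DataFrame,
                    metrics: Sequence[str] = DEFAULT_METRICS,
                    ) -> CorrelationMatrix:
    """Pairwise complete-case Spearman correlation of the metric columns.

    Mid-rank ties; large-sample t-approximation p-values.  A constant
    column yields NaN rho with a warning.  Each pair needs >= 3 complete
    observations.
    """
    metrics = [m for m in metrics if m in table.columns]
    k = len(metrics)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            x = table[metrics[i]].to_numpy(dtype=float)
            y = table[metrics[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            nmat[i, j] = nmat[j, i] = int(ok.sum())
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for "
                    f"({metrics[i]}, {metrics[j]})")
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                logger.warning("constant column in pair (%s, %s): "
                               "rho undefined", metrics[i], metrics[j])
                continue
            if i == j:
                rho[i, i], pval[i, i] = 1.0, 0.0
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = list(metrics)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_value=pd.DataFrame(pval, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx))


def state_distributions(table: pd.DataFrame, metric: str,
                        vocabulary: Sequence[str] = STATE_VOCAB_18,
                        ) -> pd.DataFrame:
    """Per-chromatin-state summary (median, quartiles, n) of one metric.

    States are emitted in vocabulary order, empty ones with n = 0.  The TF
    recruitment count is first normalized by its maximum so its summaries
    are comparable across datasets.
    """
    values = table[metric].astype(float)
    if metric == "tf_recruitment" and len(values) and values.max() > 0:
        values = values / values.max()
    work = pd.DataFrame({"state": table["chrom_state"].astype(str),
                         "value": values}).dropna()
    rows = []
    grouped = dict(list(work.groupby("state")))
    for state in vocabulary:
        grp = grouped.get(state)
        if grp is None or grp.empty:
            rows.append((state, 0, np.nan, np.nan, np.nan))
        else:
            q1, med, q3 = np.percentile(grp["value"], [25, 50, 75])
            rows.append((state, len(grp), q1, med, q3))
    return pd.DataFrame(rows, columns=["chrom_state", "n", "q1", "median",
                                       "q3"])


@dataclass(frozen=True)
class TssAssignment:
    """One (gene, eG4 region) pairing within the TSS window."""

    gene_id: str
    region_id: str
    distance: int      # signed bp from TSS to region midpoint; + downstream
    stability_class: str


def tss_proximal_assignments(regions: pd.DataFrame, tss_list: pd.DataFrame,
                             window_bp: int = 200,
                             stability_cutoff: float = STABILITY_CUTOFF,
                             ) -> list[TssAssignment]:
    """Pair genes with eG4 regions whose midpoints fall within +-window_bp.

    The window is closed on both ends.  Distance is strand-aware: positive
    means the region midpoint lies downstream of the TSS in the gene's
    reading direction.  Stability class is High iff the region's MM% is at
    or above the cutoff; regions with missing stability still pair but
    carry an empty class.  A region may pair with several genes and vice
    versa.
    """
    out = []
    for t in tss_list.itertuples():
        sign = 1 if t.strand == "+" else -1
        for r in regions.itertuples():
            if r.chrom != t.chrom:
                continue
            mid = midpoint(r.start, r.end)
            if abs(mid - t.pos) > window_bp:
                continue
            stab = getattr(r, "stability", np.nan)
            cls = "" if pd.isna(stab) else \
                (HIGH if stab >= stability_cutoff else LOW)
            out.append(TssAssignment(
                gene_id=t.gene_id,
                region_id=str(getattr(r, "region_id", r.Index)),
                distance=sign * (mid - t.pos),
                stability_class=cls))
    return out


def gene_stability_classes(assignments: Sequence[TssAssignment],
                           multi_eg4: str = "nearest") -> dict[str, str]:
    """Collapse region-level classes to one stability class per gene.

    ``"nearest"`` takes the class of the eG4 closest to the TSS;
    ``"any_high"`` calls a gene High if any assigned eG4 is High.
    Assignments with missing classes are ignored.
    """
    if multi_eg4 not in ("nearest", "any_high"):
        raise ValueError("multi_eg4 must be 'nearest' or 'any_high'")
    by_gene: dict[str, list[TssAssignment]] = {}
    for a in assignments:
        if a.stability_class:
            by_gene.setdefault(a.gene_id, []).append(a)
    out = {}
    for gene, items in by_gene.items():
        if multi_eg4 == "nearest":
            best = min(items, key=lambda a: (abs(a.distance), a.region_id))
            out[gene] = best.stability_class
        else:
            out[gene] = HIGH if any(a.stability_class == HIGH
                                    for a in items) else LOW
    return out


def assignments_frame(assignments: Sequence[TssAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in assignments],
                        columns=["gene_id", "region_id", "distance",
                                 "stability_class"])
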