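"""Discretization and stratified sampling of the merged region table.

Numeric metrics are dichotomized High/Low against cell-line-specific
medians; G4 thermostability (MM%) is instead cut at a fixed empirical
threshold of 25, reflecting its absolute in vitro scale.  The merged,
discretized table is then subsampled within cell-line strata — either a
fixed percentage per stratum (proportional allocation) or a fixed count
per stratum (equal allocation) — to feed the structure-learning loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default MM% threshold separating High from Low stability
STABILITY_CUTOFF = 25.0

#: region-table columns discretized against per-stratum medians
MEDIAN_SPLIT_COLUMNS = ("eg4_signal", "atac", "phylop", "tf_recruitment")

HIGH, LOW = "High", "Low"


@dataclass(frozen=True)
class SamplingConfig:
    """Stratified-sampling settings.

    strategy
        ``"proportional"`` draws ``k`` percent of each stratum;
        ``"equal"`` draws exactly ``k`` rows from each stratum.
    k
        Percent (proportional) or per-stratum count (equal).
    seed
        RNG seed; identical configs reproduce identical samples.
    replace
        Sample with replacement (bootstrap) instead of the default
        without-replacement draw.
    """

    strategy: str = "equal"
    k: float = 7000
    seed: int = 0
    replace: bool = False

    def __post_init__(self):
        if self.strategy not in ("proportional", "equal"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "proportional" and not 0 <= self.k <= 100:
            raise ValueError("proportional k is a percentage in [0, 100]")
        if self.k < 0:
            raise ValueError("k must be non-negative")


def discretize(table: pd.DataFrame,
               stability_cutoff: float = STABILITY_CUTOFF,
               median_columns: Sequence[str] = MEDIAN_SPLIT_COLUMNS,
               occupancy_prefix: str = "occ_",
               median_ties: str = "low") -> pd.DataFrame:
    """Discretize a numeric region table into a High/Low categorical table.

    Rows with a missing value in any used column are dropped (complete-case
    analysis; the count is logged).  Median-split metrics are High iff the
    value exceeds that stratum's median ("low" tie rule; pass
    ``median_ties="high"`` for value >= median).  Stability is High iff
    MM% >= ``stability_cutoff``.  ``chrom_state`` passes through as a
    categorical column; per-TF occupancy columns (``occ_<TF>``) become
    High iff the count exceeds the stratum median, mirroring the other
    count metrics.

    Raises
    ------
    ValueError
        If a stratum retains fewer than 2 complete rows, or ties rule is
        unknown.
    """
    if median_ties not in ("low", "high"):
        raise ValueError("median_ties must be 'low' or 'high'")
    if "stratum" not in table.columns:
        raise ValueError("table must carry a 'stratum' column")
    if "Stability" in table.columns and "stability" not in table.columns:
        # already discrete: the map is idempotent
        return table.copy()
    occ_cols = [c for c in table.columns if c.startswith(occupancy_prefix)]
    med_cols = [c for c in median_columns if c in table.columns] + occ_cols
    used = ["stability", *med_cols, "stratum"]
    if "chrom_state" in table.columns:
        used.append("chrom_state")
    missing = table[used].isna().any(axis=1)
    if missing.any():
        logger.info("discretize: dropping %d/%d incomplete rows",
                    int(missing.sum()), len(table))
    work = table.loc[~missing, used].copy()

    counts = work.groupby("stratum", observed=True).size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"strata with <2 complete rows: {list(small.index)}")

    out = pd.DataFrame(index=work.index)
    out["Stability"] = np.where(work["stability"] >= stability_cutoff,
                                HIGH, LOW)
    for col in med_cols:
        med = work.groupby("stratum", observed=True)[col].transform("median")
        if median_ties == "low":
            hi = work[col] > med
        else:
            hi = work[col] >= med
        out[_discrete_name(col, occupancy_prefix)] = np.where(hi, HIGH, LOW)
    if "chrom_state" in work.columns:
        out["ChromState"] = work["chrom_state"].astype(str)
    out["stratum"] = work["stratum"].astype(str)
    return out.reset_index(drop=True)


def _discrete_name(col: str, occupancy_prefix: str) -> str:
    names = {"eg4_signal": "eG4s", "atac": "ATACSig",
             "phylop": "phyloP", "tf_recruitment": "nTFs"}
    if col in names:
        return names[col]
    if col.startswith(occupancy_prefix):
        return col  # occ_<TF> keeps its name in the discrete table
    return col


def stratified_sample(table: pd.DataFrame,
                      config: SamplingConfig) -> pd.DataFrame:
    """Draw a stratified sample of the discrete table.

    Equal allocation draws exactly ``k`` rows per stratum; proportional
    allocation draws ``round(k% * stratum size)`` rows (round-half-even).
    Sampling is without replacement unless ``config.replace``.
    """
    if "stratum" not in table.columns:
        raise ValueError("table must carry a 'stratum' column")
    rng = np.random.default_rng(config.seed)
    parts = []
    for name, grp in table.groupby("stratum", observed=True, sort=True):
        n = len(grp)
        if config.strategy == "equal":
            size = int(config.k)
            if size > n and not config.replace:
                raise ValueError(
                    f"equal-allocation k={size} exceeds stratum "
                    f"{name!r} size {n}")
        else:
            # np.round implements round-half-even
            size = int(np.round(config.k / 100.0 * n))
        idx = rng.choice(n, size=size, replace=config.replace)
        parts.append(grp.iloc[np.sort(idx)])
    if not parts:
        return table.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)
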