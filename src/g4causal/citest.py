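"""Conditional-independence testing for discrete data.

The workhorse is a Monte-Carlo permutation test of Pearson's chi-square for
conditional independence: the observed statistic sums, over configurations
of the conditioning set S, the two-way chi-square between X and Y within
that S-stratum.  The null distribution is generated by permuting X's values
within each S-stratum, which preserves the conditional margins.  Rather
than materialising row permutations, the engine draws the per-stratum
contingency tables directly from the margin-preserving (multivariate
hypergeometric) distribution — the exact distribution a within-stratum
permutation induces — which vectorises over all B Monte-Carlo replicates.

p-values use the add-one estimator p = (1 + #{T_b >= T_obs}) / (B + 1),
so p is never exactly zero and the test is valid at any B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence
from zlib import crc32

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance when comparing permuted statistics against the observed one, so
#: exactly-tied discrete statistics (e.g. all-zero tables) count as >=.
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class CITestConfig:
    """Settings for the permutation CI test.

    alpha
        Significance level for the independence decision.
    n_permutations
        Number of Monte-Carlo replicates B; the smallest attainable p-value
        is 1/(B+1).
    seed
        Master seed; each (X, Y, S) test derives its own child stream from
        it, keyed on the variable names, so results do not depend on the
        order in which tests are executed.
    """

    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _contingency(codes_x: np.ndarray, codes_y: np.ndarray,
                 codes_s: np.ndarray, kx: int, ky: int, ks: int) -> np.ndarray:
    """Observed counts with shape (ks, kx, ky) via a single bincount."""
    flat = (codes_s * kx + codes_x) * ky + codes_y
    return np.bincount(flat, minlength=ks * kx * ky).reshape(ks, kx, ky)


def _chi2_from_tables(obs: np.ndarray) -> np.ndarray:
    """Chi-square per leading index; strata/cells with zero margins add 0.

    obs has shape (..., r, c).
    """
    rows = obs.sum(axis=-1, keepdims=True)
    cols = obs.sum(axis=-2, keepdims=True)
    total = obs.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / total
        contrib = np.where(expected > 0,
                           (obs - expected) ** 2 / np.where(expected > 0,
                                                            expected, 1.0),
                           0.0)
    return contrib.sum(axis=(-2, -1))


def chi2_statistic(data: pd.DataFrame, x: str, y: str,
                   s: Sequence[str] = ()) -> float:
    """Conditional Pearson chi-square of X vs Y given S on discrete data.

    Sum over S-configurations of the two-way chi-square between X and Y,
    with expected counts from the row/column margins inside each stratum.
    Strata where a margin is zero contribute 0.
    """
    s = list(s)
    if x == y or x in s or y in s:
        raise ValueError("X, Y and S must be distinct")
    if len(data) == 0:
        raise ValueError("empty data")
    enc = _Encoded.from_frame(data, [x, y] + s)
    obs = enc.tables(x, y, s)
    return float(_chi2_from_tables(obs).sum())


class _Encoded:
    """Integer-coded view of a discrete table, computed once per dataset."""

    def __init__(self, codes: dict[str, np.ndarray], n_levels: dict[str, int]):
        self.codes = codes
        self.n_levels = n_levels
        self.n_rows = len(next(iter(codes.values()))) if codes else 0

    @classmethod
    def from_frame(cls, data: pd.DataFrame,
                   columns: Sequence[str] | None = None) -> "_Encoded":
        cols = list(columns) if columns is not None else list(data.columns)
        codes, levels = {}, {}
        for c in cols:
            code, uniq = pd.factorize(data[c], sort=True)
            if (code < 0).any():
                raise ValueError(f"column {c!r} contains missing values")
            codes[c] = code.astype(np.int64)
            levels[c] = len(uniq)
        return cls(codes, levels)

    def stratum_codes(self, s: Sequence[str]) -> tuple[np.ndarray, int]:
        if not s:
            return np.zeros(self.n_rows, dtype=np.int64), 1
        code = np.zeros(self.n_rows, dtype=np.int64)
        k = 1
        for c in s:
            code = code * self.n_levels[c] + self.codes[c]
            k *= self.n_levels[c]
        return code, k

    def tables(self, x: str, y: str, s: Sequence[str]) -> np.ndarray:
        sc, ks = self.stratum_codes(s)
        return _contingency(self.codes[x], self.codes[y], sc,
                            self.n_levels[x], self.n_levels[y], ks)


def _sample_null_tables(obs: np.ndarray, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw n tables from the permutation null of one stratum's table.

    The permutation distribution of the X x Y table with both margins fixed
    is multivariate hypergeometric; rows are filled sequentially from the
    remaining column totals.  Returns shape (n, r, c).
    """
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    r, c = obs.shape
    out = np.zeros((n, r, c), dtype=np.int64)
    remaining = np.broadcast_to(cols, (n, c)).copy()
    for i in range(r - 1):
        ni = int(rows[i])
        if ni == 0:
            continue
        if np.all(remaining == remaining[0]):
            draw = rng.multivariate_hypergeometric(remaining[0], ni, size=n)
        else:
            draw = np.stack([rng.multivariate_hypergeometric(remaining[j], ni)
                             for j in range(n)])
        out[:, i, :] = draw
        remaining -= draw
    out[:, r - 1, :] = remaining
    return out


class PermutationCITest:
    """Callable Monte-Carlo permutation chi-square CI test bound to a dataset.

    Calling the object with ``(x, y, s)`` returns the permutation p-value.
    :meth:`independent` returns the alpha-level decision and may stop the
    Monte-Carlo loop early once the decision is settled; with the same seed
    it always agrees with the decision implied by the full p-value.
    """

    def __init__(self, data: pd.DataFrame, config: CITestConfig | None = None,
                 exclude: Sequence[str] = ("stratum",)):
        self.config = config or CITestConfig()
        cols = [c for c in data.columns if c not in exclude]
        self._enc = _Encoded.from_frame(data, cols)
        self.variables = tuple(cols)

    # -- internals ---------------------------------------------------------

    def _child_rng(self, x: str, y: str, s: Sequence[str]) -> np.random.Generator:
        key = f"{x}|{y}|{','.join(sorted(s))}"
        return np.random.default_rng(
            np.random.SeedSequence([self.config.seed, crc32(key.encode())]))

    def _null_exceedances(self, x: str, y: str, s: Sequence[str],
                          stop_at: int | None) -> int:
        """Count permutation statistics >= observed, over B replicates.

        Replicates are drawn in fixed-size batches from the test's child RNG
        so that early stopping (``stop_at``) consumes a prefix of the exact
        same replicate stream as a full run.
        """
        enc = self._enc
        if x not in enc.codes or y not in enc.codes:
            raise ValueError(f"unknown variable in test ({x!r}, {y!r})")
        obs = enc.tables(x, y, list(s))
        t_obs = float(_chi2_from_tables(obs).sum())
        rng = self._child_rng(x, y, s)
        b_total = self.config.n_permutations
        count = 0
        done = 0
        # strata that can vary under permutation (both margins non-degenerate);
        # orient each table short-side-first: the statistic and the
        # margin-fixed null are symmetric under transposition, and fewer
        # rows means fewer sequential hypergeometric fills
        active = [t if t.shape[0] <= t.shape[1] else t.T
                  for t in (obs[k] for k in range(obs.shape[0]))
                  if (t.sum(axis=1) > 0).sum() > 1
                  and (t.sum(axis=0) > 0).sum() > 1]
        if not active:
            return b_total  # statistic identically 0 under the null and observed
        # 2x2 strata share a closed form: the table is determined by its
        # (0,0) cell, hypergeometric under the null, and the chi-square is
        # N^3/(r0 r1 c0 c1) (n00 - E00)^2; all such strata draw in one
        # broadcast call
        two = np.array([t for t in active if t.shape == (2, 2)])
        twoc = []  # two-row tables with >2 columns: chi2 closed-form in row 0
        others = []
        for t in active:
            if t.shape == (2, 2):
                continue
            if t.shape[0] == 2:
                cols = t.sum(axis=0).astype(float)
                n0 = int(t[0].sum())
                n_tot = cols.sum()
                e0 = n0 * cols / n_tot
                e1 = (n_tot - n0) * cols / n_tot
                inv0 = np.where(cols > 0, 1.0 / np.where(cols > 0, e0, 1), 0)
                inv1 = np.where(cols > 0, 1.0 / np.where(cols > 0, e1, 1), 0)
                twoc.append((cols.astype(np.int64), n0, e0, inv0, inv1))
            else:
                others.append(t)
        if len(two):
            r0, r1 = two[:, 0, :].sum(1), two[:, 1, :].sum(1)
            c0, c1 = two[:, :, 0].sum(1), two[:, :, 1].sum(1)
            n_tot = r0 + r1
            coef = n_tot.astype(float) ** 3 / (r0 * r1 * c0 * c1)
            e00 = r0 * c0 / n_tot
        while done < b_total:
            batch = min(256, b_total - done)
            t_null = np.zeros(batch)
            if len(two):
                n00 = rng.hypergeometric(c0, c1, r0, size=(batch, len(two)))
                t_null += (coef * (n00 - e00) ** 2).sum(axis=1)
            for cols, n0, e0, inv0, inv1 in twoc:
                draw = rng.multivariate_hypergeometric(cols, n0, size=batch)
                d0 = draw - e0  # row-1 deviation is -d0, so both use d0^2
                t_null += (d0 * d0 * (inv0 + inv1)).sum(axis=1)
            for table in others:
                t_null += _chi2_from_tables(
                    _sample_null_tables(table, batch, rng))
            count += int(np.sum(t_null >= t_obs - _TIE_EPS))
            done += batch
            if stop_at is not None and count >= stop_at:
                return count
        return count

    # -- public API --------------------------------------------------------

    def __call__(self, x: str, y: str, s: Sequence[str] = ()) -> float:
        return self.p_value(x, y, s)

    def p_value(self, x: str, y: str, s: Sequence[str] = ()) -> float:
        """Permutation p-value; constant X or Y yields p = 1 with a warning."""
        if self._is_constant(x) or self._is_constant(y):
            logger.warning("CI test (%s, %s | %s): constant variable, p = 1",
                           x, y, ",".join(s))
            return 1.0
        b = self.config.n_permutations
        count = self._null_exceedances(x, y, s, stop_at=None)
        return (1 + count) / (b + 1)

    def independent(self, x: str, y: str, s: Sequence[str] = ()) -> bool:
        """alpha-level decision: True iff p > alpha (independence retained).

        Stops the Monte-Carlo loop as soon as enough exceedances have
        accumulated to guarantee p > alpha; the decision is identical to
        ``p_value(x, y, s) > alpha``.
        """
        if self._is_constant(x) or self._is_constant(y):
            return True
        b, alpha = self.config.n_permutations, self.config.alpha
        # p = (1 + count)/(B + 1) > alpha  <=>  count >= floor(alpha (B+1))
        stop_at = int(np.floor(alpha * (b + 1)))
        if stop_at == 0:
            return True  # alpha below the attainable floor: never reject
        count = self._null_exceedances(x, y, s, stop_at=stop_at)
        return count >= stop_at

    def _is_constant(self, col: str) -> bool:
        return self._enc.n_levels[col] <= 1


def oracle_ci_test(dag) -> "callable":
    """Exact CI oracle from a ground-truth DAG via d-separation.

    Returns a callable with the same (x, y, s) -> p signature as
    :class:`PermutationCITest`: p = 1 when d-separated, else 0.
    """
    from .graphs import d_separated

    def test(x: str, y: str, s: Sequence[str] = ()) -> float:
        return 1.0 if d_separated(dag, x, y, s) else 0.0

    return test
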