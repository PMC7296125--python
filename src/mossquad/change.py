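"""Temporal change analysis of per-quadrat percent-cover tables.

Cover change across years is tested per vegetation class with the
Friedman rank test: quadrats are blocks, years are treatments, and
within-block ranks (ties averaged) feed the tie-corrected statistic

    Q = (k - 1) * sum_j (R_j - b (k+1)/2)^2 / (sum_ij r_ij^2 - b k (k+1)^2 / 4)

which reduces to the classic 12/(b k (k+1)) * sum R_j^2 - 3 b (k+1) form
when there are no ties; Q is compared to a chi-square with k - 1 degrees
of freedom. Tie correction is always applied because cover data contain
exact zeros. Pairwise follow-up uses the Dunn-type statistic on mean
ranks, z = (Rbar_a - Rbar_b) / sqrt(k (k+1) / (6 b)), with Bonferroni
adjustment over the k (k-1)/2 comparisons; treatments are also grouped
into significance letters for plotting. Quadrats with any missing year
(e.g. snow-covered) are removed by complete-case filtering before
testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("mossquad")


class InputError(ValueError):
    """Panel does not satisfy the test's preconditions."""


@dataclass
class CoverPanel:
    """Blocks x treatments matrix of percent cover for one class."""

    blocks: list            # quadrat ids
    treatments: list        # years
    x: np.ndarray           # (b, k) percent cover

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        b, k = self.x.shape
        if len(self.blocks) != b or len(self.treatments) != k:
            raise InputError("panel dimensions do not match block/treatment labels")
        if k < 2 or b < 2:
            raise InputError("need at least 2 blocks and 2 treatments")
        if np.isnan(self.x).any():
            raise InputError("panel contains missing cells; run complete_case_filter first")


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    degenerate: bool = False  # all within-block ties: statistic undefined, reported as 0


def _within_block_ranks(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, x)


def friedman_test(panel: CoverPanel) -> FriedmanResult:
    """Tie-corrected Friedman test over the panel's blocks."""
    b, k = panel.x.shape
    r = _within_block_ranks(panel.x)
    col_sums = r.sum(axis=0)
    s = float(np.sum((col_sums - b * (k + 1) / 2.0) ** 2))
    denom = float(np.sum(r ** 2) - b * k * (k + 1) ** 2 / 4.0)
    if denom == 0:
        # every block fully tied; no information about treatment order
        return FriedmanResult(chi2=0.0, df=k - 1, p=1.0, degenerate=True)
    chi2 = (k - 1) * s / denom
    p = float(sps.chi2.sf(chi2, k - 1))
    return FriedmanResult(chi2=float(chi2), df=k - 1, p=p)


def pairwise_posthoc(panel: CoverPanel, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn-type pairwise comparisons with Bonferroni correction.

    Returns one row per treatment pair: z, raw and adjusted two-sided
    normal p-values, and a significance flag at ``alpha``. Mean ranks and
    grouping letters are attached as DataFrame attrs (``mean_ranks``,
    ``letters``) for plot annotation.
    """
    if not (0 < alpha < 1):
        raise InputError("alpha must be in (0, 1)")
    b, k = panel.x.shape
    r = _within_block_ranks(panel.x)
    mean_ranks = r.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * b))
    m = k * (k - 1) // 2
    rows = []
    sig = {}
    for i, j in combinations(range(k), 2):
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        rows.append((panel.treatments[i], panel.treatments[j], z, p_raw, p_adj, p_adj < alpha))
        sig[(i, j)] = p_adj < alpha
    out = pd.DataFrame(rows, columns=["year_a", "year_b", "z", "p_raw", "p_adjusted", "significant"])
    out.attrs["mean_ranks"] = dict(zip(panel.treatments, mean_ranks))
    out.attrs["letters"] = dict(zip(panel.treatments, _significance_letters(mean_ranks, sig)))
    return out


def _significance_letters(mean_ranks: np.ndarray, sig: dict[tuple[int, int], bool]) -> list[str]:
    """Compact letter display: treatments sharing a letter do not differ.

    Greedy sweep over treatments ordered by mean rank: extend each letter
    group while all pairs inside stay non-significant.
    """
    k = len(mean_ranks)
    order = np.argsort(mean_ranks, kind="stable")
    groups: list[set[int]] = []
    for t in order:
        placed = False
        for grp in groups:
            if all(not sig.get((min(t, u), max(t, u)), False) for u in grp):
                grp.add(int(t))
                placed = True
        if not placed:
            groups.append({int(t)})
    # drop groups fully contained in another (no new information)
    groups = [g for g in groups if not any(g < h for h in groups)]
    letters = [""] * k
    for gi, grp in enumerate(sorted(groups, key=lambda g: min(np.argsort(order)[list(g)]))):
        ch = chr(ord("a") + gi)
        for t in grp:
            letters[t] += ch
    return letters


def complete_case_filter(
    table: pd.DataFrame,
    cover_class: str,
    value_col: str = "percent",
) -> CoverPanel:
    """Build a complete-case CoverPanel from a long-format cover table.

    ``table`` columns: quadrat_id, year, class, percent. Blocks (quadrats)
    with any missing year for ``cover_class`` are dropped (logged); at
    least two complete blocks must remain.
    """
    sub = table[table["class"] == cover_class]
    if sub.empty:
        raise InputError(f"no rows for class {cover_class!r}")
    wide = sub.pivot_table(index="quadrat_id", columns="year", values=value_col, aggfunc="first")
    n_before = len(wide)
    wide = wide.dropna(axis=0, how="any")
    dropped = n_before - len(wide)
    if dropped:
        logger.info("complete-case filter: dropped %d of %d quadrats for %s",
                    dropped, n_before, cover_class)
    if len(wide) < 2 or wide.shape[1] < 2:
        raise InputError(
            f"fewer than 2 complete blocks or 2 years remain for {cover_class!r}"
        )
    return CoverPanel(blocks=list(wide.index), treatments=list(wide.columns),
                      x=wide.to_numpy())


def change_report(table: pd.DataFrame, cover_class: str, alpha: float = 0.05
                  ) -> tuple[FriedmanResult, pd.DataFrame]:
    """Friedman test plus post-hoc table for one cover class."""
    panel = complete_case_filter(table, cover_class)
    return friedman_test(panel), pairwise_posthoc(panel, alpha)
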