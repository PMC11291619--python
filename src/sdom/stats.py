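"""Seed-set categorization and association tests.

Autonomous-selfing seed counts are grouped into three categories (almost no
seeds: <10; few: 10-300; plenty: >300); the low cutoff absorbs occasional
pollen contamination.  Association between predicted SC/SI phenotype and
seed category is tested with Fisher's exact test — implemented by exact
enumeration of all tables with the observed margins, using the
Freeman-Halton "as probable or less probable" criterion so 2x3 tables are
handled without a chi-square approximation — and the focal allele's relative
SCR expression is compared across categories with the Kruskal-Wallis H test
(mid-ranks, tie-corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, prod
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

SEED_CATEGORIES = ("almost_none", "few", "plenty")
_ALMOST_NONE_MAX = 9  # "<10 seeds"
_FEW_MAX = 300  # "10-300 seeds", both endpoints inclusive


def categorize_seed_set(count: int) -> str:
    """Map a seed count to its category: <10, 10-300 (inclusive), >300."""
    if count < 0:
        raise ValueError(f"negative seed count {count}")
    if count <= _ALMOST_NONE_MAX:
        return "almost_none"
    if count <= _FEW_MAX:
        return "few"
    return "plenty"


def contingency_table(
    predictions: Sequence[str], categories: Sequence[str]
) -> pd.DataFrame:
    """2x3 counts of predicted phenotype (SC/SI) by seed category."""
    if len(predictions) != len(categories):
        raise ValueError("predictions and categories differ in length")
    table = pd.DataFrame(
        0, index=["SC", "SI"], columns=list(SEED_CATEGORIES), dtype=int
    )
    for p, c in zip(predictions, categories):
        if p not in ("SC", "SI"):
            continue  # NA predictions excluded
        table.loc[p, c] += 1
    return table


def collapse_to_plenty(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Collapse a 2x3 phenotype-by-category table to 2x2 (plenty vs rest)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 3):
        raise ValueError(f"expected a 2x3 table, got {arr.shape}")
    return np.column_stack([arr[:, :2].sum(axis=1), arr[:, 2]])


def fisher_exact(table, max_total: int = 200) -> float:
    """Exact conditional p-value for a 2xr contingency table.

    All tables with the observed margins are enumerated; under the null the
    table probability is multivariate hypergeometric, and the p-value is the
    summed probability of tables as probable or less probable than the
    observed one (Freeman-Halton criterion; for 2x2 this is the classical
    two-sided Fisher test).  Probabilities are compared as exact integers,
    so no floating-point tie tolerance is needed.

    Raises ``ValueError`` when the table total exceeds ``max_total``
    (enumeration kept deliberately bounded).
    """
    arr = np.asarray(table, dtype=int)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError(f"expected a 2xr table with r >= 2, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative counts")
    n = int(arr.sum())
    if n > max_total:
        raise ValueError(
            f"table total {n} exceeds enumeration bound {max_total}"
        )
    if n == 0:
        return 1.0
    row1 = int(arr[0].sum())
    cols = [int(c) for c in arr.sum(axis=0)]
    # unnormalized probability of a first row (x_1..x_r): prod C(col_j, x_j)
    obs_weight = prod(comb(c, int(x)) for c, x in zip(cols, arr[0]))
    total_weight = comb(n, row1)
    acc = 0

    def enumerate_rows(j: int, remaining: int, weight: int) -> None:
        nonlocal acc
        if j == len(cols) - 1:
            if remaining <= cols[j]:
                w = weight * comb(cols[j], remaining)
                if w <= obs_weight:
                    acc += w
            return
        max_here = min(cols[j], remaining)
        min_here = max(0, remaining - sum(cols[j + 1 :]))
        for x in range(min_here, max_here + 1):
            enumerate_rows(j + 1, remaining - x, weight * comb(cols[j], x))

    enumerate_rows(0, row1, 1)
    return float(min(Fraction(acc, total_weight), 1))


@dataclass
class KWResult:
    """Kruskal-Wallis H test result."""

    H_statistic: float
    df: int
    p_value: float
    tie_corrected: bool = True


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Kruskal-Wallis H over k groups (mid-ranks, tie-corrected).

    The p-value is the chi-square upper tail with k-1 degrees of freedom.
    When every observation is identical the statistic is defined as 0 with
    p = 1 (no evidence of group differences).
    """
    groups = [list(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    flat = [x for g in groups for x in g]
    if len(set(flat)) == 1:
        return KWResult(0.0, len(groups) - 1, 1.0)
    h, p = sps.kruskal(*groups)
    return KWResult(float(h), len(groups) - 1, float(p))


@dataclass
class AssociationReport:
    """Association of predicted phenotype with autonomous seed production."""

    table: pd.DataFrame
    fisher_p_2x3: float
    fisher_p_2x2: float
    kruskal: KWResult | None
    n_na_predictions: int


def association_report(
    predictions: Sequence[str],
    seed_counts: Sequence[int],
    focal_shares: Sequence[float] | None = None,
) -> AssociationReport:
    """Full association summary for a panel.

    ``predictions`` are per-individual SC/SI/NA calls, ``seed_counts`` the
    autonomous seed counts, and ``focal_shares`` (optional) the focal
    allele's relative SCR expression, compared across seed categories with
    Kruskal-Wallis when at least two categories are populated.
    """
    categories = [categorize_seed_set(c) for c in seed_counts]
    table = contingency_table(predictions, categories)
    n_na = sum(1 for p in predictions if p not in ("SC", "SI"))
    p23 = fisher_exact(table.to_numpy())
    p22 = fisher_exact(collapse_to_plenty(table))
    kw = None
    if focal_shares is not None:
        by_cat: dict[str, list[float]] = {}
        for share, cat in zip(focal_shares, categories):
            if share == share:  # drop NaN
                by_cat.setdefault(cat, []).append(share)
        populated = [v for v in by_cat.values() if v]
        if len(populated) >= 2:
            kw = kruskal_wallis(populated)
    return AssociationReport(table, p23, p22, kw, n_na)
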