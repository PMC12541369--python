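"""Statistical tests and phenotype metrics shared by the pipeline.

Two-sided Fisher's exact test (sum of outcomes no more probable than the
observed table), Mann-Whitney U, per-category frequency comparisons, and
brood-viability / male-frequency summaries. These are thin, validated fronts
over scipy.stats so every module applies the same conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FisherResult",
    "MannWhitneyResult",
    "fisher_exact",
    "mann_whitney",
    "category_comparison",
    "viability_metrics",
]


@dataclass(frozen=True)
class FisherResult:
    """Outcome of a two-sided Fisher's exact test on a 2x2 table."""

    odds_ratio: float
    p_value: float
    degenerate: bool = False  # a zero row/column margin: association undefined


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # min(U1, U2)
    p_value: float
    method: str  # "exact" or "asymptotic"


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("table counts must be finite and non-negative")
    if np.any(arr != np.round(arr)):
        raise ValueError("table counts must be integers")
    if arr.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    return arr.astype(np.int64)


def fisher_exact(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The p-value is the sum of hypergeometric probabilities of all tables with
    the observed margins whose point probability does not exceed that of the
    observed table. The odds ratio is the sample odds ratio (a*d)/(b*c),
    reported as ``inf`` when b*c = 0 with a*d > 0.

    A table with a zero row or column margin carries no information about
    association; it is reported with p = 1 and ``degenerate=True``.
    """
    arr = _as_2x2(table)
    a, b = arr[0]
    c, d = arr[1]
    row_zero = (a + b == 0) or (c + d == 0)
    col_zero = (a + c == 0) or (b + d == 0)
    if row_zero or col_zero:
        return FisherResult(odds_ratio=float("nan"), p_value=1.0, degenerate=True)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = float(a * d) / float(b * c)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return FisherResult(odds_ratio=odds, p_value=float(min(p, 1.0)))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation null when both samples are small
    (max(n1, n2) <= 8) and tie-free; otherwise the normal approximation with
    tie and continuity corrections. U is reported as min(U1, U2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # every observation identical: no evidence of a shift either way
        return MannWhitneyResult(u=n1 * n2 / 2.0, p_value=1.0, method="asymptotic")
    if not has_ties and max(n1, n2) <= 8:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    u1 = float(res.statistic)
    u2 = n1 * n2 - u1
    p = float(min(res.pvalue, 1.0))
    if u1 == u2:
        p = 1.0
    return MannWhitneyResult(u=min(u1, u2), p_value=p, method=method)


def category_comparison(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise per-category Fisher comparisons between genotypes.

    Parameters
    ----------
    counts
        Genotypes as rows (index), categories as columns, integer counts as
        values (e.g. singlet / elongated_singlet / doublet tallies).

    Returns
    -------
    One row per (category, genotype pair) with the 2x2 counts
    (in-category vs rest for each genotype), the odds ratio and the
    two-sided p-value.
    """
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least two genotypes and two categories")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"genotype(s) with zero total counts: {empty}")
    rows = []
    genotypes = list(counts.index)
    for category in counts.columns:
        for i in range(len(genotypes)):
            for j in range(i + 1, len(genotypes)):
                ga, gb = genotypes[i], genotypes[j]
                a = int(counts.loc[ga, category])
                b = int(totals[ga]) - a
                c = int(counts.loc[gb, category])
                d = int(totals[gb]) - c
                res = fisher_exact([[a, b], [c, d]])
                rows.append(
                    {
                        "category": category,
                        "genotype_a": ga,
                        "genotype_b": gb,
                        "a_in": a,
                        "a_total": a + b,
                        "b_in": c,
                        "b_total": c + d,
                        "odds_ratio": res.odds_ratio,
                        "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(rows)


def viability_metrics(brood: pd.DataFrame, group_col: str = "genotype") -> pd.DataFrame:
    """Per-genotype viability and male-frequency summaries.

    ``brood`` needs columns ``eggs_laid`` (brood size: hatched larvae plus
    unhatched eggs, unfertilized eggs excluded upstream), ``larvae`` and
    ``males`` per worm, plus a grouping column. Viability is
    100 * larvae / eggs_laid per worm; male frequency is 100 * males / larvae
    among the hatched offspring. Group means and SDs use the n-1 denominator.
    """
    required = {group_col, "eggs_laid", "larvae", "males"}
    missing = required - set(brood.columns)
    if missing:
        raise ValueError(f"brood table missing columns: {sorted(missing)}")
    if (brood["eggs_laid"] <= 0).any():
        raise ValueError("every record must have a positive brood size")
    if (brood["larvae"] > brood["eggs_laid"]).any():
        raise ValueError("larvae cannot exceed eggs_laid")
    if (brood["males"] > brood["larvae"]).any():
        raise ValueError("males cannot exceed larvae")

    per_worm = brood.copy()
    per_worm["viability_pct"] = 100.0 * per_worm["larvae"] / per_worm["eggs_laid"]
    larvae = per_worm["larvae"].to_numpy(dtype=float)
    males = per_worm["males"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        male_pct = np.where(larvae > 0, 100.0 * males / np.maximum(larvae, 1e-300), 0.0)
    per_worm["male_pct"] = male_pct

    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n": len(g),
                "viability_mean": g["viability_pct"].mean(),
                "viability_sd": g["viability_pct"].std(ddof=1) if len(g) > 1 else 0.0,
                "male_mean": g["male_pct"].mean(),
                "male_sd": g["male_pct"].std(ddof=1) if len(g) > 1 else 0.0,
            }
        )
    out = per_worm.groupby(group_col, sort=False).apply(_agg, include_groups=False)
    return out.reset_index()
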