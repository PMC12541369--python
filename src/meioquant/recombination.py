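"""Crossover calling and recombination-frequency mapping from SNP genotypes.

Progeny of Bristol/Hawaiian hybrid mothers are genotyped at five ordered SNP
markers (A-E) on chromosome V; each progeny contributes one maternal
chromatid. A phase transition between adjacent informative markers marks a
crossover in that interval. Per-interval frequencies, the overall recombinant
fraction (chromatids with >= 1 observed crossover over all scored
chromatids), and single/double/triple-crossover class counts are tallied per
cohort and compared between cohorts with two-sided Fisher's exact tests.

Even numbers of exchanges inside one interval are invisible at marker
resolution; that undercount is inherent to the assay and is documented, not
corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_exact

__all__ = [
    "MarkerMap",
    "COProfile",
    "CohortRecombination",
    "default_marker_map",
    "call_crossovers",
    "cohort_recombination",
    "compare_recombination",
]

_MISSING = {"NA", "N", "", None}


@dataclass(frozen=True)
class MarkerMap:
    """Ordered SNP markers with strictly increasing chromosome coordinates."""

    labels: tuple
    positions_bp: tuple
    chromosome: str = "V"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.positions_bp):
            raise ValueError("labels and positions must have equal length")
        if len(self.labels) < 2:
            raise ValueError("need at least two markers")
        pos = np.asarray(self.positions_bp, dtype=float)
        if not np.all(np.diff(pos) > 0):
            raise ValueError("marker positions must be strictly increasing")

    @property
    def intervals(self) -> List[str]:
        """Labels of adjacent-marker intervals, e.g. ['AB', 'BC', 'CD', 'DE']."""
        return [a + b for a, b in zip(self.labels[:-1], self.labels[1:])]

    def reversed(self) -> "MarkerMap":
        pos = self.positions_bp
        span = pos[0] + pos[-1]
        return MarkerMap(
            tuple(reversed(self.labels)),
            tuple(span - p for p in reversed(pos)),
            self.chromosome,
        )


def default_marker_map() -> MarkerMap:
    """Five markers A-E on chromosome V. The coordinates are illustrative
    placeholders (the assay depends only on marker order)."""
    return MarkerMap(("A", "B", "C", "D", "E"), (1_870_000, 4_620_000, 11_900_000,
                                                 16_050_000, 19_300_000))


@dataclass(frozen=True)
class COProfile:
    """Crossovers called on one chromatid."""

    progeny_id: str
    crossover_intervals: tuple  # interval labels, composite (e.g. 'BD') when a gap intervenes
    n_co: int
    usable: bool  # eligible for per-interval counts (no transition hidden by missing calls)


def _is_missing(call) -> bool:
    return (call in _MISSING) or (isinstance(call, float) and np.isnan(call))


def call_crossovers(
    calls: Sequence, marker_map: MarkerMap, progeny_id: str = ""
) -> COProfile:
    """Call crossovers on one chromatid from its ordered marker calls.

    A crossover is recorded between every adjacent pair of informative
    (non-missing) calls that differ. When missing calls separate the pair,
    the transition is assigned to the composite interval spanning them and
    the chromatid is flagged unusable for per-interval counts (it still
    counts toward the overall recombinant fraction).
    """
    calls = list(calls)
    if len(calls) != len(marker_map.labels):
        raise ValueError(
            f"got {len(calls)} calls for {len(marker_map.labels)} markers"
        )
    informative = [i for i, c in enumerate(calls) if not _is_missing(c)]
    if len(informative) < 2:
        raise ValueError(
            f"chromatid {progeny_id!r} has fewer than two informative calls"
        )
    for i in informative:
        if calls[i] not in ("B", "H"):
            raise ValueError(f"invalid call {calls[i]!r} at marker {marker_map.labels[i]}")
    intervals = []
    usable = True
    for i, j in zip(informative[:-1], informative[1:]):
        if calls[i] != calls[j]:
            if j == i + 1:
                intervals.append(marker_map.labels[i] + marker_map.labels[j])
            else:
                intervals.append(marker_map.labels[i] + marker_map.labels[j])
                usable = False
    return COProfile(progeny_id, tuple(intervals), len(intervals), usable)


@dataclass
class CohortRecombination:
    """Cohort-level recombination summary."""

    n_scored: int
    n_recombinant: int
    recombinant_pct: float  # percentage, 2 decimals
    n_usable: int
    interval_counts: dict  # simple interval label -> crossover count
    interval_freq: dict  # simple interval label -> count / n_usable
    co_class_counts: dict  # n_co (0,1,2,3) -> chromatid count; key 3 means >= 3
    co_class_pct: dict
    profiles: list = field(default_factory=list, repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": list(self.interval_freq),
                "n_co": [self.interval_counts[k] for k in self.interval_freq],
                "n_usable": self.n_usable,
                "frequency": list(self.interval_freq.values()),
            }
        )


def cohort_recombination(
    cohort: pd.DataFrame, marker_map: MarkerMap | None = None
) -> CohortRecombination:
    """Per-interval frequencies, overall recombinant fraction and
    crossover-class counts for one genotype cohort.

    ``cohort`` has one row per progeny with a progeny_id column plus one
    column per marker (values B / H / NA). Per-interval frequency divides by
    the usable chromatids; the overall recombinant fraction divides
    chromatids with >= 1 observed crossover by all scored chromatids.
    Percentages are reported to 2 decimals.
    """
    if marker_map is None:
        marker_map = default_marker_map()
    marker_cols = list(marker_map.labels)
    missing_cols = set(marker_cols) - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort table missing marker columns: {sorted(missing_cols)}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    profiles = []
    for _, row in cohort.iterrows():
        pid = str(row.get("progeny_id", ""))
        profiles.append(call_crossovers([row[m] for m in marker_cols], marker_map, pid))
    n_scored = len(profiles)
    n_recombinant = sum(1 for p in profiles if p.n_co >= 1)
    usable = [p for p in profiles if p.usable]
    n_usable = len(usable)
    interval_counts = {iv: 0 for iv in marker_map.intervals}
    for p in usable:
        for iv in p.crossover_intervals:
            interval_counts[iv] += 1
    interval_freq = {
        iv: (c / n_usable if n_usable else float("nan")) for iv, c in interval_counts.items()
    }
    co_class_counts = {0: 0, 1: 0, 2: 0, 3: 0}
    for p in profiles:
        co_class_counts[min(p.n_co, 3)] += 1
    co_class_pct = {k: round(100.0 * v / n_scored, 2) for k, v in co_class_counts.items()}
    return CohortRecombination(
        n_scored=n_scored,
        n_recombinant=n_recombinant,
        recombinant_pct=round(100.0 * n_recombinant / n_scored, 2),
        n_usable=n_usable,
        interval_counts=interval_counts,
        interval_freq=interval_freq,
        co_class_counts=co_class_counts,
        co_class_pct=co_class_pct,
        profiles=profiles,
    )


def compare_recombination(
    cohort_a: pd.DataFrame | CohortRecombination,
    cohort_b: pd.DataFrame | CohortRecombination,
    marker_map: MarkerMap | None = None,
) -> pd.DataFrame:
    """Fisher comparisons of two cohorts: overall recombinant-vs-not, plus
    crossover-vs-not per simple interval (usable-chromatid denominators).

    A degenerate 2x2 (zero margin) is reported with p = 1 and a warning.
    """
    if marker_map is None:
        marker_map = default_marker_map()
    ra = cohort_a if isinstance(cohort_a, CohortRecombination) else cohort_recombination(
        cohort_a, marker_map
    )
    rb = cohort_b if isinstance(cohort_b, CohortRecombination) else cohort_recombination(
        cohort_b, marker_map
    )
    rows = []

    def _row(scope, a, na, b, nb):
        res = fisher_exact([[a, na - a], [b, nb - b]])
        if res.degenerate:
            warnings.warn(f"degenerate 2x2 for {scope}: p reported as 1", stacklevel=3)
        rows.append(
            {
                "scope": scope,
                "a_events": a,
                "a_n": na,
                "b_events": b,
                "b_n": nb,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )

    _row("overall", ra.n_recombinant, ra.n_scored, rb.n_recombinant, rb.n_scored)
    for iv in marker_map.intervals:
        _row(iv, ra.interval_counts[iv], ra.n_usable, rb.interval_counts[iv], rb.n_usable)
    return pd.DataFrame(rows)
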