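"""Roll-ups of signal results along the PT -> primary-SOC hierarchy,
demographic/subset summaries, and the eosinophil PT filter.

All percentages are computed from counts and rounded half-up to two
decimals, so every printed share equals ``round_half_up(count/total*100, 2)``
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import pandas as pd

from .model import DEMOGRAPHIC_FIELDS, Dataset, ICSRReport, MedDRADictionary
from .disproportionality import DisproportionalityResult

__all__ = [
    "round_half_up",
    "SOCSummary",
    "SOCRollup",
    "SubsetShareRow",
    "DemographicsSummary",
    "rollup_by_soc",
    "subset_shares",
    "eosinophil_filter",
    "demographics_summary",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SOCSummary:
    """Signal count and report total for one system organ class."""

    soc: str
    n_signals: int
    n_reports: int


@dataclass(frozen=True)
class SOCRollup:
    """SOC summaries plus the diagnostic set of unmapped signal PTs."""

    summaries: tuple[SOCSummary, ...]
    unmapped: frozenset[str]

    def __iter__(self):
        return iter(self.summaries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.soc, s.n_signals, s.n_reports) for s in self.summaries],
            columns=["soc", "n_signals", "n_reports"],
        )


def rollup_by_soc(
    results: Iterable[DisproportionalityResult],
    dictionary: MedDRADictionary,
    *,
    signals_only: bool = True,
) -> SOCRollup:
    """Aggregate results per primary SOC.

    Each signal is counted once; ``n_reports`` sums the pair co-report
    counts.  PTs that do not resolve in the dictionary go to the
    ``unmapped`` diagnostic set and are excluded from the summaries, never
    silently dropped.  Summaries are ordered by descending ``n_signals``,
    ties broken by SOC name.
    """
    per_soc: dict[str, list[int]] = {}
    unmapped: set[str] = set()
    for r in results:
        if signals_only and not r.is_signal:
            continue
        try:
            soc = dictionary.primary_soc(r.event_pt)
        except KeyError:
            unmapped.add(r.event_pt)
            continue
        cell = per_soc.setdefault(soc, [0, 0])
        cell[0] += 1
        cell[1] += r.n_reports
    summaries = tuple(
        SOCSummary(soc, k, m)
        for soc, (k, m) in sorted(
            per_soc.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
    )
    return SOCRollup(summaries, frozenset(unmapped))


@dataclass(frozen=True)
class SubsetShareRow:
    """One PT's report count and share of a subset's signal reports."""

    event_pt: str
    n_reports: int
    share_pct: float


def subset_shares(
    results: Sequence[DisproportionalityResult],
) -> list[SubsetShareRow]:
    """Report shares within a subset of results (e.g., one SOC's signals).

    Shares are percentages of the subset's summed report count, rounded
    half-up to two decimals; rows sort by descending count, ties by PT.
    """
    if not results:
        raise ValueError("subset is empty")
    total = sum(r.n_reports for r in results)
    rows = [
        SubsetShareRow(
            r.event_pt, r.n_reports, round_half_up(100.0 * r.n_reports / total)
        )
        for r in results
    ]
    rows.sort(key=lambda row: (-row.n_reports, row.event_pt))
    return rows


def eosinophil_filter(pt_names: Iterable[str]) -> list[str]:
    """Retain PTs naming eosinophils.

    Matching is a case-insensitive substring test for ``"eosinophil"``
    (singular), which covers forms like "Eosinophilia" and
    "Eosinophil count increase" that the plural would miss.
    """
    return [pt for pt in pt_names if "eosinophil" in pt.casefold()]


@dataclass(frozen=True)
class DemographicsSummary:
    """Per-field category counts and percentages over a report subset."""

    n_total: int
    fields: dict[str, dict[str, tuple[int, float]]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (fname, cat, cnt, pct)
            for fname, cats in self.fields.items()
            for cat, (cnt, pct) in cats.items()
        ]
        return pd.DataFrame(rows, columns=["field", "category", "count", "pct"])


def demographics_summary(
    dataset: Dataset,
    subset_predicate: Callable[[ICSRReport], bool] | None = None,
) -> DemographicsSummary:
    """Tabulate demographics over reports matching ``subset_predicate``.

    Percentages are of the subset's report total (each field's counts sum
    to that total).  Categories with zero reports are included so columns
    are comparable across subsets.
    """
    reports = [
        r for r in dataset.reports if subset_predicate is None or subset_predicate(r)
    ]
    total = len(reports)
    fields: dict[str, dict[str, tuple[int, float]]] = {}
    for fname, cats in DEMOGRAPHIC_FIELDS.items():
        counts = {c: 0 for c in cats}
        for r in reports:
            counts[getattr(r, fname)] += 1
        fields[fname] = {
            c: (k, round_half_up(100.0 * k / total) if total else 0.0)
            for c, k in counts.items()
        }
    return DemographicsSummary(total, fields)
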