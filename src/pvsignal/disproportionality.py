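"""Disproportionality statistics and the composite signal criterion.

Given a 2x2 table (a, b, c, d) of report counts for a drug-event pair:

* ``PRR = [a/(a+b)] / [c/(c+d)]`` — proportional reporting ratio, the
  event's reporting rate among the drug's reports relative to all other
  drugs' reports;
* ``ROR = (a/b) / (c/d) = ad/bc`` — reporting odds ratio;
* ``IC = log2((a + 0.5) / (E + 0.5))`` with ``E = (a+b)(a+c)/n`` — the
  shrinkage information component, a Bayesian observed-to-expected measure
  whose +0.5 offsets pull small-count pairs toward 0;
* ``IC025`` — the lower bound of the IC's 95% credibility interval, by the
  closed-form approximation

      IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2.4 (a+0.5)^(-3/2)

  or by Monte-Carlo percentile of ``log2(G/(E+0.5))`` with
  ``G ~ Gamma(shape=a+0.5, rate=1)`` (the gamma posterior of the observed
  count under the shrinkage prior), used as a validation oracle.

A pair is a *signal* when all hold: at least ``min_reports`` (default 3)
co-reports, PRR >= 2, ROR >= 2 and IC025 above 0.  Statistics with zero
denominators are undefined (``None``) and fail their criterion rather than
being clamped to 0 or infinity.  No multiple-testing adjustment is applied;
this is a known property of threshold-based signal screening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, all_pair_tables
from .model import Dataset

__all__ = [
    "prr",
    "ror",
    "ic",
    "ic025",
    "SignalCriteria",
    "DisproportionalityResult",
    "evaluate",
    "screen",
    "results_frame",
]


def prr(t: ContingencyTable) -> float | None:
    """Proportional reporting ratio, or None when undefined.

    Undefined when the drug has no reports, no other report exists, or the
    event never occurs without the drug (c == 0).
    """
    if t.a + t.b == 0 or t.c + t.d == 0 or t.c == 0:
        return None
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def ror(t: ContingencyTable) -> float | None:
    """Reporting odds ratio ``ad/bc``, or None when b, c or d is zero."""
    if t.b == 0 or t.c == 0 or t.d == 0:
        return None
    return (t.a * t.d) / (t.b * t.c)


def ic(t: ContingencyTable) -> float:
    """Shrinkage information component ``log2((a+0.5)/(E+0.5))``.

    With empty margins E = 0 and a = 0, so the IC is 0 by construction; as
    counts grow the +0.5 offsets vanish and the IC tends to the plain log2
    observed-over-expected joint reporting probability.
    """
    if t.n == 0:
        raise ValueError("IC undefined for an empty table")
    return math.log2((t.a + 0.5) / (t.expected + 0.5))


def ic025(
    t: ContingencyTable,
    method: str = "approx",
    *,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """Lower 95% credibility bound of the information component.

    ``method="approx"`` uses the closed-form penalty expansion;
    ``method="mc"`` takes the 2.5th percentile of ``log2(G/(E+0.5))`` over
    ``n_draws`` gamma draws ``G ~ Gamma(a+0.5, rate=1)`` and serves as the
    independent validation oracle for the approximation.
    """
    if t.n == 0:
        raise ValueError("IC025 undefined for an empty table")
    if method == "approx":
        s = t.a + 0.5
        return ic(t) - 3.3 * s ** (-0.5) - 2.4 * s ** (-1.5)
    if method == "mc":
        rng = np.random.default_rng(seed)
        g = rng.gamma(shape=t.a + 0.5, scale=1.0, size=n_draws)
        return float(np.percentile(np.log2(g / (t.expected + 0.5)), 2.5))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the composite signal definition.

    ``ic025_strict`` selects a strict ``IC025 > ic025_min`` comparison
    (default) versus ``>=``.
    """

    min_reports: int = 3
    prr_min: float = 2.0
    ror_min: float = 2.0
    ic025_min: float = 0.0
    ic025_strict: bool = True

    def __post_init__(self) -> None:
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")
        for v in (self.prr_min, self.ror_min, self.ic025_min):
            if not math.isfinite(v):
                raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class DisproportionalityResult:
    """All statistics for one drug-event pair, plus the signal flag."""

    drug: str
    event_pt: str
    table: ContingencyTable
    prr: float | None
    ror: float | None
    ic: float
    ic025: float
    is_signal: bool

    @property
    def n_reports(self) -> int:
        """Number of co-reports of the pair (cell ``a``)."""
        return self.table.a


def evaluate(
    t: ContingencyTable,
    criteria: SignalCriteria = SignalCriteria(),
    *,
    drug: str = "",
    event_pt: str = "",
) -> DisproportionalityResult:
    """Compute all statistics for one table and apply the signal criterion.

    Undefined PRR or ROR fails its threshold, so a pair can never be
    flagged through a zero denominator.
    """
    p, r = prr(t), ror(t)
    i = ic(t)
    i025 = ic025(t, "approx")
    ic_ok = i025 > criteria.ic025_min if criteria.ic025_strict else i025 >= criteria.ic025_min
    flag = (
        t.a >= criteria.min_reports
        and p is not None
        and p >= criteria.prr_min
        and r is not None
        and r >= criteria.ror_min
        and ic_ok
    )
    return DisproportionalityResult(drug, event_pt, t, p, r, i, i025, flag)


def screen(
    dataset: Dataset,
    target_drugs: Sequence[str],
    criteria: SignalCriteria = SignalCriteria(),
    background: str = "all_reports",
    comparator_drugs: Iterable[str] | None = None,
) -> list[DisproportionalityResult]:
    """Evaluate every (target drug, co-reported PT) pair in the dataset.

    Results are ordered by drug, then descending co-report count, then PT,
    so repeated runs are reproducible.  An empty target list yields an
    empty result.
    """
    if not target_drugs:
        return []
    results = [
        evaluate(t, criteria, drug=drug, event_pt=pt)
        for drug, pt, t in all_pair_tables(
            dataset, target_drugs, background, comparator_drugs
        )
    ]
    results.sort(key=lambda r: (r.drug, -r.n_reports, r.event_pt))
    return results


def results_frame(results: Iterable[DisproportionalityResult]) -> pd.DataFrame:
    """Tabulate results for CSV export (the canonical screening output)."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "event_pt": r.event_pt,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "prr": r.prr,
                "ror": r.ror,
                "ic": r.ic,
                "ic025": r.ic025,
                "is_signal": r.is_signal,
            }
            for r in results
        ],
        columns=[
            "drug", "event_pt", "a", "b", "c", "d",
            "prr", "ror", "ic", "ic025", "is_signal",
        ],
    )
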