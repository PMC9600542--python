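"""Two-by-two contingency tables for drug-event disproportionality.

For a target drug and a specific adverse event, reports in the background
universe partition into the four classic cells:

====  =========================================
cell  reports listing
====  =========================================
a     the target drug and the specific event
b     the target drug, but not the event
c     the event, but not the target drug
d     neither
====  =========================================

The counting unit is the report (case): a report contributes to exactly one
cell, regardless of how many drugs or events it lists.  The background is
either the whole dataset (``all_reports``, the default) or only reports
listing at least one drug from a comparator set (``listed_drugs_only``),
for analyses framed against a restricted drug class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .model import Dataset, ICSRReport, normalize_term

__all__ = ["ContingencyTable", "build_table", "all_pair_tables"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts ``a, b, c, d`` plus derived margins.

    ``n_drug = a + b`` reports list the target drug, ``n_event = a + c``
    list the event, and ``expected = n_drug * n_event / n`` is the count
    expected under independent reporting.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected ``a`` under independence: ``n_drug * n_event / n``."""
        if self.n == 0:
            return 0.0
        return self.n_drug * self.n_event / self.n

    @property
    def degenerate(self) -> bool:
        """True when the drug or the event is absent from the background."""
        return self.n_drug == 0 or self.n_event == 0

    def transpose(self) -> "ContingencyTable":
        """Swap the roles of drug and event (``b`` and ``c`` exchange)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


def _background(
    dataset: Dataset,
    background: str,
    comparator_drugs: Iterable[str] | None,
) -> list[ICSRReport]:
    if background == "all_reports":
        return dataset.reports
    if background == "listed_drugs_only":
        if not comparator_drugs:
            raise ValueError("listed_drugs_only background requires comparator_drugs")
        comp = frozenset(normalize_term(d) for d in comparator_drugs)
        return [r for r in dataset.reports if r.drugs & comp]
    raise ValueError(f"unknown background {background!r}")


def build_table(
    dataset: Dataset,
    drug: str,
    event_pt: str,
    background: str = "all_reports",
    comparator_drugs: Iterable[str] | None = None,
) -> ContingencyTable:
    """Build the 2x2 table for one (drug, event) pair.

    A drug or event absent from the universe yields a degenerate table
    (``n_drug == 0`` or ``n_event == 0``), not an error; downstream
    statistics treat it as undefined.
    """
    if not dataset.reports:
        raise ValueError("dataset is empty")
    drug = normalize_term(drug)
    event_pt = normalize_term(event_pt)
    universe = _background(dataset, background, comparator_drugs)
    a = b = c = d = 0
    for r in universe:
        has_drug = drug in r.drugs
        has_event = event_pt in r.events
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def all_pair_tables(
    dataset: Dataset,
    target_drugs: Sequence[str],
    background: str = "all_reports",
    comparator_drugs: Iterable[str] | None = None,
) -> Iterator[tuple[str, str, ContingencyTable]]:
    """Yield one table per (target drug, PT co-reported with that drug).

    PTs never co-reported with a target drug are skipped (``a == 0`` can
    contribute no signal).  Pairs are yielded in deterministic
    (drug, PT) sorted order; counting is vectorized over report-by-drug
    and report-by-event indicator matrices.
    """
    if not target_drugs:
        raise ValueError("target_drugs must be non-empty")
    targets = [normalize_term(t) for t in target_drugs]
    universe = _background(dataset, background, comparator_drugs)
    if not universe:
        return

    events = sorted(set().union(*(r.events for r in universe)))
    event_ix = {e: j for j, e in enumerate(events)}
    n = len(universe)
    ev_mat = np.zeros((n, len(events)), dtype=bool)
    for i, r in enumerate(universe):
        for e in r.events:
            ev_mat[i, event_ix[e]] = True
    n_event = ev_mat.sum(axis=0)

    for drug in sorted(set(targets)):
        drug_mask = np.fromiter(
            (drug in r.drugs for r in universe), dtype=bool, count=n
        )
        n_drug = int(drug_mask.sum())
        a_vec = ev_mat[drug_mask].sum(axis=0)
        for j, pt in enumerate(events):
            a = int(a_vec[j])
            if a == 0:
                continue
            b = n_drug - a
            c = int(n_event[j]) - a
            d = n - n_drug - c
            yield drug, pt, ContingencyTable(a, b, c, d)
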