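"""Domain types for individual case safety reports (ICSRs) and a
MedDRA-like adverse-event hierarchy, plus CSV readers/writers.

An ICSR is one spontaneous report of suspected adverse drug reactions for a
single patient: one or more drugs, one or more adverse-event preferred terms
(PTs), and demographic attributes (continent, age band, sex, seriousness,
notifier).  PTs roll up to exactly one *primary* system organ class (SOC)
through a :class:`MedDRADictionary`; multiaxial secondary SOC links are not
represented.

The interchange format is plain UTF-8 CSV with a header (RFC-4180 quoting).
Two dialects exist:

``long``
    one row per report x drug x event, demographic columns repeated
    (columns: ``report_id, drug, event_pt, continent, age_group, sex,
    serious, notifier``);
``paired``
    a reports table holding one row of demographics per report plus a
    link table with ``report_id, drug, event_pt`` rows.
"""

from __future__ import annotations

import io
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

__all__ = [
    "CONTINENTS",
    "AGE_GROUPS",
    "SEXES",
    "SERIOUSNESS",
    "NOTIFIERS",
    "ICSR_COLUMNS",
    "SchemaError",
    "IntegrityError",
    "EmptyDatasetError",
    "ICSRReport",
    "SOCRecord",
    "MedDRADictionary",
    "Dataset",
    "normalize_term",
    "read_icsr_table",
    "write_icsr_table",
    "read_meddra_dictionary",
    "toy_dictionary",
]

# Closed category sets.  Age bands reproduce the reporting-database
# convention verbatim, including the adjoining "45-65"/"65-74" labels
# (boundary age 65 is assigned to "45-65 years" by the generator).
CONTINENTS = ("Africa", "Americas", "Asia", "Europe", "Oceania", "Unknown")
AGE_GROUPS = (
    "0–27 days",
    "28 days to 23 months",
    "2–11 years",
    "12–17 years",
    "18–44 years",
    "45–65 years",
    "65–74 years",
    "≥75 years",
    "Unknown",
)
SEXES = ("Male", "Female", "Unknown")
SERIOUSNESS = ("Yes", "No", "Unknown")
NOTIFIERS = (
    "Physician",
    "Pharmacist",
    "Other Health Professional",
    "Consumer/Non-Health Professional",
    "Lawyer",
    "Unknown",
)

DEMOGRAPHIC_FIELDS: dict[str, tuple[str, ...]] = {
    "continent": CONTINENTS,
    "age_group": AGE_GROUPS,
    "sex": SEXES,
    "serious": SERIOUSNESS,
    "notifier": NOTIFIERS,
}

ICSR_COLUMNS = (
    "report_id",
    "drug",
    "event_pt",
    "continent",
    "age_group",
    "sex",
    "serious",
    "notifier",
)


class SchemaError(ValueError):
    """A required column is missing or a value falls outside its category set."""


class IntegrityError(ValueError):
    """Rows contradict each other (conflicting demographics or SOC mappings)."""


class EmptyDatasetError(ValueError):
    """The source contains no reports."""


def normalize_term(s: str) -> str:
    """Canonicalize a drug name or PT: Unicode NFC + surrounding-whitespace strip.

    Matching elsewhere in the package is exact-string on the normalized
    form; no fuzzy matching is performed.
    """
    return unicodedata.normalize("NFC", str(s)).strip()


def _check_category(field_name: str, value: str, *, lenient: bool) -> str:
    allowed = DEMOGRAPHIC_FIELDS[field_name]
    value = normalize_term(value)
    if value in allowed:
        return value
    if lenient:
        return "Unknown"
    raise SchemaError(
        f"value {value!r} for field {field_name!r} is not one of {allowed}"
    )


@dataclass(frozen=True)
class ICSRReport:
    """One spontaneous report: drug set, event-PT set, and demographics.

    ``drugs`` and ``events`` are non-empty frozensets (duplicates within a
    report collapse); every demographic attribute is one of the declared
    categories.
    """

    report_id: str
    drugs: frozenset[str]
    events: frozenset[str]
    continent: str = "Unknown"
    age_group: str = "Unknown"
    sex: str = "Unknown"
    serious: str = "Unknown"
    notifier: str = "Unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(map(normalize_term, self.drugs)))
        object.__setattr__(self, "events", frozenset(map(normalize_term, self.events)))
        if not self.drugs:
            raise ValueError(f"report {self.report_id!r}: drug set is empty")
        if not self.events:
            raise ValueError(f"report {self.report_id!r}: event set is empty")
        for name in DEMOGRAPHIC_FIELDS:
            object.__setattr__(
                self, name, _check_category(name, getattr(self, name), lenient=False)
            )

    @property
    def demographics(self) -> tuple[str, str, str, str, str]:
        return (self.continent, self.age_group, self.sex, self.serious, self.notifier)

    @classmethod
    def _trusted(
        cls,
        report_id: str,
        drugs: frozenset[str],
        events: frozenset[str],
        continent: str,
        age_group: str,
        sex: str,
        serious: str,
        notifier: str,
    ) -> "ICSRReport":
        """Construct without re-validating; inputs must already be
        normalized, non-empty and within the category sets (bulk fast path
        for the synthetic generator)."""
        self = object.__new__(cls)
        sa = object.__setattr__
        sa(self, "report_id", report_id)
        sa(self, "drugs", drugs)
        sa(self, "events", events)
        sa(self, "continent", continent)
        sa(self, "age_group", age_group)
        sa(self, "sex", sex)
        sa(self, "serious", serious)
        sa(self, "notifier", notifier)
        return self


@dataclass(frozen=True)
class SOCRecord:
    """Hierarchy record for one PT: its primary SOC and optional HLT/HLGT."""

    primary_soc: str
    hlt: str | None = None
    hlgt: str | None = None


class MedDRADictionary:
    """PT -> primary-SOC mapping with a uniqueness guarantee.

    Each PT maps to exactly one primary SOC.  Lookups are case-preserving
    with a case-insensitive fallback: an exact (NFC-normalized) match wins;
    otherwise a casefolded match is used if it is unambiguous.
    """

    def __init__(self, entries: Mapping[str, SOCRecord]):
        self._entries: dict[str, SOCRecord] = {}
        for pt, rec in entries.items():
            pt = normalize_term(pt)
            if not rec.primary_soc:
                raise IntegrityError(f"PT {pt!r} has an empty primary SOC")
            if pt in self._entries and self._entries[pt] != rec:
                raise IntegrityError(
                    f"PT {pt!r} maps to both {self._entries[pt].primary_soc!r} "
                    f"and {rec.primary_soc!r}"
                )
            self._entries[pt] = rec
        self._folded: dict[str, str | None] = {}
        for pt in self._entries:
            key = pt.casefold()
            # ambiguous casefolded keys fall back to exact-only lookup
            self._folded[key] = pt if key not in self._folded else None

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pt: str) -> bool:
        return self._resolve(pt) is not None

    def _resolve(self, pt: str) -> str | None:
        pt = normalize_term(pt)
        if pt in self._entries:
            return pt
        return self._folded.get(pt.casefold())

    def lookup(self, pt: str) -> SOCRecord:
        key = self._resolve(pt)
        if key is None:
            raise KeyError(pt)
        return self._entries[key]

    def primary_soc(self, pt: str) -> str:
        return self.lookup(pt).primary_soc

    @property
    def preferred_terms(self) -> tuple[str, ...]:
        return tuple(sorted(self._entries))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MedDRADictionary):
            return NotImplemented
        return self._entries == other._entries


@dataclass
class Dataset:
    """A collection of reports plus the hierarchy dictionary.

    Event PTs that do not resolve in the dictionary are never silently
    dropped; they are surfaced through :attr:`unmapped_events`.
    """

    reports: list[ICSRReport]
    dictionary: MedDRADictionary = field(
        default_factory=lambda: MedDRADictionary({})
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise IntegrityError(f"duplicate report_id {r.report_id!r}")
            seen.add(r.report_id)

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted(set().union(*(r.drugs for r in self.reports))
                            if self.reports else set()))

    @property
    def events(self) -> tuple[str, ...]:
        return tuple(sorted(set().union(*(r.events for r in self.reports))
                            if self.reports else set()))

    @property
    def unmapped_events(self) -> frozenset[str]:
        """PTs appearing in reports that do not resolve in the dictionary."""
        return frozenset(pt for pt in self.events if pt not in self.dictionary)

    def equals(self, other: "Dataset") -> bool:
        """Order-insensitive equality on reports and dictionary."""
        key = lambda r: r.report_id
        return (
            sorted(self.reports, key=key) == sorted(other.reports, key=key)
            and self.dictionary == other.dictionary
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _reports_from_frames(
    demo: pd.DataFrame, links: pd.DataFrame, *, lenient: bool
) -> list[ICSRReport]:
    """Assemble reports from a per-row demographics frame and a link frame.

    ``demo`` may repeat report_ids (long dialect); repeated rows must agree.
    """
    demo = demo.copy()
    for col in ("report_id", *DEMOGRAPHIC_FIELDS):
        demo[col] = demo[col].astype(str)
    conflicts = demo.groupby("report_id", sort=False).nunique()
    bad = conflicts[(conflicts > 1).any(axis=1)]
    if len(bad):
        rid = bad.index[0]
        cols = list(bad.columns[(bad.iloc[0] > 1)])
        raise IntegrityError(
            f"report_id {rid!r} has conflicting demographics in column(s) {cols}"
        )
    demo = demo.drop_duplicates("report_id").set_index("report_id")

    grouped = links.groupby("report_id", sort=False)
    reports = []
    for rid, grp in grouped:
        rid = str(rid)
        row = demo.loc[rid]
        fields = {
            name: _check_category(name, row[name], lenient=lenient)
            for name in DEMOGRAPHIC_FIELDS
        }
        drugs = frozenset(normalize_term(d) for d in grp["drug"].astype(str))
        events = frozenset(normalize_term(e) for e in grp["event_pt"].astype(str))
        reports.append(ICSRReport(rid, drugs, events, **fields))
    return reports


def read_icsr_table(
    source: str | Path | IO[str],
    dialect: str = "long",
    *,
    links: str | Path | IO[str] | None = None,
    dictionary: MedDRADictionary | None = None,
    lenient: bool = False,
) -> Dataset:
    """Read an ICSR extract into a :class:`Dataset`.

    Parameters
    ----------
    source
        Path or text stream.  For ``dialect="long"`` this is the single
        long-format table; for ``dialect="paired"`` it is the reports
        (demographics) table and ``links`` must supply the
        report-drug-event link table.
    lenient
        If true, demographic strings outside the declared categories map to
        ``"Unknown"``; otherwise they raise :class:`SchemaError`.

    Raises
    ------
    SchemaError, IntegrityError, EmptyDatasetError
    """
    if dialect not in ("long", "paired"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if dialect == "long":
        _require_columns(df, ICSR_COLUMNS, "icsr table (long)")
        if df.empty:
            raise EmptyDatasetError("ICSR table contains no rows")
        reports = _reports_from_frames(
            df[["report_id", *DEMOGRAPHIC_FIELDS]], df, lenient=lenient
        )
    else:
        if links is None:
            raise ValueError("paired dialect requires a links table")
        _require_columns(df, ("report_id", *DEMOGRAPHIC_FIELDS), "reports table")
        link_df = pd.read_csv(links, dtype=str, keep_default_na=False)
        _require_columns(link_df, ("report_id", "drug", "event_pt"), "link table")
        if df.empty or link_df.empty:
            raise EmptyDatasetError("paired ICSR tables contain no rows")
        orphans = set(link_df["report_id"]) - set(df["report_id"])
        if orphans:
            raise IntegrityError(
                f"link rows reference unknown report_id(s): {sorted(orphans)[:5]}"
            )
        reports = _reports_from_frames(df, link_df, lenient=lenient)
    return Dataset(reports, dictionary or MedDRADictionary({}))


def write_icsr_table(
    dataset: Dataset,
    sink: str | Path | IO[str],
    dialect: str = "long",
    *,
    links_sink: str | Path | IO[str] | None = None,
) -> None:
    """Write a Dataset as CSV; inverse of :func:`read_icsr_table` up to row order.

    Rows are emitted sorted by (report_id, drug, event_pt) so identical
    datasets serialize byte-identically.
    """
    if dialect not in ("long", "paired"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    for r in sorted(dataset.reports, key=lambda r: r.report_id):
        for drug in sorted(r.drugs):
            for pt in sorted(r.events):
                rows.append((r.report_id, drug, pt, *r.demographics))
    long_df = pd.DataFrame(rows, columns=ICSR_COLUMNS)
    if dialect == "long":
        long_df.to_csv(sink, index=False, lineterminator="\n")
        return
    if links_sink is None:
        raise ValueError("paired dialect requires links_sink")
    demo = long_df[["report_id", *DEMOGRAPHIC_FIELDS]].drop_duplicates("report_id")
    demo.to_csv(sink, index=False, lineterminator="\n")
    long_df[["report_id", "drug", "event_pt"]].to_csv(
        links_sink, index=False, lineterminator="\n"
    )


def read_meddra_dictionary(source: str | Path | IO[str]) -> MedDRADictionary:
    """Read a ``pt, primary_soc[, hlt, hlgt]`` CSV into a dictionary.

    Duplicate PT rows with an identical mapping collapse to one entry;
    conflicting mappings raise :class:`IntegrityError`.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    _require_columns(df, ("pt", "primary_soc"), "dictionary table")
    entries: dict[str, SOCRecord] = {}
    for row in df.itertuples(index=False):
        pt = normalize_term(row.pt)
        rec = SOCRecord(
            primary_soc=normalize_term(row.primary_soc),
            hlt=normalize_term(row.hlt) or None if hasattr(row, "hlt") else None,
            hlgt=normalize_term(row.hlgt) or None if hasattr(row, "hlgt") else None,
        )
        if pt in entries and entries[pt] != rec:
            raise IntegrityError(
                f"PT {pt!r} maps to both {entries[pt].primary_soc!r} "
                f"and {rec.primary_soc!r}"
            )
        entries[pt] = rec
    return MedDRADictionary(entries)


def toy_dictionary() -> MedDRADictionary:
    """The shipped toy hierarchy fixture (see ``data/meddra_toy.csv``).

    Covers the ear-and-labyrinth PTs and eosinophil-related PTs used in the
    worked examples plus filler PTs across several SOCs.  It is a synthetic
    stand-in: real MedDRA content is licensed and not redistributable.
    """
    path = Path(__file__).parent / "data" / "meddra_toy.csv"
    return read_meddra_dictionary(path)
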