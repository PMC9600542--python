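"""Synthetic spontaneous-reporting databases with known ground truth.

Real pharmacovigilance extracts are access-restricted, so every stage of
the pipeline is exercised against simulated ICSRs whose drug-event
associations are planted and therefore known exactly.

Generative model, per report:

* each catalog drug is listed independently with its marginal probability
  (re-drawn until at least one drug is listed);
* each catalog PT is included independently with its baseline probability,
  multiplied by the *maximum* planted relative reporting ratio ``rho``
  across the report's listed drugs when any of them has a planted
  ``(drug, PT)`` entry (product capped at 1); re-drawn until at least one
  event is included.  ``rho`` is therefore the in-drug versus baseline
  reporting-rate ratio the screening stage should recover;
* demographics are drawn independently of drugs and events from per-field
  categorical marginals (the defaults reproduce the demographic mix of a
  large real biologics-for-asthma extract: ~78% Americas, ~65% female,
  ~51% serious).

Identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    DEMOGRAPHIC_FIELDS,
    Dataset,
    ICSRReport,
    MedDRADictionary,
    normalize_term,
    toy_dictionary,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ConfigurationError",
    "demographic_defaults",
    "generate",
    "default_config",
]


class ConfigurationError(ValueError):
    """The generator configuration is invalid or infeasible."""


# Demographic mix of the reference omalizumab extract (printed column
# percentages / 100, before renormalization).  Categories omitted here
# (e.g., continent Unknown) have probability 0.
_REFERENCE_MARGINALS: dict[str, dict[str, float]] = {
    "continent": {
        "Africa": 0.0044,
        "Americas": 0.7823,
        "Asia": 0.0405,
        "Europe": 0.1655,
        "Oceania": 0.0074,
    },
    "age_group": {
        "0–27 days": 0.0011,
        "28 days to 23 months": 0.0011,
        "2–11 years": 0.0130,
        "12–17 years": 0.0327,
        "18–44 years": 0.1751,
        "45–65 years": 0.2205,
        "65–74 years": 0.0602,
        "≥75 years": 0.0257,
        "Unknown": 0.4705,
    },
    "sex": {"Male": 0.2722, "Female": 0.6462, "Unknown": 0.0816},
    "serious": {"Yes": 0.5087, "No": 0.4700, "Unknown": 0.0213},
    "notifier": {
        "Physician": 0.4334,
        "Pharmacist": 0.0324,
        "Other Health Professional": 0.1957,
        "Consumer/Non-Health Professional": 0.2996,
        "Lawyer": 0.0002,
        "Unknown": 0.0386,
    },
}


def demographic_defaults(renormalize: bool = True) -> dict[str, dict[str, float]]:
    """Default per-field demographic marginals.

    With ``renormalize=True`` (the default) each field's probabilities are
    scaled to sum to exactly 1; with ``renormalize=False`` the raw
    reference proportions are returned (they sum to 1 only up to the
    rounding of the printed percentages they derive from).
    """
    out = {}
    for fname, probs in _REFERENCE_MARGINALS.items():
        if renormalize:
            total = sum(probs.values())
            out[fname] = {k: v / total for k, v in probs.items()}
        else:
            out[fname] = dict(probs)
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the report generator.

    Parameters
    ----------
    n_reports
        Number of reports to generate.
    drug_catalog
        ``(drug name, marginal probability a report lists it)`` pairs.
    event_catalog
        ``(PT, baseline inclusion probability)`` pairs.
    planted_rr
        ``(drug, PT) -> rho`` relative reporting ratios (``rho >= 0``); a
        pair with ``rho >= 2`` is a planted association the screening
        stage should flag.
    demographic_marginals
        Per-field category probabilities; defaults to
        :func:`demographic_defaults`.
    mean_events_per_report
        Optional target for the expected number of events per report
        (before the non-empty redraw); when set, baseline probabilities
        are rescaled proportionally to meet it.
    seed
        Seed of the dataset-level random stream.
    """

    n_reports: int
    drug_catalog: tuple[tuple[str, float], ...]
    event_catalog: tuple[tuple[str, float], ...]
    planted_rr: Mapping[tuple[str, str], float] = field(default_factory=dict)
    demographic_marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=demographic_defaults
    )
    mean_events_per_report: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be positive")
        object.__setattr__(
            self,
            "drug_catalog",
            tuple((normalize_term(d), float(p)) for d, p in self.drug_catalog),
        )
        object.__setattr__(
            self,
            "event_catalog",
            tuple((normalize_term(e), float(p)) for e, p in self.event_catalog),
        )
        if not self.drug_catalog or not self.event_catalog:
            raise ConfigurationError("drug and event catalogs must be non-empty")
        for name, p in (*self.drug_catalog, *self.event_catalog):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability for {name!r} outside [0, 1]: {p}")
        if all(p == 0 for _, p in self.drug_catalog) or all(
            p == 0 for _, p in self.event_catalog
        ):
            raise ConfigurationError("all-zero catalog probabilities are infeasible")
        drugs = {d for d, _ in self.drug_catalog}
        events = {e for e, _ in self.event_catalog}
        if len(drugs) < len(self.drug_catalog) or len(events) < len(self.event_catalog):
            raise ConfigurationError("duplicate catalog entries")
        planted = {}
        for (d, e), rho in dict(self.planted_rr).items():
            d, e = normalize_term(d), normalize_term(e)
            if d not in drugs:
                raise ConfigurationError(f"planted drug {d!r} not in drug catalog")
            if e not in events:
                raise ConfigurationError(f"planted PT {e!r} not in event catalog")
            if rho < 0:
                raise ConfigurationError(f"planted rho for ({d!r}, {e!r}) is negative")
            planted[(d, e)] = float(rho)
        object.__setattr__(self, "planted_rr", planted)
        for fname, probs in self.demographic_marginals.items():
            if fname not in DEMOGRAPHIC_FIELDS:
                raise ConfigurationError(f"unknown demographic field {fname!r}")
            bad = set(probs) - set(DEMOGRAPHIC_FIELDS[fname])
            if bad:
                raise ConfigurationError(f"unknown {fname} categories {sorted(bad)}")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"negative probability in {fname} marginal")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{fname} marginal does not sum to 1")
        if self.mean_events_per_report is not None and self.mean_events_per_report <= 0:
            raise ConfigurationError("mean_events_per_report must be positive")

    # -- YAML/dict round-trip used by the CLI ------------------------------

    def to_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "drug_catalog": {d: p for d, p in self.drug_catalog},
            "event_catalog": {e: p for e, p in self.event_catalog},
            "planted_rr": [
                {"drug": d, "event_pt": e, "rho": r}
                for (d, e), r in sorted(self.planted_rr.items())
            ],
            "demographic_marginals": {
                f: dict(m) for f, m in self.demographic_marginals.items()
            },
            "mean_events_per_report": self.mean_events_per_report,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        planted = {
            (row["drug"], row["event_pt"]): float(row["rho"])
            for row in d.get("planted_rr", [])
        }
        kwargs = {}
        if "demographic_marginals" in d:
            kwargs["demographic_marginals"] = d["demographic_marginals"]
        return cls(
            n_reports=int(d["n_reports"]),
            drug_catalog=tuple(d["drug_catalog"].items()),
            event_catalog=tuple(d["event_catalog"].items()),
            planted_rr=planted,
            mean_events_per_report=d.get("mean_events_per_report"),
            seed=int(d.get("seed", 0)),
            **kwargs,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Labels of the planted associations for recovery evaluation.

    ``planted_pairs`` holds the catalog pairs with ``rho >= 2``;
    ``null_pairs`` holds every other (drug, PT) catalog pair.
    """

    planted_pairs: frozenset[tuple[str, str]]
    null_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.planted_pairs & self.null_pairs:
            raise ValueError("planted and null pairs overlap")


def _redraw_until_nonempty(
    rng: np.random.Generator, mat: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Re-draw all-empty rows of a Bernoulli indicator matrix in place.

    ``probs`` is either a 1-D vector (shared across rows) or the per-row
    probability matrix.
    """
    while True:
        empty = ~mat.any(axis=1)
        if not empty.any():
            return mat
        p = probs if probs.ndim == 1 else probs[empty]
        mat[empty] = rng.random((int(empty.sum()), mat.shape[1])) < p


def generate(
    config: SyntheticConfig,
    dictionary: MedDRADictionary | None = None,
) -> tuple[Dataset, GroundTruth]:
    """Generate a synthetic reporting database and its ground truth.

    Returns exactly ``config.n_reports`` reports with ids ``R0000001`` ...;
    the run is fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_names = [d for d, _ in config.drug_catalog]
    drug_p = np.array([p for _, p in config.drug_catalog])
    event_names = [e for e, _ in config.event_catalog]
    event_p = np.array([p for _, p in config.event_catalog])
    if config.mean_events_per_report is not None:
        event_p = np.minimum(1.0, event_p * config.mean_events_per_report / event_p.sum())

    drug_mat = rng.random((n, len(drug_names))) < drug_p
    _redraw_until_nonempty(rng, drug_mat, drug_p)

    # Effective per-report event probabilities: baseline scaled by the max
    # planted rho across the report's drugs (only where a rho is planted).
    eff = np.broadcast_to(event_p, (n, len(event_names))).copy()
    if config.planted_rr:
        mult = np.full((n, len(event_names)), -1.0)
        d_ix = {d: i for i, d in enumerate(drug_names)}
        e_ix = {e: j for j, e in enumerate(event_names)}
        for (d, e), rho in config.planted_rr.items():
            rows = drug_mat[:, d_ix[d]]
            j = e_ix[e]
            mult[rows, j] = np.maximum(mult[rows, j], rho)
        planted = mult >= 0
        eff[planted] = np.minimum(1.0, eff[planted] * mult[planted])
    event_mat = rng.random((n, len(event_names))) < eff
    _redraw_until_nonempty(rng, event_mat, eff)

    demo_cols: list[list[str]] = []
    for fname in DEMOGRAPHIC_FIELDS:
        probs = config.demographic_marginals[fname]
        cats = list(probs)
        idx = rng.choice(len(cats), size=n, p=list(probs.values()))
        demo_cols.append([cats[k] for k in idx])

    # Validation happens once on the catalogs, so reports are assembled
    # through the trusted bulk constructor; repeated drug/event combinations
    # share one frozenset via the combo caches.
    def _sets(mat: np.ndarray, names: list[str]) -> list[frozenset[str]]:
        rows, cols = np.nonzero(mat)
        bounds = np.searchsorted(rows, np.arange(n + 1))
        cache: dict[tuple, frozenset[str]] = {}
        out = []
        for i in range(n):
            key = tuple(cols[bounds[i]:bounds[i + 1]])
            fs = cache.get(key)
            if fs is None:
                fs = cache[key] = frozenset(names[k] for k in key)
            out.append(fs)
        return out

    drug_sets = _sets(drug_mat, drug_names)
    event_sets = _sets(event_mat, event_names)
    width = max(7, len(str(n)))
    reports = [
        ICSRReport._trusted(
            f"R{i + 1:0{width}d}", drug_sets[i], event_sets[i],
            demo_cols[0][i], demo_cols[1][i], demo_cols[2][i],
            demo_cols[3][i], demo_cols[4][i],
        )
        for i in range(n)
    ]

    planted_pairs = frozenset(
        pair for pair, rho in config.planted_rr.items() if rho >= 2
    )
    all_pairs = {(d, e) for d in drug_names for e in event_names}
    truth = GroundTruth(
        planted_pairs=planted_pairs,
        null_pairs=frozenset(all_pairs - planted_pairs),
    )
    if dictionary is None:
        dictionary = toy_dictionary()
    return Dataset(reports, dictionary), truth


# ---------------------------------------------------------------------------
# Default study-like configuration


def default_config(n_reports: int = 50_000, seed: int = 0) -> SyntheticConfig:
    """A ready-made configuration emulating a biologics-for-asthma extract.

    Five monoclonal antibodies with marginal listing probabilities
    proportional to their real report shares, a PT catalog drawn from the
    toy hierarchy with baselines spanning common respiratory complaints
    down to rare ear disorders, and planted ear/eosinophil associations for
    the IgE-blocking antibody (plus three weaker ear associations for the
    anti-IL5 antibody) at relative reporting ratios in the range the
    screening stage reports for such signals.
    """
    drug_catalog = (
        ("omalizumab", 0.516),
        ("mepolizumab", 0.116),
        ("benralizumab", 0.038),
        ("reslizumab", 0.005),
        ("dupilumab", 0.325),
    )
    ear = {
        "Ear pain": 0.0030, "Ear discomfort": 0.0015, "Otorrhoea": 0.0004,
        "Ear pruritus": 0.0006, "Ear congestion": 0.0005, "Ear swelling": 0.0005,
        "Ear disorder": 0.0012, "Tympanic membrane perforation": 0.0003,
        "Deafness unilateral": 0.0010, "Vertigo positional": 0.0004,
        "Middle ear effusion": 0.0004, "Meniere's disease": 0.0004,
        "Cerumen impaction": 0.0002, "Tympanic membrane disorder": 0.0001,
        "Tympanic membrane scarring": 0.0001, "Eustachian tube obstruction": 0.0001,
        "Eustachian tube disorder": 0.0001,
    }
    eos = {
        "Eosinophilic granulomatosis with polyangiitis": 0.0004,
        "Eosinophilia": 0.0060, "Eosinophil count increase": 0.0012,
        "Eosinophilic pneumonia": 0.0005, "Eosinophilic oesophagitis": 0.0002,
        "Hypereosinophilic syndrome": 0.0001,
        "Eosinophilic pneumonia chronic": 0.0001,
        "Eosinophil count abnormal": 0.0002, "Eosinophilic bronchitis": 0.0002,
    }
    filler = {
        "Asthma": 0.0800, "Cough": 0.0500, "Dyspnoea": 0.0600, "Wheezing": 0.0250,
        "Fatigue": 0.0400, "Pyrexia": 0.0200, "Injection site reaction": 0.0350,
        "Chest pain": 0.0150, "Headache": 0.0500, "Dizziness": 0.0250,
        "Migraine": 0.0080, "Rash": 0.0300, "Urticaria": 0.0200, "Pruritus": 0.0250,
        "Alopecia": 0.0100, "Nausea": 0.0300, "Vomiting": 0.0150,
        "Diarrhoea": 0.0150, "Abdominal pain": 0.0120, "Arthralgia": 0.0250,
        "Myalgia": 0.0150, "Back pain": 0.0120, "Anaphylactic reaction": 0.0080,
        "Hypersensitivity": 0.0150, "Nasopharyngitis": 0.0250, "Sinusitis": 0.0120,
        "Otitis media": 0.0030,
    }
    event_catalog = tuple({**ear, **eos, **filler}.items())
    planted: dict[tuple[str, str], float] = {}
    omalizumab_rr = {
        "Ear pain": 6.3, "Ear discomfort": 7.1, "Otorrhoea": 17.2,
        "Ear pruritus": 8.2, "Ear congestion": 8.6, "Ear swelling": 7.2,
        "Ear disorder": 2.3, "Tympanic membrane perforation": 7.8,
        "Deafness unilateral": 2.2, "Vertigo positional": 4.6,
        "Middle ear effusion": 3.9, "Meniere's disease": 4.0,
        "Cerumen impaction": 4.7, "Tympanic membrane disorder": 10.7,
        "Tympanic membrane scarring": 20.0, "Eustachian tube obstruction": 17.8,
        "Eustachian tube disorder": 13.1,
        "Eosinophilic granulomatosis with polyangiitis": 30.0,
        "Eosinophilia": 2.4, "Eosinophil count increase": 12.3,
        "Eosinophilic pneumonia": 6.0, "Eosinophilic oesophagitis": 27.8,
        "Hypereosinophilic syndrome": 41.7,
        "Eosinophilic pneumonia chronic": 50.9, "Eosinophil count abnormal": 14.5,
    }
    for pt, rho in omalizumab_rr.items():
        planted[("omalizumab", pt)] = rho
    for pt, rho in {"Ear pain": 3.5, "Ear disorder": 5.1, "Ear discomfort": 3.3}.items():
        planted[("mepolizumab", pt)] = rho
    return SyntheticConfig(
        n_reports=n_reports,
        drug_catalog=drug_catalog,
        event_catalog=event_catalog,
        planted_rr=planted,
        seed=seed,
    )
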