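from pathlib import Path

import pytest

from pvsignal.contingency import ContingencyTable
from pvsignal.disproportionality import DisproportionalityResult
from pvsignal.model import Dataset, ICSRReport, toy_dictionary
from pvsignal.synth import default_config, generate

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_dict():
    return toy_dictionary()


@pytest.fixture(scope="session")
def fixture_csv() -> Path:
    return DATA_DIR / "icsr_fixture.csv"


@pytest.fixture
def tiny_dataset(toy_dict) -> Dataset:
    """Four reports: {D,E}, {D}, {E}, {X} with D=omalizumab, E=Ear pain."""
    mk = lambda rid, drugs, events: ICSRReport(rid, frozenset(drugs), frozenset(events))
    return Dataset(
        [
            mk("R1", {"omalizumab"}, {"Ear pain"}),
            mk("R2", {"omalizumab"}, {"Headache"}),
            mk("R3", {"dupilumab"}, {"Ear pain"}),
            mk("R4", {"dupilumab"}, {"Rash"}),
        ],
        toy_dict,
    )


@pytest.fixture(scope="session")
def synth_dataset():
    """A moderate synthetic database shared across read-only tests."""
    return generate(default_config(n_reports=5000, seed=11))


def make_result(
    a: int, b: int, c: int, d: int, *, drug="drugX", pt="eventY", signal=True
) -> DisproportionalityResult:
    """Hand-build a result row without running the screening pipeline."""
    from pvsignal.disproportionality import evaluate, SignalCriteria

    res = evaluate(ContingencyTable(a, b, c, d), SignalCriteria(), drug=drug, event_pt=pt)
    if signal != res.is_signal:
        res = DisproportionalityResult(
            res.drug, res.event_pt, res.table, res.prr, res.ror, res.ic, res.ic025, signal
        )
    return res
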