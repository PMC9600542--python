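"""PRR/ROR/IC/IC025 formulas against independent oracles, and the
composite signal criterion."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from pvsignal.contingency import ContingencyTable
from pvsignal.disproportionality import (
    SignalCriteria,
    evaluate,
    ic,
    ic025,
    prr,
    ror,
    screen,
)
from pvsignal.model import Dataset, ICSRReport
from pvsignal.synth import SyntheticConfig, generate


def random_tables(n, rng, low=1, high=1000):
    cells = rng.integers(low, high + 1, size=(n, 4))
    return [ContingencyTable(*map(int, row)) for row in cells]


def prr_oracle(a, b, c, d):
    """Exact rational re-implementation, independent of the package code."""
    return Fraction(a, a + b) / Fraction(c, c + d)


def ror_oracle(a, b, c, d):
    return Fraction(a, b) / Fraction(c, d)


class TestPRR:
    def test_closed_form_example(self):
        assert prr(ContingencyTable(10, 90, 10, 890)) == pytest.approx(9.0)

    def test_proportional_rows_give_unity(self):
        assert prr(ContingencyTable(5, 45, 50, 450)) == pytest.approx(1.0)

    def test_undefined_when_event_never_reported_elsewhere(self):
        assert prr(ContingencyTable(5, 5, 0, 10)) is None

    def test_matches_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for t in random_tables(200, rng):
            expected = float(prr_oracle(t.a, t.b, t.c, t.d))
            assert prr(t) == pytest.approx(expected, rel=1e-12)


class TestROR:
    def test_closed_form_example(self):
        assert ror(ContingencyTable(10, 90, 10, 890)) == pytest.approx(890 / 90)

    def test_proportional_rows_give_unity(self):
        assert ror(ContingencyTable(5, 45, 50, 450)) == pytest.approx(1.0)

    def test_undefined_on_zero_denominator(self):
        assert ror(ContingencyTable(5, 0, 3, 10)) is None
        assert ror(ContingencyTable(5, 3, 0, 10)) is None
        assert ror(ContingencyTable(5, 3, 10, 0)) is None

    def test_ror_dominates_prr_above_unity(self):
        rng = np.random.default_rng(7)
        for t in random_tables(200, rng):
            r, p = ror(t), prr(t)
            # algebraic identity ROR/PRR = D(A+B) / (B(C+D))
            assert r == pytest.approx(p * t.d * (t.a + t.b) / (t.b * (t.c + t.d)), rel=1e-12)
            if r >= 1:
                assert r >= p - 1e-12
        # equality exactly when a/b == c/d (both ratios then equal 1)
        t = ContingencyTable(10, 20, 30, 60)
        assert ror(t) == pytest.approx(prr(t)) == pytest.approx(1.0)

    def test_matches_rational_oracle_on_random_tables(self):
        rng = np.random.default_rng(43)
        for t in random_tables(200, rng):
            expected = float(ror_oracle(t.a, t.b, t.c, t.d))
            assert ror(t) == pytest.approx(expected, rel=1e-12)


class TestIC:
    def test_zero_at_independence_with_shrinkage(self):
        # e = (a+b)(a+c)/n = 100*100/1000 = 10 = a
        assert ic(ContingencyTable(10, 90, 90, 810)) == pytest.approx(0.0)

    def test_empty_margin_convention(self):
        # drug absent: a = 0 and e = 0 -> log2(0.5/0.5) = 0
        assert ic(ContingencyTable(0, 0, 50, 950)) == pytest.approx(0.0)

    def test_large_sample_limit_matches_unshrunk_ratio(self):
        t = ContingencyTable(10_000, 90_000, 0, 900_000)
        assert t.expected == pytest.approx(1000.0)
        assert ic(t) == pytest.approx(math.log2(10), abs=1e-3)


class TestIC025:
    def test_hand_evaluated_penalty_formula(self):
        t = ContingencyTable(10, 90, 90, 810)  # ic = 0, a + 0.5 = 10.5
        expected = 0.0 - 3.3 / math.sqrt(10.5) - 2.4 / 10.5**1.5
        assert ic025(t) == pytest.approx(expected)
        assert ic025(t) == pytest.approx(-1.089, abs=1e-3)

    def test_lower_bound_never_exceeds_point_estimate(self):
        rng = np.random.default_rng(3)
        for t in random_tables(100, rng):
            assert ic025(t) <= ic(t)

    def test_closed_form_is_conservative_versus_gamma_posterior(self):
        # the penalty expansion consistently bounds the gamma-posterior
        # 2.5th percentile from below (it approximates a slightly deeper
        # tail), and the gap narrows as the co-report count grows
        rng = np.random.default_rng(11)
        cells = rng.integers(1, 500, size=(15, 3))
        for i, (a, b, c) in enumerate(cells):
            t = ContingencyTable(int(a) + 3, int(b), int(c), 5000)
            mc = ic025(t, "mc", n_draws=200_000, seed=100 + i)
            assert ic025(t, "approx") <= mc + 0.01  # MC noise allowance
        for a, bound in ((3, 0.10), (100, 0.05)):
            t = ContingencyTable(a, 1000, 500, 50_000)
            mc = ic025(t, "mc", n_draws=400_000, seed=a)
            assert abs(ic025(t, "approx") - mc) <= bound

    def test_monte_carlo_matches_exact_gamma_percentile(self):
        # independent oracle: the 2.5th percentile of log2(G/(e+0.5)) is
        # log2(gamma.ppf(0.025, a+0.5)/(e+0.5))
        t = ContingencyTable(40, 500, 200, 10_000)
        exact = math.log2(stats.gamma.ppf(0.025, t.a + 0.5) / (t.expected + 0.5))
        assert ic025(t, "mc", n_draws=400_000, seed=5) == pytest.approx(exact, abs=0.01)

    def test_scaling_cells_tightens_the_bound(self):
        t1 = ContingencyTable(10, 90, 90, 810)
        t4 = ContingencyTable(40, 360, 360, 3240)
        assert prr(t4) == pytest.approx(prr(t1))
        assert ror(t4) == pytest.approx(ror(t1))
        assert ic025(t4) > ic025(t1)


class TestEvaluate:
    def test_minimum_report_count_gates_signal(self):
        # a = 2 with enormous disproportion: every statistic passes a
        # relaxed IC threshold, yet the pair is not reportable
        t = ContingencyTable(2, 3, 5, 100_000)
        relaxed = SignalCriteria(ic025_min=-10.0)
        res = evaluate(t, relaxed)
        assert res.prr > 2 and res.ror > 2 and res.ic025 > relaxed.ic025_min
        assert not res.is_signal
        assert evaluate(t, SignalCriteria(min_reports=2, ic025_min=-10.0)).is_signal

    def test_strong_disproportion_is_flagged(self):
        # a Table-5-scale pair: 152 of 32,618 drug reports vs a background
        # event rate chosen so PRR ~ 6.27
        res = evaluate(ContingencyTable(152, 32_466, 743, 998_257))
        assert res.prr == pytest.approx(6.27, abs=0.05)
        assert res.ror == pytest.approx(res.prr, abs=0.05)
        assert res.ic025 > 0
        assert res.is_signal

    def test_prr_below_threshold_blocks_signal(self):
        # a/(a+b) = 199, c/(c+d) = 100 per 1000 -> prr = 1.99
        t = ContingencyTable(199, 801, 1000, 9000)
        res = evaluate(t)
        assert res.prr == pytest.approx(1.99)
        assert not res.is_signal

    def test_undefined_statistics_fail_criterion(self):
        res = evaluate(ContingencyTable(10, 0, 5, 100))  # ror undefined
        assert res.ror is None and not res.is_signal

    def test_strictness_flag_on_ic025_boundary(self):
        t = ContingencyTable(199, 801, 1000, 9000)
        boundary = evaluate(t).ic025
        strict = SignalCriteria(prr_min=1.0, ror_min=1.0, ic025_min=boundary)
        relaxed = SignalCriteria(prr_min=1.0, ror_min=1.0, ic025_min=boundary,
                                 ic025_strict=False)
        assert not evaluate(t, strict).is_signal
        assert evaluate(t, relaxed).is_signal

    def test_result_invariants(self):
        res = evaluate(ContingencyTable(20, 80, 100, 800), drug="D", event_pt="E")
        assert res.n_reports == 20
        assert res.ic025 <= res.ic


class TestScreen:
    def test_planted_pair_recovered(self):
        cfg = SyntheticConfig(
            n_reports=20_000,
            drug_catalog=(("drugA", 0.2), ("drugB", 0.5)),
            event_catalog=(("Ear pain", 0.002), ("Cough", 0.2), ("Rash", 0.1)),
            planted_rr={("drugA", "Ear pain"): 10.0},
            seed=21,
        )
        ds, _ = generate(cfg)
        hits = {
            (r.drug, r.event_pt) for r in screen(ds, ["drugA", "drugB"]) if r.is_signal
        }
        assert ("drugA", "Ear pain") in hits

    def test_empty_target_list_yields_empty_result(self, tiny_dataset):
        assert screen(tiny_dataset, []) == []

    def test_deterministic_ordering(self, synth_dataset):
        ds, _ = synth_dataset
        res = screen(ds, ["omalizumab", "dupilumab"])
        keys = [(r.drug, -r.n_reports, r.event_pt) for r in res]
        assert keys == sorted(keys)
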