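from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from faersig.contingency import ContingencyTable
from faersig.stats import (
    BcpnnPriors,
    NotEvaluableError,
    bcpnn_ic,
    chi_square,
    compute_estimates,
    ebgm,
    evaluate_signal,
    prr,
    ror,
)

# ---------------------------------------------------------------------------
# Independent oracle: every statistic re-derived with exact rational
# arithmetic, organized differently from the implementation under test.
# ---------------------------------------------------------------------------


def oracle(a, b, c, d, alpha=2, beta=2, alpha1=1, beta1=1, g11=1):
    a, b, c, d = Fraction(int(a)), Fraction(int(b)), Fraction(int(c)), Fraction(int(d))
    n = a + b + c + d
    out = {}
    if min(a, b, c, d) > 0:
        out["ror"] = a * d / (b * c)
        se = math.sqrt(float(1 / a + 1 / b + 1 / c + 1 / d))
        out["ror_lo"] = float(out["ror"]) * math.exp(-1.96 * se)
        out["ebgm"] = a * n / ((a + c) * (a + b))
        out["ebgm_lo"] = float(out["ebgm"]) * math.exp(-1.96 * se)
    if a > 0 and c > 0:
        out["prr"] = (a / (a + b)) / (c / (c + d))
        se = math.sqrt(float(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)))
        out["prr_lo"] = float(out["prr"]) * math.exp(-1.96 * se)
    out["chi2"] = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    diff = abs(a * d - b * c) - n / 2
    diff = diff if diff > 0 else Fraction(0)
    out["chi2_yates"] = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    gamma = g11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    out["e_ic"] = math.log2(
        float((a + g11) * (n + alpha) * (n + beta) / ((n + gamma) * (a + b + alpha1) * (a + c + beta1)))
    )
    out["v_ic"] = float(
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
        + (n - (a + c) + beta - beta1) / ((a + c + beta1) * (1 + n + beta))
    ) / math.log(2) ** 2
    return out


def random_tables(n_tables, seed, low=1, high=10_000):
    rng = np.random.default_rng(seed)
    return rng.integers(low, high + 1, size=(n_tables, 4))


class TestRor:
    def test_worked_example(self, table_example):
        value, lo, hi = ror(table_example)
        assert value == pytest.approx(13.7143, abs=1e-4)
        assert lo == pytest.approx(3.38, abs=0.01)

    def test_symmetric_table(self):
        value, lo, hi = ror(ContingencyTable(5, 5, 5, 5))
        assert value == 1.0
        assert lo < 1 < hi

    def test_zero_cell_not_evaluable(self):
        with pytest.raises(NotEvaluableError):
            ror(ContingencyTable(0, 7, 30, 960))


class TestPrr:
    def test_worked_example(self, table_example):
        value, lo, hi = prr(table_example)
        assert value == pytest.approx(9.9, abs=1e-12)
        assert lo == pytest.approx(3.61, abs=0.01)

    def test_proportional_table(self):
        value, _, _ = prr(ContingencyTable(10, 90, 100, 900))
        assert value == pytest.approx(1.0)

    def test_zero_c_not_evaluable(self):
        with pytest.raises(NotEvaluableError):
            prr(ContingencyTable(3, 7, 0, 990))


class TestChiSquare:
    def test_worked_example(self, table_example):
        assert chi_square(table_example) == pytest.approx(22.5656, abs=1e-3)

    def test_worked_example_yates(self, table_example):
        assert chi_square(table_example, yates=True) == pytest.approx(14.905, abs=1e-2)

    def test_independence_is_zero(self):
        assert chi_square(ContingencyTable(10, 90, 100, 900)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_is_zero(self):
        assert chi_square(ContingencyTable(0, 0, 30, 960)) == 0.0

    def test_yates_floors_at_zero(self):
        # |ad-bc| = 10 < N/2 = 31 -> corrected statistic is exactly 0
        t = ContingencyTable(2, 10, 10, 40)
        assert abs(t.a * t.d - t.b * t.c) < t.n / 2
        assert chi_square(t, yates=True) == 0.0

    def test_matches_scipy(self):
        for a, b, c, d in random_tables(50, seed=1):
            expected = chi2_contingency([[a, b], [c, d]], correction=False).statistic
            got = chi_square(ContingencyTable(a, b, c, d))
            assert got == pytest.approx(expected, rel=1e-12)


class TestBcpnn:
    def test_worked_example(self, table_example):
        e_ic, v_ic, ic025 = bcpnn_ic(table_example)
        assert e_ic == pytest.approx(1.544, abs=2e-3)
        assert ic025 == pytest.approx(e_ic - 2 * math.sqrt(v_ic))

    def test_independence_shrinks_below_zero(self):
        e_ic, _, _ = bcpnn_ic(ContingencyTable(10, 90, 100, 900))
        assert -0.2 < e_ic < 0

    def test_defined_at_a_zero(self):
        e_ic, v_ic, ic025 = bcpnn_ic(ContingencyTable(0, 10, 30, 960))
        assert math.isfinite(e_ic) and v_ic > 0

    def test_large_count_limit(self):
        t = ContingencyTable(505, 13995, 220_000, 49_700_000)
        e_ic, _, _ = bcpnn_ic(t)
        value, _, _ = ebgm(t)
        assert abs(e_ic - math.log2(value)) < 0.02

    def test_shrinkage_vanishes_under_scaling(self, table_example):
        k = 1000  # a = 3000 >= 100, N = 1e6
        t = ContingencyTable(3 * k, 7 * k, 30 * k, 960 * k)
        e_ic, _, _ = bcpnn_ic(t)
        value, _, _ = ebgm(t)
        assert abs(e_ic - math.log2(value)) < 0.01

    def test_priors_validated(self):
        with pytest.raises(ValueError):
            BcpnnPriors(alpha=0)


class TestEbgm:
    def test_worked_example(self, table_example):
        value, lo, hi = ebgm(table_example)
        assert value == pytest.approx(3000 / 330, abs=1e-12)
        assert lo == pytest.approx(2.241, abs=2e-3)

    def test_independence(self):
        value, _, _ = ebgm(ContingencyTable(10, 90, 100, 900))
        assert value == pytest.approx(1.0)

    def test_equals_relative_reporting_ratio(self):
        for a, b, c, d in random_tables(50, seed=2):
            t = ContingencyTable(a, b, c, d)
            value, _, _ = ebgm(t)
            rrr = (a / (a + b)) / ((a + c) / t.n)
            assert value == pytest.approx(rrr, rel=1e-12)

    def test_zero_cell_point_value_without_ci(self):
        value, lo, hi = ebgm(ContingencyTable(3, 7, 0, 990))
        assert value > 0 and math.isnan(lo) and math.isnan(hi)


class TestOracleEquivalence:
    def test_random_tables(self):
        for a, b, c, d in random_tables(200, seed=3):
            t = ContingencyTable(a, b, c, d)
            ref = oracle(a, b, c, d)
            assert ror(t)[0] == pytest.approx(float(ref["ror"]), rel=1e-10)
            assert prr(t)[0] == pytest.approx(float(ref["prr"]), rel=1e-10)
            assert chi_square(t) == pytest.approx(float(ref["chi2"]), rel=1e-10)
            assert chi_square(t, yates=True) == pytest.approx(float(ref["chi2_yates"]), rel=1e-10)
            e_ic, v_ic, _ = bcpnn_ic(t)
            assert e_ic == pytest.approx(ref["e_ic"], rel=1e-10, abs=1e-10)
            assert v_ic == pytest.approx(ref["v_ic"], rel=1e-10)
            assert ebgm(t)[0] == pytest.approx(float(ref["ebgm"]), rel=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        for a, b, c, d in random_tables(50, seed=4):
            t2 = sm.stats.Table2x2([[a, b], [c, d]])
            t = ContingencyTable(a, b, c, d)
            value, lo, hi = ror(t)
            assert value == pytest.approx(t2.oddsratio, rel=1e-10)
            sm_lo, sm_hi = t2.oddsratio_confint()
            assert lo == pytest.approx(sm_lo, rel=1e-3)  # z-quantile 1.96 vs exact
            value, lo, hi = prr(t)
            assert value == pytest.approx(t2.riskratio, rel=1e-10)


class TestMonotonicity:
    def test_ror_increases_in_a(self):
        b, c, d = 7, 30, 960
        rors = [ror(ContingencyTable(a, b, c, d))[0] for a in range(1, 40)]
        assert all(x < y for x, y in zip(rors, rors[1:]))

    def test_ebgm_increases_in_a_with_margins_fixed(self):
        # EBGM is observed/expected; with the margins (and hence the
        # expectation) fixed it grows strictly with the observed count.
        # (With b, c, d fixed instead, EBGM -> 1 as a -> inf.)
        row, col, n = 50, 100, 10_000
        ebgms = [
            ebgm(ContingencyTable(a, row - a, col - a, n - row - col + a))[0]
            for a in range(1, 50)
        ]
        assert all(x < y for x, y in zip(ebgms, ebgms[1:]))

    def test_ebgm_increases_in_a_at_small_counts(self):
        b, c, d = 7, 30, 960
        ebgms = [ebgm(ContingencyTable(a, b, c, d))[0] for a in range(1, 11)]
        assert all(x < y for x, y in zip(ebgms, ebgms[1:]))


class TestEvaluateSignal:
    def test_worked_example_flags(self, table_example):
        est = compute_estimates(table_example)
        dec = evaluate_signal(est, rule="ALL")
        assert dec.pass_ror and dec.pass_prr and dec.pass_ebgm
        assert not dec.pass_bcpnn  # ic025 ~ -0.21 for this table
        assert not dec.combined
        assert evaluate_signal(est, rule="ANY").combined

    def test_min_a_gates_ror_and_prr(self):
        est = compute_estimates(ContingencyTable(2, 8, 30, 960))
        dec = evaluate_signal(est)
        assert not dec.pass_ror and not dec.pass_prr

    def test_independence_all_false(self):
        est = compute_estimates(ContingencyTable(10, 90, 100, 900))
        dec = evaluate_signal(est)
        assert not any([dec.pass_ror, dec.pass_prr, dec.pass_bcpnn, dec.pass_ebgm, dec.combined])

    def test_unknown_rule(self, table_example):
        with pytest.raises(ValueError):
            evaluate_signal(compute_estimates(table_example), rule="most")


class TestNullCoverage:
    def test_pass_ror_rate_on_null_tables(self):
        # independence tables with expected a >= 5; nominal one-sided 2.5%
        rng = np.random.default_rng(42)
        n_tables, n = 2000, 30_000
        hits = 0
        for _ in range(n_tables):
            p1 = rng.uniform(0.01, 0.05)
            p2 = rng.uniform(0.02, 0.06)
            probs = [p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)]
            a, b, c, d = rng.multinomial(n, probs)
            est = compute_estimates(ContingencyTable(int(a), int(b), int(c), int(d)))
            if evaluate_signal(est).pass_ror:
                hits += 1
        assert hits / n_tables <= 0.075
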