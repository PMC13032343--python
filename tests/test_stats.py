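"""Contingency construction and the ROR/PRR/χ² statistics."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jadersig.io import PairUniverse
from jadersig.pt import PTQuery
from jadersig.stats import (
    ContingencyTable,
    DetectionConfig,
    SignalCriteria,
    SignalMetrics,
    build_contingency,
    compute_chi_squared,
    compute_metrics,
    compute_prr,
    compute_ror,
    detect_signals,
    evaluate_criteria,
)

from oracles import oracle_chi2, oracle_prr, oracle_ror_ci, oracle_verdict

PT = PTQuery("Dysgeusia", "10013911")


def _universe(rows):
    return PairUniverse(
        pd.DataFrame(rows, columns=["case_id", "drug_name", "pt_name", "pt_code"])
    )


class TestBuildContingency:
    def test_hand_partition(self):
        rows = (
            [(f"C{i}", "D", "dysgeusia", None) for i in range(2)]
            + [(f"C{i+2}", "D", "nausea", None) for i in range(3)]
            + [("C9", "other", "dysgeusia", None)]
            + [(f"X{i}", "other", "nausea", None) for i in range(4)]
        )
        t = build_contingency(_universe(rows), "D", PT)
        assert (t.a, t.b, t.c, t.d) == (2, 3, 1, 4)
        assert t.n == 10

    def test_absent_drug_gives_zero_target_cells(self):
        rows = [("C1", "other", "dysgeusia", None), ("C2", "other", "nausea", None)]
        t = build_contingency(_universe(rows), "ghost", PT)
        assert (t.a, t.b) == (0, 0)
        assert t.c + t.d == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_cells_equal_four_independent_filters(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        rows = [
            (
                f"C{i}",
                rng.choice(["D", "E", "F"]),
                rng.choice(["dysgeusia", "nausea", "rash"]),
                None,
            )
            for i in range(n)
        ]
        uni = _universe(pd.DataFrame(rows).drop_duplicates([0, 1, 2]).values.tolist())
        t = build_contingency(uni, "D", PT)
        df = uni.pairs
        assert t.a == len(df[(df.drug_name == "D") & (df.pt_name == "dysgeusia")])
        assert t.b == len(df[(df.drug_name == "D") & (df.pt_name != "dysgeusia")])
        assert t.c == len(df[(df.drug_name != "D") & (df.pt_name == "dysgeusia")])
        assert t.d == len(df[(df.drug_name != "D") & (df.pt_name != "dysgeusia")])
        assert t.n == uni.n_total


class TestClosedForms:
    def test_symmetric_table(self):
        t = ContingencyTable(25, 25, 25, 25)
        ror, lo, hi = compute_ror(t)
        assert ror == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # CI symmetric about 1 on log scale
        assert compute_prr(t) == pytest.approx(1.0)
        assert compute_chi_squared(t, yates=False) == 0.0

    def test_hand_computed_table(self):
        t = ContingencyTable(10, 90, 100, 9800)
        ror, lo, hi = compute_ror(t)
        assert ror == pytest.approx(10.888888888888889, rel=1e-12)
        assert lo == pytest.approx(5.503342245636626, rel=1e-9)
        assert hi == pytest.approx(21.54470791428165, rel=1e-9)
        assert compute_prr(t) == pytest.approx(9.9, rel=1e-12)
        assert compute_chi_squared(t, yates=False) == pytest.approx(73.545455, rel=1e-6)
        assert compute_chi_squared(t, yates=True) == pytest.approx(65.514043, rel=1e-6)

    def test_zero_cells_are_undefined_not_raised(self):
        t = ContingencyTable(0, 10, 10, 10)
        assert all(math.isnan(v) for v in compute_ror(t))
        assert math.isnan(compute_prr(ContingencyTable(3, 2, 0, 5)))
        assert math.isnan(compute_chi_squared(ContingencyTable(0, 0, 3, 4)))

    def test_haldane_policy_defines_zero_cell_tables(self):
        ror, lo, hi = compute_ror(ContingencyTable(0, 10, 10, 10), "haldane")
        assert 0 < ror < 1 and lo < ror < hi

    def test_yates_floors_at_zero(self):
        # |ad - bc| = 2 < N/2 = 7
        t = ContingencyTable(3, 4, 4, 3)
        assert compute_chi_squared(t, yates=True) == 0.0


class TestOracleAgreement:
    GRID = list(product(range(7), repeat=4))

    def test_exhaustive_grid_metrics_and_verdicts(self):
        """All 2401 tables with cells in {0..6}: metrics match the
        rational/log-space oracle to 1e-9; verdicts exactly."""
        for a, b, c, d in self.GRID:
            t = ContingencyTable(a, b, c, d)
            m = compute_metrics(t)
            o_ror = oracle_ror_ci(a, b, c, d)
            for got, want in zip((m.ror, m.ci_low, m.ci_high), o_ror):
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                    want, rel=1e-9
                )
            o_prr = oracle_prr(a, b, c, d)
            assert (math.isnan(m.prr) and math.isnan(o_prr)) or m.prr == pytest.approx(
                o_prr, rel=1e-9
            )
            for yates in (True, False):
                got = compute_chi_squared(t, yates=yates)
                want = oracle_chi2(a, b, c, d, yates)
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                    want, rel=1e-9, abs=1e-12
                )
            assert evaluate_criteria(m) == oracle_verdict(a, b, c, d)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 500, size=4))
            t = ContingencyTable(a, b, c, d)
            m = compute_metrics(t)
            o = oracle_ror_ci(a, b, c, d)
            for got, want in zip((m.ror, m.ci_low, m.ci_high), o):
                assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(
                    want, rel=1e-9
                )
            assert evaluate_criteria(m) == oracle_verdict(a, b, c, d)

    def test_chi2_matches_scipy(self):
        """Independent library route: scipy's 2×2 test, both variants."""
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 400, size=4))
            t = ContingencyTable(a, b, c, d)
            for yates in (True, False):
                expected = chi2_contingency(
                    [[a, b], [c, d]], correction=yates
                ).statistic
                assert compute_chi_squared(t, yates=yates) == pytest.approx(
                    expected, rel=1e-9
                )

    def test_ror_matches_statsmodels(self):
        """statsmodels Table2x2 cross-check (loose: it uses the exact
        normal quantile where this package fixes z = 1.96)."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(11)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 300, size=4))
            tab = sm.Table2x2([[a, b], [c, d]])
            ror, lo, hi = compute_ror(ContingencyTable(a, b, c, d))
            assert ror == pytest.approx(tab.oddsratio, rel=1e-12)
            sm_lo, sm_hi = tab.oddsratio_confint()
            assert lo == pytest.approx(sm_lo, rel=1e-3)
            assert hi == pytest.approx(sm_hi, rel=1e-3)


class TestCriteria:
    def _metrics(self, ci_low=1.2, prr=2.5, chi2=10.0, n=5):
        return SignalMetrics(
            ror=2.0, ci_low=ci_low, ci_high=4.0, prr=prr, chi2=chi2, n=n
        )

    def test_all_met_is_signal(self):
        assert evaluate_criteria(self._metrics()) == (True, True, True)

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({"n": 2}, (True, False, False)),          # n = 2 < 3
            ({"n": 3}, (True, True, True)),            # n = 3 boundary met
            ({"prr": 1.999}, (True, False, False)),    # PRR just below 2
            ({"prr": 2.0}, (True, True, True)),        # PRR ≥ 2 inclusive
            ({"chi2": 3.999}, (True, False, False)),   # χ² just below 4
            ({"chi2": 4.0}, (True, True, True)),       # χ² ≥ 4 inclusive
            ({"ci_low": 1.0}, (False, True, False)),   # bound strict: 1.0 fails
            ({"ci_low": 1.0 + 1e-9}, (True, True, True)),
        ],
    )
    def test_threshold_boundaries_flip_verdict(self, kwargs, expected):
        assert evaluate_criteria(self._metrics(**kwargs)) == expected

    def test_undefined_metric_fails_its_criterion(self):
        nan = float("nan")
        assert evaluate_criteria(self._metrics(ci_low=nan)) == (False, True, False)
        assert evaluate_criteria(self._metrics(prr=nan)) == (True, False, False)


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 50),
        b=st.integers(1, 50),
        c=st.integers(0, 50),
        d=st.integers(0, 50),
    )
    def test_transferring_report_into_target_cell_is_monotone(self, a, b, c, d):
        """Moving one report from cell b to cell a (same drug margin,
        positively associated table) never decreases any statistic."""
        if a * d < b * c:
            return
        t0, t1 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b - 1, c, d)
        for f in (
            lambda t: compute_ror(t)[0],
            compute_prr,
            lambda t: compute_chi_squared(t, yates=False),
            lambda t: compute_chi_squared(t, yates=True),
        ):
            v0, v1 = f(t0), f(t1)
            if not math.isnan(v0) and not math.isnan(v1):
                assert v1 >= v0 - 1e-12

    def test_ror_and_prr_converge_for_rare_events(self):
        """|ROR − PRR|/PRR → 0 when a, c are small against b, d."""
        for a, c in [(2, 3), (5, 8), (1, 1)]:
            t = ContingencyTable(a, 20000, c, 3_000_000)
            ror = compute_ror(t)[0]
            prr = compute_prr(t)
            assert abs(ror - prr) / prr < 1e-3

    def test_cell_conservation_in_detection(self):
        rows = [
            ("C1", "D", "dysgeusia", None),
            ("C2", "D", "nausea", None),
            ("C3", "E", "dysgeusia", None),
            ("C4", "E", "rash", None),
        ]
        uni = _universe(rows)
        results = detect_signals(uni, [PT])
        assert results  # candidates exist
        for r in results:
            assert r.table.n == uni.n_total


class TestDetectSignals:
    def test_planted_association_is_the_only_flag(self):
        rows = [(f"C{i}", "D", "dysgeusia", None) for i in range(8)]
        rows += [(f"C{i}", "D", "nausea", None) for i in range(8, 10)]
        rows += [(f"X{i}", "other", "nausea", None) for i in range(80)]
        rows += [("X90", "other", "dysgeusia", None)]
        uni = _universe(rows)
        results = detect_signals(uni, [PT])
        flagged = [(r.drug_name, r.pt_name) for r in results if r.signal]
        assert flagged == [("D", "Dysgeusia")]

    def test_order_is_pt_then_descending_a_then_name(self):
        rows = (
            [(f"C{i}", "B", "dysgeusia", None) for i in range(3)]
            + [(f"D{i}", "A", "dysgeusia", None) for i in range(3)]
            + [(f"E{i}", "Z", "dysgeusia", None) for i in range(5)]
            + [("F1", "A", "nausea", None)]
        )
        results = detect_signals(_universe(rows), [PT])
        assert [r.drug_name for r in results] == ["Z", "A", "B"]

    def test_zero_a_drugs_omitted(self):
        rows = [("C1", "D", "dysgeusia", None), ("C2", "E", "nausea", None)]
        results = detect_signals(_universe(rows), [PT])
        assert [r.drug_name for r in results] == ["D"]
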