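import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from pvsignal.event_catalog import PTCatalog
from pvsignal.lexicon import exposure_mask
from pvsignal.signal_stats import (
    ContingencyTable,
    SignalThresholds,
    build_contingency,
    chi_square,
    classify_signal,
    compute_ror,
    coowned_strong_signals,
    mine_signals,
    per_drug_strong_signals,
    results_frame,
)

cells = st.integers(min_value=1, max_value=500)


class TestComputeRor:
    def test_wald_ci_worked_example(self):
        ror, lo, hi, corrected = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        # exp(ln 11 -/+ 1.96 * sqrt(1/10 + 1/90 + 1/100 + 1/9900)),
        # frozen from an independent high-precision evaluation
        assert lo == pytest.approx(5.559514928894626, rel=1e-9)
        assert hi == pytest.approx(21.76448872744693, rel=1e-9)
        assert not corrected

    def test_balanced_table_gives_unity(self):
        ror, lo, hi, _ = compute_ror(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo < 1 < hi

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(cells, cells, cells, cells)
    def test_swap_symmetry_gives_reciprocal(self, a, b, c, d):
        r1, *_ = compute_ror(ContingencyTable(a, b, c, d))
        r2, *_ = compute_ror(ContingencyTable(c, d, a, b))
        assert r1 * r2 == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(cells, cells, cells, cells, st.integers(min_value=2, max_value=20))
    def test_scaling_cells_keeps_point_estimate_and_narrows_ci(self, a, b, c, d, k):
        r1, lo1, hi1, _ = compute_ror(ContingencyTable(a, b, c, d))
        r2, lo2, hi2, _ = compute_ror(ContingencyTable(k * a, k * b, k * c, k * d))
        assert r2 == pytest.approx(r1, rel=1e-12)
        assert (math.log(hi2) - math.log(lo2)) < (math.log(hi1) - math.log(lo1))

    def test_zero_cell_haldane_correction(self):
        ror, lo, hi, corrected = compute_ror(ContingencyTable(0, 10, 5, 100))
        assert corrected
        expected = (0.5 * 100.5) / (10.5 * 5.5)
        assert ror == pytest.approx(expected)

    def test_all_zero_table_errors(self):
        with pytest.raises(ValueError):
            compute_ror(ContingencyTable(0, 0, 0, 0))

    def test_against_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for tab in [(10, 90, 100, 9900), (154, 23671, 3099, 8194354), (5, 374, 9, 4612)]:
            a, b, c, d = tab
            t = sm.Table2x2(np.array([[a, b], [c, d]]))
            ror, lo, hi, _ = compute_ror(ContingencyTable(a, b, c, d))
            assert ror == pytest.approx(t.oddsratio, rel=1e-12)
            sm_lo, sm_hi = t.oddsratio_confint()
            # statsmodels uses the exact normal quantile, we use the
            # conventional 1.96 -- agreement to ~1e-4 relative
            assert lo == pytest.approx(sm_lo, rel=1e-3)
            assert hi == pytest.approx(sm_hi, rel=1e-3)


class TestChiSquare:
    def test_closed_form_worked_example(self):
        chi2, p, defined = chi_square(ContingencyTable(10, 90, 100, 9900))
        assert defined
        assert chi2 == pytest.approx(74.45, abs=0.01)
        assert p < 1e-15

    def test_independence_gives_zero(self):
        chi2, p, _ = chi_square(ContingencyTable(5, 5, 5, 5))
        assert chi2 == 0
        assert p == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(cells, cells, cells, cells)
    def test_matches_scipy_without_correction(self, a, b, c, d):
        chi2, p, _ = chi_square(ContingencyTable(a, b, c, d))
        ref = chi2_contingency(np.array([[a, b], [c, d]]), correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-10, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_yates_matches_scipy_correction(self):
        chi2, _, _ = chi_square(ContingencyTable(12, 88, 110, 9890), yates=True)
        ref = chi2_contingency(np.array([[12, 88], [110, 9890]]), correction=True)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_margin_flagged_undefined(self):
        chi2, p, defined = chi_square(ContingencyTable(0, 0, 5, 5))
        assert not defined
        assert math.isnan(chi2) and math.isnan(p)

    def test_p_monotone_in_statistic(self):
        tables = [(5, 95, 50, 4950), (10, 90, 50, 4950), (30, 70, 50, 4950)]
        stats = [chi_square(ContingencyTable(*t)) for t in tables]
        chis = [s[0] for s in stats]
        ps = [s[1] for s in stats]
        assert chis == sorted(chis)
        assert ps == sorted(ps, reverse=True)


class TestClassifySignal:
    @pytest.mark.parametrize(
        "a, ror, ci_low, expected",
        [
            (3, 1.748, 0.560, "none"),  # CI spans 1: not a signal
            (5, 2.826, 1.166, "signal"),
            (154, 13.777, 11.679, "strong"),
            (2, 10.0, 5.0, "none"),  # below the case-count floor
            (3, 7.301, 2.292, "strong"),
        ],
    )
    def test_default_ci_rule(self, a, ror, ci_low, expected):
        assert classify_signal(a, ror, ci_low) == expected

    def test_point_estimate_rule_ignores_ci(self):
        thr = SignalThresholds(rule="point_estimate")
        assert classify_signal(3, 1.748, 0.560, thr) == "signal"
        assert classify_signal(3, 0.9, 0.5, thr) == "none"

    def test_strong_requires_signal_first(self):
        # huge ROR but CI crossing 1 stays a non-signal
        assert classify_signal(3, 7.0, 0.8) == "none"


def _toy_catalog():
    pts = {"Cholestasis", "Liver injury"}
    return PTCatalog(pts, set(), pts, {p: "uncategorized" for p in pts})


class TestBuildContingency:
    def test_one_report_per_quadrant(self, make_report_set):
        rows = [
            {"primaryid": 1, "drugs": [("PROTONIX", "PS")], "reactions": ["Cholestasis"]},
            {"primaryid": 2, "drugs": [("PROTONIX", "PS")], "reactions": ["Nausea"]},
            {"primaryid": 3, "drugs": [("ASPIRIN", "PS")], "reactions": ["Cholestasis"]},
            {"primaryid": 4, "drugs": [("ASPIRIN", "PS")], "reactions": ["Nausea"]},
        ]
        rs = make_report_set(rows)
        exposure = pd.Series([True, True, False, False], index=rs.primaryids)
        assert build_contingency(rs, exposure, "Cholestasis").cells() == (1, 1, 1, 1)

    def test_no_exposed_reports(self, make_report_set):
        rs = make_report_set([{"primaryid": 1, "reactions": ["Cholestasis"]}])
        exposure = pd.Series([False], index=rs.primaryids)
        tab = build_contingency(rs, exposure, "Cholestasis")
        assert (tab.a, tab.b) == (0, 0)

    def test_absent_pt(self, make_report_set):
        rs = make_report_set([{"primaryid": 1, "reactions": ["Nausea"]}])
        exposure = pd.Series([True], index=rs.primaryids)
        tab = build_contingency(rs, exposure, "Cholestasis")
        assert (tab.a, tab.c) == (0, 0)

    def test_empty_collection_errors(self, make_report_set):
        rs = make_report_set([]).subset([])
        with pytest.raises(ValueError):
            build_contingency(rs, pd.Series(dtype=bool), "Cholestasis")


class TestMineSignals:
    def test_toy_set_matches_hand_tables(self, make_report_set):
        rows = [
            {"primaryid": 1, "drugs": [("PROTONIX", "PS")], "reactions": ["Cholestasis", "Nausea"]},
            {"primaryid": 2, "drugs": [("PROTONIX", "SS")], "reactions": ["Liver injury"]},
            {"primaryid": 3, "drugs": [("PROTONIX", "C")], "reactions": ["Cholestasis"]},
            {"primaryid": 4, "drugs": [("ASPIRIN", "PS")], "reactions": ["Nausea"]},
            {"primaryid": 5, "drugs": [("ASPIRIN", "PS")], "reactions": ["Cholestasis"]},
        ]
        rs = make_report_set(rows)
        exposure = pd.Series([True, True, False, False, False], index=rs.primaryids)
        results = mine_signals(rs, exposure, _toy_catalog())
        by_pt = {r.pt: r for r in results}
        assert by_pt["Cholestasis"].table.cells() == (1, 1, 2, 1)
        assert by_pt["Liver injury"].table.cells() == (1, 1, 0, 3)
        assert [r.pt for r in results] == sorted(by_pt)  # sorted by PT name

    def test_pt_without_cases_omitted(self, make_report_set):
        rs = make_report_set([{"primaryid": 1, "reactions": ["Nausea"]}])
        exposure = pd.Series([True], index=rs.primaryids)
        assert mine_signals(rs, exposure, _toy_catalog()) == []


class TestPerDrugMining:
    def _cohort(self):
        from pvsignal.faers_model import assemble_reports
        from pvsignal.synthetic_data import (
            DrugSpec,
            EffectSpec,
            PTSpec,
            SimConfig,
            simulate_cohort,
        )

        cfg = SimConfig(
            n_reports=8000,
            seed=42,
            drugs=(
                DrugSpec("pantoprazole", ("Protonix",), 0.05, (0.7, 0.3, 0.0)),
                DrugSpec("omeprazole", ("Prilosec",), 0.05, (0.7, 0.3, 0.0)),
            ),
            pts=(PTSpec("Cholestasis", 0.01), PTSpec("Liver injury", 0.01), PTSpec("Nausea", 0.3)),
            effects=(
                EffectSpec("pantoprazole", "Cholestasis", 20.0),
                EffectSpec("omeprazole", "Cholestasis", 20.0),
            ),
            missing_age_rate=0.0,
            missing_sex_rate=0.0,
            missing_country_rate=0.0,
        )
        return assemble_reports(simulate_cohort(cfg).raw)

    def test_injected_pair_recovered_and_coowned(self, ppi_lexicon):
        rs = self._cohort()
        cat = _toy_catalog()
        per_drug = per_drug_strong_signals(rs, ppi_lexicon, cat)
        found = set(zip(per_drug["drug_scope"], per_drug["pt"]))
        assert ("PANTOPRAZOLE", "Cholestasis") in found
        assert ("OMEPRAZOLE", "Cholestasis") in found
        # the null PT must not appear at the strong threshold
        assert "Liver injury" not in set(per_drug["pt"])
        co = coowned_strong_signals(per_drug, min_drugs=2)
        assert set(co["pt"]) == {"Cholestasis"}
        assert set(co["drug_scope"]) == {"PANTOPRAZOLE", "OMEPRAZOLE"}

    def test_results_frame_shape(self):
        frame = results_frame([])
        assert list(frame.columns[:6]) == ["drug_scope", "pt", "a", "b", "c", "d"]
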