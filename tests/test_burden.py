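import math

import numpy as np
import pandas as pd
import pytest

from ptvburden import (
    ContingencyTable,
    burden_test,
    build_2x2,
    carrier_frequency,
    describe_cohort,
    diagnostic_yield,
    forest_table,
    odds_ratio,
    pool_controls,
    subgroup_reanalysis,
    table_from_counts,
    woolf_ci,
)
from ptvburden import fixtures

# the four published comparisons: cells, OR, 95% CI at 2-dp rounding
PUBLISHED = [
    ((36, 2330, 16, 22432), 21.66, (12.00, 39.10)),
    ((36, 2330, 15, 10290), 10.60, (5.79, 19.39)),
    ((36, 2330, 8, 5988), 11.56, (5.37, 24.92)),
    ((36, 2330, 39, 38710), 15.34, (9.73, 24.17)),
]


class TestOddsRatio:
    @pytest.mark.parametrize("cells,expected,_ci", PUBLISHED)
    def test_published_or_values(self, cells, expected, _ci):
        assert round(odds_ratio(ContingencyTable(*cells)), 2) == expected

    def test_null_table(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_zero_cell_behaviour(self):
        assert math.isinf(odds_ratio(ContingencyTable(1, 1, 0, 1)))
        corrected = odds_ratio(ContingencyTable(1, 1, 0, 1), correction=True)
        assert math.isfinite(corrected) and corrected > 0

    def test_scaling_control_cells_leaves_or_unchanged(self):
        t = ContingencyTable(36, 2330, 16, 22432)
        for k in (2, 5, 10):
            scaled = ContingencyTable(36, 2330, 16 * k, 22432 * k)
            assert odds_ratio(scaled) == pytest.approx(odds_ratio(t))

    def test_transposition_inverts_or(self):
        t = ContingencyTable(36, 2330, 16, 22432)
        swapped = ContingencyTable(16, 22432, 36, 2330)
        assert odds_ratio(swapped) == pytest.approx(1 / odds_ratio(t))
        lo, hi = woolf_ci(t)
        slo, shi = woolf_ci(swapped)
        assert (slo, shi) == (pytest.approx(1 / hi), pytest.approx(1 / lo))

    def test_or_strictly_increases_in_case_carriers(self):
        ors = [odds_ratio(ContingencyTable(a, 2330, 16, 22432)) for a in range(1, 60)]
        assert all(x < y for x, y in zip(ors, ors[1:]))


class TestWoolfCi:
    @pytest.mark.parametrize("cells,_or,ci", PUBLISHED)
    def test_published_ci_values(self, cells, _or, ci):
        lo, hi = woolf_ci(ContingencyTable(*cells))
        assert (round(lo, 2), round(hi, 2)) == ci

    def test_symmetric_table_interval_symmetric_on_log_scale(self):
        lo, hi = woolf_ci(ContingencyTable(20, 20, 20, 20))
        assert math.log(lo) == pytest.approx(-math.log(hi))

    def test_zero_cell_raises_without_correction(self):
        with pytest.raises(ValueError):
            woolf_ci(ContingencyTable(0, 10, 5, 10))
        lo, hi = woolf_ci(ContingencyTable(0, 10, 5, 10), correction=True)
        assert 0 < lo < hi

    def test_matches_statsmodels_cross_check(self):
        """Independent OR/CI computation via statsmodels Table2x2."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for cells, _, _ in PUBLISHED:
            a, b, c, d = cells
            t2 = sm.Table2x2(np.array([[a, b], [c, d]]))
            assert odds_ratio(ContingencyTable(*cells)) == pytest.approx(t2.oddsratio)
            lo, hi = woolf_ci(ContingencyTable(*cells), exact_z=True)
            slo, shi = t2.oddsratio_confint(0.05)
            assert (lo, hi) == (pytest.approx(slo), pytest.approx(shi))


class TestCarrierFrequency:
    @pytest.mark.parametrize(
        "carriers,n,decimals,expected",
        [
            (36, 2366, 1, 1.5),
            (16, 22448, 2, 0.07),
            (15, 10305, 2, 0.15),
            (39, 38749, 2, 0.10),
            (0, 100, 1, 0.0),
        ],
    )
    def test_published_frequencies(self, carriers, n, decimals, expected):
        assert round(carrier_frequency(carriers, n), decimals) == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            carrier_frequency(0, 0)


class TestPooling:
    def test_pooled_panels(self):
        assert pool_controls([(22448, 16), (10305, 15), (5996, 8)]) == (38749, 39)

    def test_single_panel_identity(self):
        assert pool_controls([(100, 3)]) == (100, 3)


class TestBuild2x2:
    def test_counts_mode_derives_noncarrier_cells(self):
        t = table_from_counts(2366, 36, 22448, 16)
        assert (t.a, t.b, t.c, t.d) == (36, 2330, 16, 22432)

    def test_manifest_mode(self):
        case = pd.DataFrame({"carrier": [True] * 3 + [False] * 7},
                            index=[f"A{i}" for i in range(10)])
        ctrl = pd.DataFrame({"carrier": [True] * 1 + [False] * 19},
                            index=[f"B{i}" for i in range(20)])
        t = build_2x2(case, ctrl)
        assert (t.a, t.b, t.c, t.d) == (3, 7, 1, 19)

    def test_overlapping_sample_ids_rejected(self):
        case = pd.DataFrame({"carrier": [True]}, index=["X"])
        ctrl = pd.DataFrame({"carrier": [False]}, index=["X"])
        with pytest.raises(ValueError, match="both panels"):
            build_2x2(case, ctrl)

    def test_zero_carriers_everywhere(self):
        t = table_from_counts(10, 0, 20, 0)
        assert (t.a, t.c) == (0, 0)
        assert math.isnan(odds_ratio(t))


class TestSubgroupReanalysis:
    @staticmethod
    def _manifests(rng):
        case = pd.DataFrame(
            {"carrier": rng.random(300) < 0.1, "age": rng.integers(10, 90, 300)},
            index=[f"C{i}" for i in range(300)],
        )
        ctrl = pd.DataFrame(
            {"carrier": rng.random(900) < 0.02, "age": rng.integers(1, 90, 900)},
            index=[f"K{i}" for i in range(900)],
        )
        return case, ctrl

    def test_always_true_predicate_equals_unfiltered(self, rng):
        case, ctrl = self._manifests(rng)
        full = burden_test(build_2x2(case, ctrl))
        sub = subgroup_reanalysis(case, ctrl, lambda m: m["age"] >= 0)
        assert sub.or_estimate == pytest.approx(full.or_estimate)

    def test_age_filter_matches_bruteforce_recount(self, rng):
        case, ctrl = self._manifests(rng)
        res = subgroup_reanalysis(case, ctrl, lambda m: m["age"] >= 17)
        # independent recount from the individual lists
        ca = case[case["age"] >= 17]
        co = ctrl[ctrl["age"] >= 17]
        a, b = int(ca["carrier"].sum()), int((~ca["carrier"]).sum())
        c, d = int(co["carrier"].sum()), int((~co["carrier"]).sum())
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (a, b, c, d)
        assert res.or_estimate == pytest.approx((a * d) / (b * c))

    def test_excluding_young_control_carriers_shrinks_cell(self, rng):
        case, ctrl = self._manifests(rng)
        young_carriers = int((ctrl["carrier"] & (ctrl["age"] < 17)).sum())
        res = subgroup_reanalysis(case, ctrl, lambda m: m["age"] >= 17)
        assert res.table.c == int(ctrl["carrier"].sum()) - young_carriers

    def test_emptied_panel_rejected(self, rng):
        case, ctrl = self._manifests(rng)
        with pytest.raises(ValueError, match="emptied"):
            subgroup_reanalysis(case, ctrl, lambda m: m["age"] > 1000)


class TestDescriptives:
    def test_carrier_ages_match_published_summary(self):
        roster = fixtures.load_carrier_table()
        summary = describe_cohort(roster.rename(columns={"age": "age"}))
        assert summary.n == 36
        assert summary.median_age == 52
        assert round(summary.mean_age) == 53
        assert round(summary.sd_age, 1) == 17.1

    def test_lvef_matches_published_summary(self):
        from ptvburden.burden import describe_numeric

        clinical = fixtures.load_clinical_table()
        stats = describe_numeric(clinical["lvef_percent"])
        assert stats["n"] == 24
        assert round(stats["mean"], 1) == 64.1
        assert round(stats["sd"], 1) == 11.4

    def test_single_row_sd_undefined(self):
        df = pd.DataFrame({"age": [40]}, index=["S1"])
        s = describe_cohort(df)
        assert s.median_age == s.mean_age == 40
        assert s.sd_age is None


class TestDiagnosticYield:
    def test_published_gene_shares(self):
        manifest = fixtures.diagnostic_manifest()
        res = diagnostic_yield(manifest)
        assert round(res["yield_percent"], 1) == 20.4
        shares = res["gene_shares_percent"]
        assert round(shares["MYBPC3"], 1) == 40.7
        assert round(shares["MYH7"], 1) == 24.9
        assert round(shares["TNNI3"], 1) == 12.2

    def test_multi_gene_individuals_count_once_in_yield(self):
        df = pd.DataFrame({"reported_genes": ["A;B", "A", "", ""]},
                          index=list("wxyz"))
        res = diagnostic_yield(df)
        assert res["n_diagnosed"] == 2
        assert res["gene_counts"] == {"A": 2, "B": 1}

    def test_empty_diagnosed_set(self):
        df = pd.DataFrame({"reported_genes": ["", ""]}, index=["a", "b"])
        res = diagnostic_yield(df)
        assert res["yield_percent"] == 0.0 and res["gene_shares_percent"] == {}


class TestForestTable:
    def test_published_comparisons_render_in_order(self):
        results = [burden_test(t) for _, t in fixtures.published_tables()]
        df = forest_table(results)
        assert list(df["or"].round(2)) == [21.66, 10.60, 11.56, 15.34]
        assert df.attrs["axis_scale"] == "log"

    def test_or_always_inside_own_interval(self):
        results = [burden_test(t) for _, t in fixtures.published_tables()]
        df = forest_table(results)
        assert ((df["ci_low"] <= df["or"]) & (df["or"] <= df["ci_high"])).all()
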