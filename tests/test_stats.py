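"""Fisher exact test, UP/DN classification, enrichment, scatter and CDFs."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uarna import (
    StatsConfig,
    cdf_curves,
    change_scatter,
    chi_squared_tail,
    classify_gene,
    classify_table,
    fisher_exact_one_sided_greater,
    fisher_exact_two_sided,
    global_enrichment,
)

CFG = StatsConfig(test="mut", reference="ctrl")


def fisher_oracle(a, b, c, d, tie_scale=10**7):
    """Exhaustive hypergeometric enumeration in exact integer arithmetic."""
    n = a + b + c + d
    r, c1 = a + b, a + c
    if n == 0 or r in (0, n) or c1 in (0, n):
        return 1.0
    nums = [
        comb(c1, x) * comb(n - c1, r - x)
        for x in range(max(0, r + c1 - n), min(r, c1) + 1)
    ]
    obs = comb(c1, a) * comb(n - c1, r - a)
    kept = sum(x for x in nums if x * tie_scale <= obs * (tie_scale + 1))
    return float(Fraction(kept, comb(n, r)))


class TestFisherTwoSided:
    def test_empty_column_gives_one(self):
        assert fisher_exact_two_sided(0, 10, 0, 10) == 1.0

    def test_perfect_separation(self):
        assert fisher_exact_two_sided(5, 0, 0, 5) == pytest.approx(2 / 252, abs=1e-12)

    def test_moderate_table(self):
        assert fisher_exact_two_sided(3, 7, 6, 4) == pytest.approx(
            68332 / 184756, abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 1, 1, 1)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_agrees_with_enumeration_oracle(self, cells):
        a, b, c, d = cells
        assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-10
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_symmetric_under_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_sided(a, b, c, d)
        assert fisher_exact_two_sided(c, d, a, b) == pytest.approx(p, rel=1e-9, abs=1e-12)
        assert fisher_exact_two_sided(b, a, d, c) == pytest.approx(p, rel=1e-9, abs=1e-12)

    def test_one_sided_monotone_in_up_direction(self):
        for b, c, d in [(5, 3, 7), (20, 10, 20), (0, 4, 9)]:
            prev = 1.1
            for a in range(0, 40):
                p = fisher_exact_one_sided_greater(a, b, c, d)
                assert p <= prev + 1e-12
                prev = p


class TestChiSquaredTail:
    def test_matches_closed_form(self):
        from scipy.special import erfc

        for x in (0.0, 0.5, 3.84, 13.235, 36.0, 80.0):
            assert chi_squared_tail(x) == pytest.approx(
                float(erfc(np.sqrt(x / 2))), rel=1e-12
            )


class TestClassifyGene:
    def test_strong_ua_increase_called_up(self):
        r = classify_gene("g", 40, 100, 10, 100, CFG)
        assert r.call == "UP" and r.odds_ratio == pytest.approx(4.0) and r.p < 0.05

    def test_identical_counts_are_nc(self):
        r = classify_gene("g", 7, 100, 7, 100, CFG)
        assert r.call == "NC" and r.odds_ratio == 1.0
        assert r.p == pytest.approx(1.0, abs=1e-12)

    def test_no_ua_reads_anywhere_is_nc_without_testing(self):
        r = classify_gene("g", 0, 50, 0, 80, CFG)
        assert (r.call, r.p) == ("NC", 1.0)

    def test_zero_cell_direction_still_classified(self):
        r = classify_gene("g", 12, 100, 0, 100, CFG)
        assert r.call == "UP" and np.isinf(r.odds_ratio)

    def test_swapping_sample_roles_maps_up_to_dn(self):
        table = pd.DataFrame(
            {"sense_mut": [100], "ua_mut": [40], "sense_ctrl": [100], "ua_ctrl": [10]},
            index=pd.Index(["g"], name="gene_id"),
        )
        fwd = classify_table(table, CFG)
        rev = classify_table(table, StatsConfig(test="ctrl", reference="mut"))
        assert fwd.loc["g", "call"] == "UP" and rev.loc["g", "call"] == "DN"
        assert rev.loc["g", "p"] == pytest.approx(fwd.loc["g", "p"], abs=1e-12)

    def test_classify_table_and_bh_column(self):
        table = pd.DataFrame(
            {
                "sense_mut": [100, 100, 50],
                "ua_mut": [40, 7, 0],
                "sense_ctrl": [100, 100, 80],
                "ua_ctrl": [10, 7, 0],
            },
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        res = classify_table(table, CFG)
        assert list(res["call"]) == ["UP", "NC", "NC"]
        assert res.loc["a", "p_bh"] >= res.loc["a", "p"]


class TestGlobalEnrichment:
    def test_balanced_calls_null(self):
        df = pd.DataFrame({"call": ["UP"] * 50 + ["DN"] * 50})
        e = global_enrichment(df)
        assert (e.chi2, e.p_chi2, e.ratio) == (0.0, 1.0, 1.0)

    def test_eighty_twenty(self):
        e = global_enrichment(pd.DataFrame({"call": ["UP"] * 80 + ["DN"] * 20}))
        assert e.chi2 == pytest.approx(36.0)
        assert e.p_chi2 == pytest.approx(1.97e-9, rel=2e-2)

    def test_sixteen_to_one(self):
        e = global_enrichment(pd.DataFrame({"call": ["UP"] * 16 + ["DN"] * 1}))
        assert e.chi2 == pytest.approx(225 / 17, rel=1e-12)
        assert e.p_chi2 == pytest.approx(2.75e-4, rel=2e-2)

    def test_no_dn_gives_infinite_ratio(self):
        e = global_enrichment(pd.DataFrame({"call": ["UP"] * 9}))
        assert np.isinf(e.ratio) and e.chi2 == 9.0

    def test_nothing_called(self):
        e = global_enrichment(pd.DataFrame({"call": ["NC"] * 5}))
        assert np.isnan(e.ratio) and e.p_chi2 == 1.0


def _rpm_table(ua_mut, ua_ctrl, sense_mut, sense_ctrl):
    return pd.DataFrame(
        {
            "ua_mut": [1], "ua_ctrl": [1], "sense_mut": [25], "sense_ctrl": [25],
            "ua_rpm_mut": [ua_mut], "ua_rpm_ctrl": [ua_ctrl],
            "sense_rpm_mut": [sense_mut], "sense_rpm_ctrl": [sense_ctrl],
        },
        index=pd.Index(["g"], name="gene_id"),
    )


TOTALS = {"mut": 1_000_000, "ctrl": 1_000_000}


class TestChangeScatter:
    def test_no_change_is_origin_and_insignificant(self):
        cfg = StatsConfig(test="mut", reference="ctrl", pseudocount_reads=0.0)
        table = _rpm_table(4, 4, 10, 10)
        res = pd.DataFrame({"call": ["NC"]}, index=table.index)
        out = change_scatter(table, res, cfg, TOTALS)
        assert out.loc["g", "log2_ua_change"] == 0.0
        assert not out.loc["g", "significant"]

    def test_exact_log2_doubling(self):
        cfg = StatsConfig(test="mut", reference="ctrl", pseudocount_reads=0.0)
        table = _rpm_table(8, 4, 10, 10)
        res = pd.DataFrame({"call": ["UP"]}, index=table.index)
        out = change_scatter(table, res, cfg, TOTALS)
        assert out.loc["g", "log2_ua_change"] == pytest.approx(1.0)
        assert out.loc["g", "log2_sense_change"] == pytest.approx(0.0)
        assert bool(out.loc["g", "significant"])

    def test_pseudocount_keeps_zero_rpm_finite(self):
        table = _rpm_table(0, 4, 10, 10)
        res = pd.DataFrame({"call": ["NC"]}, index=table.index)
        out = change_scatter(table, res, CFG, TOTALS)
        assert np.isfinite(out.loc["g", "log2_ua_change"])


class TestCdfCurves:
    def _table(self, rows):
        df = pd.DataFrame(rows).set_index("gene_id")
        for cat in ("sense", "ua"):
            for s in ("mut", "ctrl"):
                df[f"{cat}_rpm_{s}"] = df[f"{cat}_{s}"] * 1e6 / TOTALS[s]
        return df

    def test_empirical_cdf_definition(self):
        v = pd.Series([-1.0, 0.0, 1.0])
        from uarna.stats import _ecdf

        out = _ecdf(v)
        assert list(out["value"]) == [-1.0, 0.0, 1.0]
        assert list(out["cdf"]) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_min_read_filter_excludes_nineteen(self):
        rows = [
            {"gene_id": "low", "sense_mut": 100, "sense_ctrl": 100, "ua_mut": 9, "ua_ctrl": 10},
            {"gene_id": "ok", "sense_mut": 100, "sense_ctrl": 100, "ua_mut": 10, "ua_ctrl": 10},
        ]
        table = self._table(rows)
        res = pd.DataFrame({"call": ["NC", "NC"]}, index=table.index)
        curves = cdf_curves(table, res, CFG, TOTALS)
        assert len(curves["uaRNA"]) == 1  # 19 combined uaRNA reads excluded
        assert len(curves["sense_all"]) == 2

    def test_categories_cover_ua_status(self, small_result):
        assert {"uaRNA", "sense_all", "sense_no_ua"} <= set(small_result.cdfs)
        for frame in small_result.cdfs.values():
            cdf = frame["cdf"].to_numpy()
            assert (np.diff(cdf) >= 0).all() and cdf[-1] == pytest.approx(1.0)

    def test_planted_ua_excess_right_shifts_ua_curve(self, allup_result):
        curves = allup_result.cdfs
        ua = curves["uaRNA"]["value"]
        sense = curves["sense_all"]["value"]
        for q in (0.25, 0.5, 0.75):
            assert ua.quantile(q) > sense.quantile(q)
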