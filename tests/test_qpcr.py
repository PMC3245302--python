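"""ddCt copy number, relative expression, and standard-curve QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dermadup as dd
from dermadup.qpcr import QC_SLOPE_RANGE


def _cn_table(noise_sd=0.0, seed=1):
    design = dd.copy_number_design(
        {"WT01": 2, "HET1": 3, "FM1": 4},
        {"WT01": "WT", "HET1": "HET", "FM1": "FM"},
        calibrator_sample="WT01",
    )
    return dd.simulate_qpcr_ct(design, seed=seed, noise_sd=noise_sd)


class TestCopyNumber:
    def test_noiseless_het_is_three(self):
        calls = {c.sample: c for c in dd.copy_number_ddct(_cn_table(), "Dup1", "SOX5", "WT01")}
        assert calls["HET1"].estimate == pytest.approx(3.0, abs=1e-9)

    def test_noiseless_homozygote_is_four(self):
        calls = {c.sample: c for c in dd.copy_number_ddct(_cn_table(), "Dup1", "SOX5", "WT01")}
        assert calls["FM1"].estimate == pytest.approx(4.0, abs=1e-9)

    def test_calibrator_vs_itself_exactly_two(self):
        calls = {c.sample: c for c in dd.copy_number_ddct(_cn_table(), "Dup1", "SOX5", "WT01")}
        assert calls["WT01"].estimate == 2.0

    def test_replicate_minmax_brackets_estimate(self):
        for c in dd.copy_number_ddct(_cn_table(noise_sd=0.1), "Dup1", "SOX5", "WT01"):
            assert c.cn_min <= c.estimate <= c.cn_max

    def test_missing_calibrator_rejected(self):
        with pytest.raises(ValueError):
            dd.copy_number_ddct(_cn_table(), "Dup1", "SOX5", "NOPE")

    def test_noiseless_delta_ct_closed_form(self):
        """het vs calibrator: target dCt difference is -log2(3/2)."""
        ct = _cn_table()
        t = ct[ct["assay"] == "Dup1"].groupby("sample")["ct"].mean()
        r = ct[ct["assay"] == "SOX5"].groupby("sample")["ct"].mean()
        ddct = (t - r)["HET1"] - (t - r)["WT01"]
        assert ddct == pytest.approx(-np.log2(1.5), abs=1e-12)


class TestExpression:
    def _table(self, folds, noise_sd=0.0):
        design = dd.expression_design(fold_changes=folds, tissue="skin")
        return dd.simulate_qpcr_ct(design, seed=3, noise_sd=noise_sd)

    def test_noiseless_tenfold_recovered(self):
        ct = self._table({"EDN3": {"skin": 10.0}})
        (res,) = dd.relative_expression_ddct(ct, "EDN3", "GAPDH", "N")
        assert res.fold_change == pytest.approx(10.0, rel=1e-9)

    def test_identical_groups_unit_fold(self):
        ct = self._table({"EDN3": {"skin": 1.0}})
        (res,) = dd.relative_expression_ddct(ct, "EDN3", "GAPDH", "N")
        assert res.fold_change == pytest.approx(1.0, rel=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_reference_shift_cancels(self):
        """A reference gene shifted equally in both groups leaves ddCt
        fold change untouched."""
        ct = self._table({"EDN3": {"skin": 2.0}})
        shifted = ct.copy()
        mask = shifted["assay"] == "GAPDH"
        shifted.loc[mask, "ct"] += 3.7
        (res,) = dd.relative_expression_ddct(shifted, "EDN3", "GAPDH", "N")
        assert res.fold_change == pytest.approx(2.0, rel=1e-9)

    def test_undetected_target_flagged(self):
        ct = self._table({"EDN3": {"skin": 4.0}})
        ct.loc[(ct["assay"] == "EDN3") & (ct["group"] == "FM"), "ct"] = np.nan
        (res,) = dd.relative_expression_ddct(ct, "EDN3", "GAPDH", "N")
        assert not res.detected and res.fold_change is None

    def test_ci_contains_point_estimate(self):
        ct = self._table({"EDN3": {"skin": 5.0}}, noise_sd=0.2)
        (res,) = dd.relative_expression_ddct(ct, "EDN3", "GAPDH", "N")
        assert res.ci95[0] <= res.fold_change <= res.ci95[1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(offsets=st.lists(st.floats(-5, 5, allow_nan=False), min_size=6, max_size=6))
    def test_per_sample_offset_invariance(self, offsets):
        """ddCt is invariant to any per-sample additive Ct offset applied to
        both target and reference assays."""
        ct = self._table({"EDN3": {"skin": 10.0}})
        base, = dd.relative_expression_ddct(ct, "EDN3", "GAPDH", "N")
        shifted = ct.copy()
        for sid, off in zip(shifted["sample"].unique(), offsets):
            shifted.loc[shifted["sample"] == sid, "ct"] += off
        res, = dd.relative_expression_ddct(shifted, "EDN3", "GAPDH", "N")
        assert res.fold_change == pytest.approx(base.fold_change, rel=1e-9)


class TestStandardCurve:
    @pytest.mark.parametrize(
        "slope,eff",
        [(-3.3219, 100.0), (-3.7762, 92.0), (-3.1035, 105.0)],
    )
    def test_slope_efficiency_mapping(self, slope, eff):
        curve = dd.fit_standard_curve(dd.dilution_series_cts(slope=slope))
        assert round(curve.efficiency_percent) == eff
        assert curve.slope == pytest.approx(slope, abs=1e-9)

    def test_qc_window_monotone(self):
        inside = np.linspace(QC_SLOPE_RANGE[0] + 1e-6, QC_SLOPE_RANGE[1] - 1e-6, 5)
        for slope in inside:
            assert dd.fit_standard_curve(dd.dilution_series_cts(slope=slope)).qc_pass
        for slope in (-3.9, -3.0, -2.5, -4.5):
            assert not dd.fit_standard_curve(dd.dilution_series_cts(slope=slope)).qc_pass

    def test_paired_intercept_check(self):
        a = dd.fit_standard_curve(dd.dilution_series_cts(slope=-3.3219, y_intercept=35.0))
        b = dd.fit_standard_curve(
            dd.dilution_series_cts(slope=-3.3219, y_intercept=36.5), paired_curve=a
        )
        assert b.qc_intercept_ok is False and not b.qc_pass

    def test_degenerate_dilutions_rejected(self):
        df = pd.DataFrame({"template": [100.0, 100.0, 100.0], "ct": [20.0, 20.1, 19.9]})
        with pytest.raises(ValueError):
            dd.fit_standard_curve(df)
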