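"""Delta-delta-Ct quantification: genomic copy number and relative expression.

Copy number.  The target Ct is first normalized to a single-copy reference
assay within each sample (dCt = Ct_target - Ct_reference), then across
samples to a calibrator of known diploid copy number:

    CN(s) = CN_cal * 2 ** -(dCt_s - dCt_cal)

Error bars are the minimum and maximum copy number recomputed replicate-wise.

Expression.  Per-sample dCt = Ct_gene - Ct_reference_gene; a group's fold
change versus the control group is 2 ** -(mean dCt_group - mean dCt_control),
with a normal-theory 95% CI on the mean ddCt back-transformed through
2**-x, an unpaired t-test for two-group comparisons and a one-way ANOVA for
multi-group comparisons.  A target with no detectable Ct in a group is
flagged "not detected" and gets no fold change.

Standard-curve QC follows the published acceptance window: slope in
[-3.7762, -3.1035] (92-105% efficiency), R > 0.995, and for a paired
simplex/duplex curve a y-intercept difference below 1.  Efficiency is
reported as percent-of-perfect-doubling, 100 * 10**(-1/slope) / 2, which is
the mapping that reproduces the published slope<->efficiency endpoints; the
textbook (10**(-1/slope) - 1) * 100 is carried as a secondary field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

QC_SLOPE_RANGE = (-3.7762, -3.1035)
QC_MIN_R = 0.995
QC_MAX_INTERCEPT_DIFF = 1.0


@dataclass
class StandardCurve:
    slope: float
    y_intercept: float
    r: float
    efficiency_percent: float            # 100 * 10**(-1/slope) / 2
    efficiency_standard_percent: float   # (10**(-1/slope) - 1) * 100
    n_points: int
    qc_pass: bool
    qc_slope_ok: bool
    qc_r_ok: bool
    qc_intercept_ok: bool | None = None  # None when no paired curve given


def fit_standard_curve(
    dilutions: pd.DataFrame,
    paired_curve: "StandardCurve | None" = None,
) -> StandardCurve:
    """Least-squares fit of Ct against log10(template amount).

    ``dilutions`` needs columns ``template`` and ``ct`` with >= 3 distinct
    template amounts.
    """
    t = np.asarray(dilutions["template"], dtype=float)
    ct = np.asarray(dilutions["ct"], dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("standard curve needs at least 3 distinct dilution points")
    fit = stats.linregress(np.log10(t), ct)
    slope = float(fit.slope)
    eff = 100.0 * 10.0 ** (-1.0 / slope) / 2.0
    eff_std = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    slope_ok = bool(QC_SLOPE_RANGE[0] <= slope <= QC_SLOPE_RANGE[1])
    r_ok = bool(abs(fit.rvalue) > QC_MIN_R)
    icpt_ok = None
    if paired_curve is not None:
        icpt_ok = bool(abs(fit.intercept - paired_curve.y_intercept) < QC_MAX_INTERCEPT_DIFF)
    return StandardCurve(
        slope=slope,
        y_intercept=float(fit.intercept),
        r=float(abs(fit.rvalue)),
        efficiency_percent=eff,
        efficiency_standard_percent=eff_std,
        n_points=len(t),
        qc_pass=slope_ok and r_ok and (icpt_ok is not False),
        qc_slope_ok=slope_ok,
        qc_r_ok=r_ok,
        qc_intercept_ok=icpt_ok,
    )


@dataclass
class CopyNumberEstimate:
    sample: str
    group: str
    estimate: float
    cn_min: float
    cn_max: float
    calibrator_cn: float


def _delta_ct(ct: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Replicate-paired dCt per sample (replicate i target vs replicate i
    reference; unpaired replicates are dropped)."""
    t = ct[ct["assay"] == target].set_index(["sample", "replicate"])["ct"]
    r = ct[ct["assay"] == reference].set_index(["sample", "replicate"])["ct"]
    d = (t - r).dropna().rename("dct").reset_index()
    groups = ct.drop_duplicates("sample").set_index("sample")["group"]
    d["group"] = d["sample"].map(groups)
    return d


def copy_number_ddct(
    ct: pd.DataFrame,
    target_assay: str,
    reference_assay: str = "SOX5",
    calibrator_sample: str | None = None,
    calibrator_cn: float = 2.0,
) -> list[CopyNumberEstimate]:
    d = _delta_ct(ct, target_assay, reference_assay)
    if calibrator_sample is None:
        raise ValueError("a calibrator sample of known copy number is required")
    cal = d[d["sample"] == calibrator_sample]["dct"]
    if len(cal) == 0:
        raise ValueError(f"no replicates for calibrator {calibrator_sample!r}")
    cal_mean = cal.mean()
    out = []
    for sid, sub in d.groupby("sample", sort=False):
        ddct = sub["dct"].to_numpy() - cal_mean
        cns = calibrator_cn * 2.0 ** (-ddct)
        out.append(
            CopyNumberEstimate(
                sample=str(sid),
                group=str(sub["group"].iloc[0]),
                estimate=float(calibrator_cn * 2.0 ** (-(sub["dct"].mean() - cal_mean))),
                cn_min=float(cns.min()),
                cn_max=float(cns.max()),
                calibrator_cn=calibrator_cn,
            )
        )
    return out


@dataclass
class ExpressionResult:
    gene: str
    group: str
    control_group: str
    fold_change: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    test: str
    detected: bool = True


def relative_expression_ddct(
    ct: pd.DataFrame,
    gene: str,
    reference_gene: str = "GAPDH",
    control_group: str = "N",
) -> list[ExpressionResult]:
    """Group fold changes for one gene, normalized to the reference gene and
    the control group."""
    d = _delta_ct(ct, gene, reference_gene)
    sample_d = d.groupby(["group", "sample"])["dct"].mean().reset_index()
    groups = [g for g in ct["group"].unique() if g in set(sample_d["group"])]
    gene_rows = ct[ct["assay"] == gene]
    all_groups = list(dict.fromkeys(ct["group"]))
    if control_group not in all_groups:
        raise ValueError(f"control group {control_group!r} not in Ct table")

    out: list[ExpressionResult] = []
    ctrl = sample_d[sample_d["group"] == control_group]["dct"].to_numpy()
    test_groups = [g for g in all_groups if g != control_group]
    multi = len(test_groups) > 1

    for g in all_groups:
        if g == control_group:
            continue
        g_ct = gene_rows[gene_rows["group"] == g]["ct"]
        if g_ct.isna().all() or g not in set(sample_d["group"]):
            out.append(
                ExpressionResult(gene, g, control_group, None, None, None, "none", detected=False)
            )
            continue
        x = sample_d[sample_d["group"] == g]["dct"].to_numpy()
        if len(ctrl) == 0:
            raise ValueError("control group has no detected samples")
        ddct = x.mean() - ctrl.mean()
        fold = 2.0 ** (-ddct)
        se = math.sqrt(
            (x.var(ddof=1) / len(x) if len(x) > 1 else 0.0)
            + (ctrl.var(ddof=1) / len(ctrl) if len(ctrl) > 1 else 0.0)
        )
        ci = (2.0 ** (-(ddct + 1.96 * se)), 2.0 ** (-(ddct - 1.96 * se)))
        ci = (min(ci), max(ci))
        if multi:
            samples_by_group = [
                sample_d[sample_d["group"] == gg]["dct"].to_numpy() for gg in all_groups
                if gg in set(sample_d["group"])
            ]
            stat = stats.f_oneway(*samples_by_group)
            p, test = float(stat.pvalue), "one-way ANOVA"
        else:
            test = "t-test"
            degenerate = np.allclose(x, x.mean()) and np.allclose(ctrl, ctrl.mean())
            if degenerate:  # noiseless input: no within-group variance
                p = 1.0 if np.isclose(x.mean(), ctrl.mean()) else 0.0
            else:
                stat = stats.ttest_ind(x, ctrl, equal_var=True)
                p = float(stat.pvalue)
        if math.isnan(p):
            p = 1.0 if np.isclose(x.mean(), ctrl.mean()) else 0.0
        out.append(ExpressionResult(gene, str(g), control_group, float(fold), ci, p, test))
    return out
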