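#!/usr/bin/env python
"""qPCR stage: standard-curve QC, ddCt genomic copy number for the cohort,
and ddCt relative expression for the planted skin contrasts.

Writes results/qpcr.json.
"""

from pathlib import Path

import dermadup as dd
from dermadup import io as dio

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

# standard curves at the QC window endpoints and at perfect doubling
curves = {}
for slope in (-3.3219, -3.1035, -3.7762):
    c = dd.fit_standard_curve(dd.dilution_series_cts(slope=slope))
    curves[f"{slope}"] = {"efficiency_percent": round(c.efficiency_percent, 1),
                          "r": round(c.r, 4), "qc_pass": c.qc_pass}
    print(f"standard curve slope {slope}: efficiency {c.efficiency_percent:.1f}%, "
          f"R {c.r:.4f}, QC {'pass' if c.qc_pass else 'fail'}")

# genomic copy number for a small panel (noiseless: exact recovery)
ref = dd.build_reference()
allele = dd.build_fm_allele(ref, "FM_2")
cohort = dd.simulate_array_cohort(ref, allele, dd.ArrayCohortSpec(seed=1))
cn_truth = {sid: cns["D1"] for sid, cns in cohort.truth.copy_numbers.items()}
calibrator = cohort.ids("WT")[0]
design = dd.copy_number_design(cn_truth, cohort.truth.groups, calibrator_sample=calibrator)
ct = dd.simulate_qpcr_ct(design, seed=1, noise_sd=0.15)
calls = dd.copy_number_ddct(ct, "Dup1", "SOX5", calibrator, 2.0)
print("genomic copy number (Dup1 amplicon, technical noise SD 0.15 cycles):")
by_group = {}
for c in calls:
    by_group.setdefault(c.group, []).append(c.estimate)
for group, ests in by_group.items():
    print(f"  {group}: mean {sum(ests)/len(ests):.2f} over {len(ests)} samples")

# relative expression, adult skin
expr_ct = dd.simulate_qpcr_ct(dd.expression_design(tissue="skin"), seed=1, noise_sd=0.1)
expression = {}
for gene in ("EDN3", "SLMO2", "TUBB1"):
    (res,) = dd.relative_expression_ddct(expr_ct, gene, "GAPDH", "N")
    expression[gene] = {"fold_change": round(res.fold_change, 2),
                        "ci95": [round(v, 2) for v in res.ci95],
                        "p_value": res.p_value, "test": res.test}
    print(f"expression {gene} (FM vs N skin): {res.fold_change:.2f}-fold "
          f"[{res.ci95[0]:.2f}, {res.ci95[1]:.2f}], p={res.p_value:.2e} ({res.test})")

dio.write_json(
    OUT / "qpcr.json",
    {
        "standard_curves": curves,
        "copy_number": [
            {"sample": c.sample, "group": c.group, "estimate": round(c.estimate, 3),
             "min": round(c.cn_min, 3), "max": round(c.cn_max, 3),
             "truth": cn_truth[c.sample]}
            for c in calls
        ],
        "expression_skin": expression,
    },
)
print(f"wrote {OUT/'qpcr.json'}")
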