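"""Synthetic qPCR threshold-cycle (Ct) tables.

The idealized amplification model: with per-cycle efficiency E (fraction,
1.0 = perfect doubling), the threshold cycle of a sample with template
amount T is

    Ct = intercept - log2(T) / log2(1 + E)

so at 100% efficiency one extra log2 of template advances Ct by exactly one
cycle.  A design row lists a sample, its group, an assay and the truth
template amount (genomic copies for copy-number assays, relative transcript
abundance for expression assays); zero/absent template yields an undetected
(missing) Ct.  Technical replicates add independent Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class QpcrDesign:
    """Long-format design: one row per sample x assay."""

    table: pd.DataFrame  # columns: sample, group, assay, template
    reference_assay: str
    calibrator_sample: str | None = None

    def __post_init__(self) -> None:
        need = {"sample", "group", "assay", "template"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"design table must have columns {sorted(need)}")
        if self.reference_assay not in set(self.table["assay"]):
            raise ValueError("reference assay missing from design")
        if self.calibrator_sample is not None and self.calibrator_sample not in set(self.table["sample"]):
            raise ValueError("calibrator sample missing from design")


def simulate_qpcr_ct(
    design: QpcrDesign,
    seed: int = 1,
    noise_sd: float = 0.0,
    replicates: int = 3,
    intercept: float = 35.0,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Ct table (sample, group, assay, replicate, ct); NaN ct = undetected."""
    rng = np.random.default_rng(seed)
    slope_factor = 1.0 / math.log2(1.0 + efficiency)
    rows = []
    for _, r in design.table.iterrows():
        t = r["template"]
        for rep in range(1, replicates + 1):
            if t is None or (isinstance(t, float) and (np.isnan(t))) or t <= 0:
                ct = np.nan
            else:
                ct = intercept - slope_factor * math.log2(t)
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
            rows.append((r["sample"], r["group"], r["assay"], rep, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "assay", "replicate", "ct"])


def copy_number_design(
    copy_numbers: dict[str, float],
    groups: dict[str, str],
    target_assays: tuple[str, ...] = ("Dup1", "Dup2"),
    reference_assay: str = "SOX5",
    calibrator_sample: str | None = None,
    reference_cn: float = 2.0,
) -> QpcrDesign:
    """Genomic copy-number design: target template = locus copies, reference
    assay (single-copy gene) = 2 in every sample."""
    rows = []
    for sid, cn in copy_numbers.items():
        for assay in target_assays:
            rows.append((sid, groups.get(sid, ""), assay, float(cn)))
        rows.append((sid, groups.get(sid, ""), reference_assay, reference_cn))
    return QpcrDesign(
        table=pd.DataFrame(rows, columns=["sample", "group", "assay", "template"]),
        reference_assay=reference_assay,
        calibrator_sample=calibrator_sample,
    )


#: planted relative-expression contrasts (carrier vs wild-type), by gene and tissue.
#: EDN3 in adult skin is the printed ~10-fold contrast; the others are
#: plausible in-duplication upregulation magnitudes.
DEFAULT_EXPRESSION_FOLDS: dict[str, dict[str, float]] = {
    "EDN3": {"skin": 10.0, "muscle": 4.0},
    "SLMO2": {"skin": 2.5, "muscle": 2.0},
    "TUBB1": {"skin": 2.0, "muscle": 2.0},
}


def expression_design(
    fold_changes: dict[str, dict[str, float]] | None = None,
    tissue: str = "skin",
    n_per_group: int = 3,
    reference_gene: str = "GAPDH",
    base_abundance: float = 100.0,
) -> QpcrDesign:
    """Two-group (carrier FM vs wild-type N) expression design for one tissue.

    Target template = base_abundance in wild-type, fold * base in carriers;
    the reference gene is invariant across groups.
    """
    folds = fold_changes or DEFAULT_EXPRESSION_FOLDS
    rows = []
    for group, prefix in (("FM", "FM"), ("N", "N")):
        for i in range(1, n_per_group + 1):
            sid = f"{prefix}_{tissue}_{i}"
            for gene, per_tissue in folds.items():
                fold = per_tissue.get(tissue)
                if fold is None:
                    continue
                amount = base_abundance * (fold if group == "FM" else 1.0)
                rows.append((sid, group, gene, amount))
            rows.append((sid, group, reference_gene, base_abundance))
    return QpcrDesign(
        table=pd.DataFrame(rows, columns=["sample", "group", "assay", "template"]),
        reference_assay=reference_gene,
    )


def dilution_series_cts(
    slope: float,
    y_intercept: float = 35.0,
    points: int = 7,
    dilution_factor: float = 5.0,
    start_template: float = 1e5,
    noise_sd: float = 0.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Standard-curve input: Ct = y_intercept + slope * log10(template)."""
    rng = np.random.default_rng(seed)
    template = start_template / dilution_factor ** np.arange(points)
    ct = y_intercept + slope * np.log10(template)
    if noise_sd > 0:
        ct = ct + rng.normal(0, noise_sd, size=points)
    return pd.DataFrame({"template": template, "ct": ct})
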