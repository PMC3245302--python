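"""SNP-array cohort simulator: genotype calls and Log R ratios.

Emulates a 60K-chip style panel over the locus: markers on a regular grid,
per-individual Log R ratios (normalized total intensity, mean 0 in diploid
state) and genotype calls.  Duplication carriers get an additive mean LRR
shift at markers inside the duplicated regions (+0.30 for four copies,
+0.15 for three -- the compressed magnitudes arrays actually show, rather
than the ideal log2(CN/2)), Gaussian noise on top.  Five markers inside D1
are paralogous sequence variants: fixed differences between the duplicate
copies that the array reads as constitutive heterozygosity in every carrier.
Carriers additionally share an identical-by-descent haplotype across the
PSV block, with forced discordance at the immediately flanking markers so
the planted shared interval is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele import FmAllele
from .reference import ReferenceModel
from .truth import TruthSet

GENOTYPES = np.array(["AA", "AB", "BB"], dtype=object)
MISSING = "NC"


@dataclass
class ArrayCohortSpec:
    n_fm: int = 12
    n_het: int = 3
    n_wt: int = 12
    marker_spacing: int = 6_000
    lrr_noise_sd: float = 0.15
    lrr_shift_cn4: float = 0.30  # 4 copies vs 2
    lrr_shift_cn3: float = 0.15  # 3 copies vs 2
    psv_marker_count: int = 5
    psv_fixed_ref_count: int = 2  # of the PSVs, how many are fixed-reference in wild-type
    psv_span: int = 75_000       # approximate span of the PSV block inside D1
    genotype_noise: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_fm < 1 or self.n_wt < 1:
            raise ValueError("cohort needs at least one FM and one WT individual")
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be positive")
        if self.psv_fixed_ref_count > self.psv_marker_count:
            raise ValueError("more fixed-reference PSVs than PSVs")


@dataclass
class ArrayCohort:
    """Markers x individuals matrices plus sample labels."""

    markers: pd.DataFrame           # index marker id; columns chrom, pos
    genotypes: pd.DataFrame         # index marker id; columns sample ids
    lrr: pd.DataFrame               # index marker id; columns sample ids
    samples: pd.DataFrame           # index sample id; column group in {FM, HET, WT}
    truth: TruthSet

    def ids(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])


def _marker_grid(ref: ReferenceModel, spacing: int) -> pd.DataFrame:
    pos = np.arange(ref.locus.start, ref.locus.end + 1, spacing, dtype=np.int64)
    ids = [f"m{i:04d}" for i in range(len(pos))]
    return pd.DataFrame({"chrom": ref.chrom_name, "pos": pos}, index=pd.Index(ids, name="id"))


def simulate_array_cohort(
    ref: ReferenceModel,
    allele: FmAllele,
    spec: ArrayCohortSpec,
) -> ArrayCohort:
    rng = np.random.default_rng(spec.seed)
    markers = _marker_grid(ref, spec.marker_spacing)
    pos = markers["pos"].to_numpy()
    d1, d2 = ref.blocks["D1"], ref.blocks["D2"]
    in_dup = ((pos >= d1.start) & (pos <= d1.end)) | ((pos >= d2.start) & (pos <= d2.end))

    fm_ids = [f"FM{i:02d}" for i in range(spec.n_fm)]
    het_ids = [f"HET{i:02d}" for i in range(spec.n_het)]
    wt_ids = [f"WT{i:02d}" for i in range(spec.n_wt)]
    samples = pd.DataFrame(
        {"group": ["FM"] * spec.n_fm + ["HET"] * spec.n_het + ["WT"] * spec.n_wt},
        index=pd.Index(fm_ids + het_ids + wt_ids, name="sample"),
    )
    all_ids = list(samples.index)
    n_markers, n_samples = len(markers), len(all_ids)

    # copy numbers follow the allele's block copy counts (a wild-type
    # "mutant" arrangement yields the diploid state everywhere)
    copies = allele.arrangement.copy_numbers
    cn_by_group = {
        "FM": {b: 2 * copies[b] for b in ("D1", "S", "D2")},
        "HET": {b: copies[b] + 1 for b in ("D1", "S", "D2")},
        "WT": {b: 2 for b in ("D1", "S", "D2")},
    }
    shift_for = {4: spec.lrr_shift_cn4, 3: spec.lrr_shift_cn3}

    # --- Log R ratios: additive copy-state shift + Gaussian noise
    shift = np.zeros((n_markers, n_samples))
    block_masks = {
        b: (pos >= ref.blocks[b].start) & (pos <= ref.blocks[b].end) for b in ("D1", "D2")
    }
    for j, sid in enumerate(all_ids):
        g = samples.loc[sid, "group"]
        for b, mask in block_masks.items():
            shift[mask, j] = shift_for.get(cn_by_group[g][b], 0.0)
    lrr = shift + rng.normal(0.0, spec.lrr_noise_sd, size=(n_markers, n_samples))
    lrr_df = pd.DataFrame(lrr, index=markers.index, columns=all_ids)

    # --- genotypes: random population calls, then planted structure
    gt = rng.choice(GENOTYPES, size=(n_markers, n_samples), p=[0.4, 0.2, 0.4])

    carriers = [j for j, sid in enumerate(all_ids) if samples.loc[sid, "group"] in ("FM", "HET")]
    wt_cols = [j for j, sid in enumerate(all_ids) if samples.loc[sid, "group"] == "WT"]
    fm_cols = [j for j, sid in enumerate(all_ids) if samples.loc[sid, "group"] == "FM"]

    psv_ids: list[str] = []
    psv_classes: dict[str, str] = {}
    shared_block: list[int] | None = None
    if spec.psv_marker_count > 0:
        # PSV block: markers inside D1 spanning ~psv_span
        d1_idx = np.where((pos >= d1.start) & (pos <= d1.end))[0]
        if len(d1_idx) < spec.psv_marker_count:
            raise ValueError("not enough in-D1 markers for the requested PSV count")
        span_markers = d1_idx[pos[d1_idx] <= pos[d1_idx[0]] + spec.psv_span]
        if len(span_markers) < spec.psv_marker_count:
            span_markers = d1_idx[: spec.psv_marker_count]
        psv_idx = np.unique(
            np.linspace(span_markers[0], span_markers[-1], spec.psv_marker_count).round().astype(int)
        )
        psv_ids = list(markers.index[psv_idx])

        # shared carrier haplotype across the PSV block (homozygous carriers identical)
        block_lo, block_hi = psv_idx[0], psv_idx[-1]
        shared_block = [int(pos[block_lo]), int(pos[block_hi])]
        for i in range(block_lo, block_hi + 1):
            hap_gt = GENOTYPES[int(rng.integers(0, 2)) * 2]  # AA or BB, never AB off-PSV
            for j in fm_cols:
                gt[i, j] = hap_gt
        # force discordance just outside the shared block
        if len(fm_cols) >= 2:
            for i in (block_lo - 1, block_hi + 1):
                if 0 <= i < n_markers:
                    gt[i, fm_cols[0]] = "AA"
                    gt[i, fm_cols[1]] = "BB"

        # PSVs read as constitutive heterozygosity in every carrier
        for i in psv_idx:
            for j in carriers:
                gt[i, j] = "AB"
        # wild-type classification at PSVs: fixed-reference vs segregating
        for rank, i in enumerate(psv_idx):
            if rank < spec.psv_fixed_ref_count:
                for j in wt_cols:
                    gt[i, j] = "AA"
                psv_classes[markers.index[i]] = "fixed_ref"
            else:
                for j in wt_cols:
                    gt[i, j] = GENOTYPES[int(rng.integers(0, 3))]
                gt[i, wt_cols[0]] = "AA"  # guarantee both alleles observed
                gt[i, wt_cols[-1]] = "AB"
                psv_classes[markers.index[i]] = "segregating"

    if spec.genotype_noise > 0:
        flip = rng.random(gt.shape) < spec.genotype_noise
        gt[flip] = rng.choice(GENOTYPES, size=int(flip.sum()))

    gt_df = pd.DataFrame(gt, index=markers.index, columns=all_ids)

    truth = TruthSet(
        breakpoints={"D1": [d1.start, d1.end], "D2": [d2.start, d2.end]},
        copy_numbers={sid: dict(cn_by_group[samples.loc[sid, "group"]]) for sid in all_ids},
        psv_markers=psv_ids,
        psv_classes=psv_classes,
        shared_haplotype=shared_block,
        junction_overlaps={j.kind: j.overlap for j in allele.junctions},
        junctions=allele.truth_fragment()["junctions"],
        groups={sid: samples.loc[sid, "group"] for sid in all_ids},
        lrr_shift={"FM": spec.lrr_shift_cn4, "HET": spec.lrr_shift_cn3, "WT": 0.0},
    )
    return ArrayCohort(markers=markers, genotypes=gt_df, lrr=lrr_df, samples=samples, truth=truth)
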