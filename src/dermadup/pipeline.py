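"""End-to-end orchestration: simulate -> scan -> enumerate -> quantify.

``run_all`` executes every stage on one seed and one configuration and
returns a JSON-serializable run report with truth-versus-called comparisons
(boundary errors, copy-number errors, fold-change errors) and the surviving
rearrangement scenarios.  Regenerating with the same configuration
reproduces the report exactly (no timestamps are embedded).
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .allele import build_fm_allele
from .array_scan import call_elevated_regions, fixed_het_scan, groupwise_delta, shared_haplotype_interval
from .cbs import CbsParams, cbs_segment
from .cohort import ArrayCohortSpec, simulate_array_cohort
from .intervals import GenomicInterval, gap, to_kb
from .pooled_sv import SvParams, candidate_sv_windows, depth_gain_regions, log2_fold_change, refine_junction, window_depth
from .pools import PoolSpec, mapping_distance_stats, simulate_matepair_pool
from .qpcr import copy_number_ddct, fit_standard_curve, relative_expression_ddct
from .qpcr_sim import (
    QpcrDesign,
    copy_number_design,
    dilution_series_cts,
    expression_design,
    simulate_qpcr_ct,
)
from .rearrange import RecombinantObservation, consistent_scenarios, enumerate_arrangements
from .reference import build_reference
from . import io as dio


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


@dataclass
class RunConfig:
    seed: int = 1
    scenario: str = "FM_2"
    array: ArrayCohortSpec = field(default_factory=ArrayCohortSpec)
    pool: PoolSpec = field(default_factory=PoolSpec)
    cbs: CbsParams = field(default_factory=CbsParams)
    sv: SvParams = field(default_factory=SvParams)
    delta_threshold: float = 0.1
    delta_min_run: int = 5
    cbs_individuals: int = 1  # how many carriers to segment individually
    qpcr_noise_sd: float = 0.0
    expression_tissue: str = "skin"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name, sub_cls in (
            ("array", ArrayCohortSpec),
            ("pool", PoolSpec),
            ("cbs", CbsParams),
            ("sv", SvParams),
        ):
            if name in raw:
                kwargs[name] = sub_cls(**raw.pop(name))
        kwargs.update(raw)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one top-level seed to every stage."""
        child = np.random.SeedSequence(seed).generate_state(4) % (2**31 - 1)
        return dataclasses.replace(
            self,
            seed=seed,
            array=dataclasses.replace(self.array, seed=int(child[0])),
            pool=dataclasses.replace(self.pool, seed=int(child[1])),
        )


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    report: dict = {"version": __version__, "config": _config_dict(config)}

    _log("reference", "building reference model and mutant allele")
    ref = build_reference(seed=config.seed + 7)
    allele = build_fm_allele(ref, config.scenario)
    d1, d2 = ref.blocks["D1"], ref.blocks["D2"]
    report["reference"] = {
        "locus": str(ref.locus),
        "D1": str(d1),
        "D2": str(d2),
        "D1_len": d1.length,
        "D2_len": d2.length,
        "gap_bp": gap(d1, d2),
        "gap_kb": to_kb(gap(d1, d2)),
    }

    # --- SNP array stage
    _log("array", f"simulating cohort ({config.array.n_fm} FM / {config.array.n_wt} WT)")
    cohort = simulate_array_cohort(ref, allele, config.array)
    fm, wt = cohort.ids("FM"), cohort.ids("WT")
    track = groupwise_delta(
        cohort.lrr[fm], cohort.lrr[wt], cohort.markers["pos"],
        threshold=config.delta_threshold, min_run=config.delta_min_run, chrom=ref.chrom_name,
    )
    regions = call_elevated_regions(track)
    truth_bounds = [d1.start, d1.end, d2.start, d2.end]
    boundary_errors = _boundary_errors(regions, d1, d2)
    het_markers = fixed_het_scan(cohort.genotypes, cohort.markers, fm, wt)
    try:
        shared = shared_haplotype_interval(cohort.genotypes, cohort.markers, fm)
    except ValueError:
        shared = None  # no fixed-heterozygosity block (e.g. wild-type-only run)
    segments = {}
    for sid in fm[: config.cbs_individuals]:
        segs = cbs_segment(
            cohort.lrr[sid].to_numpy(), cohort.markers["pos"].to_numpy(), config.cbs, ref.chrom_name
        )
        segments[sid] = [
            {"interval": str(s.interval), "n_markers": s.n_markers, "mean_lrr": round(s.mean_lrr, 4)}
            for s in segs
        ]
    report["array"] = {
        "regions": [
            {
                "interval": str(r.interval),
                "boundaries": r.boundary_estimates,
                "n_markers": r.n_markers,
                "mean_delta": round(r.mean_delta, 4),
            }
            for r in regions
        ],
        "n_regions": len(regions),
        "boundary_errors_bp": boundary_errors,
        "max_boundary_error_bp": max(boundary_errors) if boundary_errors else None,
        "truth_boundaries": truth_bounds,
        "fixed_het_markers": [dataclasses.asdict(m) for m in het_markers],
        "n_fixed_het": len(het_markers),
        "shared_haplotype": None if shared is None else str(shared),
        "cbs_segments": segments,
    }

    # --- pooled sequencing stage
    _log("pools", f"simulating mate-pair pools at {config.pool.target_depth}x")
    fm_pool = simulate_matepair_pool(ref, allele, dataclasses.replace(config.pool, genotype="FM/FM"))
    wt_pool = simulate_matepair_pool(
        ref, None, dataclasses.replace(config.pool, genotype="N/N", seed=config.pool.seed + 1)
    )
    t_fm = window_depth(fm_pool, ref.locus, config.sv.window_size)
    t_wt = window_depth(wt_pool, ref.locus, config.sv.window_size)
    fc = log2_fold_change(t_fm, t_wt)
    gains = depth_gain_regions(fc, config.sv.window_size, ref.locus.start, chrom=ref.chrom_name)
    stats_fm = mapping_distance_stats(fm_pool)
    candidates = candidate_sv_windows(fm_pool, config.sv, stats_fm, ref.locus)
    in_dup = _windows_inside(t_fm, d1, d2)
    median_fc_dup = float(np.median(2.0 ** fc[in_dup]))
    in_gap = _windows_inside(t_fm, ref.blocks["S"])
    junctions = {}
    for j in allele.junctions:
        call = refine_junction(allele.junction_fragment(j.kind), ref)
        junctions[j.kind] = {
            "microhomology_len": call.microhomology_len,
            "microhomology_seq": call.microhomology_seq,
            "inserted_seq": call.inserted_seq,
            "breakpoint_a": call.breakpoint_a,
            "breakpoint_b": call.breakpoint_b,
            "truth_overlap": j.overlap,
        }
    report["pools"] = {
        "n_pairs": {"FM": len(fm_pool), "WT": len(wt_pool)},
        "distance_stats_FM": {"mean": round(stats_fm[0], 1), "sd": round(stats_fm[1], 1)},
        "median_fold_change_in_duplications": round(median_fc_dup, 3),
        "median_fold_change_in_gap": round(float(np.median(2.0 ** fc[in_gap])), 3),
        "depth_gain_regions": [str(g) for g in gains],
        "n_sv_candidates": len(candidates),
        "sv_candidates": [
            {
                "window": str(c.window),
                "partner": str(c.partner_window),
                "support": c.supporting_pairs,
                "inversion": c.inversion_flag,
            }
            for c in candidates
        ],
        "junctions": junctions,
    }

    # --- rearrangement logic stage
    _log("rearrange", "enumerating arrangements and applying recombinant elimination")
    arrangements = enumerate_arrangements()
    survivors = consistent_scenarios(arrangements, RecombinantObservation())
    report["rearrangement"] = {
        "n_arrangements": len(arrangements),
        "arrangements": [str(a) for a in arrangements],
        "survivors": [str(a) for a in survivors],
    }

    # --- qPCR stage
    _log("qpcr", "copy-number and expression ddCt")
    cn_truth = {sid: cns["D1"] for sid, cns in cohort.truth.copy_numbers.items()}
    calibrator = wt[0]
    design = copy_number_design(cn_truth, cohort.truth.groups, calibrator_sample=calibrator)
    ct = simulate_qpcr_ct(design, seed=config.seed + 11, noise_sd=config.qpcr_noise_sd)
    cn_calls = copy_number_ddct(ct, "Dup1", "SOX5", calibrator, 2.0)
    cn_errors = [abs(c.estimate - cn_truth[c.sample]) for c in cn_calls]
    expr_design = expression_design(tissue=config.expression_tissue)
    expr_ct = simulate_qpcr_ct(expr_design, seed=config.seed + 13, noise_sd=config.qpcr_noise_sd)
    expr = relative_expression_ddct(expr_ct, "EDN3", "GAPDH", "N")
    curve = fit_standard_curve(dilution_series_cts(slope=-3.3219))
    report["qpcr"] = {
        "copy_number": [
            {"sample": c.sample, "group": c.group, "estimate": round(c.estimate, 3),
             "min": round(c.cn_min, 3), "max": round(c.cn_max, 3)}
            for c in cn_calls
        ],
        "max_copy_number_error": round(max(cn_errors), 4),
        "expression_EDN3": [
            {"group": e.group, "fold_change": None if e.fold_change is None else round(e.fold_change, 3),
             "p_value": e.p_value, "test": e.test, "detected": e.detected}
            for e in expr
        ],
        "standard_curve": {
            "slope": round(curve.slope, 4),
            "efficiency_percent": round(curve.efficiency_percent, 1),
            "qc_pass": curve.qc_pass,
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_json(outdir / "run_report.json", report)
        dio.write_matrix_tsv(outdir / "lrr.tsv", cohort.markers, cohort.lrr)
        dio.write_matrix_tsv(outdir / "genotypes.tsv", cohort.markers, cohort.genotypes)
        dio.write_samples_tsv(outdir / "samples.tsv", cohort.samples)
        dio.write_bed(outdir / "regions.bed", [r.interval for r in regions])
        dio.write_bedgraph(outdir / "log2fc.bedgraph", ref.chrom_name, ref.locus.start, config.sv.window_size, fc)
        dio.write_bed(outdir / "sv_candidates.bed", [c.window for c in candidates],
                      [f"sv{k}_inv{int(c.inversion_flag)}" for k, c in enumerate(candidates)])
        cohort.truth.to_json(outdir / "truth.json")
        _log("pipeline", f"wrote outputs to {outdir}")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _boundary_errors(regions, d1: GenomicInterval, d2: GenomicInterval) -> list[float]:
    errs = []
    for dup in (d1, d2):
        overlapping = [r for r in regions if r.interval.overlaps(dup)]
        if not overlapping:
            continue
        for truth, pick in ((dup.start, 0), (dup.end, 1)):
            est = min((r.boundary_estimates[pick] for r in overlapping), key=lambda e: abs(e - truth))
            errs.append(abs(est - truth))
    return errs


def _windows_inside(track, *intervals: GenomicInterval) -> np.ndarray:
    idx = []
    for w in range(len(track.counts)):
        wi = track.window_interval(w)
        if any(iv.contains_interval(wi) for iv in intervals):
            idx.append(w)
    return np.array(idx, dtype=int)
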