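#!/usr/bin/env python
"""Pooled mate-pair sequencing stage: 30x carrier and control pools, 1 kb
window depth fold change, candidate structural variants, and base-pair
junction refinement.

Writes results/pools.json, results/log2fc.bedgraph and
results/sv_candidates.bed.
"""

from pathlib import Path

import numpy as np

import dermadup as dd
from dermadup import io as dio
from dermadup.pipeline import _windows_inside
from dermadup.pools import mapping_distance_stats

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

ref = dd.build_reference()
allele = dd.build_fm_allele(ref, "FM_2")
fm_pool = dd.simulate_matepair_pool(ref, allele, dd.PoolSpec(seed=1, genotype="FM/FM"))
wt_pool = dd.simulate_matepair_pool(ref, None, dd.PoolSpec(seed=2))
print(f"simulated pools: carrier {len(fm_pool):,} pairs, control {len(wt_pool):,} pairs (30x)")

t_fm = dd.window_depth(fm_pool, ref.locus)
t_wt = dd.window_depth(wt_pool, ref.locus)
fc = dd.log2_fold_change(t_fm, t_wt)
in_dup = _windows_inside(t_fm, ref.blocks["D1"], ref.blocks["D2"])
in_gap = _windows_inside(t_fm, ref.blocks["S"])
med_dup = float(np.median(2.0 ** fc[in_dup]))
med_gap = float(np.median(2.0 ** fc[in_gap]))
print(f"median depth fold change: {med_dup:.3f} inside duplications, {med_gap:.3f} in the gap")

gains = dd.depth_gain_regions(fc, 1000, ref.locus.start, chrom=ref.chrom_name)
print(f"depth-gain regions (>= 20 windows with log2FC >= 0.8): {[str(g) for g in gains]}")

stats = mapping_distance_stats(fm_pool)
cands = dd.candidate_sv_windows(fm_pool, dd.SvParams(), stats, ref.locus)
print(f"candidate SV windows in carrier pool ({stats[0]:.0f} +/- {stats[1]:.0f} bp distances):")
for c in cands:
    print(f"  {c.window} -> {c.partner_window}  {c.supporting_pairs} pairs  "
          f"inversion={c.inversion_flag}")
wt_cands = dd.candidate_sv_windows(wt_pool, dd.SvParams(), mapping_distance_stats(wt_pool), ref.locus)
print(f"candidate SV windows in control pool: {len(wt_cands)}")

junctions = {}
for j in allele.junctions:
    call = dd.refine_junction(allele.junction_fragment(j.kind), ref)
    junctions[j.kind] = call
    print(f"junction {j.kind}: microhomology {call.microhomology_len} bp "
          f"{call.microhomology_seq!r}, breakpoints {call.breakpoint_a:,} / {call.breakpoint_b:,}")

dio.write_bedgraph(OUT / "log2fc.bedgraph", ref.chrom_name, ref.locus.start, 1000, fc)
dio.write_bed(OUT / "sv_candidates.bed", [c.window for c in cands],
              [f"sv{k}_inv{int(c.inversion_flag)}" for k, c in enumerate(cands)])
dio.write_json(
    OUT / "pools.json",
    {
        "n_pairs": {"carrier": len(fm_pool), "control": len(wt_pool)},
        "median_fold_change": {"in_duplications": round(med_dup, 4), "in_gap": round(med_gap, 4)},
        "depth_gain_regions": [str(g) for g in gains],
        "sv_candidates": [
            {"window": str(c.window), "partner": str(c.partner_window),
             "support": c.supporting_pairs, "inversion": c.inversion_flag}
            for c in cands
        ],
        "control_pool_candidates": len(wt_cands),
        "junctions": {
            k: {"microhomology_len": v.microhomology_len,
                "microhomology_seq": v.microhomology_seq,
                "breakpoint_a": v.breakpoint_a, "breakpoint_b": v.breakpoint_b}
            for k, v in junctions.items()
        },
    },
)
print(f"wrote {OUT/'pools.json'}")
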