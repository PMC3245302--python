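#!/usr/bin/env python
"""Build the synthetic study inputs: wild-type reference, rearranged allele,
and the machine-readable truth record.

Prints the locus geometry (the quantities every later stage is scored
against) and writes results/locus.json and results/truth.json.
"""

from pathlib import Path

import dermadup as dd
from dermadup import io as dio
from dermadup.intervals import gap, to_kb

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

ref = dd.build_reference()
allele = dd.build_fm_allele(ref, "FM_2")
d1, d2 = ref.blocks["D1"], ref.blocks["D2"]

print(f"locus            {ref.locus}  ({to_kb(ref.locus.length)} kb)")
print(f"duplication 1    {d1}  ({d1.length:,} bp)")
print(f"duplication 2    {d2}  ({d2.length:,} bp)")
print(f"single-copy gap  {gap(d1, d2):,} bp  ({to_kb(gap(d1, d2))} kb)")
print(f"allele length    {len(allele.sequence):,} bp "
      f"(wild-type + D1 + D2 - 1 bp junction overlap)")
for j in allele.junctions:
    print(f"junction {j.kind}: {j.side_a} joined to {j.side_b}, "
          f"breakpoints {j.breakpoint_a:,} / {j.breakpoint_b:,}, overlap {j.overlap} bp")

dio.write_json(
    OUT / "locus.json",
    {
        "locus": str(ref.locus),
        "D1": {"interval": str(d1), "bp": d1.length, "kb": to_kb(d1.length)},
        "D2": {"interval": str(d2), "bp": d2.length, "kb": to_kb(d2.length)},
        "gap": {"bp": gap(d1, d2), "kb": to_kb(gap(d1, d2))},
        "refined_region_kb": to_kb(dd.GenomicInterval(10_518_217, 11_000_943).length),
        "shared_haplotype_kb": to_kb(dd.GenomicInterval(10_717_600, 10_792_608).length),
        "junctions": allele.truth_fragment()["junctions"],
    },
)

cohort = dd.simulate_array_cohort(ref, allele, dd.ArrayCohortSpec(seed=1))
cohort.truth.to_json(OUT / "truth.json")
print(f"wrote {OUT/'locus.json'} and {OUT/'truth.json'}")
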