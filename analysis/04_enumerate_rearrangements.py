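#!/usr/bin/env python
"""Rearrangement-logic stage: enumerate every locus architecture consistent
with the junction evidence, run the diagnostic in-silico PCR on each, and
apply the recombinant-offspring elimination.

Writes results/rearrangement.json.
"""

from pathlib import Path

import dermadup as dd
from dermadup import io as dio
from dermadup.rearrange import (
    WILDTYPE,
    RecombinantObservation,
    crossover_products,
    diagnostic_assays,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

ref = dd.build_reference()
lens = {name: iv.length for name, iv in ref.blocks.items()}

arrangements = dd.enumerate_arrangements({"D1": 2, "S": 1, "D2": 2})
print(f"{len(arrangements)} arrangements consume the six junction/boundary adjacencies:")
for a in arrangements:
    print(f"  {a}")

assays = diagnostic_assays()
pcr = {}
print("diagnostic in-silico PCR (product sizes, bp):")
for arr in [WILDTYPE] + arrangements:
    sizes = {
        name: [p.size for p in dd.insilico_pcr(arr, primers, lens)]
        for name, primers in assays.items()
    }
    pcr[str(arr)] = sizes
    print(f"  {arr}: {sizes}")

cross = {}
for arr in arrangements:
    out = crossover_products(WILDTYPE, arr, "S")
    cross[str(arr)] = (
        "chromosomal loss (inverted single-copy pairing)"
        if out.loss
        else [str(p) for p in out.products]
    )
    print(f"crossover N x ({arr}): {cross[str(arr)]}")

survivors = dd.consistent_scenarios(arrangements, RecombinantObservation())
print(f"after the wild-type recombinant observation, surviving arrangement(s): "
      f"{[str(a) for a in survivors]}")

dio.write_json(
    OUT / "rearrangement.json",
    {
        "arrangements": [str(a) for a in arrangements],
        "diagnostic_pcr_sizes": pcr,
        "crossover_with_wildtype": cross,
        "survivors": [str(a) for a in survivors],
    },
)
print(f"wrote {OUT/'rearrangement.json'}")
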