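"""Machine-readable record of everything planted by the generators.

The truth set is the scoring surface for every downstream stage: planted
breakpoints, per-individual copy numbers, the constitutively heterozygous
(paralogous sequence variant) markers, junction microhomology lengths, and
planted qPCR quantities.  It serializes losslessly to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class TruthSet:
    breakpoints: dict[str, list[int]] = field(default_factory=dict)  # {"D1": [s, e], ...}
    copy_numbers: dict[str, dict[str, int]] = field(default_factory=dict)  # sample -> block -> CN
    psv_markers: list[str] = field(default_factory=list)
    psv_classes: dict[str, str] = field(default_factory=dict)  # marker -> fixed_ref | segregating
    shared_haplotype: list[int] | None = None  # [start, end] of the planted identical block
    junction_overlaps: dict[str, int] = field(default_factory=dict)  # {"5p": 0, "3p": 1}
    junctions: list[dict] = field(default_factory=list)
    expression_fold_changes: dict[str, dict[str, float]] = field(default_factory=dict)
    qpcr_copy_numbers: dict[str, float] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)  # sample -> FM | HET | WT
    lrr_shift: dict[str, float] = field(default_factory=dict)  # group -> in-duplication shift

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthSet":
        text = str(source)
        if not text.lstrip().startswith("{"):  # a path, not JSON text
            text = Path(source).read_text()
        return cls(**json.loads(text))

    def merge(self, other: "TruthSet") -> "TruthSet":
        """Field-wise union (dicts/lists updated, scalars overwritten if set)."""
        for name in self.__dataclass_fields__:
            mine, theirs = getattr(self, name), getattr(other, name)
            if isinstance(mine, dict):
                mine.update(theirs)
            elif isinstance(mine, list):
                mine.extend(x for x in theirs if x not in mine)
            elif theirs is not None:
                setattr(self, name, theirs)
        return self
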