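"""Pooled mate-pair sequencing simulator.

Pairs are drawn uniformly along a template chromosome -- the wild-type toy
chromosome, or the same chromosome with the locus replaced by a rearranged
allele -- with Normal(mean_insert, insert_sd) fragment lengths, and emitted
directly as mapped reference coordinates through the template's span map
(no alignment step; mapping ambiguity is out of scope).  Reads that straddle
a junction between spans are unmappable and their pair is dropped, as they
would be by a gapped-intolerant short-read mapper.

A pair whose fragment spans a novel junction acquires an aberrant implied
distance and/or a discordant strand pattern in reference coordinates: that
is the raw signal the structural-variant scan consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allele import FmAllele, Span, wildtype_spans
from .reference import ReferenceModel


@dataclass
class PoolSpec:
    mean_insert: float = 2_500.0
    insert_sd: float = 300.0
    read_length: int = 50
    target_depth: float = 30.0
    genotype: str = "N/N"  # "FM/FM" or "N/N"; informational label
    seed: int = 1
    region_only: bool = False  # restrict the template to the locus (no chromosome background)

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if self.mean_insert <= 2 * self.read_length:
            raise ValueError("mean insert must exceed two read lengths")


@dataclass
class MatePairSet:
    """Mapped mate pairs in reference coordinates (leftmost base, 1-based)."""

    pos1: np.ndarray
    strand1: np.ndarray  # +1 / -1
    pos2: np.ndarray
    strand2: np.ndarray
    read_length: int
    chrom: str
    library_total_reads: int  # chromosome-wide mapped reads (both mates)

    def __len__(self) -> int:
        return len(self.pos1)

    @property
    def distance(self) -> np.ndarray:
        """Mapping distance: absolute difference of leftmost coordinates."""
        return np.abs(self.pos2 - self.pos1)

    @property
    def leftmost(self) -> np.ndarray:
        return np.minimum(self.pos1, self.pos2)

    @property
    def strand_discordant(self) -> np.ndarray:
        """True where both mates map to the same strand (inversion signature
        for a forward/reverse library)."""
        return self.strand1 == self.strand2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pos1": self.pos1,
                "strand1": self.strand1,
                "pos2": self.pos2,
                "strand2": self.strand2,
            }
        )


def _template_spans(ref: ReferenceModel, allele: FmAllele | None, region_only: bool) -> list[Span]:
    locus_spans = allele.spans if allele is not None else wildtype_spans(ref)
    if region_only:
        return list(locus_spans)
    left_len = ref.locus.start - 1
    shifted = [
        Span(s.t_start + left_len, s.length, s.ref0, s.strand) for s in locus_spans
    ]
    locus_t_len = sum(s.length for s in locus_spans)
    right_len = ref.chrom_len - ref.locus.end
    spans = [Span(1, left_len, 1, 1)] + shifted
    if right_len > 0:
        spans.append(Span(left_len + locus_t_len + 1, right_len, ref.locus.end + 1, 1))
    return spans


def _map_reads(
    t_left: np.ndarray, spans: list[Span], read_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Template leftmost positions -> (ref leftmost, span strand, mappable)."""
    t_starts = np.array([s.t_start for s in spans], dtype=np.int64)
    t_lens = np.array([s.length for s in spans], dtype=np.int64)
    ref0 = np.array([s.ref0 for s in spans], dtype=np.int64)
    strands = np.array([s.strand for s in spans], dtype=np.int64)
    idx = np.searchsorted(t_starts, t_left, side="right") - 1
    idx = np.clip(idx, 0, len(spans) - 1)
    offset = t_left - t_starts[idx]
    ok = (offset >= 0) & (offset + read_len <= t_lens[idx])
    sp_strand = strands[idx]
    ref_left = np.where(
        sp_strand > 0,
        ref0[idx] + offset,
        ref0[idx] - offset - (read_len - 1),
    )
    return ref_left, sp_strand, ok


def simulate_matepair_pool(
    ref: ReferenceModel,
    allele: FmAllele | None,
    spec: PoolSpec,
) -> MatePairSet:
    """Draw pairs at ``target_depth`` x coverage of the template.

    Pair count = depth * template_length / (2 * read_length); pairs whose
    reads cannot be placed (off-template fragment or junction-straddling
    read) are dropped, so the mapped count is marginally lower.
    """
    rng = np.random.default_rng(spec.seed)
    spans = _template_spans(ref, allele, spec.region_only)
    template_len = sum(s.length for s in spans)
    r = spec.read_length
    n_pairs = int(round(spec.target_depth * template_len / (2 * r)))

    frag = np.rint(rng.normal(spec.mean_insert, spec.insert_sd, size=n_pairs)).astype(np.int64)
    frag = np.clip(frag, 2 * r, None)
    start = rng.integers(1, template_len + 1, size=n_pairs)
    keep = start + frag - 1 <= template_len
    start, frag = start[keep], frag[keep]

    # forward read at the fragment start, reverse read at the far end
    left1, sp1, ok1 = _map_reads(start, spans, r)
    left2, sp2, ok2 = _map_reads(start + frag - r, spans, r)
    ok = ok1 & ok2
    strand1 = sp1[ok]          # template-forward read
    strand2 = -sp2[ok]         # template-reverse read
    return MatePairSet(
        pos1=left1[ok],
        strand1=strand1,
        pos2=left2[ok],
        strand2=strand2,
        read_length=r,
        chrom=ref.chrom_name,
        library_total_reads=int(2 * ok.sum()),
    )


def mapping_distance_stats(pairs: MatePairSet) -> tuple[float, float]:
    """Chromosome-wide (mean, SD) of mapping distances for a library."""
    d = pairs.distance.astype(float)
    return float(d.mean()), float(d.std())
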