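"""Pooled-sequencing structural-variant analysis.

Three layers of evidence are extracted from mapped mate pairs:

* read depth in 1 kb windows, depth-normalized (reads per window per million
  mapped) and compared between pools as a per-window log2 fold change --
  a duplicated region shows ~2x coverage in the carrier pool;
* a candidate structural-variant scan: windows where at least 20% of mate
  pairs have mapping distances exceeding six standard deviations above the
  library average, clustered within +/-1500 bp of the median aberrant
  distance; a strand-discordant majority flags an inversion;
* base-pair breakpoint refinement of a junction-spanning fragment against
  the reference, reporting the microhomology shared by the two joined ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval
from .pools import MatePairSet
from .reference import ReferenceModel, revcomp


@dataclass
class DepthTrack:
    window_size: int
    start: int  # locus start (1-based); window w covers [start + w*size, ...]
    counts: np.ndarray  # reads per window
    library_total: int  # chromosome-wide mapped reads of the library
    chrom: str = "chr20"

    @property
    def normalized(self) -> np.ndarray:
        """Reads per window per million mapped."""
        return self.counts * (1e6 / self.library_total)

    def window_interval(self, w: int) -> GenomicInterval:
        lo = self.start + w * self.window_size
        return GenomicInterval(lo, lo + self.window_size - 1, self.chrom)


def window_depth(
    pairs: MatePairSet,
    locus: GenomicInterval,
    window_size: int = 1_000,
) -> DepthTrack:
    """Count reads per window; each read increments the window containing its
    leftmost base.  Reads mapped outside the locus contribute only to the
    library total."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    n_windows = -(-locus.length // window_size)  # ceil
    counts = np.zeros(n_windows, dtype=np.int64)
    for pos in (pairs.pos1, pairs.pos2):
        inside = (pos >= locus.start) & (pos <= locus.end)
        w = (pos[inside] - locus.start) // window_size
        np.add.at(counts, w, 1)
    return DepthTrack(
        window_size=window_size,
        start=locus.start,
        counts=counts,
        library_total=pairs.library_total_reads,
        chrom=locus.chrom,
    )


def log2_fold_change(
    track_a: DepthTrack,
    track_b: DepthTrack,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-window log2((a_norm + eps) / (b_norm + eps)), each track first
    normalized to its own library total (per million mapped reads)."""
    if (
        track_a.window_size != track_b.window_size
        or track_a.start != track_b.start
        or len(track_a.counts) != len(track_b.counts)
    ):
        raise ValueError("windowing mismatch between tracks")
    return np.log2((track_a.normalized + pseudocount) / (track_b.normalized + pseudocount))


def depth_gain_regions(
    track_fc: np.ndarray,
    window_size: int,
    start: int,
    min_windows: int = 20,
    min_log2fc: float = 0.8,
    chrom: str = "chr20",
) -> list[GenomicInterval]:
    """Report runs of >= min_windows consecutive windows with
    log2 fold change >= min_log2fc (the 2x guide-line rule)."""
    above = track_fc >= min_log2fc
    regions = []
    run_start = None
    for w, flag in enumerate(np.append(above, False)):
        if flag and run_start is None:
            run_start = w
        elif not flag and run_start is not None:
            if w - run_start >= min_windows:
                regions.append(
                    GenomicInterval(start + run_start * window_size, start + w * window_size - 1, chrom)
                )
            run_start = None
    return regions


@dataclass
class SvParams:
    min_discordant_fraction: float = 0.20
    sd_multiplier: float = 6.0
    median_band: int = 1_500
    min_pairs_per_window: int = 10
    window_size: int = 1_000

    def __post_init__(self) -> None:
        for v in (self.min_discordant_fraction, self.sd_multiplier, self.median_band, self.min_pairs_per_window):
            if v <= 0:
                raise ValueError("all SV-scan parameters must be positive")


@dataclass
class SVCandidate:
    window: GenomicInterval
    partner_window: GenomicInterval
    supporting_pairs: int
    discordant_fraction: float
    median_distance: float
    inversion_flag: bool


def candidate_sv_windows(
    pairs: MatePairSet,
    params: SvParams,
    chrom_stats: tuple[float, float],
    locus: GenomicInterval,
) -> list[SVCandidate]:
    """The windowed mate-pair candidate-SV rule.

    Per window (pairs assigned by the leftmost read, each pair counted
    once): pairs with mapping distance above mean + sd_multiplier * SD are
    the aberrant set; if they make up at least ``min_discordant_fraction``
    of the window's pairs, keep the subset within +/- ``median_band`` of
    the aberrant-set median distance and emit a candidate whose partner
    window contains the median far-read position.  The inversion flag is a
    strict strand-discordant majority of the supporting pairs (ties are
    not flagged).  Windows with fewer than ``min_pairs_per_window`` pairs
    are skipped.
    """
    mean, sd = chrom_stats
    cutoff = mean + params.sd_multiplier * sd
    left = pairs.leftmost
    far = np.where(pairs.pos1 <= pairs.pos2, pairs.pos2, pairs.pos1)
    dist = pairs.distance
    disc_strand = pairs.strand_discordant

    inside = (left >= locus.start) & (left <= locus.end)
    widx = (left[inside] - locus.start) // params.window_size
    dist_in, far_in, strand_in = dist[inside], far[inside], disc_strand[inside]

    out: list[SVCandidate] = []
    order = np.argsort(widx, kind="stable")
    widx_s = widx[order]
    bounds = np.searchsorted(widx_s, np.arange(widx_s[-1] + 2) if len(widx_s) else np.array([0]))
    for w in np.unique(widx_s):
        lo, hi = bounds[w], bounds[w + 1]
        sel = order[lo:hi]
        if len(sel) < params.min_pairs_per_window:
            continue
        d = dist_in[sel]
        aberrant = d > cutoff
        frac = aberrant.mean()
        if frac < params.min_discordant_fraction:
            continue
        med = float(np.median(d[aberrant]))
        keep = aberrant & (np.abs(d - med) <= params.median_band)
        if not keep.any():
            continue
        far_keep = far_in[sel][keep]
        strands = strand_in[sel][keep]
        partner_pos = float(np.median(far_keep))
        pw = int((partner_pos - locus.start) // params.window_size)
        lo_w = int(locus.start + w * params.window_size)
        lo_p = int(locus.start + pw * params.window_size)
        out.append(
            SVCandidate(
                window=GenomicInterval(lo_w, lo_w + params.window_size - 1, locus.chrom),
                partner_window=GenomicInterval(lo_p, lo_p + params.window_size - 1, locus.chrom),
                supporting_pairs=int(keep.sum()),
                discordant_fraction=float(frac),
                median_distance=float(np.median(d[keep])),
                inversion_flag=bool(strands.sum() * 2 > keep.sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# junction refinement


class JunctionNoCall(ValueError):
    """Neither side of a junction fragment could be anchored to the reference."""


@dataclass
class JunctionCall:
    side_a: str   # "+"/"-" strand descriptor of the 5' (prefix) side
    side_b: str
    breakpoint_a: int  # reference coordinate of the last base matched on side A
    breakpoint_b: int  # reference coordinate of the first base matched on side B
    microhomology_len: int
    microhomology_seq: str
    inserted_seq: str


def _locate(seq: str, ref_fw: str, ref_rc: str) -> tuple[int, int] | None:
    """Find an anchor on either strand; returns (strand, index in that strand's
    string) or None.  Anchors are expected to be unique in a random reference."""
    i = ref_fw.find(seq)
    if i >= 0:
        return (1, i)
    i = ref_rc.find(seq)
    if i >= 0:
        return (-1, i)
    return None


def refine_junction(
    fragment: str,
    ref: ReferenceModel | str,
    anchor_len: int = 30,
) -> JunctionCall:
    """Locate the two reference-matching ends of a junction fragment and
    measure their overlap on the fragment.

    The maximal reference-matching prefix (side A) and suffix (side B) are
    found by exact extension from an ``anchor_len``-mer seed at each end of
    the fragment; microhomology length = overlap of the two matched
    intervals on the fragment (0 when they abut; a gap instead is reported
    as inserted sequence).  Exact and deterministic.
    """
    ref_seq = ref.sequence if isinstance(ref, ReferenceModel) else ref
    offset = ref.locus.start if isinstance(ref, ReferenceModel) else 1
    ref_rc = revcomp(ref_seq)
    n, L = len(fragment), len(ref_seq)
    if n < 2 * anchor_len:
        raise JunctionNoCall("fragment shorter than two anchors")

    hit_a = _locate(fragment[:anchor_len], ref_seq, ref_rc)
    hit_b = _locate(fragment[-anchor_len:], ref_seq, ref_rc)
    if hit_a is None or hit_b is None:
        raise JunctionNoCall("could not anchor both fragment ends to the reference")

    strand_a, ia = hit_a
    ref_a = ref_seq if strand_a > 0 else ref_rc
    p = anchor_len
    while p < n and ia + p < L and fragment[p] == ref_a[ia + p]:
        p += 1

    strand_b, ib = hit_b
    ref_b = ref_seq if strand_b > 0 else ref_rc
    # ib is the index of the suffix anchor start; extend the match backwards
    s = n - anchor_len
    while s > 0 and ib - (n - anchor_len - s) > 0 and fragment[s - 1] == ref_b[ib - (n - anchor_len - s) - 1]:
        s -= 1
    ib_start = ib - (n - anchor_len - s)  # ref_b index matching fragment[s]

    micro = max(p - s, 0)
    inserted = fragment[p:s] if s > p else ""

    def ref_coord(strand: int, idx: int) -> int:
        return offset + idx if strand > 0 else offset + (L - 1 - idx)

    return JunctionCall(
        side_a="+" if strand_a > 0 else "-",
        side_b="+" if strand_b > 0 else "-",
        breakpoint_a=ref_coord(strand_a, ia + p - 1),
        breakpoint_b=ref_coord(strand_b, ib_start),
        microhomology_len=micro,
        microhomology_seq=fragment[s:p] if micro else "",
        inserted_seq=inserted,
    )
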