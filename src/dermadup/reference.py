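"""Synthetic wild-type reference model of the pigmentation locus.

The locus spans 10.218-11.935 Mb of a toy chromosome 20 and tiles into five
blocks in reference order::

    L | D1 | S | D2 | R

where ``D1`` and ``D2`` are the two regions duplicated on the mutant
chromosome and ``S`` is the 417 kb single-copy spacer between them.  The
sequence is random DNA (fixed seed), with the bases immediately flanking the
four duplication breakpoints adjusted so that the mutant junctions carry an
exactly known microhomology (by default a single shared base at the 3'/3'
junction and none at the 5'/5' junction, matching the sequenced junctions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, gap

BLOCK_ORDER = ("L", "D1", "S", "D2", "R")

DEFAULT_CHROM = "chr20"
#: toy chromosome length emulating chicken chromosome 20 (~13.9 Mb)
DEFAULT_CHROM_LEN = 13_900_000
DEFAULT_LOCUS = GenomicInterval(10_218_000, 11_935_000)
DEFAULT_D1 = GenomicInterval(10_717_294, 10_846_232)
DEFAULT_D2 = GenomicInterval(11_262_904, 11_435_256)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_COMP_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def comp(base: str) -> str:
    return _COMP[base]


class ConfigurationError(ValueError):
    """Raised for an inconsistent locus/block configuration."""


@dataclass
class ReferenceModel:
    """Wild-type locus: block map plus the synthetic sequence.

    Coordinates are in the chromosome frame (1-based inclusive); the
    sequence string covers only the locus, index ``pos - locus.start``.
    """

    chrom_name: str
    locus: GenomicInterval
    blocks: dict[str, GenomicInterval]
    sequence: str
    seed: int
    chrom_len: int = DEFAULT_CHROM_LEN
    junction_overlap_3p: int = 1
    junction_overlap_5p: int = 0

    def index(self, pos: int) -> int:
        """Chromosome coordinate -> index into :attr:`sequence`."""
        if not self.locus.contains(pos):
            raise ValueError(f"position {pos} outside locus {self.locus}")
        return pos - self.locus.start

    def base(self, pos: int) -> str:
        return self.sequence[self.index(pos)]

    def block_seq(self, name: str, strand: int = 1) -> str:
        b = self.blocks[name]
        s = self.sequence[self.index(b.start) : self.index(b.end) + 1]
        return s if strand > 0 else revcomp(s)

    @property
    def inter_duplication_gap(self) -> int:
        return gap(self.blocks["D1"], self.blocks["D2"])


def _random_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _set(seq: np.ndarray, idx: int, base: str) -> None:
    seq[idx] = ord(base)


def _get(seq: np.ndarray, idx: int) -> str:
    return chr(seq[idx])


def _force_mismatch(seq: np.ndarray, idx: int, forbidden: str, rng: np.random.Generator) -> None:
    """Replace seq[idx] if it equals `forbidden` (keeps planted microhomology exact)."""
    if _get(seq, idx) == forbidden:
        choices = [b for b in "ACGT" if b != forbidden]
        _set(seq, idx, choices[int(rng.integers(0, 3))])


def _plant_junction_overlaps(
    seq: np.ndarray,
    locus: GenomicInterval,
    d1: GenomicInterval,
    d2: GenomicInterval,
    k3: int,
    k5: int,
    rng: np.random.Generator,
) -> None:
    """Engineer breakpoint-flanking bases so the mutant junctions carry an
    exact microhomology of k3 bases (3'/3' junction) and k5 bases (5'/5').

    The 3' junction joins D1 read forward up to d1.end with D2 read on the
    minus strand from d2.end; a k-base microhomology means the last k bases
    of D1 equal the complement of the last k bases of D2 (read backwards),
    with a guaranteed mismatch at position k+1 on either side so chance
    matches cannot extend the homology.  Symmetrically for the 5' junction.
    """
    off = locus.start
    d1s, d1e = d1.start - off, d1.end - off
    d2s, d2e = d2.start - off, d2.end - off

    # -- 3' junction: shared bases seq[d1e-k3+1+j] == comp(seq[d2e-j])
    if k3 == 1:
        _set(seq, d2e, "G")  # the junction's single shared base is a C on the plus strand
    for j in range(k3):
        _set(seq, d1e - k3 + 1 + j, comp(_get(seq, d2e - j)))
    _force_mismatch(seq, d1e + 1, comp(_get(seq, d2e - k3)), rng)
    _force_mismatch(seq, d1e - k3, comp(_get(seq, d2e + 1)), rng)

    # -- 5' junction: shared bases seq[d1s+j] == comp(seq[d2s+k5-1-j])
    for j in range(k5):
        _set(seq, d1s + j, comp(_get(seq, d2s + k5 - 1 - j)))
    _force_mismatch(seq, d1s + k5, comp(_get(seq, d2s - 1)), rng)
    _force_mismatch(seq, d2s + k5, comp(_get(seq, d1s - 1)), rng)


def build_reference(
    locus: GenomicInterval = DEFAULT_LOCUS,
    d1: GenomicInterval = DEFAULT_D1,
    d2: GenomicInterval = DEFAULT_D2,
    seed: int = 2011,
    chrom_name: str = DEFAULT_CHROM,
    chrom_len: int = DEFAULT_CHROM_LEN,
    junction_overlap_3p: int = 1,
    junction_overlap_5p: int = 0,
) -> ReferenceModel:
    """Build the wild-type reference model with a deterministic sequence.

    Raises :class:`ConfigurationError` if the blocks do not tile the locus
    in order L, D1, S, D2, R with non-empty flanks and spacer.
    """
    if not (locus.start < d1.start and d1.end < d2.start - 1 and d2.end < locus.end):
        raise ConfigurationError("blocks must be ordered and strictly inside the locus")
    if d1.start <= locus.start or d2.end >= locus.end:
        raise ConfigurationError("L and R flanks must be non-empty")
    if chrom_len < locus.end:
        raise ConfigurationError("chromosome shorter than locus end")
    blocks = {
        "L": GenomicInterval(locus.start, d1.start - 1, locus.chrom),
        "D1": GenomicInterval(d1.start, d1.end, locus.chrom),
        "S": GenomicInterval(d1.end + 1, d2.start - 1, locus.chrom),
        "D2": GenomicInterval(d2.start, d2.end, locus.chrom),
        "R": GenomicInterval(d2.end + 1, locus.end, locus.chrom),
    }
    rng = np.random.default_rng(seed)
    arr = _random_sequence(locus.length, rng)
    _plant_junction_overlaps(arr, locus, d1, d2, junction_overlap_3p, junction_overlap_5p, rng)
    return ReferenceModel(
        chrom_name=chrom_name,
        locus=locus,
        blocks=blocks,
        sequence=arr.tobytes().decode("ascii"),
        seed=seed,
        chrom_len=chrom_len,
        junction_overlap_3p=junction_overlap_3p,
        junction_overlap_5p=junction_overlap_5p,
    )
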