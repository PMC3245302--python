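"""Construction of the rearranged (mutant) locus haplotype.

The mutant allele is built from a :class:`~dermadup.rearrange.BlockArrangement`
by concatenating oriented block sequences of the wild-type reference.  At each
novel junction the planted terminal microhomology (k shared bases) is merged:
the incoming segment drops its first k oriented bases, so the junction carries
the shared sequence exactly once -- no gain or loss of sequence other than the
overlap, as observed at the sequenced junctions.

Besides the sequence, the builder records an exact template-to-reference span
map (used by the mate-pair simulator to emit mapped coordinates without an
alignment step) and the template positions of the novel junctions (used to cut
junction-spanning fragments for breakpoint refinement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval
from .rearrange import (
    FM_SCENARIOS,
    JUNCTION_3P,
    JUNCTION_5P,
    WILDTYPE,
    BlockArrangement,
    adjacency,
    _entry_end,
    _exit_end,
)
from .reference import ReferenceModel, revcomp


@dataclass(frozen=True)
class Span:
    """Affine map from a template interval to reference coordinates.

    Template positions are 1-based over the allele sequence.  For
    ``strand=+1``, template position t maps to ``ref0 + (t - t_start)``;
    for ``strand=-1`` it maps to ``ref0 - (t - t_start)`` (minus strand).
    """

    t_start: int
    length: int
    ref0: int
    strand: int

    @property
    def t_end(self) -> int:
        return self.t_start + self.length - 1


@dataclass(frozen=True)
class JunctionRecord:
    """A novel junction on the allele template.

    ``template_pos`` is the last template base contributed by the outgoing
    side; microhomology bases (if any) sit immediately at this position.
    """

    kind: str  # "5p" or "3p"
    template_pos: int
    side_a: str  # e.g. "D1.3p(+)"
    side_b: str
    breakpoint_a: int  # reference coordinate of side A's joined end
    breakpoint_b: int
    overlap: int


@dataclass
class FmAllele:
    """A rearranged locus haplotype with full provenance."""

    scenario: str
    arrangement: BlockArrangement
    sequence: str
    spans: list[Span]
    junctions: list[JunctionRecord]
    ref: ReferenceModel

    @property
    def junction_5p(self) -> JunctionRecord | None:
        return next((j for j in self.junctions if j.kind == "5p"), None)

    @property
    def junction_3p(self) -> JunctionRecord | None:
        return next((j for j in self.junctions if j.kind == "3p"), None)

    def junction_fragment(self, kind: str, flank: int = 400) -> str:
        """Sequence of ``flank`` template bases on each side of a junction,
        emulating a sequenced junction-spanning PCR product."""
        j = next(jr for jr in self.junctions if jr.kind == kind)
        lo = max(0, j.template_pos - flank)
        hi = min(len(self.sequence), j.template_pos + flank)
        return self.sequence[lo:hi]

    def truth_fragment(self) -> dict:
        """Machine-readable truth about the planted rearrangement."""
        return {
            "scenario": self.scenario,
            "arrangement": str(self.arrangement),
            "junctions": [
                {
                    "kind": j.kind,
                    "template_pos": j.template_pos,
                    "side_a": j.side_a,
                    "side_b": j.side_b,
                    "breakpoint_a": j.breakpoint_a,
                    "breakpoint_b": j.breakpoint_b,
                    "overlap": j.overlap,
                }
                for j in self.junctions
            ],
        }


def _oriented(ref: ReferenceModel, name: str, strand: int) -> str:
    return ref.block_seq(name, strand)


def build_fm_allele(
    ref: ReferenceModel,
    scenario: str = "FM_2",
    overlap_3p: int | None = None,
    overlap_5p: int | None = None,
) -> FmAllele:
    """Assemble the mutant allele sequence for one of the three architectures.

    The junction microhomologies are properties of the reference sequence
    (planted at :func:`~dermadup.reference.build_reference` time); requesting
    a different overlap than the reference was built with is an error.
    """
    if scenario == "N":
        arrangement = WILDTYPE
    elif scenario in FM_SCENARIOS:
        arrangement = FM_SCENARIOS[scenario]
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected FM_1/FM_2/FM_3 or N")
    if overlap_3p is None:
        overlap_3p = ref.junction_overlap_3p
    if overlap_5p is None:
        overlap_5p = ref.junction_overlap_5p
    if overlap_3p != ref.junction_overlap_3p or overlap_5p != ref.junction_overlap_5p:
        raise ValueError(
            "requested junction overlaps differ from those planted in the reference; "
            "rebuild the reference with the desired overlaps"
        )

    segments = (("L", 1),) + tuple(arrangement.blocks) + (("R", 1),)
    parts: list[str] = []
    spans: list[Span] = []
    junctions: list[JunctionRecord] = []
    tpos = 1  # next template position
    prev = None
    for blk in segments:
        name, strand = blk
        seq = _oriented(ref, name, strand)
        iv = ref.blocks[name]
        drop = 0
        if prev is not None:
            adj = adjacency(_exit_end(prev), _entry_end(blk))
            kind = None
            if adj == JUNCTION_5P:
                kind, drop = "5p", overlap_5p
            elif adj == JUNCTION_3P:
                kind, drop = "3p", overlap_3p
            if kind is not None:
                pname, pstrand = prev
                piv = ref.blocks[pname]
                bp_a = (piv.end if pstrand > 0 else piv.start)
                bp_b = (iv.start if strand > 0 else iv.end)
                junctions.append(
                    JunctionRecord(
                        kind=kind,
                        template_pos=tpos - 1,
                        side_a=f"{pname}.{'3p' if pstrand > 0 else '5p'}({'+' if pstrand > 0 else '-'})",
                        side_b=f"{name}.{'5p' if strand > 0 else '3p'}({'+' if strand > 0 else '-'})",
                        breakpoint_a=bp_a,
                        breakpoint_b=bp_b,
                        overlap=drop,
                    )
                )
        seq = seq[drop:]
        # reference coordinate of the first emitted template base
        if strand > 0:
            ref0 = iv.start + drop
        else:
            ref0 = iv.end - drop
        spans.append(Span(t_start=tpos, length=len(seq), ref0=ref0, strand=strand))
        parts.append(seq)
        tpos += len(seq)
        prev = blk

    return FmAllele(
        scenario=scenario,
        arrangement=arrangement,
        sequence="".join(parts),
        spans=spans,
        junctions=junctions,
        ref=ref,
    )


def wildtype_spans(ref: ReferenceModel) -> list[Span]:
    """Identity span map for the wild-type locus template."""
    return [Span(t_start=1, length=ref.locus.length, ref0=ref.locus.start, strand=1)]
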