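"""Block-level genome rearrangement logic for the duplication locus.

A candidate architecture of the mutant locus is a signed sequence of the
internal blocks (D1, S, D2, with multiplicity) between the fixed flanks L
and R.  Each block has a 5' and a 3' end defined in *reference* orientation;
an arrangement induces a multiset of orientation-aware adjacencies (unordered
pairs of block ends), which is exactly what junction PCR between outward
facing primers observes.  The module enumerates all arrangements consistent
with an adjacency multiset, simulates diagnostic PCR on an arrangement, and
computes the products of meiotic crossover between two arrangements --
the logic used to eliminate candidate architectures with a single
recombinant offspring.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

#: signed block: (name, strand) with strand +1 (reference) or -1 (inverted)
SignedBlock = tuple[str, int]

#: block end in reference orientation: (block name, "5p" | "3p");
#: the flanks contribute a single end each, written ("L", "3p") / ("R", "5p").
BlockEnd = tuple[str, str]

#: an adjacency is an unordered pair of block ends
Adjacency = tuple[BlockEnd, BlockEnd]


def adjacency(a: BlockEnd, b: BlockEnd) -> Adjacency:
    return (a, b) if a <= b else (b, a)


def _entry_end(block: SignedBlock) -> BlockEnd:
    name, strand = block
    return (name, "5p" if strand > 0 else "3p")


def _exit_end(block: SignedBlock) -> BlockEnd:
    name, strand = block
    return (name, "3p" if strand > 0 else "5p")


def _revcomp_blocks(blocks: Sequence[SignedBlock]) -> tuple[SignedBlock, ...]:
    return tuple((name, -strand) for name, strand in reversed(blocks))


#: the four wild-type boundary adjacencies
WT_ADJACENCIES: tuple[Adjacency, ...] = (
    adjacency(("L", "3p"), ("D1", "5p")),
    adjacency(("D1", "3p"), ("S", "5p")),
    adjacency(("S", "3p"), ("D2", "5p")),
    adjacency(("D2", "3p"), ("R", "5p")),
)

#: the two novel junctions observed by junction PCR (5'-to-5' and 3'-to-3')
JUNCTION_5P: Adjacency = adjacency(("D1", "5p"), ("D2", "5p"))
JUNCTION_3P: Adjacency = adjacency(("D1", "3p"), ("D2", "3p"))


@dataclass(frozen=True)
class BlockArrangement:
    """A signed block sequence between the fixed flanks L and R."""

    blocks: tuple[SignedBlock, ...]

    def __post_init__(self) -> None:
        for name, strand in self.blocks:
            if name in ("L", "R") or strand not in (-1, 1):
                raise ValueError(f"bad signed block ({name},{strand})")

    @property
    def adjacencies(self) -> Counter:
        """Orientation-aware adjacency multiset; k internal blocks -> k+1 pairs."""
        path: list[BlockEnd] = [("L", "3p")]
        for blk in self.blocks:
            path.extend([_entry_end(blk), _exit_end(blk)])
        path.append(("R", "5p"))
        return Counter(adjacency(path[i], path[i + 1]) for i in range(0, len(path), 2))

    @property
    def copy_numbers(self) -> Counter:
        return Counter(name for name, _ in self.blocks)

    @property
    def junctions(self) -> Counter:
        """Adjacencies not present on the wild-type chromosome."""
        adj = self.adjacencies
        for wt in WT_ADJACENCIES:
            if adj[wt]:
                adj[wt] -= 1
        return +adj

    def canonical(self) -> "BlockArrangement":
        """Representative under whole-arrangement reverse complement."""
        return BlockArrangement(min(self.blocks, _revcomp_blocks(self.blocks)))

    def __str__(self) -> str:
        inner = " ".join(("+" if s > 0 else "-") + n for n, s in self.blocks)
        return f"L {inner} R".strip()

    @classmethod
    def parse(cls, text: str) -> "BlockArrangement":
        """Parse the serialized form, e.g. ``"L +D1 -D2 +D1 +S +D2 R"``."""
        toks = text.split()
        if toks and toks[0] == "L":
            toks = toks[1:]
        if toks and toks[-1] == "R":
            toks = toks[:-1]
        blocks = []
        for t in toks:
            sign = {"+": 1, "-": -1}.get(t[0])
            if sign is None:
                raise ValueError(f"bad signed block token {t!r}")
            blocks.append((t[1:], sign))
        return cls(tuple(blocks))


WILDTYPE = BlockArrangement((("D1", 1), ("S", 1), ("D2", 1)))
FM_SCENARIOS = {
    "FM_1": BlockArrangement.parse("L +D1 -D2 -S -D1 +D2 R"),
    "FM_2": BlockArrangement.parse("L +D1 -D2 +D1 +S +D2 R"),
    "FM_3": BlockArrangement.parse("L +D1 +S +D2 -D1 +D2 R"),
}


@dataclass(frozen=True)
class AdjacencyEvidence:
    """Required adjacency multiset, as established by junction/boundary PCR."""

    required: tuple[Adjacency, ...] = WT_ADJACENCIES + (JUNCTION_5P, JUNCTION_3P)

    @property
    def multiset(self) -> Counter:
        return Counter(self.required)


def enumerate_arrangements(
    copies: dict[str, int] | None = None,
    evidence: AdjacencyEvidence | None = None,
) -> list[BlockArrangement]:
    """All arrangements of the given block copies whose adjacency multiset
    equals the evidence multiset exactly, de-duplicated under reverse
    complement and under relabeling of identical copies.

    Exhaustive: the block multiset is small (5 internal blocks), so all
    distinct orderings x orientations are checked (<= 960 candidates).
    """
    copies = dict(copies or {"D1": 2, "S": 1, "D2": 2})
    evidence = evidence or AdjacencyEvidence()
    n_internal = sum(copies.values())
    if len(list(evidence.required)) != n_internal + 1:
        raise ValueError(
            f"evidence lists {len(evidence.required)} adjacencies; "
            f"{n_internal} internal blocks require {n_internal + 1}"
        )
    want = evidence.multiset
    names = [n for n, c in copies.items() for _ in range(c)]
    seen_orders = set()
    out: list[BlockArrangement] = []
    seen_canonical = set()
    for order in itertools.permutations(names):
        if order in seen_orders:  # identical-copy relabeling
            continue
        seen_orders.add(order)
        for signs in itertools.product((1, -1), repeat=n_internal):
            blocks = tuple(zip(order, signs))
            arr = BlockArrangement(blocks)
            if arr.adjacencies != want:
                continue
            canon = min(blocks, _revcomp_blocks(blocks))
            if canon in seen_canonical:
                continue
            seen_canonical.add(canon)
            out.append(arr)
    return out


# ---------------------------------------------------------------------------
# in-silico PCR


@dataclass(frozen=True)
class PrimerModel:
    """A primer site anchored to one end of a host block.

    ``offset`` is the distance (bp) of the site from the anchoring block end
    measured into the block; ``facing`` is "out" for outward facing primers
    (pointing away from the block across the anchored end) or "in".
    Flank hosts L/R anchor at their single interior end.
    """

    name: str
    host: str
    end: str  # "5p" | "3p" (ignored for L/R flanks)
    offset: int
    facing: str = "out"
    max_amplicon: int = 5000

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.facing not in ("in", "out"):
            raise ValueError("facing must be 'in' or 'out'")


@dataclass(frozen=True)
class Amplicon:
    primer_a: str
    primer_b: str
    size: int
    description: str = ""


def _layout(arr: BlockArrangement, block_lengths: dict[str, int]) -> list[tuple[str, int, int, int]]:
    """Linearize an arrangement: (name, strand, seg_start, seg_len) per segment,
    flanks included, on a 0-based coordinate line."""
    segs = []
    pos = 0
    for name, strand in (("L", 1),) + tuple(arr.blocks) + (("R", 1),):
        ln = block_lengths[name]
        segs.append((name, strand, pos, ln))
        pos += ln
    return segs


def _primer_sites(
    primers: Iterable[PrimerModel],
    segs: list[tuple[str, int, int, int]],
) -> list[tuple[PrimerModel, int, int]]:
    """All (primer, position, direction) sites on the linearized arrangement;
    direction +1 means the primer extends rightward."""
    sites = []
    for p in primers:
        for name, strand, seg_start, seg_len in segs:
            if name != p.host:
                continue
            end = p.end
            if name == "L":
                end = "3p"
            elif name == "R":
                end = "5p"
            # distance of the site from the segment's left edge, in reference
            # orientation; a minus-strand segment mirrors it.
            from_left_ref = p.offset if end == "5p" else seg_len - 1 - p.offset
            from_left = from_left_ref if strand > 0 else seg_len - 1 - from_left_ref
            # direction the primer extends, in reference orientation
            toward_3p = (end == "5p") == (p.facing == "in")
            direction = 1 if toward_3p else -1
            if strand < 0:
                direction = -direction
            sites.append((p, seg_start + from_left, direction))
    return sites


def insilico_pcr(
    arr: BlockArrangement,
    primers: Sequence[PrimerModel],
    block_lengths: dict[str, int],
) -> list[Amplicon]:
    """Amplicons from every convergent primer-site pair within size range.

    Sizes are block-level point-to-point distances on the linearized
    arrangement (primer sites are treated as points, product size =
    |site_b - site_a|); sub-base-pair junction overlap bookkeeping is
    deliberately ignored at this abstraction level.
    """
    sites = _primer_sites(primers, _layout(arr, block_lengths))
    out = []
    for (pa, xa, da), (pb, xb, db) in itertools.combinations(sites, 2):
        if xa > xb:
            (pa, xa, da), (pb, xb, db) = (pb, xb, db), (pa, xa, da)
        if da == 1 and db == -1:  # facing each other
            size = xb - xa  # site-to-site distance on the linearized arrangement
            if 0 < size <= min(pa.max_amplicon, pb.max_amplicon):
                out.append(Amplicon(pa.name, pb.name, size))
    return sorted(out, key=lambda a: (a.size, a.primer_a, a.primer_b))


def diagnostic_assays() -> dict[str, list[PrimerModel]]:
    """The three-primer diagnostic assays for each duplication junction.

    Offsets are placed so that the wild-type and mutant products have the
    published diagnostic sizes: assay A gives 379 bp (D1 5' wild-type
    boundary) and 280 bp (5'/5' junction); assay B gives 302 bp (D2 3'
    wild-type boundary) and 159 bp (3'/3' junction).
    """
    return {
        "A": [
            PrimerModel("P232", "L", "3p", 228, "out"),     # in L, pointing into D1
            PrimerModel("P234", "D1", "5p", 150, "out"),    # inside D1, pointing out of its 5' end
            PrimerModel("P200", "D2", "5p", 129, "out"),    # inside D2, pointing out of its 5' end
        ],
        "B": [
            PrimerModel("P202", "R", "5p", 201, "out"),     # in R, pointing into D2
            PrimerModel("P201", "D2", "3p", 100, "out"),    # inside D2, pointing out of its 3' end
            PrimerModel("P197", "D1", "3p", 58, "out"),     # inside D1, pointing out of its 3' end
        ],
    }


# ---------------------------------------------------------------------------
# crossover logic


@dataclass
class CrossoverOutcome:
    """Products of a single crossover inside one copy of a block.

    When the paired copies lie in opposite orientations the exchange yields
    dicentric/acentric chromosomes and ``loss`` is set instead of products.
    """

    loss: bool
    products: list[BlockArrangement] = field(default_factory=list)
    copy_numbers: list[Counter] = field(default_factory=list)
    junctions: list[Counter] = field(default_factory=list)
    #: per product: which parent ("a"/"b") contributed left/right of the crossover
    provenance: list[tuple[str, str]] = field(default_factory=list)


def crossover_products(
    arr_a: BlockArrangement,
    arr_b: BlockArrangement,
    block: str = "S",
    copy_a: int = 0,
    copy_b: int = 0,
) -> CrossoverOutcome:
    """Reciprocal recombination between one copy of ``block`` in each parent."""

    def locate(arr: BlockArrangement, which: int) -> int:
        idxs = [i for i, (n, _) in enumerate(arr.blocks) if n == block]
        if not idxs:
            raise ValueError(f"block {block} absent from arrangement {arr}")
        return idxs[which]

    ia, ib = locate(arr_a, copy_a), locate(arr_b, copy_b)
    sa, sb = arr_a.blocks[ia][1], arr_b.blocks[ib][1]
    if sa != sb:
        return CrossoverOutcome(loss=True)
    # crossover inside the block: left part + the block + right part of the other
    p1 = BlockArrangement(arr_a.blocks[: ia + 1] + arr_b.blocks[ib + 1 :])
    p2 = BlockArrangement(arr_b.blocks[: ib + 1] + arr_a.blocks[ia + 1 :])
    return CrossoverOutcome(
        loss=False,
        products=[p1, p2],
        copy_numbers=[p1.copy_numbers, p2.copy_numbers],
        junctions=[p1.junctions, p2.junctions],
        provenance=[("a", "b"), ("b", "a")],
    )


def has_fm_phenotype(arr: BlockArrangement) -> bool:
    """Dominant-allele rule: mutant phenotype iff the chromosome carries
    either novel junction."""
    j = arr.junctions
    return bool(j[JUNCTION_5P] or j[JUNCTION_3P])


@dataclass(frozen=True)
class RecombinantObservation:
    """An observed crossover offspring used to discriminate architectures.

    The decisive real observation: a recombinant inheriting the wild-type
    founder's alleles left of a crossover in the single-copy region and the
    mutant founder's alleles to its right, phenotypically wild-type, with
    normal copy number of both duplications.
    """

    seen: bool = True
    left_parent: str = "N"  # provenance left of the crossover: "N" or "FM"
    phenotype: Optional[str] = "wt"  # "wt", "fm", or None for unconstrained
    normal_copy_number: Optional[bool] = True
    block: str = "S"


def consistent_scenarios(
    arrangements: Sequence[BlockArrangement],
    observation: RecombinantObservation,
    wildtype: BlockArrangement = WILDTYPE,
) -> list[BlockArrangement]:
    """Keep arrangements for which a crossover with the wild-type chromosome
    can produce the observed recombinant."""
    if not arrangements:
        raise ValueError("empty arrangement list")
    if not observation.seen:
        return list(arrangements)
    survivors = []
    for arr in arrangements:
        n_copies = wildtype.copy_numbers[observation.block]
        f_copies = arr.copy_numbers[observation.block]
        ok = False
        for ca in range(n_copies):
            for cb in range(f_copies):
                out = crossover_products(wildtype, arr, observation.block, ca, cb)
                if out.loss:
                    continue
                for prod, prov in zip(out.products, out.provenance):
                    left = {"a": "N", "b": "FM"}[prov[0]]
                    if left != observation.left_parent:
                        continue
                    if observation.phenotype == "wt" and has_fm_phenotype(prod):
                        continue
                    if observation.phenotype == "fm" and not has_fm_phenotype(prod):
                        continue
                    if observation.normal_copy_number:
                        if prod.copy_numbers != wildtype.copy_numbers:
                            continue
                    ok = True
        if ok:
            survivors.append(arr)
    return survivors
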