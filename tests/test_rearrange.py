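"""Arrangement enumeration, in-silico PCR, and crossover elimination."""

import itertools
from collections import Counter

import pytest

from dermadup.rearrange import (
    FM_SCENARIOS,
    JUNCTION_3P,
    JUNCTION_5P,
    WILDTYPE,
    WT_ADJACENCIES,
    AdjacencyEvidence,
    BlockArrangement,
    PrimerModel,
    RecombinantObservation,
    consistent_scenarios,
    crossover_products,
    diagnostic_assays,
    enumerate_arrangements,
    has_fm_phenotype,
    insilico_pcr,
)


class TestEnumeration:
    def test_default_evidence_yields_exactly_three(self):
        arrs = enumerate_arrangements()
        texts = {str(a) for a in arrs}
        assert len(arrs) == 3
        assert texts == {
            "L +D1 -D2 -S -D1 +D2 R",
            "L +D1 -D2 +D1 +S +D2 R",
            "L +D1 +S +D2 -D1 +D2 R",
        }

    def test_wildtype_evidence_single_arrangement(self):
        arrs = enumerate_arrangements(
            {"D1": 1, "S": 1, "D2": 1}, AdjacencyEvidence(WT_ADJACENCIES)
        )
        assert [str(a) for a in arrs] == ["L +D1 +S +D2 R"]

    def test_missing_junction_infeasible(self):
        evidence = AdjacencyEvidence(
            WT_ADJACENCIES + (JUNCTION_5P, JUNCTION_5P)  # no 3'/3' junction
        )
        assert enumerate_arrangements(evidence=evidence) == []

    def test_adjacency_multiset_consumed_exactly(self):
        evidence = AdjacencyEvidence()
        for arr in enumerate_arrangements(evidence=evidence):
            assert arr.adjacencies == evidence.multiset

    def test_reverse_complement_invariance(self):
        """Reverse-complementing the chromosome preserves the adjacency
        multiset once the flank ends swap roles (L's inner end becomes R's)."""

        def flip_flanks(end):
            return {("L", "3p"): ("R", "5p"), ("R", "5p"): ("L", "3p")}.get(end, end)

        for arr in enumerate_arrangements():
            rc = BlockArrangement(tuple((n, -s) for n, s in reversed(arr.blocks)))
            relabeled = Counter(
                tuple(sorted((flip_flanks(a), flip_flanks(b)))) for (a, b) in rc.adjacencies.elements()
            )
            assert relabeled == arr.adjacencies

    def test_adjacency_count_k_plus_one(self):
        for arr in [WILDTYPE] + list(FM_SCENARIOS.values()):
            assert sum(arr.adjacencies.values()) == len(arr.blocks) + 1

    def test_evidence_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            enumerate_arrangements({"D1": 1, "S": 1, "D2": 1}, AdjacencyEvidence())

    def test_serialization_round_trip(self):
        for arr in enumerate_arrangements():
            assert BlockArrangement.parse(str(arr)) == arr


class TestInsilicoPcr:
    def test_wildtype_diagnostic_sizes(self, block_lengths):
        assays = diagnostic_assays()
        a = insilico_pcr(WILDTYPE, assays["A"], block_lengths)
        b = insilico_pcr(WILDTYPE, assays["B"], block_lengths)
        assert [p.size for p in a] == [379]
        assert [p.size for p in b] == [302]

    def test_mutant_shows_wildtype_and_junction_products(self, block_lengths):
        assays = diagnostic_assays()
        fm2 = FM_SCENARIOS["FM_2"]
        a = sorted(p.size for p in insilico_pcr(fm2, assays["A"], block_lengths))
        b = sorted(p.size for p in insilico_pcr(fm2, assays["B"], block_lengths))
        assert a == [280, 379]
        assert b == [159, 302]

    def test_heterozygote_pattern_equals_homozygote(self, block_lengths):
        """Carriers retain all wild-type boundaries, so the band pattern of
        FM_2 includes every wild-type band: the three-primer assay cannot
        separate het from hom."""
        assays = diagnostic_assays()
        for assay in assays.values():
            wt_sizes = {p.size for p in insilico_pcr(WILDTYPE, assay, block_lengths)}
            fm_sizes = {p.size for p in insilico_pcr(FM_SCENARIOS["FM_2"], assay, block_lengths)}
            assert wt_sizes <= fm_sizes

    def test_all_scenarios_report_wildtype_products(self, block_lengths):
        assays = diagnostic_assays()
        for arr in FM_SCENARIOS.values():
            for assay, wt_size in (("A", 379), ("B", 302)):
                sizes = [p.size for p in insilico_pcr(arr, assays[assay], block_lengths)]
                assert wt_size in sizes

    def test_tandem_duplication_assay_negative(self, block_lengths):
        tandem = [
            PrimerModel("T5", "D1", "5p", 100, "out"),
            PrimerModel("T3", "D1", "3p", 100, "out"),
        ]
        for arr in (WILDTYPE, FM_SCENARIOS["FM_2"]):
            assert insilico_pcr(arr, tandem, block_lengths) == []


class TestCrossover:
    def test_inverted_spacer_causes_loss(self):
        out = crossover_products(WILDTYPE, FM_SCENARIOS["FM_1"], "S")
        assert out.loss and out.products == []

    def test_fm3_product_retains_duplications(self):
        out = crossover_products(WILDTYPE, FM_SCENARIOS["FM_3"], "S")
        assert not out.loss
        n_left = out.products[out.provenance.index(("a", "b"))]
        assert n_left.copy_numbers["D1"] == 2 and n_left.copy_numbers["D2"] == 2

    def test_fm2_product_is_wildtype(self):
        out = crossover_products(WILDTYPE, FM_SCENARIOS["FM_2"], "S")
        n_left = out.products[out.provenance.index(("a", "b"))]
        assert n_left == WILDTYPE
        assert not has_fm_phenotype(n_left)

    def test_wildtype_self_cross(self):
        out = crossover_products(WILDTYPE, WILDTYPE, "S")
        assert out.products == [WILDTYPE, WILDTYPE]

    def test_copy_number_conservation(self):
        """Viable crossovers conserve the total copy number of every block."""
        pool = [WILDTYPE] + list(FM_SCENARIOS.values())
        for a, b in itertools.product(pool, repeat=2):
            out = crossover_products(a, b, "S")
            if out.loss:
                continue
            total = out.products[0].copy_numbers + out.products[1].copy_numbers
            assert total == a.copy_numbers + b.copy_numbers

    def test_block_absent_rejected(self):
        with pytest.raises(ValueError):
            crossover_products(WILDTYPE, WILDTYPE, "X")


class TestElimination:
    def test_observation_selects_fm2_only(self):
        arrs = enumerate_arrangements()
        survivors = consistent_scenarios(arrs, RecombinantObservation())
        assert [str(a) for a in survivors] == ["L +D1 -D2 +D1 +S +D2 R"]

    def test_vacuous_observation_keeps_all(self):
        arrs = enumerate_arrangements()
        assert consistent_scenarios(arrs, RecombinantObservation(seen=False)) == arrs

    def test_unconstrained_phenotype_keeps_fm2_and_fm3(self):
        arrs = enumerate_arrangements()
        survivors = consistent_scenarios(
            arrs, RecombinantObservation(phenotype=None, normal_copy_number=False)
        )
        assert {str(a) for a in survivors} == {
            "L +D1 -D2 +D1 +S +D2 R",
            "L +D1 +S +D2 -D1 +D2 R",
        }

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consistent_scenarios([], RecombinantObservation())
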