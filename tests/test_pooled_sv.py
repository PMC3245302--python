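"""Depth fold change, candidate-SV rule, and junction microhomology."""

import numpy as np
import pytest

import dermadup as dd
from dermadup.pools import mapping_distance_stats
from dermadup.reference import build_reference, revcomp


class TestFoldChange:
    def test_identical_tracks_zero(self, ref, small_pools):
        _, wt = small_pools
        t = dd.window_depth(wt, ref.locus)
        assert np.allclose(dd.log2_fold_change(t, t), 0.0)

    def test_swap_negates(self, ref, small_pools):
        fm, wt = small_pools
        ta, tb = dd.window_depth(fm, ref.locus), dd.window_depth(wt, ref.locus)
        assert np.allclose(
            dd.log2_fold_change(ta, tb), -dd.log2_fold_change(tb, ta), atol=1e-12
        )

    def test_per_million_normalization_sums(self, ref, small_pools):
        """Locus-only pools: all mapped reads fall in locus windows, so the
        normalized track sums to one million."""
        _, wt = small_pools
        t = dd.window_depth(wt, ref.locus)
        assert t.normalized.sum() == pytest.approx(1e6, rel=1e-9)

    def test_windowing_mismatch_rejected(self, ref, small_pools):
        _, wt = small_pools
        a = dd.window_depth(wt, ref.locus, 1000)
        b = dd.window_depth(wt, ref.locus, 2000)
        with pytest.raises(ValueError):
            dd.log2_fold_change(a, b)

    def test_depth_gain_regions_cover_duplications(self, ref, full_pools):
        fm, wt = full_pools
        fc = dd.log2_fold_change(dd.window_depth(fm, ref.locus), dd.window_depth(wt, ref.locus))
        gains = dd.depth_gain_regions(fc, 1000, ref.locus.start)
        d1, d2 = ref.blocks["D1"], ref.blocks["D2"]
        assert any(g.overlaps(d1) for g in gains)
        assert any(g.overlaps(d2) for g in gains)


class TestCandidateSvWindows:
    def test_wt_pool_zero_candidates(self, ref, small_pools):
        _, wt = small_pools
        cands = dd.candidate_sv_windows(wt, dd.SvParams(), mapping_distance_stats(wt), ref.locus)
        assert cands == []

    def test_fm_pool_junction_candidates(self, ref, small_pools):
        fm, _ = small_pools
        stats = mapping_distance_stats(fm)
        cands = dd.candidate_sv_windows(fm, dd.SvParams(), stats, ref.locus)
        assert cands
        d1, d2 = ref.blocks["D1"], ref.blocks["D2"]
        # 5' feature: window at D1's 5' area pairing with D2's 5' area, inverted
        five = [
            c for c in cands
            if abs(c.window.start - d1.start) < 5000 and abs(c.partner_window.start - d2.start) < 5000
        ]
        assert five and all(c.inversion_flag for c in five)
        # feature span approximates the planted junction distance
        planted = d2.start - d1.start
        for c in five:
            span = c.partner_window.midpoint - c.window.midpoint
            assert abs(span - planted) <= dd.SvParams().median_band + 1000

    def test_monotone_in_fraction(self, ref, small_pools):
        fm, _ = small_pools
        stats = mapping_distance_stats(fm)
        lo = dd.candidate_sv_windows(fm, dd.SvParams(min_discordant_fraction=0.1), stats, ref.locus)
        hi = dd.candidate_sv_windows(fm, dd.SvParams(min_discordant_fraction=0.4), stats, ref.locus)
        lo_windows = {c.window for c in lo}
        assert all(c.window in lo_windows for c in hi)
        assert len(hi) <= len(lo)

    def test_support_within_median_band(self, ref, small_pools):
        fm, _ = small_pools
        params = dd.SvParams()
        for c in dd.candidate_sv_windows(fm, params, mapping_distance_stats(fm), ref.locus):
            assert c.discordant_fraction >= params.min_discordant_fraction
            assert c.supporting_pairs > 0


class TestRefineJunction:
    def test_planted_junction_microhomologies(self, ref, allele):
        j3 = dd.refine_junction(allele.junction_fragment("3p"), ref)
        j5 = dd.refine_junction(allele.junction_fragment("5p"), ref)
        assert j3.microhomology_len == 1
        assert j3.microhomology_seq == "C"
        assert j5.microhomology_len == 0
        assert j3.inserted_seq == "" and j5.inserted_seq == ""

    def test_breakpoints_at_planted_coordinates(self, ref, allele):
        j3 = dd.refine_junction(allele.junction_fragment("3p"), ref)
        assert {j3.breakpoint_a, j3.breakpoint_b} == {10_846_232, 11_435_256}

    def test_unmappable_fragment_no_call(self, ref):
        with pytest.raises(dd.pooled_sv.JunctionNoCall):
            dd.refine_junction("ACGT" * 50, ref)

    @pytest.mark.parametrize("k", list(range(11)))
    def test_planted_overlap_recovered(self, k):
        """Planted junction overlaps 0..10 are recovered exactly (the
        reference planting guarantees no chance extension)."""
        small = build_reference(
            locus=dd.GenomicInterval(10_218_000, 10_258_000),
            d1=dd.GenomicInterval(10_228_000, 10_238_000),
            d2=dd.GenomicInterval(10_244_000, 10_252_000),
            seed=100 + k,
            junction_overlap_3p=k,
            junction_overlap_5p=k // 2,
        )
        al = dd.build_fm_allele(small, "FM_2")
        call3 = dd.refine_junction(al.junction_fragment("3p", flank=200), small)
        call5 = dd.refine_junction(al.junction_fragment("5p", flank=200), small)
        assert call3.microhomology_len == k
        assert call5.microhomology_len == k // 2


def test_random_fragment_overlap_oracle(ref):
    """200 seeded random junction fragments (plus-strand side A joined to a
    minus-strand side B with a random number of merged terminal bases),
    checked against an independent character-by-character oracle for the
    maximal prefix/suffix matches and their overlap."""
    rng = np.random.default_rng(2024)
    seq = ref.sequence
    checked = 0
    while checked < 200:
        k = int(rng.integers(0, 8))
        a_end = int(rng.integers(100_000, 200_000))
        b_end = int(rng.integers(800_000, 900_000))
        flank = int(rng.integers(80, 250))
        side_a = seq[a_end - flank : a_end + 1]
        side_b = revcomp(seq[b_end - flank : b_end + 1])
        frag = side_a + side_b[min(k, len(side_b)) :]
        try:
            call = dd.refine_junction(frag, ref, anchor_len=40)
        except dd.pooled_sv.JunctionNoCall:  # pragma: no cover - vanishingly rare
            continue
        n = len(frag)
        # oracle prefix: frag matches the plus strand starting at a_end - flank
        p = 0
        while p < n and frag[p] == seq[a_end - flank + p]:
            p += 1
        # oracle suffix: frag tail matches the minus strand ending at
        # position b_end - flank; frag[j] aligns with the complement of
        # seq[b_end - flank + (n - 1 - j)]
        s = n
        while s > 0:
            ref_idx = b_end - flank + (n - s)
            if ref_idx >= len(seq) or frag[s - 1] != revcomp(seq[ref_idx]):
                break
            s -= 1
        assert call.microhomology_len == max(p - s, 0)
        assert call.microhomology_len >= k or side_a[-k:] != side_b[:k]
        checked += 1
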