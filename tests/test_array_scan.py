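"""Group-wise delta scan, region calling, fixed-het and shared-haplotype scans."""

import numpy as np
import pandas as pd
import pytest

import dermadup as dd
from dermadup.array_scan import GroupDeltaTrack, call_elevated_regions


def _track(delta, spacing=6000, threshold=0.1, min_run=5):
    delta = np.asarray(delta, dtype=float)
    pos = np.arange(len(delta)) * spacing + 1
    ids = [f"m{i}" for i in range(len(delta))]
    return GroupDeltaTrack(ids, pos, delta, threshold, min_run)


class TestGroupwiseDelta:
    def test_identical_groups_zero(self, cohort):
        fm = cohort.ids("FM")
        t = dd.groupwise_delta(cohort.lrr[fm], cohort.lrr[fm], cohort.markers["pos"])
        assert np.allclose(t.delta, 0.0)

    def test_single_individual_groups(self, cohort):
        a, b = cohort.ids("FM")[0], cohort.ids("WT")[0]
        t = dd.groupwise_delta(cohort.lrr[[a]], cohort.lrr[[b]], cohort.markers["pos"])
        assert np.allclose(t.delta, (cohort.lrr[a] - cohort.lrr[b]).to_numpy())

    def test_marker_mismatch_rejected(self, cohort):
        fm, wt = cohort.ids("FM"), cohort.ids("WT")
        with pytest.raises(ValueError):
            dd.groupwise_delta(cohort.lrr[fm].iloc[:-1], cohort.lrr[wt], cohort.markers["pos"])


class TestCallElevatedRegions:
    def test_all_below_threshold_empty(self):
        assert call_elevated_regions(_track(np.zeros(50))) == []

    def test_threshold_tie_counts_as_below(self):
        delta = np.zeros(30)
        delta[10:20] = 0.1  # exactly at threshold
        assert call_elevated_regions(_track(delta)) == []

    def test_single_run_midpoint_boundaries(self):
        delta = np.zeros(40)
        delta[10:20] = 0.3
        (r,) = call_elevated_regions(_track(delta, spacing=1000))
        assert (r.interval.start, r.interval.end) == (10_001, 19_001)
        assert r.boundary_estimates == (9_501.0, 19_501.0)
        assert r.n_markers == 10

    def test_track_edge_uses_marker_position(self):
        delta = np.zeros(20)
        delta[:6] = 0.5
        (r,) = call_elevated_regions(_track(delta, spacing=1000))
        assert r.boundary_estimates[0] == 1.0  # first marker, no outside neighbour

    def test_short_run_ignored(self):
        delta = np.zeros(30)
        delta[10:14] = 0.5  # 4 < min_run
        assert call_elevated_regions(_track(delta)) == []

    def test_nearby_runs_merge_distant_runs_split(self):
        delta = np.zeros(60)
        delta[5:12] = 0.3
        delta[14:21] = 0.3   # 2 below markers between: merges
        delta[40:47] = 0.3   # >= 5 below markers: distinct
        regions = call_elevated_regions(_track(delta))
        assert len(regions) == 2
        assert regions[0].n_markers == 16  # 5..20 inclusive

    def test_default_cohort_two_regions_with_bounded_error(self, ref, cohort):
        fm, wt = cohort.ids("FM"), cohort.ids("WT")
        track = dd.groupwise_delta(cohort.lrr[fm], cohort.lrr[wt], cohort.markers["pos"])
        regions = call_elevated_regions(track)
        assert len(regions) == 2
        for dup, region in zip((ref.blocks["D1"], ref.blocks["D2"]), regions):
            assert region.interval.overlaps(dup)

    def test_wt_vs_wt_contrast_rarely_calls_regions(self, ref, allele):
        """Null contrast: two disjoint wild-type groups give no regions in
        >= 95% of seeded replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            spec = dd.ArrayCohortSpec(n_fm=1, n_het=0, n_wt=24, seed=1000 + seed)
            c = dd.simulate_array_cohort(ref, allele, spec)
            wt = c.ids("WT")
            track = dd.groupwise_delta(c.lrr[wt[:12]], c.lrr[wt[12:]], c.markers["pos"])
            if call_elevated_regions(track):
                hits += 1
        assert hits <= 5


class TestFixedHetScan:
    def test_default_cohort_recovers_five_psvs(self, cohort):
        res = dd.fixed_het_scan(
            cohort.genotypes, cohort.markers, cohort.ids("FM"), cohort.ids("WT")
        )
        assert len(res) == 5
        assert {m.marker_id for m in res} == set(cohort.truth.psv_markers)

    def test_wt_classification(self, cohort):
        res = dd.fixed_het_scan(
            cohort.genotypes, cohort.markers, cohort.ids("FM"), cohort.ids("WT")
        )
        classes = [m.wt_class for m in res]
        assert classes.count("fixed_ref") == 2 and classes.count("segregating") == 3

    def test_homozygous_carrier_breaks_all_markers(self, cohort):
        gt = cohort.genotypes.copy()
        gt[cohort.ids("FM")[0]] = "AA"
        res = dd.fixed_het_scan(gt, cohort.markers, cohort.ids("FM"), cohort.ids("WT"))
        assert res == []

    def test_missing_call_strictness(self, cohort):
        gt = cohort.genotypes.copy()
        psv = cohort.truth.psv_markers[0]
        gt.loc[psv, cohort.ids("FM")[0]] = "NC"
        strict = dd.fixed_het_scan(gt, cohort.markers, cohort.ids("FM"), cohort.ids("WT"))
        lax = dd.fixed_het_scan(
            gt, cohort.markers, cohort.ids("FM"), cohort.ids("WT"), missing_disqualifies=False
        )
        assert len(strict) == 4 and len(lax) == 5

    def test_empty_carrier_group_rejected(self, cohort):
        with pytest.raises(ValueError):
            dd.fixed_het_scan(cohort.genotypes, cohort.markers, [], cohort.ids("WT"))


class TestSharedHaplotype:
    def test_recovers_planted_block(self, cohort):
        iv = dd.shared_haplotype_interval(cohort.genotypes, cohort.markers, cohort.ids("FM"))
        assert [iv.start, iv.end] == cohort.truth.shared_haplotype

    def test_recombinant_flank_shrinks_interval(self, cohort):
        gt = cohort.genotypes.copy()
        truth_lo, truth_hi = cohort.truth.shared_haplotype
        pos = cohort.markers["pos"]
        block = gt.index[(pos >= truth_lo) & (pos <= truth_hi)]
        # one carrier loses identity over the right half of the block
        non_psv = [m for m in block[len(block) // 2 :] if m not in cohort.truth.psv_markers]
        rec = cohort.ids("FM")[0]
        for mid in non_psv:
            gt.loc[mid, rec] = "BB" if gt.loc[mid, rec] != "BB" else "AA"
        iv = dd.shared_haplotype_interval(gt, cohort.markers, cohort.ids("FM"))
        assert iv.start == truth_lo and iv.end < truth_hi

    def test_no_fixed_het_block_errors(self, cohort):
        gt = cohort.genotypes.copy()
        for sid in cohort.ids("FM"):
            gt[sid] = "AA"
        with pytest.raises(ValueError):
            dd.shared_haplotype_interval(gt, cohort.markers, cohort.ids("FM"))
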