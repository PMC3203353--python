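import numpy as np
import pytest

from vishotspot import (
    BinProfile,
    ChromSizes,
    Cluster,
    ThresholdSpec,
    VISDataset,
    bin_counts,
    call_hotbins,
    generate_synthetic_vis,
    get_threshold,
    partition_genome,
    refine_hotspots,
    zscores,
    zthreshold_hotspots,
)


def profile_from_z(z):
    """A BinProfile with a hand-set z-vector on a single-chromosome genome."""
    n = len(z)
    g = ChromSizes((("chr1", n * 1_000_000),))
    gp = partition_genome(g)
    prof = BinProfile(gp, np.zeros(n, dtype=np.int64))
    prof.z = np.asarray(z, dtype=float)
    return prof


class TestGetThreshold:
    def test_percentile_uses_linear_interpolation(self):
        z = np.zeros(100)
        z[-1] = 10.0
        prof = profile_from_z(z)
        spec = get_threshold(prof, 99.0)
        # between the 99th and 100th order statistics: 0 + 0.01*(10-0)/...
        assert spec.value == pytest.approx(np.percentile(z, 99.0))
        assert 0.0 < spec.value < 10.0
        assert spec.source == "calibrated-from-reference"

    def test_percentile_100_is_max(self):
        prof = profile_from_z([1.0, 5.0, 3.0])
        assert get_threshold(prof, 100.0).value == 5.0

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            get_threshold(profile_from_z([2.0, 2.0, 2.0]), 99.0)


class TestCallHotbins:
    def test_none_above(self):
        prof = profile_from_z([0.0, 1.0, 2.0])
        assert call_hotbins(prof, ThresholdSpec(5.0)).size == 0

    def test_exact_tie_excluded_with_warning(self):
        prof = profile_from_z([0.0, 5.0, 7.0])
        with pytest.warns(UserWarning, match="at the threshold"):
            hot = call_hotbins(prof, ThresholdSpec(5.0))
        assert hot.tolist() == [2]

    def test_planted_exceedances_found_exactly(self):
        z = np.linspace(-1, 1, 50)
        z[[7, 20, 33]] = [10.0, 12.0, 11.0]
        prof = profile_from_z(z)
        assert call_hotbins(prof, ThresholdSpec(5.0)).tolist() == [7, 20, 33]

    def test_missing_score_errors(self):
        prof = profile_from_z([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="not computed"):
            call_hotbins(prof, ThresholdSpec(0.5), score="posterior_mean")


class TestRefineHotspots:
    def test_boundaries_move_to_member_vis(self):
        g = ChromSizes((("chr1", 5_000_000),))
        gp = partition_genome(g)
        vis = VISDataset.from_records(
            "t", g, [("chr1", 1_200_000), ("chr1", 1_800_000)]
        )
        hs = refine_hotspots([1], vis, gp)
        assert len(hs) == 1
        assert (hs[0].start, hs[0].end) == (1_200_000, 1_800_000)
        assert hs[0].n_vis == 2

    def test_refinement_crosses_bin_edge_to_closer_outside_vis(self):
        g = ChromSizes((("chr1", 5_000_000),))
        gp = partition_genome(g)
        # VIS just outside the hot bin (1-2 Mb) is closer to the left edge
        # than any member VIS
        vis = VISDataset.from_records(
            "t", g,
            [("chr1", 950_000), ("chr1", 1_500_000), ("chr1", 1_900_000)],
        )
        hs = refine_hotspots([1], vis, gp)
        assert (hs[0].start, hs[0].end) == (950_000, 1_900_000)

    def test_adjacent_hotbins_group_but_gaps_do_not(self):
        g = ChromSizes((("chr1", 9_000_000),))
        gp = partition_genome(g)
        vis = VISDataset.from_records(
            "t", g, [("chr1", p) for p in
                     (1_100_000, 2_100_000, 2_900_000, 5_500_000)]
        )
        hs = refine_hotspots([1, 2, 5], vis, gp)
        assert len(hs) == 2
        assert hs[0].n_vis == 3  # bins 1-2 grouped

    def test_runs_do_not_cross_chromosomes(self, toy_genome):
        gp = partition_genome(toy_genome, 1_000)
        vis = VISDataset.from_records(
            "t", toy_genome, [("chrA", 9_500), ("chrB", 400)]
        )
        # chrA has 10 bins; bin 9 is chrA's last, bin 10 is chrB's first
        hs = refine_hotspots([9, 10], vis, gp)
        assert len(hs) == 2

    def test_empty_chromosome_falls_back_to_bin_edges(self):
        g = ChromSizes((("chr1", 5_000_000), ("chr2", 5_000_000)))
        gp = partition_genome(g)
        vis = VISDataset.from_records("t", g, [("chr2", 10)])
        with pytest.warns(UserWarning, match="fall back"):
            hs = refine_hotspots([1], vis, gp)
        assert (hs[0].start, hs[0].end) == (1_000_001, 2_000_000)
        assert hs[0].n_vis == 0

    def test_equidistant_tie_prefers_interior(self):
        g = ChromSizes((("chr1", 5_000_000),))
        gp = partition_genome(g)
        vis = VISDataset.from_records(
            "t", g, [("chr1", 1_000_000), ("chr1", 1_000_001),
                     ("chr1", 1_700_000)]
        )
        hs = refine_hotspots([1], vis, gp)
        assert hs[0].start == 1_000_001  # inside wins the tie


class TestPlantedClusterCalibration:
    def test_full_recall_zero_false_positives_between_scales(self):
        """Any threshold between the background max and the weakest planted
        cluster's z recovers exactly the planted bins."""
        g = ChromSizes((("chr1", 60_000_000), ("chr2", 40_000_000)))
        gp = partition_genome(g)
        clusters = [
            Cluster("chr1", 10_500_000, 600_000, 40),
            Cluster("chr1", 42_500_000, 600_000, 55),
            Cluster("chr2", 20_500_000, 600_000, 45),
        ]
        vis = generate_synthetic_vis(g, 400, clusters, seed=11)
        prof = zscores(bin_counts(vis, gp))
        truth = sorted(
            int(gp.bin_index(
                np.array([g.index_of(c.chrom)]), np.array([c.center])
            )[0])
            for c in clusters
        )
        background = np.setdiff1d(np.arange(gp.n), truth)
        lo, hi = prof.z[background].max(), prof.z[truth].min()
        assert lo < hi, "fixture must separate background from clusters"
        for thr in np.linspace(lo, hi, 5)[1:-1]:
            hot = call_hotbins(prof, ThresholdSpec(float(thr)))
            assert hot.tolist() == truth

    def test_hotspots_carry_all_member_vis(self):
        g = ChromSizes((("chr1", 60_000_000),))
        gp = partition_genome(g)
        vis = generate_synthetic_vis(
            g, 200, [Cluster("chr1", 30_500_000, 500_000, 50)], seed=3
        )
        prof = zscores(bin_counts(vis, gp))
        hs = zthreshold_hotspots(prof, vis, get_threshold(prof, 99.0))
        assert len(hs) >= 1
        total_pct = sum(h.pct_vis for h in hs)
        assert sum(h.n_vis for h in hs) == round(total_pct * len(vis) / 100)
        for h in hs:
            pos = vis.positions_on(h.chrom)
            np.testing.assert_array_equal(
                h.vis_positions, pos[(pos >= h.start) & (pos <= h.end)]
            )
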