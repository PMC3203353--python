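import numpy as np
import pandas as pd
import pytest

from vishotspot import (
    ChromSizes,
    FeatureTrack,
    cancer_gene_pct,
    compare_to_genome,
    feature_density,
    genes_in_hotspots,
    genome_density_profile,
    partition_genome,
)
from vishotspot.hotspot import make_hotspot

from .oracles import interval_overlap_count


def track(intervals, name="t"):
    return FeatureTrack(
        name,
        pd.DataFrame(
            [
                {"chrom": c, "start": s, "end": e, "name": n}
                for c, s, e, n in intervals
            ]
        ),
    )


def hs(chrom, start, end):
    return make_hotspot(
        chrom, start, end, np.array([start, end]), 100, method="bcp"
    )


class TestBedInput:
    def test_three_and_four_column_bed(self, tmp_path):
        p3 = tmp_path / "t3.bed"
        p3.write_text("chr1\t100\t200\nchr1\t300\t400\n")
        t3 = FeatureTrack.from_bed(p3)
        assert len(t3) == 2 and (t3.df["name"] == "").all()
        p4 = tmp_path / "t4.bed"
        p4.write_text("chr1\t100\t200\tgeneA\nchr2\t5\t50\tgeneB\n")
        t4 = FeatureTrack.from_bed(p4, name="genes")
        assert t4.name == "genes"
        assert t4.df["name"].tolist() == ["geneA", "geneB"]

    def test_too_few_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\nchr1\t300\n")
        with pytest.raises(ValueError, match=">= 3 columns"):
            FeatureTrack.from_bed(p)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "inv.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="start < end"):
            FeatureTrack.from_bed(p)


class TestFeatureDensity:
    def test_two_features_in_half_mb(self):
        t = track([("chr1", 1_100_000, 1_110_000, "g1"),
                   ("chr1", 1_200_000, 1_210_000, "g2")])
        d = feature_density([hs("chr1", 1_000_000, 1_500_000)], t)
        assert d.tolist() == [4.0]

    def test_straddling_feature_counts_once(self):
        t = track([("chr1", 900_000, 1_100_000, "g")])
        d = feature_density([hs("chr1", 1_000_000, 1_500_000)], t)
        assert d.tolist() == [2.0]

    def test_empty_track_zero_density(self):
        t = track([("chr9", 1, 10, "x")])
        d = feature_density([hs("chr1", 1_000_000, 1_500_000)], t)
        assert d.tolist() == [0.0]

    def test_matches_interval_intersection_oracle(self):
        rng = np.random.default_rng(8)
        ivs = []
        for k in range(200):
            s = int(rng.integers(0, 5_000_000))
            ivs.append(("chr1", s, s + int(rng.integers(1, 50_000)), f"f{k}"))
        t = track(ivs)
        spots = [hs("chr1", int(a) + 1, int(a) + 400_000)
                 for a in rng.integers(0, 4_500_000, size=20)]
        fast = feature_density(spots, t)
        for spot, d in zip(spots, fast):
            slow = interval_overlap_count(
                [(s, e) for _, s, e, _ in ivs], spot.start - 1, spot.end
            )
            assert d == pytest.approx(slow / spot.size_mb)


class TestGenomeDensity:
    def test_uniform_one_per_bin(self):
        g = ChromSizes((("chr1", 4_000_000),))
        gp = partition_genome(g)
        t = track([("chr1", k * 1_000_000 + 10, k * 1_000_000 + 20, f"f{k}")
                   for k in range(4)])
        dens, med = genome_density_profile(t, gp)
        assert dens.tolist() == [1.0] * 4 and med == 1.0

    def test_even_count_median_interpolates(self):
        g = ChromSizes((("chr1", 4_000_000),))
        gp = partition_genome(g)
        t = track([("chr1", 10, 20, "a"), ("chr1", 30, 40, "b"),
                   ("chr1", 1_000_010, 1_000_020, "c")])
        dens, med = genome_density_profile(t, gp)
        assert sorted(dens.tolist()) == [0.0, 0.0, 1.0, 2.0]
        assert med == 0.5

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        g = ChromSizes((("chr1", 20_000_000),))
        gp = partition_genome(g)
        ivs = [("chr1", int(s), int(s) + 500, f"f{i}")
               for i, s in enumerate(rng.integers(0, 19_999_000, size=300))]
        dens, med = genome_density_profile(track(ivs), gp)
        s = sorted(dens)
        n = len(s)
        oracle = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert med == pytest.approx(oracle)


class TestCompareToGenome:
    def test_null_draws_give_large_p(self):
        rng = np.random.default_rng(0)
        genome = rng.poisson(5, size=2_000).astype(float)
        ps = [
            compare_to_genome(rng.choice(genome, 8), genome).wilcoxon_p
            for _ in range(50)
        ]
        assert np.median(ps) > 0.2
        assert sum(p < 0.0025 for p in ps) <= 1

    def test_extreme_densities_significant(self):
        genome = np.concatenate([np.zeros(1_500), np.ones(1_500)])
        comp = compare_to_genome(np.full(10, 25.0), genome)
        assert comp.significant and comp.wilcoxon_p < 1e-6

    def test_single_hotspot_runs_flagged_low_power(self):
        comp = compare_to_genome(np.array([3.0]), np.arange(100.0))
        assert comp.low_power and comp.wilcoxon_p > 0.0025

    def test_rank_test_invariant_to_scale(self):
        rng = np.random.default_rng(1)
        hs_d = rng.gamma(2, 2, size=12)
        ge = rng.gamma(2, 2, size=500)
        p1 = compare_to_genome(hs_d, ge).wilcoxon_p
        p2 = compare_to_genome(hs_d * 37.0, ge * 37.0).wilcoxon_p
        assert p1 == pytest.approx(p2)


class TestCancerGenes:
    def test_one_of_seven(self):
        pct, _ = cancer_gene_pct(
            [f"g{i}" for i in range(6)] + ["EVI1"], {"EVI1", "MYC"}
        )
        assert pct == pytest.approx(100 / 7)

    def test_zero_of_ten(self):
        pct, _ = cancer_gene_pct([f"g{i}" for i in range(10)], {"EVI1"})
        assert pct == 0.0

    def test_no_genes_undefined(self):
        pct, p = cancer_gene_pct([], {"EVI1"})
        assert pct is None and p is None

    def test_enrichment_p_uniform_under_null(self):
        rng = np.random.default_rng(9)
        genome_genes = [f"g{i}" for i in range(500)]
        cancer = set(rng.choice(genome_genes, size=50, replace=False))
        ps = []
        for _ in range(200):
            in_hs = list(rng.choice(genome_genes, size=20, replace=False))
            _, p = cancer_gene_pct(in_hs, cancer, genome_genes)
            ps.append(p)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.2):
            assert (ps <= alpha).mean() <= alpha + 0.05

    def test_genes_in_hotspots_unique_overlap(self):
        genes = track(
            [("chr1", 1_050_000, 1_060_000, "A"),
             ("chr1", 1_400_000, 1_600_000, "B"),
             ("chr1", 3_000_000, 3_100_000, "C")],
            name="genes",
        )
        spots = [hs("chr1", 1_000_000, 1_500_000),
                 hs("chr1", 1_450_000, 1_700_000)]
        assert genes_in_hotspots(spots, genes) == ["A", "B"]
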