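"""Genomic-feature characterization of hot-spots.

Per-hot-spot feature densities (features per Mb, any >= 1 bp overlap
counts a feature once per region) are compared to the genome-wide per-bin
density distribution with a continuity-corrected Wilcoxon rank-sum test;
significance uses a Bonferroni-corrected level of 0.0025 (20 tests:
5 dataset comparisons x 4 feature classes in the reference analysis).
The cancer-gene percentage divides cancer-related genes in hot-spots by
all genes in hot-spots, controlling for gene density, with a Fisher exact
enrichment test against the genome-wide gene catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .genome import ChromSizes, GenomePartition
from .hotspot import HotSpot

__all__ = [
    "FeatureTrack",
    "DensityComparison",
    "feature_density",
    "genome_density_profile",
    "compare_to_genome",
    "genes_in_hotspots",
    "cancer_gene_pct",
]

BONFERRONI_ALPHA = 0.0025


@dataclass
class FeatureTrack:
    """A named set of genomic intervals (0-based half-open, sorted)."""

    name: str
    df: pd.DataFrame = field(repr=False)  # columns: chrom, start, end, name

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"track needs columns {sorted(need)}")
        if "name" not in self.df.columns:
            self.df = self.df.assign(name="")
        if (self.df["end"] <= self.df["start"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.df = self.df.sort_values(["chrom", "start"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path, name: str | None = None) -> "FeatureTrack":
        df = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            engine="python",
            on_bad_lines="error",
        )
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED-like input needs >= 3 columns")
        df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name="")
        df.columns = ["chrom", "start", "end", "name"]
        df = df.astype(
            {"chrom": str, "start": np.int64, "end": np.int64, "name": str}
        )
        if name is None:
            import os

            name = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(name, df)

    def validate_against(self, chrom_sizes: ChromSizes) -> None:
        for chrom, grp in self.df.groupby("chrom"):
            length = chrom_sizes.length_of(str(chrom))
            if (grp["start"] < 0).any() or (grp["end"] > length).any():
                raise ValueError(f"track {self.name}: interval outside {chrom}")

    def _count_overlaps(self, chrom: str, start0: int, end0: int) -> int:
        grp = self.df[self.df["chrom"] == chrom]
        return int(((grp["start"] < end0) & (grp["end"] > start0)).sum())

    def names_overlapping(self, chrom: str, start0: int, end0: int) -> list[str]:
        grp = self.df[self.df["chrom"] == chrom]
        hit = grp[(grp["start"] < end0) & (grp["end"] > start0)]
        return list(hit["name"])


def feature_density(hotspots: list[HotSpot], track: FeatureTrack) -> np.ndarray:
    """Features per Mb for each hot-spot (>= 1 bp overlap counts once)."""
    out = np.empty(len(hotspots))
    for j, hs in enumerate(hotspots):
        if hs.size_mb <= 0:
            raise ValueError(f"zero-size hot-spot at {hs.chrom}:{hs.start}")
        k = track._count_overlaps(hs.chrom, hs.start - 1, hs.end)
        out[j] = k / hs.size_mb
    return out


def genome_density_profile(
    track: FeatureTrack, partition: GenomePartition
) -> tuple[np.ndarray, float]:
    """Per-bin feature densities over the whole genome, plus their median."""
    dens = np.empty(partition.n)
    names = partition.chrom_sizes.names
    for i in range(partition.n):
        chrom = names[int(partition.bin_chrom[i])]
        s, e = int(partition.bin_start[i]), int(partition.bin_end[i])
        width_mb = (e - s) / 1e6
        dens[i] = track._count_overlaps(chrom, s, e) / width_mb
    return dens, float(np.median(dens))


@dataclass(frozen=True)
class DensityComparison:
    track: str
    hotspot_densities: np.ndarray = field(repr=False)
    genome_median: float = 0.0
    wilcoxon_p: float = 1.0
    significant: bool = False
    low_power: bool = False  # single hot-spot: the test is nearly powerless


def compare_to_genome(
    hotspot_densities: np.ndarray,
    genome_bin_densities: np.ndarray,
    track_name: str = "",
    alpha: float = BONFERRONI_ALPHA,
) -> DensityComparison:
    """Rank-sum test of hot-spot densities against the genome distribution.

    The genome side of the comparison is the full per-bin density vector
    (a rank test needs a second sample; its median is the published
    "genome median" reference point).
    """
    hs = np.asarray(hotspot_densities, dtype=float)
    ge = np.asarray(genome_bin_densities, dtype=float)
    if len(hs) == 0 or len(ge) == 0:
        raise ValueError("empty density input")
    _, p = scipy.stats.mannwhitneyu(
        hs, ge, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return DensityComparison(
        track=track_name,
        hotspot_densities=hs,
        genome_median=float(np.median(ge)),
        wilcoxon_p=float(p),
        significant=bool(p < alpha),
        low_power=len(hs) == 1,
    )


def genes_in_hotspots(hotspots: list[HotSpot], genes: FeatureTrack) -> list[str]:
    """Unique gene names overlapping any hot-spot (>= 1 bp)."""
    seen: dict[str, None] = {}
    for hs in hotspots:
        for nm in genes.names_overlapping(hs.chrom, hs.start - 1, hs.end):
            seen.setdefault(nm, None)
    return list(seen)


def cancer_gene_pct(
    hotspot_genes: list[str],
    cancer_genes,
    genome_genes: list[str] | None = None,
) -> tuple[float | None, float | None]:
    """Percentage of hot-spot genes that are cancer-related, with a Fisher
    enrichment test against the genome-wide gene catalogue.

    Returns (percentage, p-value); the percentage is None when no genes
    lie in hot-spots, and the p-value is None when no genome catalogue is
    supplied.
    """
    cancer = (
        set(cancer_genes.df["name"])
        if isinstance(cancer_genes, FeatureTrack)
        else set(cancer_genes)
    )
    k = sum(1 for g in hotspot_genes if g in cancer)
    m = len(hotspot_genes)
    if m == 0:
        return None, None
    pct = 100.0 * k / m
    if genome_genes is None:
        return pct, None
    kg = sum(1 for g in genome_genes if g in cancer)
    mg = len(genome_genes)
    table = [[k, m - k], [kg - k, (mg - m) - (kg - k)]]
    p = float(scipy.stats.fisher_exact(table)[1])
    return pct, p
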