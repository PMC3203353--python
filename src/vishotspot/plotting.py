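"""Stripchart and barplot views of hot-spot results.

Three styles: a genome-wide stripchart of all datasets, a per-chromosome
stripchart, and a per-bin barplot (y-axis is the bin rate, # VIS per bin /
total # VIS, which unlike a z-score is never negative).  VIS inside
hot-spots are colored by the quantile class of their bin's z-score within
the dataset's occupied-bin (>= 1 VIS) z-score distribution:
<= 85th percentile light blue, (85, 95] dark blue, (95, 97.5] purple,
(97.5, 99] pink, > 99 red; VIS outside hot-spots are grey.  Ties at a
class edge fall to the lower class; x-axes are in Mb.
"""

from __future__ import annotations

import numpy as np

from .binning import BinProfile, VISDataset
from .hotspot import HotSpot

__all__ = ["color_classes", "CLASS_COLORS", "plot_results"]

CLASS_COLORS = ("#9ecae9", "#2161a6", "#7b3294", "#f191bf", "#d7191c")
_GREY = "#999999"
_QUANTS = (85.0, 95.0, 97.5, 99.0)


def color_classes(z: np.ndarray, occupied: np.ndarray) -> np.ndarray:
    """Quantile class (0..4) of each bin's z-score among occupied bins.

    ``occupied`` masks the bins with at least one VIS; quantile cut
    points use linear interpolation and a value equal to a cut point
    falls in the lower class.
    """
    cuts = np.percentile(z[occupied], _QUANTS)
    return np.searchsorted(cuts, z, side="left")


def _dataset_colors(
    profile: BinProfile, vis: VISDataset, hotspots: list[HotSpot]
) -> np.ndarray:
    """Per-VIS colors for one dataset."""
    part = profile.partition
    classes = color_classes(profile.z, profile.counts > 0)
    bin_of = part.bin_index(vis.chrom_idx, vis.positions)
    colors = np.full(len(vis), _GREY, dtype=object)
    name_to_idx = {n: i for i, n in enumerate(part.chrom_sizes.names)}
    for hs in hotspots:
        ci = name_to_idx[hs.chrom]
        inside = (
            (vis.chrom_idx == ci)
            & (vis.positions >= hs.start)
            & (vis.positions <= hs.end)
        )
        colors[inside] = [CLASS_COLORS[classes[b]] for b in bin_of[inside]]
    return colors


def plot_results(
    results: list[tuple[VISDataset, BinProfile, list[HotSpot]]],
    style: str = "genome_stripchart",
    chromosome: str | None = None,
    out: str | None = None,
):
    """Render one of the three plot styles; returns the matplotlib figure.

    ``results`` pairs each dataset with its bin profile and hot-spot
    calls.  ``chromosome`` is required for the per-chromosome styles;
    ``bin_barplot`` uses only the first dataset.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if style not in ("genome_stripchart", "chromosome_stripchart", "bin_barplot"):
        raise ValueError(f"unknown plot style {style!r}")
    if style != "genome_stripchart":
        if chromosome is None:
            raise ValueError(f"{style} requires a chromosome")
        sizes = results[0][0].chrom_sizes
        if chromosome not in sizes:
            raise KeyError(f"unknown chromosome {chromosome!r}")

    fig, ax = plt.subplots(figsize=(10, max(2, 0.6 * len(results) + 1)))
    if style in ("genome_stripchart", "chromosome_stripchart"):
        labels = []
        for row, (vis, profile, hotspots) in enumerate(results):
            colors = _dataset_colors(profile, vis, hotspots)
            if style == "genome_stripchart":
                offsets = np.concatenate(
                    ([0], np.cumsum(vis.chrom_sizes.lengths))
                )[:-1]
                x = (offsets[vis.chrom_idx] + vis.positions) / 1e6
            else:
                ci = vis.chrom_sizes.index_of(chromosome)
                mask = vis.chrom_idx == ci
                x = vis.positions[mask] / 1e6
                colors = colors[mask]
            ax.scatter(x, np.full(len(x), row), s=6, c=list(colors),
                       marker="|")
            labels.append(vis.name)
        ax.set_yticks(range(len(labels)), labels)
        ax.set_xlabel("position (Mb)")
    else:  # bin_barplot
        vis, profile, hotspots = results[0]
        part = profile.partition
        sl = part.bins_for_chrom(chromosome)
        rates = profile.counts[sl] / max(profile.total, 1)
        classes = color_classes(profile.z, profile.counts > 0)[sl]
        hot_bins = np.zeros(sl.stop - sl.start, dtype=bool)
        for hs in hotspots:
            if hs.chrom != chromosome:
                continue
            idx = np.arange(sl.start, sl.stop)
            hot_bins |= (part.bin_end[sl] >= hs.start) & (
                part.bin_start[sl] < hs.end
            )
        colors = [
            CLASS_COLORS[c] if h else _GREY for c, h in zip(classes, hot_bins)
        ]
        centers = (part.bin_start[sl] + part.bin_end[sl]) / 2 / 1e6
        widths = (part.bin_end[sl] - part.bin_start[sl]) / 1e6
        ax.bar(centers, rates, width=widths, color=colors)
        ax.set_xlabel(f"{chromosome} position (Mb)")
        ax.set_ylabel("bin rate (# VIS per bin / total # VIS)")
        ax.set_title(vis.name)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
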