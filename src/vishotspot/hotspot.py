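"""The HotSpot record shared by all three detectors.

A hot-spot is a genomic interval whose boundaries are occupied VIS
positions (1-based, inclusive).  Summary statistics follow the published
table conventions: ``pct_vis`` is the percentage of the dataset's VIS
inside the interval, ``size_mb`` is (end - start)/1e6, and ``pct_density``
is pct_vis / size_mb (percent of the dataset per megabase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HotSpot", "make_hotspot"]


@dataclass
class HotSpot:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    vis_positions: np.ndarray = field(repr=False)
    n_vis: int
    pct_vis: float
    size_mb: float
    pct_density: float
    method: str  # cis | zthreshold | bcp
    shifts: tuple[int, ...] = ()  # contributing partition shifts, if merged

    def overlaps(self, other: "HotSpot") -> bool:
        """At least 1 bp of shared interval on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def make_hotspot(
    chrom: str,
    start: int,
    end: int,
    member_positions: np.ndarray,
    dataset_total: int,
    method: str,
    shifts: tuple[int, ...] = (),
) -> HotSpot:
    member_positions = np.asarray(member_positions, dtype=np.int64)
    n = len(member_positions)
    pct = 100.0 * n / dataset_total if dataset_total else 0.0
    size_mb = (end - start) / 1e6
    density = pct / size_mb if size_mb > 0 else math.inf
    return HotSpot(
        chrom=chrom,
        start=int(start),
        end=int(end),
        vis_positions=member_positions,
        n_vis=n,
        pct_vis=pct,
        size_mb=size_mb,
        pct_density=density,
        method=method,
        shifts=shifts,
    )
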