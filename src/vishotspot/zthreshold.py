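"""z-threshold hot-spot detection and hot-bin -> hot-spot refinement.

Hot-bins are bins whose score (z-score by default; bin rate or BCP
posterior mean as alternatives) strictly exceeds a threshold.  The default
threshold of 422 is the 99.92 percentile of a reference (acute-infection)
dataset's z-scores; ``get_threshold`` recalibrates it for other studies.
Maximal runs of consecutive hot-bins on one chromosome become hot-spots
whose external boundaries move to the VIS closest to each outer bin edge,
searching both inside and outside the run (ties go to the interior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import BinProfile, VISDataset
from .genome import GenomePartition
from .hotspot import HotSpot, make_hotspot

__all__ = [
    "ThresholdSpec",
    "DEFAULT_Z_THRESHOLD",
    "DEFAULT_RATE_THRESHOLD",
    "get_threshold",
    "call_hotbins",
    "refine_hotspots",
    "zthreshold_hotspots",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """A hot-bin threshold and where it came from.

    Quantile convention for calibrated thresholds: linear interpolation
    between order statistics (numpy/R type-7), recorded here so calibrated
    values are reproducible.
    """

    value: float
    percentile: float | None = None
    source: str = "fixed"  # fixed | calibrated-from-reference
    score: str = "zscore"  # zscore | rate | posterior_mean

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("threshold value must be finite")
        if self.percentile is not None and not (0 < self.percentile <= 100):
            raise ValueError("percentile must lie in (0, 100]")


#: z-scale default, the 99.92 percentile of the reference acute-infection data
DEFAULT_Z_THRESHOLD = ThresholdSpec(422.0, percentile=99.92)
#: bin-rate-scale default from the same reference calibration
DEFAULT_RATE_THRESHOLD = ThresholdSpec(0.006, percentile=99.92, score="rate")


def get_threshold(
    reference: BinProfile, percentile: float = 99.92, score: str = "zscore"
) -> ThresholdSpec:
    """Calibrate a threshold as a percentile of a reference score vector."""
    arr = reference.score(score)
    if np.ptp(arr) == 0:
        raise ValueError("degenerate reference: constant scores")
    value = float(np.percentile(arr, percentile))  # linear interpolation
    return ThresholdSpec(
        value, percentile=percentile, source="calibrated-from-reference",
        score=score,
    )


def call_hotbins(
    profile: BinProfile, threshold: ThresholdSpec, score: str | None = None
) -> np.ndarray:
    """Indices of bins whose score strictly exceeds the threshold."""
    kind = score or threshold.score
    arr = profile.score(kind)
    hot = np.nonzero(arr > threshold.value)[0]
    n_ties = int((arr == threshold.value).sum())
    if n_ties:
        warnings.warn(
            f"{n_ties} bin(s) exactly at the threshold were excluded "
            "(strict inequality)",
            stacklevel=2,
        )
    return hot


def _nearest_vis(pos: np.ndarray, edge: float, prefer_above: bool) -> int | None:
    """VIS nearest to a bin edge; ties broken toward the run interior.

    ``edge`` is the coordinate between two bins expressed as the stored
    0-based boundary b (the gap between positions b and b+1); distances are
    measured to b + 0.5 so a VIS at b and one at b+1 tie exactly.
    """
    if len(pos) == 0:
        return None
    d = np.abs(2 * pos - (2 * int(edge) + 1))  # twice distance to edge+0.5
    best = d.min()
    cand = pos[d == best]
    interior = cand[cand > edge] if prefer_above else cand[cand <= edge]
    pick = interior if len(interior) else cand
    return int(pick[0] if prefer_above else pick[-1])


def refine_hotspots(
    hotbins: np.ndarray,
    vis: VISDataset,
    partition: GenomePartition,
    method: str = "zthreshold",
) -> list[HotSpot]:
    """Group consecutive hot-bins and refine boundaries to the nearest VIS.

    Runs are never merged across a non-hot gap.  A run with no VIS in or
    near it keeps its bin edges (with a warning).
    """
    hotbins = np.asarray(sorted(set(int(i) for i in hotbins)), dtype=np.int64)
    if len(hotbins) and (hotbins[0] < 0 or hotbins[-1] >= partition.n):
        raise IndexError("hot-bin index outside the partition")
    hotspots: list[HotSpot] = []
    total = len(vis)
    runs: list[list[int]] = []
    for b in hotbins:
        if (
            runs
            and b == runs[-1][-1] + 1
            and partition.bin_chrom[b] == partition.bin_chrom[runs[-1][-1]]
        ):
            runs[-1].append(int(b))
        else:
            runs.append([int(b)])
    for run in runs:
        ci = int(partition.bin_chrom[run[0]])
        chrom = partition.chrom_sizes.names[ci]
        left_edge = int(partition.bin_start[run[0]])
        right_edge = int(partition.bin_end[run[-1]])
        pos = vis.positions[vis.chrom_idx == ci]
        start = _nearest_vis(pos, left_edge, prefer_above=True)
        end = _nearest_vis(pos, right_edge, prefer_above=False)
        if start is None or end is None or start > end:
            warnings.warn(
                f"hot-bin run on {chrom} has no usable VIS near its edges; "
                "boundaries fall back to bin edges",
                stacklevel=2,
            )
            start, end = left_edge + 1, right_edge
        members = pos[(pos >= start) & (pos <= end)]
        hotspots.append(
            make_hotspot(chrom, start, end, members, total, method=method)
        )
    return hotspots


def zthreshold_hotspots(
    profile: BinProfile,
    vis: VISDataset,
    threshold: ThresholdSpec = DEFAULT_Z_THRESHOLD,
    score: str | None = None,
) -> list[HotSpot]:
    """Convenience wrapper: call hot-bins then refine to hot-spots."""
    hot = call_hotbins(profile, threshold, score=score)
    return refine_hotspots(hot, vis, profile.partition)
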