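"""Conventional Common Insertion Site (CIS) detection.

A region qualifies under a rule (window X kb, minimum count Y) when some
window of X kb contains at least Y VIS.  The literal procedure slides a
window 1 bp at a time along each chromosome; because the VIS are points,
an equivalent O(m) formulation is used: Y consecutive sorted VIS form a
qualifying run iff their span is smaller than the window width (a
half-open window of width w covers integer positions p..q iff q - p < w).
Qualifying runs from all rules are pooled and overlapping or book-ended
runs merge into maximal disjoint hot-spots whose boundaries are the
outermost member VIS.

The default rule set is >= 3 VIS within 50 kb or >= 4 within 100 kb —
either density triggers a call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import VISDataset
from .hotspot import HotSpot, make_hotspot

__all__ = ["CISRule", "DEFAULT_CIS_RULES", "cis_scan"]


@dataclass(frozen=True)
class CISRule:
    window: int  # bp
    min_count: int

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_count < 2:
            raise ValueError("min_count must be >= 2")

    @classmethod
    def parse(cls, text: str) -> "CISRule":
        """Parse "count:window_bp", e.g. "3:50000"."""
        count, window = text.split(":")
        return cls(window=int(window), min_count=int(count))


DEFAULT_CIS_RULES = (CISRule(50_000, 3), CISRule(100_000, 4))


def cis_scan(
    vis: VISDataset, rules=DEFAULT_CIS_RULES
) -> list[HotSpot]:
    """Run the sliding-window CIS analysis under one or more rules."""
    rules = list(rules)
    if not rules:
        raise ValueError("at least one CIS rule required")
    hotspots: list[HotSpot] = []
    total = len(vis)
    for ci, chrom in enumerate(vis.chrom_sizes.names):
        pos = vis.positions[vis.chrom_idx == ci]
        m = len(pos)
        if m == 0:
            continue
        # collect qualifying [start_pos, end_pos] intervals from all rules
        intervals: list[tuple[int, int]] = []
        for rule in rules:
            y, w = rule.min_count, rule.window
            if m < y:
                continue
            span = pos[y - 1:] - pos[: m - y + 1]
            for i in np.nonzero(span < w)[0]:
                intervals.append((int(pos[i]), int(pos[i + y - 1])))
        if not intervals:
            continue
        intervals.sort()
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s <= merged[-1][1]:  # overlap or book-ended on a shared VIS
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            members = pos[(pos >= s) & (pos <= e)]
            hotspots.append(
                make_hotspot(chrom, s, e, members, total, method="cis")
            )
    return hotspots
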