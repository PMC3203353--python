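"""Merging hot-spot calls from shifted genome partitions.

Hot-spot calls can depend on where the bin boundaries fall; running the
detection on one or more shifted partitions and merging the results gives
a more comprehensive hot-spot set.  Intervals overlapping by at least
1 bp union into one hot-spot whose statistics are recomputed from the
dataset's VIS inside the union (never averaged from the parents), with
provenance listing the contributing shifts.
"""

from __future__ import annotations

import numpy as np

from .binning import VISDataset
from .hotspot import HotSpot, make_hotspot

__all__ = ["merge_hotspots", "match_hotspots"]


def merge_hotspots(
    results: list[list[HotSpot]],
    vis: VISDataset,
    shifts: list[int] | None = None,
) -> list[HotSpot]:
    """Union hot-spot sets from different partitions of one dataset.

    Merging is commutative and associative; merging a set with itself is
    the identity.
    """
    if shifts is not None and len(shifts) != len(results):
        raise ValueError("one shift per result set required")
    flat: list[tuple[str, int, int, int, str]] = []
    for k, hs_set in enumerate(results):
        for hs in hs_set:
            shift = shifts[k] if shifts is not None else k
            flat.append((hs.chrom, hs.start, hs.end, shift, hs.method))
    merged: list[HotSpot] = []
    total = len(vis)
    order = {nm: i for i, nm in enumerate(vis.chrom_sizes.names)}
    flat.sort(key=lambda t: (order[t[0]], t[1], t[2]))
    i = 0
    while i < len(flat):
        chrom, start, end, shift, method = flat[i]
        shifts_here = {shift}
        methods = {method}
        j = i + 1
        while j < len(flat) and flat[j][0] == chrom and flat[j][1] <= end:
            end = max(end, flat[j][2])
            shifts_here.add(flat[j][3])
            methods.add(flat[j][4])
            j += 1
        pos = vis.positions_on(chrom)
        members = pos[(pos >= start) & (pos <= end)]
        merged.append(
            make_hotspot(
                chrom, start, end, members, total,
                method="+".join(sorted(methods)),
                shifts=tuple(sorted(shifts_here)),
            )
        )
        i = j
    return merged


def match_hotspots(
    set_a: list[HotSpot], set_b: list[HotSpot]
) -> tuple[int, float, list[tuple[int, int]]]:
    """Count hot-spots of ``set_a`` overlapping (>= 1 bp) any of ``set_b``.

    Returns (match count, correspondence ratio = matches / len(set_a),
    list of overlapping (index_a, index_b) pairs).
    """
    pairs = [
        (i, j)
        for i, a in enumerate(set_a)
        for j, b in enumerate(set_b)
        if a.overlaps(b)
    ]
    matched_a = {i for i, _ in pairs}
    ratio = len(matched_a) / len(set_a) if set_a else 0.0
    return len(matched_a), ratio, pairs
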