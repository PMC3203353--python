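"""Readers and writers for the plain-text interchange formats.

VIS input is a whitespace/tab-delimited table with at least (chromosome,
1-based position) columns; an optional third column is carried through as a
per-record label and an optional strand column is ignored.  Hot-spot output
comes in two flavours: BED (0-based half-open) for interoperability, and a
stats TSV with the columns Chr, Location (Mb), # VIS (%), Size (Mb),
% Density.
"""

from __future__ import annotations

import numpy as np

from .binning import VISDataset
from .genome import ChromSizes

__all__ = ["read_vis", "read_track", "write_hotspots_bed", "write_hotspots_stats"]


def _looks_like_header(parts: list[str]) -> bool:
    try:
        int(parts[1])
    except (ValueError, IndexError):
        return True
    return False


def read_vis(path, chrom_sizes: ChromSizes, name: str | None = None) -> VISDataset:
    """Read a VIS coordinate file and validate it against ``chrom_sizes``.

    Rejects unknown chromosomes and out-of-bounds positions with the
    offending line numbers.  Records are returned sorted.
    """
    chroms, positions, labels = [], [], []
    errors = []
    known = {n: i for i, n in enumerate(chrom_sizes.names)}
    lengths = chrom_sizes.lengths
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if lineno == 1 and _looks_like_header(parts):
                continue
            if len(parts) < 2:
                errors.append(f"line {lineno}: expected >= 2 columns")
                continue
            chrom = parts[0]
            if chrom not in known:
                errors.append(f"line {lineno}: unknown chromosome {chrom!r}")
                continue
            try:
                pos = int(parts[1])
            except ValueError:
                errors.append(f"line {lineno}: non-integer position {parts[1]!r}")
                continue
            ci = known[chrom]
            if not (1 <= pos <= lengths[ci]):
                errors.append(
                    f"line {lineno}: position {pos} outside {chrom} "
                    f"[1, {lengths[ci]}]"
                )
                continue
            chroms.append(ci)
            positions.append(pos)
            labels.append(parts[2] if len(parts) > 2 else "")
    if errors:
        raise ValueError(f"{path}: invalid VIS records:\n" + "\n".join(errors))
    if not positions:
        raise ValueError(f"{path}: no parseable VIS records")
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return VISDataset(
        name,
        chrom_sizes,
        np.asarray(chroms, dtype=np.int64),
        np.asarray(positions, dtype=np.int64),
        labels=np.asarray(labels) if any(labels) else None,
    )


def read_track(path, name: str | None = None):
    """Read a BED-like interval track; see :mod:`vishotspot.features`."""
    from .features import FeatureTrack

    return FeatureTrack.from_bed(path, name=name)


def write_hotspots_bed(hotspots, path) -> None:
    """Write hot-spots as BED (0-based half-open) with the method as name."""
    with open(path, "w") as fh:
        for hs in hotspots:
            fh.write(f"{hs.chrom}\t{hs.start - 1}\t{hs.end}\t{hs.method}\n")


def write_hotspots_stats(hotspots, path) -> None:
    """Write the per-hot-spot summary table (locations in Mb, 3 decimals)."""
    with open(path, "w") as fh:
        fh.write("Chr\tLocation (Mb)\t# VIS (%)\tSize (Mb)\t% Density\tMethod\n")
        for hs in hotspots:
            fh.write(
                f"{hs.chrom}\t{hs.start / 1e6:.3f}-{hs.end / 1e6:.3f}\t"
                f"{hs.n_vis} ({hs.pct_vis:.2f}%)\t{hs.size_mb:.2f}\t"
                f"{hs.pct_density:.2f}\t{hs.method}\n"
            )
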