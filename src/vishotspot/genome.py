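"""Genome coordinate scaffolding: chromosome sizes and fixed-width bin partitions.

Both hot-spot detectors operate on a partition of the genome into
non-overlapping bins (1 Mb by default).  Chromosomes are "strung together"
into one continuous bin index so that genome-wide density context is shared
across chromosomes; bins never span a chromosome boundary, and the last bin
of each chromosome is a partial bin (ceiling division).  An optional shift
moves every bin boundary downstream by a fixed amount, creating an initial
partial bin of exactly that width — used to probe sensitivity of hot-spot
calls to bin placement.

Coordinates: input positions are 1-based; a bin with stored bounds
``(start, end)`` covers the 1-based half-open interval ``(start, end]``,
i.e. positions ``start+1 .. end``.  This makes ``(start, end)`` directly
usable as a 0-based half-open BED interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChromSizes", "GenomePartition", "partition_genome", "hg18"]

# UCSC hg18 chromInfo lengths, chr1-22 + X + Y (random/haplotype contigs
# excluded).  Ceiling division at 1 Mb yields 3091 bins in total.
_HG18_SIZES: tuple[tuple[str, int], ...] = (
    ("chr1", 247249719), ("chr2", 242951149), ("chr3", 199501827),
    ("chr4", 191273063), ("chr5", 180857866), ("chr6", 170899992),
    ("chr7", 158821424), ("chr8", 146274826), ("chr9", 140273252),
    ("chr10", 135374737), ("chr11", 134452384), ("chr12", 132349534),
    ("chr13", 114142980), ("chr14", 106368585), ("chr15", 100338915),
    ("chr16", 88827254), ("chr17", 78774742), ("chr18", 76117153),
    ("chr19", 63811651), ("chr20", 62435964), ("chr21", 46944323),
    ("chr22", 49691432), ("chrX", 154913754), ("chrY", 57772954),
)


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name/length table.

    The order is fixed and defines the concatenated ("strung together")
    genomic index used by every partition built from it.
    """

    items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.items]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        for name, length in self.items:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.items]

    @property
    def lengths(self) -> list[int]:
        return [l for _, l in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, name: str) -> bool:
        return name in dict(self.items)

    def length_of(self, name: str) -> int:
        try:
            return dict(self.items)[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def index_of(self, name: str) -> int:
        for i, (n, _) in enumerate(self.items):
            if n == name:
                return i
        raise KeyError(f"unknown chromosome {name!r}")

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        """Read a UCSC chromInfo-style two-column TSV (name, length)."""
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                items.append((parts[0], int(parts[1])))
        if not items:
            raise ValueError(f"{path}: no chromosome records")
        return cls(tuple(items))


def hg18() -> ChromSizes:
    """The embedded human hg18 (chr1-22, X, Y) chromosome-sizes fixture."""
    return ChromSizes(_HG18_SIZES)


@dataclass
class GenomePartition:
    """Non-overlapping bins over a concatenated genome.

    Attributes
    ----------
    bin_chrom : int array, chromosome index (into ``chrom_sizes``) per bin
    bin_start, bin_end : int arrays; bin i covers 1-based positions
        ``bin_start[i]+1 .. bin_end[i]``
    """

    chrom_sizes: ChromSizes
    bin_size: int
    shift: int
    bin_chrom: np.ndarray = field(repr=False)
    bin_start: np.ndarray = field(repr=False)
    bin_end: np.ndarray = field(repr=False)
    _chrom_offset: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        """Total number of bins across all chromosomes."""
        return len(self.bin_start)

    def bin_widths(self) -> np.ndarray:
        return self.bin_end - self.bin_start

    def bin_index(self, chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Map (chromosome index, 1-based position) to global bin index."""
        chrom_idx = np.asarray(chrom_idx, dtype=np.int64)
        pos = np.asarray(pos, dtype=np.int64)
        shift, size = self.shift, self.bin_size
        if shift > 0:
            local = np.where(pos <= shift, 0, (pos - shift - 1) // size + 1)
        else:
            local = (pos - 1) // size
        # clamp positions inside the shift-window on short chromosomes
        per_chrom = self._bins_per_chrom
        local = np.minimum(local, per_chrom[chrom_idx] - 1)
        return self._chrom_offset[chrom_idx] + local

    @property
    def _bins_per_chrom(self) -> np.ndarray:
        return np.diff(np.append(self._chrom_offset, self.n))

    def bins_for_chrom(self, name: str) -> slice:
        ci = self.chrom_sizes.index_of(name)
        off = self._chrom_offset
        stop = off[ci + 1] if ci + 1 < len(off) else self.n
        return slice(int(off[ci]), int(stop))

    def same_partition(self, other: "GenomePartition") -> bool:
        return (
            self.chrom_sizes.items == other.chrom_sizes.items
            and self.bin_size == other.bin_size
            and self.shift == other.shift
        )


def partition_genome(
    chrom_sizes: ChromSizes, bin_size: int = 1_000_000, shift: int = 0
) -> GenomePartition:
    """Partition every chromosome into contiguous ``bin_size`` bins.

    With ``shift > 0`` the first bin of each chromosome is ``[1, shift]``
    and subsequent bins are full-width; the final bin always truncates at
    the chromosome end (ceiling division).

    >>> gp = partition_genome(hg18())
    >>> gp.n
    3091
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not (0 <= shift < bin_size):
        raise ValueError(f"shift must lie in [0, bin_size); got {shift}")
    chroms, starts, ends = [], [], []
    offsets = []
    for ci, (_name, length) in enumerate(chrom_sizes.items):
        offsets.append(len(starts))
        edges = [0]
        if shift > 0 and shift < length:
            edges.append(shift)
        e = edges[-1] + bin_size
        while e < length:
            edges.append(e)
            e += bin_size
        edges.append(length)
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(ci)
            starts.append(s)
            ends.append(e)
    return GenomePartition(
        chrom_sizes=chrom_sizes,
        bin_size=bin_size,
        shift=shift,
        bin_chrom=np.asarray(chroms, dtype=np.int64),
        bin_start=np.asarray(starts, dtype=np.int64),
        bin_end=np.asarray(ends, dtype=np.int64),
        _chrom_offset=np.asarray(offsets, dtype=np.int64),
    )
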