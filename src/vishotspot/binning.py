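"""VIS datasets, per-bin counts and the z-score transform.

The z-score of bin *i* is ``X_i = (C_i - Cbar) / SE(C)`` where ``C`` is the
vector of per-bin VIS counts over the whole strung-together genome, ``Cbar``
its mean, and ``SE(C)`` the standard error of the mean, i.e. the sample
standard deviation of the counts divided by sqrt(n).  Scaling by the
standard error rather than the standard deviation inflates the scores by
sqrt(n); the default hot-bin threshold of 422 lives on this scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import ChromSizes, GenomePartition

__all__ = ["VISDataset", "BinProfile", "bin_counts", "zscores", "rate_profile"]


@dataclass
class VISDataset:
    """A named set of single-bp insertion coordinates.

    ``chrom_idx`` indexes into ``chrom_sizes``; records are kept sorted by
    (chromosome order, position).  Duplicate positions are permitted but
    counted in ``n_duplicates`` for QC.
    """

    name: str
    chrom_sizes: ChromSizes
    chrom_idx: np.ndarray
    positions: np.ndarray
    labels: np.ndarray | None = None  # optional per-record annotation

    def __post_init__(self) -> None:
        self.chrom_idx = np.asarray(self.chrom_idx, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.chrom_idx.shape != self.positions.shape:
            raise ValueError("chrom_idx and positions length mismatch")
        lengths = np.asarray(self.chrom_sizes.lengths)
        if len(self.positions):
            if self.chrom_idx.min() < 0 or self.chrom_idx.max() >= len(lengths):
                raise ValueError("chromosome index out of range")
            bad = (self.positions < 1) | (self.positions > lengths[self.chrom_idx])
            if bad.any():
                raise ValueError(
                    f"{bad.sum()} position(s) outside chromosome bounds"
                )
        order = np.lexsort((self.positions, self.chrom_idx))
        self.chrom_idx = self.chrom_idx[order]
        self.positions = self.positions[order]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)[order]
        if self.n_duplicates:
            warnings.warn(
                f"dataset {self.name!r}: {self.n_duplicates} duplicate "
                "position(s) retained (counted separately)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_duplicates(self) -> int:
        if len(self.positions) < 2:
            return 0
        same = (np.diff(self.positions) == 0) & (np.diff(self.chrom_idx) == 0)
        return int(same.sum())

    @classmethod
    def from_records(
        cls,
        name: str,
        chrom_sizes: ChromSizes,
        records,
        labels=None,
    ) -> "VISDataset":
        """Build from an iterable of (chromosome name, 1-based position)."""
        chroms, positions = [], []
        for chrom, pos in records:
            chroms.append(chrom_sizes.index_of(chrom))
            positions.append(int(pos))
        return cls(name, chrom_sizes, np.asarray(chroms, dtype=np.int64),
                   np.asarray(positions, dtype=np.int64), labels)

    def positions_on(self, chrom: str) -> np.ndarray:
        ci = self.chrom_sizes.index_of(chrom)
        return self.positions[self.chrom_idx == ci]


@dataclass
class BinProfile:
    """Per-bin counts with derived scores for one dataset on one partition."""

    partition: GenomePartition
    counts: np.ndarray
    dataset_name: str = ""
    mean: float | None = None
    se: float | None = None
    z: np.ndarray | None = field(default=None, repr=False)
    rates: np.ndarray | None = field(default=None, repr=False)
    posterior_means: np.ndarray | None = field(default=None, repr=False)
    change_probs: np.ndarray | None = field(default=None, repr=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def score(self, kind: str) -> np.ndarray:
        """Return one of the per-bin score vectors by name."""
        arr = {
            "zscore": self.z,
            "rate": self.rates,
            "posterior_mean": self.posterior_means,
        }.get(kind)
        if kind not in ("zscore", "rate", "posterior_mean"):
            raise ValueError(f"unknown score kind {kind!r}")
        if arr is None:
            raise ValueError(f"score {kind!r} not computed on this profile")
        return arr


def bin_counts(vis: VISDataset, partition: GenomePartition) -> BinProfile:
    """Tally the number of VIS per bin of ``partition``."""
    if vis.chrom_sizes.items != partition.chrom_sizes.items:
        raise ValueError("dataset and partition use different chromosome tables")
    if len(vis):
        idx = partition.bin_index(vis.chrom_idx, vis.positions)
        counts = np.bincount(idx, minlength=partition.n).astype(np.int64)
    else:
        counts = np.zeros(partition.n, dtype=np.int64)
    return BinProfile(partition=partition, counts=counts, dataset_name=vis.name)


def zscores(profile: BinProfile) -> BinProfile:
    """Standardize bin counts by the mean and standard error across bins.

    Raises a degenerate-input error when all counts are identical (the
    scale is then undefined).
    """
    c = profile.counts.astype(float)
    n = len(c)
    if n < 2:
        raise ValueError("need at least 2 bins to standardize")
    sd = c.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate input: all bin counts identical")
    profile.mean = float(c.mean())
    profile.se = float(sd / np.sqrt(n))
    profile.z = (c - profile.mean) / profile.se
    return profile


def rate_profile(profile: BinProfile) -> BinProfile:
    """Per-bin rates C_i / sum(C); the rates sum to one."""
    total = profile.total
    if total == 0:
        raise ValueError("empty dataset: rates undefined")
    profile.rates = profile.counts / total
    return profile
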