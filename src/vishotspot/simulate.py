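"""Synthetic VIS generation, subsampling and the size-invariance study.

The generator emulates repopulating-sample VIS data: a uniform genomic
background plus planted clusters of given width and intensity.  The
default "ALD-like" fixture reproduces the published full X-linked ALD
study conditions (2401 VIS, five hot-spots jointly holding ~6% of the
VIS, at the published hot-spot locations); the "acute-like" fixture
mirrors the acute-infection reference (922 VIS, three weak clusters) used
for threshold calibration.

The size-invariance study subsamples a source dataset without replacement
at sizes 200-2000, runs each detector on every subsample with a fixed
threshold, and Spearman-tests the median percentage of VIS in hot-spots
against dataset size: a detector is size-invariant when no significant
trend remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .binning import VISDataset, bin_counts, zscores
from .cis import DEFAULT_CIS_RULES, cis_scan
from .genome import ChromSizes, GenomePartition, hg18
from .zthreshold import ThresholdSpec, call_hotbins, refine_hotspots

__all__ = [
    "Cluster",
    "generate_synthetic_vis",
    "ald_like",
    "acute_like",
    "subsample_vis",
    "size_invariance_study",
    "DEFAULT_STUDY_SIZES",
]

#: Simulated dataset sizes used by the size-invariance study.
DEFAULT_STUDY_SIZES = (200, 300, 400, 500, 600, 800, 1000, 1200, 1400, 1600,
                       1800, 2000)


@dataclass(frozen=True)
class Cluster:
    """A planted cluster: ``n_vis`` positions uniform on a width around a
    center."""

    chrom: str
    center: int
    width: int
    n_vis: int

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.start + self.width

    def contains(self, pos: int) -> bool:
        return self.start < pos <= self.end


# Planted-cluster layouts copied from the published BCP hot-spot tables so
# the synthetic fixtures reproduce the real studies' conditions.
_ALD_CLUSTERS = (
    Cluster("chr6", 32_483_500, 1_033_000, 35),
    Cluster("chr11", 65_487_000, 2_964_000, 61),
    Cluster("chr12", 6_539_000, 908_000, 16),
    Cluster("chr17", 2_261_000, 522_000, 17),
    Cluster("chr17", 73_675_000, 1_154_000, 20),
)
_ACUTE_CLUSTERS = (
    Cluster("chr11", 65_370_500, 701_000, 12),
    Cluster("chr16", 1_177_000, 1_504_000, 7),
    Cluster("chr17", 77_651_000, 932_000, 8),
)


def generate_synthetic_vis(
    genome: ChromSizes,
    n_background: int,
    clusters=(),
    seed: int = 0,
    name: str = "synthetic",
) -> VISDataset:
    """Uniform background plus planted clusters; truth labels retained.

    Background positions are uniform over the concatenated genome
    (chromosomes weighted by length); each cluster contributes
    ``n_vis`` positions uniform on its interval.  The returned dataset's
    ``labels`` array holds "background" or "cluster<i>" per record.
    Overlapping clusters are permitted (a warning is emitted).
    """
    import warnings

    rng = np.random.default_rng(seed)
    lengths = np.asarray(genome.lengths, dtype=np.int64)
    chroms, positions, labels = [], [], []
    if n_background:
        ci = rng.choice(len(lengths), size=n_background,
                        p=lengths / lengths.sum())
        pos = rng.integers(1, lengths[ci] + 1)
        chroms.extend(ci.tolist())
        positions.extend(pos.tolist())
        labels.extend(["background"] * n_background)
    clusters = list(clusters)
    for i, cl in enumerate(clusters):
        idx = genome.index_of(cl.chrom)
        length = genome.length_of(cl.chrom)
        lo = max(cl.start + 1, 1)
        hi = min(cl.end, length)
        if hi < lo:
            raise ValueError(f"cluster {i} outside {cl.chrom} bounds")
        pos = rng.integers(lo, hi + 1, size=cl.n_vis)
        chroms.extend([idx] * cl.n_vis)
        positions.extend(pos.tolist())
        labels.extend([f"cluster{i}"] * cl.n_vis)
        for j, other in enumerate(clusters[:i]):
            if other.chrom == cl.chrom and cl.start < other.end \
                    and other.start < cl.end:
                warnings.warn(
                    f"clusters {j} and {i} overlap on {cl.chrom}",
                    stacklevel=2,
                )
    return VISDataset(
        name,
        genome,
        np.asarray(chroms, dtype=np.int64),
        np.asarray(positions, dtype=np.int64),
        labels=np.asarray(labels),
    )


def ald_like(seed: int = 0, genome: ChromSizes | None = None) -> VISDataset:
    """Synthetic stand-in for the full X-linked ALD repopulating dataset:
    2401 VIS with five planted hot-spots holding 149 VIS (6.2%)."""
    return generate_synthetic_vis(
        genome or hg18(), 2401 - 149, _ALD_CLUSTERS, seed=seed,
        name="synthetic-ALD",
    )


def acute_like(seed: int = 0, genome: ChromSizes | None = None) -> VISDataset:
    """Synthetic stand-in for the LV acute-infection reference: 922 VIS
    with three weak clusters (27 VIS)."""
    return generate_synthetic_vis(
        genome or hg18(), 922 - 27, _ACUTE_CLUSTERS, seed=seed,
        name="synthetic-acute",
    )


def subsample_vis(dataset: VISDataset, size: int, seed: int = 0) -> VISDataset:
    """Uniform sample of ``size`` records without replacement."""
    if size > len(dataset):
        raise ValueError(f"requested {size} of {len(dataset)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(dataset), size=size, replace=False)
    return VISDataset(
        f"{dataset.name}[{size}]",
        dataset.chrom_sizes,
        dataset.chrom_idx[idx],
        dataset.positions[idx],
        labels=dataset.labels[idx] if dataset.labels is not None else None,
    )


def _spawn_seed(master: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def _pct_in_hotspots(hotspots, n_total: int) -> float:
    return 100.0 * sum(hs.n_vis for hs in hotspots) / n_total


def size_invariance_study(
    dataset: VISDataset,
    partition: GenomePartition,
    threshold: ThresholdSpec,
    sizes=DEFAULT_STUDY_SIZES,
    replicates: int = 10,
    methods=("cis", "zthreshold", "bcp"),
    seed: int = 0,
    cis_rules=DEFAULT_CIS_RULES,
    bcp_config=None,
    apply_selection_rules: bool = True,
):
    """Subsample ``dataset`` and measure % VIS in hot-spots per detector.

    Returns (results DataFrame with one row per (method, size, replicate),
    dict of method -> (spearman rho, p) over per-size medians).  With
    ``apply_selection_rules`` (the default) BCP cells for sizes below its
    300-VIS lower bound are marked inapplicable (NaN); disabling it runs
    every method at every size, the design under which the published
    size-trend comparison of all four methods was made.  One master seed
    spawns an independent stream per (size, replicate), so the study is
    reproducible and parallelizable.
    """
    from .bcp import BCPConfig, bcp_fit, bcp_hotbins, select_method

    if replicates < 2:
        raise ValueError("need >= 2 replicates")
    sizes = sorted(int(s) for s in sizes)
    if sizes[-1] > len(dataset):
        raise ValueError("largest size exceeds the source dataset")
    bcp_config = bcp_config or BCPConfig(iterations=500)
    rows = []
    for size in sizes:
        for rep in range(replicates):
            sub = subsample_vis(dataset, size, _spawn_seed(seed, size, rep))
            profile = zscores(bin_counts(sub, partition))
            for method in methods:
                if method == "cis":
                    hs = cis_scan(sub, cis_rules)
                elif method == "zthreshold":
                    hot = call_hotbins(profile, threshold, score="zscore")
                    hs = refine_hotspots(hot, sub, partition)
                elif method == "bcp":
                    if apply_selection_rules:
                        try:
                            applicable = select_method(size) == "bcp"
                        except ValueError:
                            applicable = False
                    else:
                        applicable = True
                    if not applicable:
                        rows.append(
                            {"method": method, "size": size, "rep": rep,
                             "pct_vis_in_hotspots": np.nan}
                        )
                        continue
                    from dataclasses import replace

                    cfg = replace(
                        bcp_config, seed=_spawn_seed(seed, size, rep, 97)
                    )
                    res = bcp_fit(profile, cfg)
                    hot = bcp_hotbins(res, threshold)
                    hs = refine_hotspots(hot, sub, partition, method="bcp")
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append(
                    {"method": method, "size": size, "rep": rep,
                     "pct_vis_in_hotspots": _pct_in_hotspots(hs, size)}
                )
    results = pd.DataFrame(rows)
    tests = {}
    for method in methods:
        sub = results[results["method"] == method].dropna()
        med = sub.groupby("size")["pct_vis_in_hotspots"].median()
        if len(med) < 3 or med.nunique() == 1:
            tests[method] = (0.0, 1.0)
            continue
        rho, p = scipy.stats.spearmanr(med.index.to_numpy(), med.to_numpy())
        tests[method] = (float(rho), float(p))
    return results, tests
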