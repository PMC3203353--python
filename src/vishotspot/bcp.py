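"""Bayesian change-point (BCP) hot-spot detection.

Runs a Gibbs sampler for the Barry-Hartigan product-partition Gaussian
model over the strung-together genome's bin z-scores (chromosome
boundaries are deliberately not forced change-points, so genome-wide
density context is shared).  The posterior bin means are thresholded with
the same threshold used by the z-threshold method; the mean change
probability summarizes how clustered a dataset is (1 - Pbar > 0.98 flags
high clustering).

Method-selection rules for routing a dataset between BCP and z-threshold:
BCP needs >= 300 VIS and a not-highly-clustered signal; datasets in
(100, 300] fall back to z-threshold; datasets with <= 100 VIS are refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import betainc, betaln

from .binning import BinProfile
from .zthreshold import ThresholdSpec

__all__ = [
    "BCPConfig",
    "BCPResult",
    "bcp_fit",
    "bcp_hotbins",
    "check_convergence",
    "chromosome_boundary_changes",
    "select_method",
]


@dataclass(frozen=True)
class BCPConfig:
    """Sampler settings.

    iterations : sweeps kept for averaging (default 10000; at least 5000
        is recommended for stable calls near the threshold)
    burnin : initial sweeps discarded (default 50)
    p0 : upper bound of the uniform prior on the change probability
    w0 : upper bound of the uniform prior on the variance ratio
    """

    iterations: int = 10_000
    burnin: int = 50
    p0: float = 0.2
    w0: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        for nm in ("p0", "w0"):
            v = getattr(self, nm)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{nm} must lie in (0, 1]")


@dataclass
class BCPResult:
    posterior_means: np.ndarray = field(repr=False)
    change_probs: np.ndarray = field(repr=False)
    config: BCPConfig = field(default_factory=BCPConfig)

    @property
    def p_bar(self) -> float:
        """Mean posterior change probability across internal boundaries."""
        return float(self.change_probs.mean())

    @property
    def cluster_score(self) -> float:
        """1 - Pbar; values above 0.98 indicate a highly clustered dataset."""
        return 1.0 - self.p_bar


def _log_prior_table(n: int, p0: float) -> np.ndarray:
    """lbp[c] = log int_0^p0 p^c (1-p)^(n-1-c) dp for c = 0..n-1."""
    c = np.arange(n, dtype=float)
    a, b = c + 1.0, n - c
    with np.errstate(divide="ignore"):
        return betaln(a, b) + np.log(betainc(a, b, p0))


def bcp_fit(z, config: BCPConfig = BCPConfig()) -> BCPResult:
    """Fit the change-point model to a z-score vector or BinProfile.

    Identical (config, seed) pairs produce bit-identical results.  When a
    BinProfile is given, its ``posterior_means`` and ``change_probs``
    fields are filled in place as well.
    """
    from ._gibbs import gibbs_run

    profile = None
    if isinstance(z, BinProfile):
        profile = z
        if profile.z is None:
            raise ValueError("profile has no z-scores; run zscores() first")
        x = np.asarray(profile.z, dtype=float)
    else:
        x = np.asarray(z, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 bins for change-point analysis")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite z-scores")
    lbp = _log_prior_table(n, config.p0)
    mu, p = gibbs_run(
        x, config.w0, config.iterations, config.burnin, lbp, config.seed
    )
    result = BCPResult(posterior_means=mu, change_probs=p, config=config)
    if profile is not None:
        profile.posterior_means = mu
        profile.change_probs = p
    return result


def bcp_hotbins(result: BCPResult, threshold: ThresholdSpec) -> np.ndarray:
    """Bins whose posterior mean strictly exceeds the threshold."""
    return np.nonzero(result.posterior_means > threshold.value)[0]


@dataclass
class ConvergenceReport:
    seeds: list[int]
    mu_range: np.ndarray = field(repr=False)  # per-bin max-min across seeds
    mu_sd: np.ndarray = field(repr=False)  # per-bin SD across seeds
    inconsistent_hotbins: np.ndarray = field(repr=False)
    hotbin_mu_sd: float = 0.0  # max SD among bins ever called hot
    recommend_more_iterations: bool = False

    @property
    def consistent(self) -> bool:
        return len(self.inconsistent_hotbins) == 0


def check_convergence(
    z,
    config: BCPConfig = BCPConfig(),
    n_seeds: int = 5,
    threshold: ThresholdSpec | None = None,
) -> ConvergenceReport:
    """Assess sampler stability across differently-seeded runs.

    Flags bins whose hot-bin call flips between seeds and recommends
    >= 5000 iterations when the posterior-mean SD among hot bins exceeds
    0.007 (the stability level achievable at that run length).
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds")
    from .zthreshold import DEFAULT_Z_THRESHOLD

    thr = threshold or DEFAULT_Z_THRESHOLD
    seeds = [config.seed + k for k in range(n_seeds)]
    mus = np.vstack(
        [bcp_fit(z, replace(config, seed=s)).posterior_means for s in seeds]
    )
    calls = mus > thr.value
    ever_hot = calls.any(axis=0)
    inconsistent = np.nonzero(ever_hot & ~calls.all(axis=0))[0]
    mu_sd = mus.std(axis=0, ddof=1)
    hot_sd = float(mu_sd[ever_hot].max()) if ever_hot.any() else 0.0
    return ConvergenceReport(
        seeds=seeds,
        mu_range=mus.max(axis=0) - mus.min(axis=0),
        mu_sd=mu_sd,
        inconsistent_hotbins=inconsistent,
        hotbin_mu_sd=hot_sd,
        recommend_more_iterations=hot_sd > 0.007 and config.iterations < 5000,
    )


def chromosome_boundary_changes(
    result: BCPResult, partition, min_prob: float = 0.5
):
    """QC: change-points that sit exactly on a chromosome join.

    The model treats the strung-together genome as one sequence, so a
    density difference between the end of one chromosome and the start of
    the next legitimately registers as a change-point there; this helper
    lists the joins whose posterior change probability reaches
    ``min_prob`` so they can be reviewed rather than read as intra-
    chromosomal structure.  Returns a list of
    (boundary index, left chromosome, right chromosome, probability).
    """
    import numpy as np

    p = result.change_probs
    names = partition.chrom_sizes.names
    joins = np.nonzero(np.diff(partition.bin_chrom) != 0)[0]  # boundary i
    out = []
    for i in joins:
        prob = float(p[i])
        if prob >= min_prob:
            out.append(
                (
                    int(i),
                    names[int(partition.bin_chrom[i])],
                    names[int(partition.bin_chrom[i + 1])],
                    prob,
                )
            )
    return out


def select_method(n_vis: int, cluster_score: float | None = None) -> str:
    """Route a dataset to "bcp" or "zthreshold" by size and clustering.

    ``cluster_score`` is 1 - Pbar from a completed BCP run (may be None
    when no BCP run is available, in which case only the size rule
    applies).  Datasets with <= 100 VIS are refused.
    """
    if n_vis <= 100:
        raise ValueError(
            f"dataset too small for hot-spot analysis ({n_vis} VIS <= 100); "
            "collect more integration sites or interpret raw positions "
            "directly"
        )
    if n_vis < 300:
        return "zthreshold"
    if cluster_score is not None and cluster_score > 0.98:
        return "zthreshold"
    return "bcp"
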