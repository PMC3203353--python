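"""End-to-end driver: from a YAML/dict config to a results directory.

Mirrors the seven analysis steps of a full hot-spot study: load inputs
and parameters; call hot-bins/hot-spots per method (with the automatic
BCP vs z-threshold routing rules, logged with their justification); run
the conventional CIS analysis; annotate genes; test hot-bin conservation
between dataset pairs; compute feature statistics; and merge results from
shifted partitions.  Outputs are plain-text TSV/BED/JSON (plus optional
plots) and are a pure function of (inputs, config, seeds).

Config keys (all optional except ``datasets``)::

    genome: path to a chrom-sizes TSV (default: embedded hg18)
    datasets: {name: path} of VIS files, or prebuilt VISDataset objects
    bin_size: 1000000      shifts: [0]          seed: 0
    threshold: 422.0       percentile: null     calibrate_to: <dataset name>
    methods: [auto] | subset of [cis, zthreshold, bcp]
    cis_rules: ["3:50000", "4:100000"]
    bcp: {iterations: 10000, burnin: 50, p0: 0.2, w0: 0.2}
    tracks: {name: path}   cancer_genes: path   plots: false
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, replace

import numpy as np
import yaml

from . import __version__
from .bcp import BCPConfig, bcp_fit, bcp_hotbins, select_method
from .binning import VISDataset, bin_counts, rate_profile, zscores
from .cis import DEFAULT_CIS_RULES, CISRule, cis_scan
from .conservation import cluster_metrics, conservation_report
from .features import (
    compare_to_genome,
    feature_density,
    genes_in_hotspots,
    genome_density_profile,
)
from .genome import ChromSizes, hg18, partition_genome
from .io import read_track, read_vis, write_hotspots_bed, write_hotspots_stats
from .merge import merge_hotspots
from .zthreshold import (
    ThresholdSpec,
    call_hotbins,
    get_threshold,
    refine_hotspots,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("vishotspot")

_SIZE_RULE = (
    "datasets with more than 300 VIS use BCP; (100, 300] VIS fall back to "
    "the z-threshold method"
)
_CLUSTER_RULE = (
    "highly clustered datasets (1 - Pbar > 0.98) fall back to the "
    "z-threshold method"
)


def _load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, outdir: str) -> str:
    """Run the full analysis described by ``config`` into ``outdir``."""
    cfg = _load_config(config)
    if "datasets" not in cfg or not cfg["datasets"]:
        raise ValueError("config must name at least one dataset")
    os.makedirs(outdir, exist_ok=True)

    if cfg.get("genome"):
        genome = ChromSizes.from_file(cfg["genome"])
    else:
        prebuilt = [
            d for d in cfg["datasets"].values() if isinstance(d, VISDataset)
        ]
        genome = prebuilt[0].chrom_sizes if prebuilt else hg18()
    # fail early on missing inputs
    for key in ("datasets", "tracks"):
        for name, path in (cfg.get(key) or {}).items():
            if isinstance(path, (str, os.PathLike)) and not os.path.exists(path):
                raise FileNotFoundError(f"{key} entry {name!r}: {path}")

    bin_size = int(cfg.get("bin_size", 1_000_000))
    shifts = [int(s) for s in cfg.get("shifts", [0])]
    seed = int(cfg.get("seed", 0))
    methods = list(cfg.get("methods", ["auto"]))
    cis_rules = [CISRule.parse(r) for r in cfg.get("cis_rules", [])] or list(
        DEFAULT_CIS_RULES
    )
    bcp_cfg = BCPConfig(seed=seed, **(cfg.get("bcp") or {}))

    datasets: dict[str, VISDataset] = {}
    for name, src in cfg["datasets"].items():
        datasets[name] = (
            src if isinstance(src, VISDataset) else read_vis(src, genome, name)
        )

    partitions = {s: partition_genome(genome, bin_size, s) for s in shifts}
    base = partitions[shifts[0]]

    # threshold: fixed value, or calibrated from a named reference dataset
    if cfg.get("calibrate_to"):
        ref = datasets[cfg["calibrate_to"]]
        ref_profile = zscores(bin_counts(ref, base))
        threshold = get_threshold(
            ref_profile, float(cfg.get("percentile", 99.92))
        )
        log.info(
            "threshold calibrated to %.2f (%.4g percentile of %s)",
            threshold.value, threshold.percentile, ref.name,
        )
    else:
        threshold = ThresholdSpec(float(cfg.get("threshold", 422.0)))

    hotbin_sets: dict[str, np.ndarray] = {}
    hotbin_methods: dict[str, str] = {}
    metrics_rows = []
    all_hotspots: dict[str, list] = {}

    for name, vis in datasets.items():
        per_shift = {m: [] for m in ("cis", "zthreshold", "bcp")}
        bcp_res = None
        for k, (shift, part) in enumerate(partitions.items()):
            profile = rate_profile(zscores(bin_counts(vis, part)))
            run_bcp = any(m in ("bcp", "auto") for m in methods)
            if run_bcp and len(vis) > 100:
                res = bcp_fit(profile, replace(bcp_cfg, seed=seed + k))
                if shift == shifts[0]:
                    bcp_res = res
            else:
                res = None
            chosen = set(methods)
            if "auto" in chosen:
                chosen.discard("auto")
                picked = select_method(
                    len(vis), res.cluster_score if res else None
                )
                if picked == "zthreshold":
                    rule = (
                        _CLUSTER_RULE
                        if res is not None and res.cluster_score > 0.98
                        else _SIZE_RULE
                    )
                    log.info("%s: auto-selected %s (%s)", name, picked, rule)
                chosen.add(picked)
                chosen.add("cis")
            if "cis" in chosen:
                per_shift["cis"].append(cis_scan(vis, cis_rules))
            if "zthreshold" in chosen:
                hot = call_hotbins(profile, threshold, score="zscore")
                per_shift["zthreshold"].append(
                    refine_hotspots(hot, vis, part)
                )
                if shift == shifts[0]:
                    hotbin_sets.setdefault(name, hot)
                    hotbin_methods.setdefault(name, "zthreshold")
            if "bcp" in chosen and res is not None:
                hot = bcp_hotbins(res, threshold)
                per_shift["bcp"].append(
                    refine_hotspots(hot, vis, part, method="bcp")
                )
                if shift == shifts[0]:
                    hotbin_sets[name] = hot
                    hotbin_methods[name] = "bcp"

        profile0 = rate_profile(zscores(bin_counts(vis, base)))
        if bcp_res is not None:
            from .bcp import chromosome_boundary_changes

            for i, left, right, prob in chromosome_boundary_changes(
                bcp_res, base
            ):
                log.info(
                    "%s: change-point on the %s/%s join (boundary %d, "
                    "P=%.3f) — review before reading as intra-chromosomal "
                    "structure", name, left, right, i, prob,
                )
        cm = cluster_metrics(profile0, bcp_res)
        metrics_rows.append(
            {
                "dataset": name, "n_vis": len(vis),
                "max_percent": cm.max_percent,
                "bcp_score": cm.bcp_score,
                "clustered_by_max": cm.clustered_by_max,
                "clustered_by_bcp": cm.clustered_by_bcp,
            }
        )
        for method, sets in per_shift.items():
            sets = [s for s in sets if s is not None]
            if not sets:
                continue
            hs = (
                merge_hotspots(sets, vis, shifts=shifts[: len(sets)])
                if len(sets) > 1
                else sets[0]
            )
            all_hotspots[f"{name}.{method}"] = hs
            write_hotspots_bed(hs, os.path.join(outdir, f"{name}.{method}.bed"))
            write_hotspots_stats(
                hs, os.path.join(outdir, f"{name}.{method}.stats.tsv")
            )
        # per-bin profile dump for the base partition
        import pandas as pd

        pd.DataFrame(
            {
                "chrom": [genome.names[c] for c in base.bin_chrom],
                "start": base.bin_start,
                "end": base.bin_end,
                "count": profile0.counts,
                "z": profile0.z,
                "rate": profile0.rates,
                "posterior_mean": (
                    bcp_res.posterior_means if bcp_res is not None else np.nan
                ),
            }
        ).to_csv(os.path.join(outdir, f"{name}.bins.tsv"), sep="\t",
                 index=False)

    import pandas as pd

    pd.DataFrame(metrics_rows).to_csv(
        os.path.join(outdir, "cluster_metrics.tsv"), sep="\t", index=False
    )

    if len(hotbin_sets) >= 2:
        names = list(hotbin_sets)
        report = conservation_report(
            names,
            [hotbin_sets[n] for n in names],
            base.n,
            methods=[hotbin_methods[n] for n in names],
        )
        report.to_csv(
            os.path.join(outdir, "conservation.tsv"), sep="\t", index=False
        )

    if cfg.get("tracks"):
        rows = []
        for tname, path in cfg["tracks"].items():
            track = read_track(path, name=tname)
            gdens, gmed = genome_density_profile(track, base)
            for key, hs in all_hotspots.items():
                if not hs or key.endswith(".cis"):
                    continue
                dens = feature_density(hs, track)
                comp = compare_to_genome(dens, gdens, track_name=tname)
                rows.append(
                    {
                        "dataset_method": key, "track": tname,
                        "median_density": float(np.median(dens)),
                        "genome_median": comp.genome_median,
                        "wilcoxon_p": comp.wilcoxon_p,
                        "significant": comp.significant,
                    }
                )
        if rows:
            pd.DataFrame(rows).to_csv(
                os.path.join(outdir, "feature_analysis.tsv"), sep="\t",
                index=False,
            )

    if cfg.get("plots"):
        from .plotting import plot_results

        for name, vis in datasets.items():
            profile = zscores(bin_counts(vis, base))
            for method in ("bcp", "zthreshold", "cis"):
                hs = all_hotspots.get(f"{name}.{method}")
                if hs is not None:
                    break
            else:
                hs = []
            plot_results(
                [(vis, profile, hs)],
                style="genome_stripchart",
                out=os.path.join(outdir, f"{name}.genome.png"),
            )

    meta = {
        "version": __version__,
        "seed": seed,
        "bin_size": bin_size,
        "shifts": shifts,
        "threshold": asdict(threshold),
        "quantile_convention": "linear interpolation (numpy/R type 7)",
        "plot_color_quantiles": "occupied (>=1 VIS) bins, classes "
        "85/95/97.5/99, ties to lower class",
        "bcp": asdict(bcp_cfg),
        "datasets": {n: len(d) for n, d in datasets.items()},
    }
    with open(os.path.join(outdir, "run_metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return outdir
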