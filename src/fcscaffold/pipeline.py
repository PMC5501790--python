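"""End-to-end pipeline: cohort -> group matrix -> nulls -> percolation -> scaffold.

``run_pipeline`` executes every stage with reproducible seeds and writes all
artifacts (delimited-text tables, edge lists, GraphML graphs) plus a
machine-readable run report; ``report_summary`` condenses a finished run
directory into the headline quantities.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import correlation as corr
from . import nullmodel, percolation, spanning, synthetic, timeseries

logger = logging.getLogger("fcscaffold")

WEIGHT_MODES = ("r2", "r", "abs_r")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of ``manifest`` (path to a cohort manifest of time-series
    files) or ``synthetic_spec`` (a CohortSpec) must be given. Defaults:
    weights are squared correlations, 100 null randomizations, plateau
    selection at mean + 4 SD, FDR at q = 0.05.
    """

    output_dir: str | Path
    manifest: str | Path | None = None
    synthetic_spec: synthetic.CohortSpec | None = None
    weight_mode: str = "r2"
    n_null: int = 100
    k_sd: float = 4.0
    fdr_q: float = 0.05
    master_seed: int = 0
    max_snapshots: int = 6

    def __post_init__(self) -> None:
        if (self.manifest is None) == (self.synthetic_spec is None):
            raise ValueError("give exactly one of manifest / synthetic_spec")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
        if self.n_null < 2:
            raise ValueError("need n_null >= 2")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.n_null < 10:
            warnings.warn(
                f"n_null={self.n_null}: plateau-selection SD is unstable below 10 nulls",
                stacklevel=2,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        spec = None
        if "synthetic" in raw:
            syn = raw.pop("synthetic")
            mods = [
                synthetic.ModuleSpec(m["name"], m["members"], m.get("topology", "chain"))
                for m in syn.pop("modules")
            ]
            spec = synthetic.CohortSpec(modules=mods, **syn)
        return cls(synthetic_spec=spec, **raw)


def _spectrum_hash(r: np.ndarray) -> str:
    lam = np.sort(np.linalg.eigvalsh(r))
    return hashlib.sha256(np.round(lam, 8).tobytes()).hexdigest()[:16]


def _edge_table(edges, labels, path: Path, header: str) -> None:
    lines = [header]
    for e in edges:
        a, b, w = e[0], e[1], e[2]
        extra = list(e[3:])
        lines.append("\t".join([labels[a], labels[b], f"{w:.10g}"] + [str(x) for x in extra]))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts under ``config.output_dir``.

    Stage order: correlate -> variability -> null ensemble -> percolation
    (real and every null) -> threshold selection -> snapshots -> MSF -> MST
    -> degree profiles. Returns the run report (also written as
    ``report.json``). Deterministic given the config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        "weight_mode": config.weight_mode, "n_null": config.n_null,
        "k_sd": config.k_sd, "fdr_q": config.fdr_q,
        "master_seed": config.master_seed,
    }}
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("load")
    if config.synthetic_spec is not None:
        cohort = synthetic.generate_cohort(config.synthetic_spec)
        timeseries.write_manifest(cohort, out / "cohort")
    else:
        cohort = timeseries.read_manifest(config.manifest)
    done("load")

    stage("correlate")
    stack = corr.CorrelationStack.from_cohort(cohort)
    group = corr.fisher_average(stack)
    labels = list(group.roi_labels)
    timeseries.write_matrix(group.r, out / "group_r.tsv", labels)
    timeseries.write_matrix(group.w, out / "group_w.tsv", labels)
    done("correlate")

    stage("variability")
    maps = corr.variability_maps(stack, fdr_q=config.fdr_q)
    timeseries.write_matrix(maps.mean, out / "variability_mean.tsv", labels)
    timeseries.write_matrix(maps.sd, out / "variability_sd.tsv", labels)
    timeseries.write_matrix(np.nan_to_num(maps.cv, nan=-1.0), out / "variability_cv.tsv", labels)
    iu = np.triu_indices(group.n_rois, k=1)
    report["variability"] = {
        "sd_range": [float(maps.sd[iu].min()), float(maps.sd[iu].max())],
        "edges_retained_by_fdr": int(maps.retained[iu].sum()),
    }
    done("variability")

    stage("nulls")
    ensemble = nullmodel.ensemble_generate(group, n=config.n_null, master_seed=config.master_seed)
    report["spectrum_hash"] = _spectrum_hash(group.r)
    done("nulls")

    stage("percolate")
    w = group.weights(config.weight_mode)
    real_curve = percolation.percolate(w)
    real_plateaus = percolation.plateau_lengths(real_curve)
    null_w = ensemble.squared() if config.weight_mode == "r2" else [
        np.abs(m) if config.weight_mode == "abs_r" else m.copy() for m in ensemble.matrices
    ]
    null_plateaus = []
    for nw in null_w:
        np.fill_diagonal(nw, 0.0)
        null_plateaus.append(percolation.plateau_lengths(percolation.percolate(nw)))
    curve_lines = ["weight_removed\tn_components"]
    curve_lines += [
        f"{wt:.10g}\t{c}"
        for wt, c in zip(real_curve.weights_removed, real_curve.n_components)
    ]
    (out / "percolation_curve.tsv").write_text("\n".join(curve_lines) + "\n")
    pl_lines = ["start\tend\tlength\tn_components"]
    pl_lines += [
        f"{s:.10g}\t{e:.10g}\t{l:.10g}\t{c}"
        for s, e, l, c in zip(
            real_plateaus.starts, real_plateaus.ends, real_plateaus.lengths,
            real_plateaus.counts,
        )
    ]
    (out / "plateaus.tsv").write_text("\n".join(pl_lines) + "\n")
    done("percolate")

    stage("thresholds")
    thresholds = percolation.select_thresholds(real_plateaus, null_plateaus, k_sd=config.k_sd)
    pooled_mask = percolation.significant_plateaus(
        real_plateaus, null_plateaus, k_sd=config.k_sd, method="pooled"
    )
    mu, sigma, per_curve = percolation.null_plateau_stats(null_plateaus)
    thr_lines = ["threshold_w\tthreshold_r"]
    thr_lines += [f"{t:.10g}\t{np.sqrt(t):.10g}" for t in thresholds]
    (out / "thresholds.tsv").write_text("\n".join(thr_lines) + "\n")
    report["percolation"] = {
        "n_plateaus": int(len(real_plateaus.lengths)),
        "max_real_plateau": float(real_plateaus.lengths.max()) if len(real_plateaus.lengths) else 0.0,
        "max_null_plateau": float(max((p.lengths.max() for p in null_plateaus if p.lengths.size), default=0.0)),
        "null_mu": mu,
        "null_sigma": sigma,
        "null_mean_plateau_per_curve": float(np.nanmean(per_curve)),
        "sd_bands": {f"mu_plus_{k}sd": mu + k * sigma for k in (1, 2, 3, 4)},
        "n_thresholds_pooled": int(pooled_mask.sum()),
        "n_thresholds": int(len(thresholds)),
        "thresholds_w": [float(t) for t in thresholds],
        "thresholds_r": [float(np.sqrt(t)) for t in thresholds],
    }
    done("thresholds")

    stage("snapshots")
    snap_dir = out / "snapshots"
    snap_dir.mkdir(exist_ok=True)
    for k, t in enumerate(thresholds[: config.max_snapshots]):
        g = percolation.snapshot_graph(w, float(t), labels)
        nx.write_graphml(g, snap_dir / f"snapshot_{k:02d}.graphml")
        _edge_table(
            [(a, b, d["weight"]) for a, b, d in g.edges(data=True)],
            labels, snap_dir / f"snapshot_{k:02d}_edges.tsv", "source\ttarget\tweight",
        )
    done("snapshots")

    stage("msf")
    forest = spanning.msf_rowmax(w)
    recip = forest.reciprocated_pairs
    _edge_table(
        [(s, t, wt, frozenset((s, t)) in recip) for s, t, wt in forest.arcs],
        labels, out / "msf_arcs.tsv", "source\ttarget\tweight\treciprocated",
    )
    spanning.component_summary(forest, labels).to_csv(out / "msf_components.tsv", sep="\t", index=False)
    msf_profile = spanning.degree_profiles(forest)
    null_forests = [spanning.msf_rowmax(nw) for nw in null_w]
    null_max_indeg = [int(spanning.degree_profiles(f).max_degree) for f in null_forests]
    report["msf"] = {
        "n_components": len(forest.components),
        "component_sizes": sorted((len(c) for c in forest.components), reverse=True),
        "n_reciprocated_pairs": len(recip),
        "in_degree_histogram": msf_profile.counts,
        "max_in_degree": msf_profile.max_degree,
        "chain_score": msf_profile.chain_score,
        "null_max_in_degree_mean": float(np.mean(null_max_indeg)),
        "null_n_components_range": [
            min(len(f.components) for f in null_forests),
            max(len(f.components) for f in null_forests),
        ],
    }
    done("msf")

    stage("mst")
    tree = spanning.mst_complete(forest, w)
    _edge_table(tree.edges, labels, out / "mst_edges.tsv", "source\ttarget\tweight")
    gt = tree.graph()
    for i, lab in enumerate(labels):
        gt.nodes[i]["label"] = lab
    nx.write_graphml(gt, out / "mst.graphml")
    tree_profile = spanning.degree_profiles(tree)
    deg = tree.degrees()
    hubs = np.argsort(-deg)[:5]
    report["mst"] = {
        "total_weight": tree.total_weight,
        "degree_histogram": tree_profile.counts,
        "max_degree": tree_profile.max_degree,
        "chain_score": tree_profile.chain_score,
        "hubs_top5": [[labels[i], int(deg[i])] for i in hubs],
    }
    done("mst")

    report["timings_s"] = timings
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", out / "report.json")
    return report


REQUIRED_ARTIFACTS = [
    "group_r.tsv", "group_w.tsv", "percolation_curve.tsv", "plateaus.tsv",
    "thresholds.tsv", "msf_arcs.tsv", "msf_components.tsv", "mst_edges.tsv",
    "report.json",
]


def report_summary(run_dir: str | Path) -> dict:
    """Condense a completed run directory into the headline quantities.

    Raises ``FileNotFoundError`` listing every missing artifact if the run is
    incomplete.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory {run_dir}: missing {missing}")
    report = json.loads((run_dir / "report.json").read_text())
    summary = {
        "msf_n_components": report["msf"]["n_components"],
        "msf_component_sizes": report["msf"]["component_sizes"],
        "msf_reciprocated_pairs": report["msf"]["n_reciprocated_pairs"],
        "msf_max_in_degree": report["msf"]["max_in_degree"],
        "null_msf_max_in_degree_mean": report["msf"]["null_max_in_degree_mean"],
        "n_selected_thresholds": report["percolation"]["n_thresholds"],
        "thresholds_w": report["percolation"]["thresholds_w"],
        "thresholds_r": report["percolation"]["thresholds_r"],
        "min_threshold_r": min(report["percolation"]["thresholds_r"], default=None),
        "max_real_plateau": report["percolation"]["max_real_plateau"],
        "max_null_plateau": report["percolation"]["max_null_plateau"],
        "mst_total_weight": report["mst"]["total_weight"],
        "mst_hubs_top5": report["mst"]["hubs_top5"],
        "mst_degree_histogram": report["mst"]["degree_histogram"],
        "sd_range": report["variability"]["sd_range"],
    }
    return summary
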