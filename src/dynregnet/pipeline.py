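"""End-to-end orchestration: simulate -> preprocess -> NCA -> sub-networks
-> topology -> motifs, with one config, one global seed, and TSV/SIF
artifacts for every stage.

Stage seeds are derived deterministically from the global seed and the
stage name, so each stage is independently reproducible and a rerun with
the same config produces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import nca, preprocess, simulate, subnetworks, topology
from .datatypes import ExpressionMatrix, RegulatoryNetwork
from .motifs import motif_significance
from .subnetworks import RANGE_LABELS

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2b(
        f"{global_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs for a full run; round-trips through YAML unchanged."""

    expression_path: str | None = None
    network_path: str | None = None
    output_dir: str = "results/pipeline"
    # synthetic study (used when no input paths are given)
    n_tfs: int = 10
    n_tgs: int = 150
    targets_per_tf: int = 8
    tf_tf_edges: int = 10
    n_replicates: int = 2
    noise_sd: float = 0.1
    timepoints: list[float] = field(
        default_factory=lambda: list(simulate.DEFAULT_TIMEPOINTS)
    )
    # preprocessing
    quantile: bool = True
    alpha: float = 0.05
    min_sig_timepoints: int = 3
    fourier_harmonics: int = 3
    period_factor: float = 2.0
    baseline_index: int = 0
    # NCA
    nca_tol: float = 1e-6
    nca_max_iter: int = 500
    nca_restarts: int = 5
    # sub-networks
    range_boundaries: list[float] = field(default_factory=lambda: [1.0, 3.0, 8.0])
    amplitude_threshold: float = 1.0
    # topology / motifs
    ensemble_reps: int = 100
    motif_sizes: list[int] = field(default_factory=lambda: [3, 4])
    motif_n_random: int = 100
    switches_per_edge: int = 3
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def param_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    Inputs are simulated when no expression/network paths are configured.
    Each stage writes its artifacts under ``output_dir``; failures raise
    with the stage name attached, leaving earlier outputs in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "stages": {},
        "outputs": [],
    }

    def record(path: Path) -> str:
        rel = str(path.relative_to(out))
        manifest["outputs"].append(rel)
        return rel

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = "ok"
        return result

    # ------------------------------------------------------------- simulate
    def _simulate():
        if config.expression_path and config.network_path:
            expr = dio.read_replicated_expression(config.expression_path)
            network = dio.read_network(config.network_path)
            return expr, network, None
        truth = simulate.make_ground_truth(
            n_tfs=config.n_tfs,
            n_tgs=config.n_tgs,
            targets_per_tf=config.targets_per_tf,
            tf_tf_edges=config.tf_tf_edges,
            timepoints=config.timepoints,
            range_boundaries=tuple(config.range_boundaries),
            noise_sd=config.noise_sd,
            seed=stage_seed(config.seed, "simulate"),
        )
        expr = simulate.generate_expression(truth, config.n_replicates)
        dio.write_replicated_expression(expr, out / "expression.tsv")
        dio.write_network(truth.network, out / "network.sif")
        record(out / "expression.tsv")
        record(out / "network.sif")
        return expr, truth.network, truth

    expr, network, truth = run_stage("simulate", _simulate)
    logger.info(
        "inputs: %d genes, %d time points, %d replicates; network %d TFs / %d TGs / %d edges",
        len(expr.gene_ids), len(expr.timepoints), expr.n_replicates,
        len(network.tfs), len(network.tgs), network.n_edges,
    )

    # ----------------------------------------------------------- preprocess
    def _preprocess():
        values = expr.values
        if config.quantile:
            norm = np.empty_like(values)
            for r in range(values.shape[2]):
                mat = ExpressionMatrix(values[:, :, r], expr.gene_ids, expr.timepoints)
                norm[:, :, r] = preprocess.quantile_normalize(mat).values
            normalized = expr.__class__(
                norm, list(expr.gene_ids), expr.timepoints, list(expr.replicate_labels)
            )
        else:
            normalized = expr
        degs = preprocess.select_degs(
            normalized,
            baseline_index=config.baseline_index,
            alpha=config.alpha,
            min_sig_timepoints=config.min_sig_timepoints,
        )
        averaged = preprocess.average_replicates(normalized)
        smoothed = preprocess.smooth_matrix(
            averaged, config.fourier_harmonics, config.period_factor
        )
        (out / "degs.txt").write_text("".join(f"{g}\n" for g in sorted(degs)))
        record(out / "degs.txt")
        dio.write_matrix(smoothed, out / "expression_smoothed.tsv")
        record(out / "expression_smoothed.tsv")
        return degs, smoothed

    degs, smoothed = run_stage("preprocess", _preprocess)
    logger.info("selected %d differentially expressed genes", len(degs))

    # ------------------------------------------------------------------ NCA
    def _nca():
        tg_degs = sorted(degs & set(network.tgs))
        if not tg_degs:
            raise ValueError("no differentially expressed target genes")
        pattern = nca.build_connectivity(network, tg_degs, network.tfs)
        pattern = nca.reduce_to_compliant(
            pattern, len(expr.timepoints), seed=stage_seed(config.seed, "nca")
        )
        E = smoothed.subset(pattern.gene_ids)
        fit = nca.fit_nca_restarts(
            E,
            pattern,
            n_restarts=config.nca_restarts,
            max_iter=config.nca_max_iter,
            tol=config.nca_tol,
            seed=stage_seed(config.seed, "nca"),
        )
        fit = nca.normalize_fit(fit)
        activities = pd.DataFrame(
            fit.T,
            index=pd.Index(pattern.tf_ids, name="tf"),
            columns=[f"time_{t:g}" for t in expr.timepoints],
        )
        dio.write_table(activities, out / "tf_activities.tsv")
        record(out / "tf_activities.tsv")
        triplets = [
            (pattern.gene_ids[i], pattern.tf_ids[j], fit.C[i, j])
            for i, j in zip(*np.nonzero(pattern.Z0))
        ]
        dio.write_table(
            pd.DataFrame(triplets, columns=["gene", "tf", "strength"]),
            out / "control_strengths.tsv",
            index=False,
        )
        record(out / "control_strengths.tsv")
        return fit

    fit = run_stage("nca", _nca)

    # --------------------------------------------------------- sub-networks
    def _subnets():
        ranges = subnetworks.default_ranges(
            float(expr.timepoints[-1]), tuple(config.range_boundaries)
        )
        deg_list = sorted(degs & set(network.tgs))
        tg_profiles = smoothed.subset(deg_list).values
        tg_bins = subnetworks.select_active(
            tg_profiles, deg_list, expr.timepoints, ranges,
            config.amplitude_threshold, config.baseline_index,
        )
        tf_bins = subnetworks.select_active(
            fit.T, fit.pattern.tf_ids, expr.timepoints, ranges,
            config.amplitude_threshold, config.baseline_index,
        )
        subnets = {}
        attr_rows = []
        for r in ranges:
            sub = subnetworks.extract_subnetwork(
                network, tf_bins[r.label], tg_bins[r.label], r
            )
            subnets[r.label] = sub
            net_out = RegulatoryNetwork()
            net_out.graph = sub.graph
            dio.write_network(net_out, out / f"subnetwork_{r.label}.sif")
            record(out / f"subnetwork_{r.label}.sif")
            for node in sorted(sub.graph.nodes):
                attr_rows.append(
                    {"node": node, "role": network.role(node), "range": r.label}
                )
        dio.write_table(
            pd.DataFrame(attr_rows), out / "subnetwork_nodes.tsv", index=False
        )
        record(out / "subnetwork_nodes.tsv")
        return subnets

    subnets = run_stage("subnetworks", _subnets)

    # ------------------------------------------------------------- topology
    def _topology():
        rows = []
        static_report = topology.summarize(network.graph)
        rows.append({"network": "static", **static_report.network})
        for label in RANGE_LABELS:
            sub = subnets[label]
            rows.append({"network": label, **topology.summarize(sub.graph).network})
            n_tfs = len(sub.active_tfs & set(sub.graph.nodes))
            n_tgs = len(sub.active_tgs & set(sub.graph.nodes))
            if min(n_tfs, n_tgs) == 0:
                continue
            stats = topology.random_subnetwork_ensemble(
                network, n_tfs, n_tgs, config.ensemble_reps,
                seed=stage_seed(config.seed, f"topology:{label}"),
            )
            rows.append({"network": f"{label}_random_mean", **stats.mean})
            rows.append({"network": f"{label}_random_sd", **stats.sd})
        table = pd.DataFrame(rows).set_index("network")
        dio.write_table(table, out / "topology.tsv")
        record(out / "topology.tsv")
        return table

    run_stage("topology", _topology)

    # --------------------------------------------------------------- motifs
    def _motifs():
        n_tables = 0
        for label in RANGE_LABELS:
            graph = subnets[label].graph
            for k in config.motif_sizes:
                if graph.number_of_nodes() < k or graph.number_of_edges() < 2:
                    continue
                results = motif_significance(
                    graph, k,
                    n_random=config.motif_n_random,
                    switches_per_edge=config.switches_per_edge,
                    seed=stage_seed(config.seed, f"motifs:{label}:{k}"),
                )
                frame = pd.DataFrame(
                    [
                        {
                            "canonical_label": r.canonical_label,
                            "count": r.count_original,
                            "mean_random": r.mean_random,
                            "sd_random": r.sd_random,
                            "z_score": r.z_score,
                            "p_empirical": r.p_empirical,
                            "significant": r.significant,
                        }
                        for r in results
                    ]
                )
                dio.write_table(frame, out / f"motifs_{label}_k{k}.tsv", index=False)
                record(out / f"motifs_{label}_k{k}.tsv")
                n_tables += 1
        return n_tables

    run_stage("motifs", _motifs)

    config.to_yaml(out / "config.yaml")
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
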