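"""Self-contained validation experiments at the study's design point.

Each function builds its own synthetic inputs (network sizes, sampling
grid, noise level and replicate count follow the package defaults: 11 time
points over 14 h, two replicates), runs the relevant pipeline stage, and
returns the measured quantities.  They back the analysis drivers and the
reproducibility script.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .datatypes import ExpressionMatrix, ReplicatedExpression
from .motifs import FFL_LABEL, motif_significance
from .nca import align_to_truth, build_connectivity, fit_nca_restarts, normalize_fit
from .preprocess import average_replicates, deg_pvalues, select_degs
from .simulate import generate_expression, generate_static_network, make_ground_truth


def nca_recovery_experiment(
    n_tfs: int = 10,
    n_tgs: int = 150,
    targets_per_tf: int = 8,
    noise_frac: float = 0.05,
    n_replicates: int = 2,
    n_restarts: int = 5,
    seed: int = 11,
) -> dict:
    """Recover planted TF activities from noisy synthetic expression.

    The noise SD is ``noise_frac`` times the SD of the noiseless signal
    C.T.  Returns per-TF absolute Pearson correlations between recovered
    and true activities plus the relative residual of a noiseless fit.
    """
    truth = make_ground_truth(
        n_tfs=n_tfs, n_tgs=n_tgs, targets_per_tf=targets_per_tf,
        tf_tf_edges=n_tfs, noise_sd=0.0, seed=seed,
    )
    clean = truth.C_true @ truth.T_true
    truth.noise_sd = noise_frac * float(clean.std())
    expr = generate_expression(truth, n_replicates)
    E = average_replicates(expr)
    pattern = build_connectivity(truth.network, truth.gene_ids, truth.tf_ids)
    fit = normalize_fit(
        fit_nca_restarts(E.subset(pattern.gene_ids), pattern,
                         n_restarts=n_restarts, seed=seed)
    )
    order = [truth.tf_ids.index(tf) for tf in pattern.tf_ids]
    correlations = align_to_truth(fit.T, truth.T_true[order])

    clean_E = ExpressionMatrix(clean, truth.gene_ids, truth.timepoints)
    clean_fit = fit_nca_restarts(
        clean_E.subset(pattern.gene_ids), pattern, n_restarts=n_restarts, seed=seed
    )
    rel_obj = clean_fit.objective / np.linalg.norm(
        clean_E.subset(pattern.gene_ids).values, "fro"
    ) ** 2
    return {
        "correlations": correlations,
        "mean_abs_corr": float(correlations.mean()),
        "noiseless_relative_objective": float(rel_obj),
        "n_tfs_fit": pattern.n_tfs,
    }


def deg_calibration_experiment(
    n_genes: int = 2000,
    n_timepoints: int = 11,
    n_replicates: int = 3,
    alpha: float = 0.05,
    shift_sd: float = 10.0,
    n_shifted_timepoints: int = 4,
    n_planted: int = 100,
    seed: int = 21,
) -> dict:
    """False-positive rate under the null and power for planted shifts.

    Null genes are pure Gaussian noise; planted genes get a +shift_sd * SD
    mean shift at ``n_shifted_timepoints`` time points, which the per-time-
    point baseline t-test should detect essentially always.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 14.0, n_timepoints)
    null_values = rng.normal(size=(n_genes, n_timepoints, n_replicates))
    null = ReplicatedExpression(
        null_values, [f"g{i}" for i in range(n_genes)], t
    )
    fpr = float((deg_pvalues(null) < alpha).mean())

    planted_values = rng.normal(size=(n_planted, n_timepoints, n_replicates))
    planted_values[:, 3 : 3 + n_shifted_timepoints, :] += shift_sd
    planted = ReplicatedExpression(
        planted_values, [f"p{i}" for i in range(n_planted)], t
    )
    detected = select_degs(planted, alpha=alpha, min_sig_timepoints=3)
    return {
        "false_positive_rate": fpr,
        "power": len(detected) / n_planted,
        "n_tests": n_genes * (n_timepoints - 1),
    }


def planted_ffl_network(
    n_tfs: int = 30,
    n_tgs: int = 170,
    targets_per_tf: int = 4,
    tf_tf_edges: int = 30,
    n_ffls: int = 30,
    seed: int = 31,
) -> nx.DiGraph:
    """Bipartite + TF-TF scaffold with feed-forward loops planted on top."""
    net = generate_static_network(n_tfs, n_tgs, targets_per_tf, tf_tf_edges, seed=seed)
    graph = net.graph.copy()
    tfs, tgs = net.tfs, net.tgs
    rng = np.random.default_rng(seed + 1)
    planted = 0
    while planted < n_ffls:
        a, b = (tfs[i] for i in rng.choice(len(tfs), 2, replace=False))
        c = tgs[int(rng.integers(len(tgs)))]
        if graph.has_edge(a, b) and graph.has_edge(a, c) and graph.has_edge(b, c):
            continue
        graph.add_edge(a, b, kind="interacts")
        graph.add_edge(a, c, kind="regulates")
        graph.add_edge(b, c, kind="regulates")
        planted += 1
    return graph


def planted_ffl_experiment(
    n_ffls: int = 30, n_random: int = 100, seed: int = 31
) -> dict:
    """Feed-forward-loop enrichment against the degree-preserving null."""
    graph = planted_ffl_network(n_ffls=n_ffls, seed=seed)
    results = motif_significance(graph, k=3, n_random=n_random, seed=seed + 2)
    ffl = next(r for r in results if r.canonical_label == FFL_LABEL)
    return {
        "ffl_count": ffl.count_original,
        "ffl_z": ffl.z_score,
        "ffl_p": ffl.p_empirical,
        "n_nodes": graph.number_of_nodes(),
    }


def motif_null_calibration(
    n_repetitions: int = 20,
    n_nodes: int = 25,
    edge_prob: float = 0.15,
    n_random: int = 50,
    alpha: float = 0.05,
    seed: int = 41,
) -> dict:
    """Significance rate of an unstructured random digraph vs its own null.

    A graph with no planted structure should rarely beat its degree-matched
    randomizations, so the fraction of (repetition, class) pairs flagged at
    alpha stays near the nominal level.
    """
    rng = np.random.default_rng(seed)
    flagged = total = 0
    for _ in range(n_repetitions):
        g = nx.gnp_random_graph(
            n_nodes, edge_prob, seed=int(rng.integers(2**31)), directed=True
        )
        results = motif_significance(
            g, k=3, n_random=n_random, seed=int(rng.integers(2**31)), alpha=alpha
        )
        flagged += sum(r.significant for r in results)
        total += len(results)
    return {"significant_fraction": flagged / total, "n_class_tests": total}
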