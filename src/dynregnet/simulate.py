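"""Synthetic ground-truth generator for the full analysis pipeline.

Emulates a stimulus-response experiment: a sparse bipartite TF->TG network
with TF-TF interactions, impulse-shaped (Gaussian-bump) TF activity
profiles whose peaks are spread over four post-stimulus time ranges, signed
control strengths, and replicated noisy expression E_r = C.T + eps_r.

The defaults mirror the study design the pipeline targets: 11 sampling
times over 14 h and two replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import RegulatoryNetwork, ReplicatedExpression

#: Default sampling grid, hours. Dense early sampling, sparse late —
#: the usual design for impulse-like transcriptional responses.
DEFAULT_TIMEPOINTS = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 10.0, 14.0)

#: Boundaries (hours) splitting (0, t_max] into the four activity ranges
#: immediate-early, mid-early, mid-late, very-late.
DEFAULT_RANGE_BOUNDARIES = (1.0, 3.0, 8.0)


@dataclass
class GroundTruth:
    """Everything downstream stages are asked to recover.

    ``C_true`` is N x L with support exactly the TF->TG edge set;
    ``T_true`` is L x M TF activities on ``timepoints``.
    """

    network: RegulatoryNetwork
    C_true: np.ndarray
    T_true: np.ndarray
    timepoints: np.ndarray
    noise_sd: float
    seed: int

    @property
    def tf_ids(self) -> list[str]:
        return self.network.tfs

    @property
    def gene_ids(self) -> list[str]:
        return self.network.tgs


def generate_static_network(
    n_tfs: int,
    n_tgs: int,
    targets_per_tf: int,
    tf_tf_edges: int = 0,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Random sparse bipartite regulatory scaffold plus TF-TF edges.

    Every TF regulates exactly ``targets_per_tf`` distinct TGs; no two TFs
    share an identical target set (distinct sets are what make the
    connectivity pattern identifiable for activity reconstruction).
    """
    if n_tfs < 1:
        raise ValueError("need at least one TF")
    if targets_per_tf > n_tgs:
        raise ValueError("targets_per_tf cannot exceed n_tgs")
    if math.comb(n_tgs, targets_per_tf) < n_tfs:
        raise ValueError(
            "cannot give every TF a distinct target set: "
            f"C({n_tgs},{targets_per_tf}) < {n_tfs}"
        )
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    tg_ids = [f"G{i + 1:04d}" for i in range(n_tgs)]

    net = RegulatoryNetwork()
    seen: set[frozenset[int]] = set()
    for tf in tf_ids:
        while True:
            targets = frozenset(rng.choice(n_tgs, size=targets_per_tf, replace=False))
            if targets not in seen:
                seen.add(targets)
                break
        for idx in sorted(targets):
            net.add_regulation(tf, tg_ids[idx])
    # TGs no TF happened to pick stay in the network as isolated targets
    for tg in tg_ids:
        if tg not in net.graph:
            net._add_node(tg, "TG")

    if tf_tf_edges:
        if n_tfs < 2:
            raise ValueError("TF-TF edges require at least two TFs")
        pairs: set[tuple[int, int]] = set()
        while len(pairs) < tf_tf_edges:
            a, b = rng.integers(n_tfs), rng.integers(n_tfs)
            if a != b:
                pairs.add((int(a), int(b)))
        for a, b in sorted(pairs):
            net.add_interaction(tf_ids[a], tf_ids[b])
    return net


def generate_tf_activities(
    n_tfs: int,
    timepoints,
    range_boundaries=DEFAULT_RANGE_BOUNDARIES,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian-bump activity profiles a*exp(-(t-t_peak)^2 / (2 w^2)).

    Peak times are dealt round-robin across the four ranges delimited by
    ``range_boundaries`` within (t_min, t_max], so all ranges are occupied
    whenever n_tfs >= 4; amplitudes are uniform in [1, 3].
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if n_tfs < 4:
        warnings.warn("fewer than 4 TFs: some time ranges will be unoccupied")
    b1, b2, b3 = range_boundaries
    edges = [(t[0], b1), (b1, b2), (b2, b3), (b3, t[-1])]
    rng = np.random.default_rng(seed)
    profiles = np.empty((n_tfs, len(t)))
    for i in range(n_tfs):
        lo, hi = edges[i % 4]
        # keep the peak strictly inside the range so argmax binning is clean
        t_peak = rng.uniform(lo + 0.15 * (hi - lo), hi - 0.05 * (hi - lo))
        width = rng.uniform(0.25, 0.6) * (hi - lo)
        amp = rng.uniform(1.0, 3.0)
        profiles[i] = amp * np.exp(-((t - t_peak) ** 2) / (2.0 * width**2))
    return profiles


def generate_control_strengths(
    network: RegulatoryNetwork, seed: int = 0
) -> np.ndarray:
    """Signed control-strength matrix on the TF->TG edge support.

    Magnitudes uniform in [0.5, 2] with random sign so both activation and
    repression occur.
    """
    rng = np.random.default_rng(seed)
    tfs, tgs = network.tfs, network.tgs
    tf_index = {tf: j for j, tf in enumerate(tfs)}
    tg_index = {tg: i for i, tg in enumerate(tgs)}
    C = np.zeros((len(tgs), len(tfs)))
    for tf, tg in network.regulation_edges():
        C[tg_index[tg], tf_index[tf]] = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
    return C


def make_ground_truth(
    n_tfs: int = 10,
    n_tgs: int = 150,
    targets_per_tf: int = 8,
    tf_tf_edges: int = 10,
    timepoints=DEFAULT_TIMEPOINTS,
    range_boundaries=DEFAULT_RANGE_BOUNDARIES,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> GroundTruth:
    """Assemble a complete synthetic study (network, C, T)."""
    rng = np.random.default_rng(seed)
    s_net, s_act, s_c = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    network = generate_static_network(
        n_tfs, n_tgs, targets_per_tf, tf_tf_edges, seed=s_net
    )
    t = np.asarray(timepoints, dtype=float)
    T_true = generate_tf_activities(n_tfs, t, range_boundaries, seed=s_act)
    C_true = generate_control_strengths(network, seed=s_c)
    return GroundTruth(network, C_true, T_true, t, float(noise_sd), int(seed))


def generate_expression(
    ground_truth: GroundTruth, n_replicates: int = 2
) -> ReplicatedExpression:
    """Replicated noisy expression: E_r = C_true . T_true + eps_r.

    Noise is i.i.d. Gaussian(0, noise_sd^2) per entry and replicate; at
    noise_sd = 0 every replicate equals the noiseless product exactly.
    """
    C, T = ground_truth.C_true, ground_truth.T_true
    if C.shape[1] != T.shape[0]:
        raise ValueError("C_true and T_true dimensions are inconsistent")
    clean = C @ T
    rng = np.random.default_rng(ground_truth.seed + 1)
    values = np.empty(clean.shape + (n_replicates,))
    for r in range(n_replicates):
        noise = (
            rng.normal(0.0, ground_truth.noise_sd, size=clean.shape)
            if ground_truth.noise_sd > 0
            else 0.0
        )
        values[:, :, r] = clean + noise
    return ReplicatedExpression(
        values=values,
        gene_ids=ground_truth.gene_ids,
        timepoints=ground_truth.timepoints,
    )
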