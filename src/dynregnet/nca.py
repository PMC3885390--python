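"""Network component analysis: E ~= C.T with fixed connectivity support.

Expression E (N genes x M time points) is decomposed into control
strengths C (N x L) and hidden TF activities T (L x M), where the support
of C is pinned to the known TF->TG connectivity pattern Z0.  The
decomposition is unique up to a diagonal rescaling exactly when the three
identifiability criteria hold:

1. the connectivity matrix has full column rank;
2. removing any one TF together with all of its targets leaves a matrix
   of full column rank (L - 1);
3. the activity matrix can have full row rank, i.e. M >= L.

Fitting is alternating least squares: solve T given C in one full least
squares, then refit each gene's row of C restricted to its Z0 support.
The scale/sign ambiguity is resolved by a diagonal matrix S chosen so that
each column of C has unit Euclidean norm and a positive dominant entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import ExpressionMatrix, RegulatoryNetwork

logger = logging.getLogger(__name__)

_RANK_RTOL = 1e-10


@dataclass
class ConnectivityPattern:
    """Binary support Z0 (genes x TFs) of the control-strength matrix."""

    Z0: np.ndarray
    gene_ids: list[str]
    tf_ids: list[str]

    def __post_init__(self) -> None:
        self.Z0 = np.asarray(self.Z0, dtype=np.int8)
        if self.Z0.shape != (len(self.gene_ids), len(self.tf_ids)):
            raise ValueError("Z0 shape inconsistent with labels")

    @property
    def n_genes(self) -> int:
        return self.Z0.shape[0]

    @property
    def n_tfs(self) -> int:
        return self.Z0.shape[1]


@dataclass
class CriteriaReport:
    full_column_rank: bool
    reduced_rank_ok: dict[str, bool]
    t_full_row_rank_possible: bool

    @property
    def compliant(self) -> bool:
        return (
            self.full_column_rank
            and all(self.reduced_rank_ok.values())
            and self.t_full_row_rank_possible
        )

    @property
    def n_violations(self) -> int:
        return (
            int(not self.full_column_rank)
            + sum(not ok for ok in self.reduced_rank_ok.values())
            + int(not self.t_full_row_rank_possible)
        )


@dataclass
class NCAFit:
    C: np.ndarray
    T: np.ndarray
    pattern: ConnectivityPattern
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    seed: int = 0

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def build_connectivity(
    network: RegulatoryNetwork,
    gene_ids,
    tf_ids,
) -> ConnectivityPattern:
    """Materialize Z0 for a gene/TF selection from the static network.

    Rows (genes with no selected regulator) and columns (TFs with no
    selected target) that would be all-zero are dropped and logged.
    """
    gene_ids = sorted(gene_ids)
    tf_ids = sorted(tf_ids)
    tf_targets = {tf: network.targets_of(tf) for tf in tf_ids}
    Z0 = np.zeros((len(gene_ids), len(tf_ids)), dtype=np.int8)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for j, tf in enumerate(tf_ids):
        for tg in tf_targets[tf]:
            if tg in gene_index:
                Z0[gene_index[tg], j] = 1

    keep_cols = Z0.sum(axis=0) > 0
    dropped_tfs = [tf for tf, k in zip(tf_ids, keep_cols) if not k]
    Z0 = Z0[:, keep_cols]
    tf_ids = [tf for tf, k in zip(tf_ids, keep_cols) if k]
    keep_rows = Z0.sum(axis=1) > 0
    dropped_genes = [g for g, k in zip(gene_ids, keep_rows) if not k]
    Z0 = Z0[keep_rows]
    gene_ids = [g for g, k in zip(gene_ids, keep_rows) if k]
    if dropped_tfs:
        logger.info("dropped %d TFs with no selected target", len(dropped_tfs))
    if dropped_genes:
        logger.info("dropped %d genes with no selected regulator", len(dropped_genes))
    if Z0.size == 0:
        raise ValueError("connectivity pattern empty after dropping")
    return ConnectivityPattern(Z0, gene_ids, tf_ids)


def _generic_rank(support: np.ndarray, rng: np.random.Generator) -> int:
    """Rank of a random matrix with the given sparsity support."""
    filled = support * rng.uniform(0.5, 1.5, size=support.shape)
    if min(filled.shape) == 0:
        return 0
    s = np.linalg.svd(filled, compute_uv=False)
    return int(np.sum(s > _RANK_RTOL * s[0]))


def check_nca_criteria(
    pattern: ConnectivityPattern,
    n_timepoints: int,
    n_probes: int = 5,
    seed: int = 0,
) -> CriteriaReport:
    """Test the three identifiability criteria on a connectivity pattern.

    Rank conditions are generic-rank tests: the support is filled with
    random values ``n_probes`` times and the majority verdict is taken
    (a pattern can only lose rank by structure, not gain it).
    """
    rng = np.random.default_rng(seed)
    Z = pattern.Z0.astype(float)
    L = pattern.n_tfs

    votes = [_generic_rank(Z, rng) == L for _ in range(n_probes)]
    full_rank = sum(votes) > n_probes / 2

    reduced_ok: dict[str, bool] = {}
    for l, tf in enumerate(pattern.tf_ids):
        keep_rows = Z[:, l] == 0
        reduced = np.delete(Z[keep_rows], l, axis=1)
        if reduced.shape[1] == 0:
            reduced_ok[tf] = True  # single-TF pattern: nothing left to test
            continue
        votes = [_generic_rank(reduced, rng) == L - 1 for _ in range(n_probes)]
        reduced_ok[tf] = sum(votes) > n_probes / 2

    return CriteriaReport(
        full_column_rank=full_rank,
        reduced_rank_ok=reduced_ok,
        t_full_row_rank_possible=n_timepoints >= L,
    )


def _drop_tf(pattern: ConnectivityPattern, tf: str) -> ConnectivityPattern:
    j = pattern.tf_ids.index(tf)
    Z = np.delete(pattern.Z0, j, axis=1)
    tf_ids = [t for t in pattern.tf_ids if t != tf]
    keep = Z.sum(axis=1) > 0
    return ConnectivityPattern(
        Z[keep], [g for g, k in zip(pattern.gene_ids, keep) if k], tf_ids
    )


def reduce_to_compliant(
    pattern: ConnectivityPattern,
    n_timepoints: int,
    seed: int = 0,
) -> ConnectivityPattern:
    """Greedily remove TFs until the identifiability criteria hold.

    At each step the TF whose removal most reduces the number of criterion
    violations is dropped; ties are broken by fewest targets, then by
    lexicographic id.  Genes left without a regulator are dropped too.
    """
    current = pattern
    report = check_nca_criteria(current, n_timepoints, seed=seed)
    while not report.compliant:
        if current.n_tfs <= 2:
            raise ValueError("cannot reach compliance without going below 2 TFs")
        best = None
        for tf in current.tf_ids:
            candidate = _drop_tf(current, tf)
            cand_report = check_nca_criteria(candidate, n_timepoints, seed=seed)
            n_targets = int(current.Z0[:, current.tf_ids.index(tf)].sum())
            key = (cand_report.n_violations, n_targets, tf)
            if best is None or key < best[0]:
                best = (key, tf, candidate, cand_report)
        _, tf, current, report = best
        logger.info("removed TF %s (remaining: %d)", tf, current.n_tfs)
    return current


def fit_nca(
    E: ExpressionMatrix,
    pattern: ConnectivityPattern,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> NCAFit:
    """Alternating least squares with fixed support.

    C is initialized with i.i.d. uniform(0.5, 1.5) magnitudes and random
    signs on the Z0 support.  Each iteration solves T = argmin ||E - CT||_F
    (full least squares) and then refits every gene's row of C restricted
    to its support; the Frobenius objective is recorded after each full
    iteration and is non-increasing.
    """
    if E.gene_ids != pattern.gene_ids:
        raise ValueError("expression rows are not aligned with the pattern genes")
    report = check_nca_criteria(pattern, len(E.timepoints), seed=seed)
    if not report.compliant:
        warnings.warn("connectivity pattern violates the identifiability criteria")
    X = E.values
    Z = pattern.Z0.astype(bool)
    rng = np.random.default_rng(seed)
    C = np.zeros(Z.shape)
    C[Z] = rng.uniform(0.5, 1.5, size=int(Z.sum())) * rng.choice([-1.0, 1.0], int(Z.sum()))

    supports = [np.flatnonzero(Z[i]) for i in range(Z.shape[0])]
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        T, *_ = np.linalg.lstsq(C, X, rcond=None)
        for i, sup in enumerate(supports):
            coef, *_ = np.linalg.lstsq(T[sup].T, X[i], rcond=None)
            C[i, sup] = coef
        if not (np.isfinite(C).all() and np.isfinite(T).all()):
            raise FloatingPointError("non-finite values during alternating fit")
        obj = float(np.linalg.norm(X - C @ T, "fro") ** 2)
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(prev - obj) <= tol * max(prev, np.finfo(float).tiny):
                converged = True
                break
    return NCAFit(
        C=C, T=T, pattern=pattern, objective_trace=trace,
        converged=converged, n_iter=n_iter, seed=seed,
    )


def normalize_fit(fit: NCAFit) -> NCAFit:
    """Resolve the diagonal scale/sign ambiguity.

    S is diagonal with S_ll = ||C[:,l]|| * sign(dominant entry of C[:,l]);
    C -> C S^-1 and T -> S T leaves the product C.T unchanged while giving
    every column of C unit norm and a positive maximum-magnitude entry.
    """
    norms = np.linalg.norm(fit.C, axis=0)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a fit with an all-zero column of C")
    dominant = fit.C[np.abs(fit.C).argmax(axis=0), np.arange(fit.C.shape[1])]
    s = norms * np.sign(dominant)
    return replace(fit, C=fit.C / s, T=fit.T * s[:, None])


def fit_nca_restarts(
    E: ExpressionMatrix,
    pattern: ConnectivityPattern,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> NCAFit:
    """Run several seeded restarts and keep the lowest final objective.

    Alternating least squares can land in local minima; restarts with
    independent random initializations make recovery reliable.
    """
    rng = np.random.default_rng(seed)
    best: NCAFit | None = None
    for s in rng.integers(0, 2**31 - 1, size=n_restarts):
        fit = fit_nca(E, pattern, max_iter=max_iter, tol=tol, seed=int(s))
        if best is None or fit.objective < best.objective:
            best = fit
    return best


def align_to_truth(T_est: np.ndarray, T_true: np.ndarray) -> np.ndarray:
    """Per-TF absolute Pearson correlation between estimated and true rows.

    Activities are only identified up to per-TF scale and sign, so |r| is
    the natural recovery score; zero-variance rows score 0 with a warning.
    """
    T_est = np.asarray(T_est, dtype=float)
    T_true = np.asarray(T_true, dtype=float)
    if T_est.shape != T_true.shape:
        raise ValueError("matrices must have the same shape")
    out = np.empty(T_est.shape[0])
    for i in range(T_est.shape[0]):
        a, b = T_est[i], T_true[i]
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"zero-variance activity row {i}: correlation set to 0")
            out[i] = 0.0
        else:
            out[i] = abs(np.corrcoef(a, b)[0, 1])
    return out
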