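import numpy as np
import pytest

from dynregnet.datatypes import ExpressionMatrix, RegulatoryNetwork
from dynregnet.nca import (
    ConnectivityPattern,
    align_to_truth,
    build_connectivity,
    check_nca_criteria,
    fit_nca,
    fit_nca_restarts,
    normalize_fit,
    reduce_to_compliant,
)


def pattern_from(Z0):
    Z0 = np.asarray(Z0)
    return ConnectivityPattern(
        Z0,
        [f"g{i}" for i in range(Z0.shape[0])],
        [f"t{j}" for j in range(Z0.shape[1])],
    )


def expression_from(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        np.arange(values.shape[1], dtype=float),
    )


class TestBuildConnectivity:
    def _network(self):
        net = RegulatoryNetwork()
        net.add_regulation("T1", "G1")
        net.add_regulation("T1", "G2")
        net.add_regulation("T2", "G2")
        net.add_regulation("T2", "G3")
        return net

    def test_direct_transcription(self):
        pat = build_connectivity(self._network(), ["G1", "G2", "G3"], ["T1", "T2"])
        np.testing.assert_array_equal(pat.Z0, [[1, 0], [1, 1], [0, 1]])
        assert pat.gene_ids == ["G1", "G2", "G3"]
        assert pat.tf_ids == ["T1", "T2"]

    def test_targetless_tf_column_dropped(self):
        net = self._network()
        net.add_regulation("T3", "G9")  # G9 not selected
        pat = build_connectivity(net, ["G1", "G2", "G3"], ["T1", "T2", "T3"])
        assert pat.tf_ids == ["T1", "T2"]

    def test_unregulated_gene_row_dropped(self):
        pat = build_connectivity(self._network(), ["G1", "G3"], ["T1"])
        assert pat.gene_ids == ["G1"]

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity(self._network(), ["G3"], ["T1"])


class TestCriteria:
    def test_identity_pattern_passes(self):
        report = check_nca_criteria(pattern_from(np.eye(3)), n_timepoints=11)
        assert report.compliant

    def test_duplicate_target_sets_fail_reduced_rank(self):
        Z0 = np.array([[1, 1], [1, 1], [1, 1]])  # t0 and t1 share every target
        report = check_nca_criteria(pattern_from(Z0), n_timepoints=11)
        assert report.reduced_rank_ok == {"t0": False, "t1": False}
        assert not report.compliant

    def test_too_few_timepoints(self):
        Z0 = np.eye(12)
        report = check_nca_criteria(pattern_from(Z0), n_timepoints=11)
        assert not report.t_full_row_rank_possible
        assert not report.compliant


class TestReduceToCompliant:
    def test_compliant_pattern_unchanged(self):
        pat = pattern_from(np.eye(4))
        out = reduce_to_compliant(pat, n_timepoints=11)
        np.testing.assert_array_equal(out.Z0, pat.Z0)
        assert out.tf_ids == pat.tf_ids

    def test_duplicate_columns_resolved_by_single_removal(self):
        Z0 = np.array(
            [[1, 1, 0], [1, 1, 0], [1, 1, 1], [0, 0, 1], [0, 0, 1]]
        )
        out = reduce_to_compliant(pattern_from(Z0), n_timepoints=11)
        assert out.n_tfs == 2
        assert check_nca_criteria(out, 11).compliant

    def test_excess_tfs_removed_to_meet_timepoint_bound(self):
        rng = np.random.default_rng(0)
        L, M = 8, 6
        Z0 = (rng.random((40, L)) < 0.4).astype(int)
        Z0[np.arange(L), np.arange(L)] = 1  # no empty columns
        Z0[Z0.sum(axis=1) == 0, 0] = 1
        pat = pattern_from(Z0)
        assert check_nca_criteria(pat, M).n_violations == 1  # only the M >= L bound
        out = reduce_to_compliant(pat, n_timepoints=M)
        assert out.n_tfs == M
        assert check_nca_criteria(out, M).compliant


class TestFit:
    def test_identity_support_is_exact(self):
        E = expression_from(np.arange(12, dtype=float).reshape(3, 4) + 1)
        fit = normalize_fit(fit_nca(E, pattern_from(np.eye(3)), seed=0))
        np.testing.assert_allclose(fit.C, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fit.T, E.values, atol=1e-12)
        assert fit.objective < 1e-20

    def test_noiseless_recovery_reaches_machine_floor(self, small_truth):
        clean = small_truth.C_true @ small_truth.T_true
        pat = build_connectivity(
            small_truth.network, small_truth.gene_ids, small_truth.tf_ids
        )
        E = ExpressionMatrix(clean, small_truth.gene_ids, small_truth.timepoints)
        E = E.subset(pat.gene_ids)
        fit = fit_nca_restarts(E, pat, n_restarts=3, seed=1)
        assert fit.objective < 1e-8 * np.linalg.norm(E.values, "fro") ** 2

    def test_objective_trace_non_increasing(self, small_truth):
        rng = np.random.default_rng(2)
        pat = build_connectivity(
            small_truth.network, small_truth.gene_ids, small_truth.tf_ids
        )
        noisy = small_truth.C_true @ small_truth.T_true + rng.normal(
            0, 0.5, (len(small_truth.gene_ids), 11)
        )
        E = ExpressionMatrix(
            noisy, small_truth.gene_ids, small_truth.timepoints
        ).subset(pat.gene_ids)
        fit = fit_nca(E, pat, seed=3)
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10 * trace[:-1])

    def test_support_preserved(self, small_truth):
        pat = build_connectivity(
            small_truth.network, small_truth.gene_ids, small_truth.tf_ids
        )
        E = ExpressionMatrix(
            small_truth.C_true @ small_truth.T_true,
            small_truth.gene_ids,
            small_truth.timepoints,
        ).subset(pat.gene_ids)
        fit = fit_nca(E, pat, seed=4)
        assert np.all(fit.C[pat.Z0 == 0] == 0)

    def test_seeded_determinism(self, small_truth):
        pat = build_connectivity(
            small_truth.network, small_truth.gene_ids, small_truth.tf_ids
        )
        E = ExpressionMatrix(
            small_truth.C_true @ small_truth.T_true,
            small_truth.gene_ids,
            small_truth.timepoints,
        ).subset(pat.gene_ids)
        a = fit_nca(E, pat, seed=9)
        b = fit_nca(E, pat, seed=9)
        assert a.objective_trace == b.objective_trace
        np.testing.assert_array_equal(a.T, b.T)


class TestNormalize:
    def test_scale_absorbed(self):
        fit = fit_nca(
            expression_from([[2.0, 2.0], [0.0, 0.0]]),
            pattern_from([[1], [1]]),
            seed=0,
        )
        fit.C = np.array([[2.0], [0.0]])
        fit.T = np.array([[1.0, 1.0]])
        out = normalize_fit(fit)
        np.testing.assert_allclose(out.C, [[1.0], [0.0]])
        np.testing.assert_allclose(out.T, [[2.0, 2.0]])

    def test_sign_flip_absorbed(self):
        fit = fit_nca(
            expression_from([[-3.0]]), pattern_from([[1]]), seed=0
        )
        fit.C = np.array([[-3.0]])
        fit.T = np.array([[1.0]])
        out = normalize_fit(fit)
        np.testing.assert_allclose(out.C, [[1.0]])
        np.testing.assert_allclose(out.T, [[-3.0]])

    def test_product_invariant_and_unit_columns(self, small_truth):
        pat = build_connectivity(
            small_truth.network, small_truth.gene_ids, small_truth.tf_ids
        )
        E = ExpressionMatrix(
            small_truth.C_true @ small_truth.T_true,
            small_truth.gene_ids,
            small_truth.timepoints,
        ).subset(pat.gene_ids)
        fit = fit_nca(E, pat, seed=6)
        out = normalize_fit(fit)
        np.testing.assert_allclose(out.C @ out.T, fit.C @ fit.T, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(out.C, axis=0), 1.0)
        dominant = out.C[np.abs(out.C).argmax(axis=0), np.arange(out.C.shape[1])]
        assert np.all(dominant > 0)


class TestAlignToTruth:
    def test_diagonal_rescaling_scores_one(self):
        rng = np.random.default_rng(0)
        T = rng.normal(size=(4, 11))
        D = np.diag([2.0, -3.0, 0.5, -1.0])
        np.testing.assert_allclose(align_to_truth(D @ T, T), 1.0)

    def test_negation_scores_one(self):
        rng = np.random.default_rng(1)
        T = rng.normal(size=(3, 11))
        np.testing.assert_allclose(align_to_truth(-T, T), 1.0)

    def test_independent_rows_score_low(self):
        rng = np.random.default_rng(2)
        scores = align_to_truth(rng.normal(size=(200, 11)), rng.normal(size=(200, 11)))
        assert scores.mean() < 0.6

    def test_zero_variance_row_warns(self):
        with pytest.warns(UserWarning):
            scores = align_to_truth(np.zeros((1, 5)), np.ones((1, 5)) * 2)
        assert scores[0] == 0.0
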