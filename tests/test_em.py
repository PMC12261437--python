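"""EM abundance estimation: E/M steps, fixed points, oracle optimality."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st
from sklearn.base import clone

from lrquant import EMAbundance, EMConfig, e_step, log_likelihood, m_step, run_em
from util_oracles import grid_search_loglik


def csr_from_rows(rows, n_txp):
    """rows: list of dict {transcript: q}."""
    mat = np.zeros((len(rows), n_txp))
    for n, row in enumerate(rows):
        for j, q in row.items():
            mat[n, j] = q
    return sp.csr_matrix(mat)


class TestESstep:
    def test_unique_read_gets_full_responsibility(self):
        X = csr_from_rows([{0: 0.8}], 2)
        r = e_step(np.array([0.01, 0.99]), X).toarray()
        np.testing.assert_allclose(r, [[1.0, 0.0]])

    def test_equal_conditionals_follow_theta(self):
        X = csr_from_rows([{0: 1.0, 1: 1.0}], 2)
        r = e_step(np.array([0.75, 0.25]), X).toarray()
        np.testing.assert_allclose(r, [[0.75, 0.25]])

    def test_uniform_theta_follows_conditionals(self):
        X = csr_from_rows([{0: 0.7, 1: 0.3}], 2)
        r = e_step(np.array([0.5, 0.5]), X).toarray()
        np.testing.assert_allclose(r, [[0.7, 0.3]])

    def test_dead_row_assigned_uniformly(self):
        X = csr_from_rows([{0: 0.7, 1: 0.3}], 3)
        r = e_step(np.array([0.0, 0.0, 1.0]), X).toarray()
        np.testing.assert_allclose(r, [[0.5, 0.5, 0.0]])


class TestMStep:
    @pytest.mark.parametrize(
        "resp,expected",
        [
            ([[1, 0], [1, 0], [0, 1], [0, 1]], [0.5, 0.5]),
            ([[1, 0], [1, 0]], [1.0, 0.0]),
            ([[1, 0], [0.5, 0.5]], [0.75, 0.25]),
        ],
    )
    def test_theta_is_mean_responsibility(self, resp, expected):
        np.testing.assert_allclose(m_step(sp.csr_matrix(np.array(resp, dtype=float))), expected)


class TestRunEM:
    def test_unique_plus_ambiguous_collapses_to_unique_target(self):
        # likelihood ~ theta_A * (theta_A + theta_B) is maximised at theta_A = 1
        X = csr_from_rows([{0: 1.0}, {0: 0.5, 1: 0.5}], 2)
        est = run_em(X, EMConfig(max_iters=5000, tol=1e-9))
        np.testing.assert_allclose(est.theta, [1.0, 0.0], atol=1e-6)
        np.testing.assert_allclose(est.counts, [2.0, 0.0], atol=1e-5)

    def test_symmetric_instance_fixed_point(self):
        rows = [{0: 1.0}] * 2 + [{1: 1.0}] * 2 + [{0: 0.5, 1: 0.5}] * 4
        est = run_em(csr_from_rows(rows, 2))
        np.testing.assert_array_equal(est.counts, [4.0, 4.0])  # exact by symmetry

    def test_all_unique_exact_after_one_iteration(self):
        rows = [{0: 1.0}] * 3 + [{1: 0.9}] * 1
        est = run_em(csr_from_rows(rows, 2))
        np.testing.assert_array_equal(est.counts, [3.0, 1.0])
        assert est.n_iters <= 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_em(sp.csr_matrix((0, 2)))

    def test_row_without_entries_rejected(self):
        with pytest.raises(ValueError):
            run_em(csr_from_rows([{0: 1.0}, {}], 2))

    @given(seed=st.integers(0, 500))
    def test_loglik_monotone_and_counts_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n_txp = int(rng.integers(2, 6))
        rows = []
        for n in range(int(rng.integers(2, 30))):
            k = int(rng.integers(1, n_txp + 1))
            targets = rng.choice(n_txp, size=k, replace=False)
            rows.append({int(j): float(rng.uniform(0.05, 1.0)) for j in targets})
        est = run_em(csr_from_rows(rows, n_txp), EMConfig(max_iters=200, tol=1e-6))
        diffs = np.diff(est.loglik_trace)
        assert np.all(diffs >= -1e-9)
        assert est.counts.sum() == pytest.approx(len(rows), abs=1e-6)
        assert est.theta.sum() == pytest.approx(1.0, abs=1e-12)

    @given(seed=st.integers(0, 120))
    def test_final_loglik_beats_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_txp = int(rng.integers(2, 4))
        rows = []
        for n in range(int(rng.integers(1, 7))):
            k = int(rng.integers(1, n_txp + 1))
            targets = rng.choice(n_txp, size=k, replace=False)
            rows.append({int(j): float(rng.uniform(0.1, 1.0)) for j in targets})
        est = run_em(csr_from_rows(rows, n_txp), EMConfig(max_iters=20000, tol=1e-10))
        oracle_ll, _ = grid_search_loglik(rows, n_txp, resolution=1e-3)
        assert est.loglik_trace[-1] >= oracle_ll - 1e-6

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        rows = []
        for n in range(20):
            targets = rng.choice(4, size=int(rng.integers(1, 4)), replace=False)
            rows.append({int(j): float(rng.uniform(0.1, 1.0)) for j in targets})
        X = csr_from_rows(rows, 4)
        perm = np.array([2, 0, 3, 1])
        Xp = csr_from_rows([{int(perm[j]): q for j, q in row.items()} for row in rows], 4)
        est, est_p = run_em(X), run_em(Xp)
        np.testing.assert_allclose(est_p.counts[perm], est.counts, atol=1e-9)

    def test_custom_init_must_be_simplex(self):
        X = csr_from_rows([{0: 1.0}], 2)
        with pytest.raises(ValueError):
            run_em(X, EMConfig(init=np.array([0.9, 0.9])))


class TestEMAbundanceEstimator:
    def test_sklearn_params_round_trip(self):
        est = EMAbundance(max_iters=50, tol=1e-4)
        assert clone(est).get_params() == {"max_iters": 50, "tol": 1e-4}

    def test_fit_exposes_fitted_attributes(self):
        X = csr_from_rows([{0: 1.0}, {1: 1.0}], 2)
        est = EMAbundance().fit(X)
        np.testing.assert_allclose(est.theta_, [0.5, 0.5])
        assert est.n_assigned_ == 2
        assert est.score(X) == pytest.approx(log_likelihood(est.theta_, X) / 2)

    def test_predict_proba_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        rows = [
            {int(j): float(rng.uniform(0.1, 1)) for j in rng.choice(3, size=2, replace=False)}
            for _ in range(10)
        ]
        X = csr_from_rows(rows, 3)
        resp = EMAbundance().fit(X).predict_proba(X)
        np.testing.assert_allclose(np.asarray(resp.sum(axis=1)).ravel(), 1.0)
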