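"""Expectation-Maximization over the fragment-level mixture likelihood.

With fixed conditionals ``q_nj`` the marginal likelihood of the reads is

    L(theta) = prod_n  sum_{j in A(r_n)}  theta_j * q_nj,

a standard finite-mixture likelihood in the abundance simplex ``theta``.  The
E-step computes responsibilities ``r_nj = theta_j q_nj / sum_j' theta_j'
q_nj'``; the M-step sets ``theta_j`` to the mean responsibility.  Iteration
starts from the uniform simplex (inference is deterministic; there is no RNG
anywhere in the quantifier) and stops when the largest per-transcript change
in expected read counts drops below ``tol`` (default 1e-3 reads).

Abundances are reported as ``theta`` itself: the generative model has no
length or effective-length term, so theta is simultaneously the molar
fraction and the expected read fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .assignment import ConditionalProbMatrix


@dataclass(frozen=True)
class EMConfig:
    max_iters: int = 1000
    tol: float = 1e-3  # max absolute change in expected counts, in reads
    init: np.ndarray | None = None  # custom starting theta; None = uniform

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not (self.tol > 0):
            raise ValueError("tol must be > 0")


@dataclass
class AbundanceEstimate:
    """Fitted relative abundances and expected read counts."""

    theta: np.ndarray
    counts: np.ndarray
    n_assigned: int
    n_iters: int
    final_delta: float
    loglik_trace: list[float] = field(default_factory=list)


def _csr_arrays(
    conds: ConditionalProbMatrix | sp.spmatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Extract (indptr, txp_idx, q, n_reads, n_transcripts) from any input form."""
    if isinstance(conds, ConditionalProbMatrix):
        return conds.indptr, conds.txp_idx, conds.probs, conds.n_reads, conds.n_transcripts
    X = sp.csr_matrix(conds)
    X.sort_indices()
    if X.shape[0] == 0:
        raise ValueError("no reads to quantify")
    if np.any(np.diff(X.indptr) == 0):
        raise ValueError("every read must have at least one positive conditional probability")
    if np.any(X.data <= 0):
        raise ValueError("conditional probabilities must be positive where stored")
    return X.indptr, X.indices, X.data, X.shape[0], X.shape[1]


def e_step(
    theta: np.ndarray,
    conds: ConditionalProbMatrix | sp.spmatrix | np.ndarray,
) -> sp.csr_matrix:
    """Responsibilities ``r_nj``, one row per read, each row summing to one.

    A read whose entire row has zero posterior weight (theta zero on all its
    transcripts) is assigned uniformly over its alignment set.
    """
    indptr, idx, q, n_reads, n_txp = _csr_arrays(conds)
    r, _ = _responsibilities(np.asarray(theta, dtype=float), indptr, idx, q)
    return sp.csr_matrix((r, idx, indptr), shape=(n_reads, n_txp))


def m_step(responsibilities: sp.spmatrix) -> np.ndarray:
    """Maximum-likelihood theta given responsibilities: per-transcript means."""
    R = sp.csr_matrix(responsibilities)
    counts = np.asarray(R.sum(axis=0)).ravel()
    return counts / R.shape[0]


def _responsibilities(
    theta: np.ndarray, indptr: np.ndarray, idx: np.ndarray, q: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    w = q * theta[idx]
    # rows are non-empty by construction, so reduceat segments are valid
    row_sum = np.add.reduceat(w, indptr[:-1])
    nnz = np.diff(indptr)
    dead = row_sum == 0
    if dead.any():
        w = w.copy()
        w[np.repeat(dead, nnz)] = 1.0
        denom = np.where(dead, nnz.astype(float), row_sum)
    else:
        denom = row_sum
    return w / np.repeat(denom, nnz), row_sum


def log_likelihood(
    theta: np.ndarray, conds: ConditionalProbMatrix | sp.spmatrix | np.ndarray
) -> float:
    """``sum_n log sum_j theta_j q_nj`` (reads with zero inner sum contribute -inf)."""
    indptr, idx, q, _, _ = _csr_arrays(conds)
    w = q * np.asarray(theta, dtype=float)[idx]
    row_sum = np.add.reduceat(w, indptr[:-1])
    with np.errstate(divide="ignore"):
        return float(np.log(row_sum).sum())


def run_em(
    conds: ConditionalProbMatrix | sp.spmatrix | np.ndarray,
    config: EMConfig = EMConfig(),
) -> AbundanceEstimate:
    """Iterate E/M from uniform theta until the expected counts stabilise."""
    indptr, idx, q, n_reads, n_txp = _csr_arrays(conds)
    if n_reads == 0:
        raise ValueError("no reads to quantify")
    if config.init is not None:
        theta = np.asarray(config.init, dtype=float)
        if theta.shape != (n_txp,) or np.any(theta < 0) or not np.isclose(theta.sum(), 1.0):
            raise ValueError("init must be a length-M simplex vector")
        theta = theta / theta.sum()
    else:
        theta = np.full(n_txp, 1.0 / n_txp)
    counts = theta * n_reads
    trace: list[float] = []
    delta = np.inf
    n_iters = 0
    for n_iters in range(1, config.max_iters + 1):
        r, row_sum = _responsibilities(theta, indptr, idx, q)
        with np.errstate(divide="ignore"):
            trace.append(float(np.log(row_sum).sum()))
        new_counts = np.bincount(idx, weights=r, minlength=n_txp)
        delta = float(np.abs(new_counts - counts).max())
        counts = new_counts
        theta = counts / n_reads
        if delta < config.tol:
            break
    return AbundanceEstimate(
        theta=theta,
        counts=counts,
        n_assigned=n_reads,
        n_iters=n_iters,
        final_delta=delta,
        loglik_trace=trace,
    )


class EMAbundance(BaseEstimator):
    """Mixture-weight MLE over a sparse read x transcript conditional matrix.

    A scikit-learn style estimator: ``fit(X)`` takes an (n_reads,
    n_transcripts) matrix of positive conditional probabilities (sparse or
    dense; zeros mean "read does not align there") and exposes the fitted
    abundances as trailing-underscore attributes.

    Attributes
    ----------
    theta_ : ndarray of shape (n_transcripts,)
        Relative abundances on the simplex.
    counts_ : ndarray of shape (n_transcripts,)
        Expected read counts ``theta_ * n_reads``.
    n_iter_ : int
        EM iterations performed.
    loglik_trace_ : list of float
        Log-likelihood at the start of each iteration (non-decreasing).
    """

    def __init__(self, max_iters: int = 1000, tol: float = 1e-3):
        self.max_iters = max_iters
        self.tol = tol

    def fit(self, X, y=None) -> "EMAbundance":
        est = run_em(X, EMConfig(max_iters=self.max_iters, tol=self.tol))
        self.theta_ = est.theta
        self.counts_ = est.counts
        self.n_assigned_ = est.n_assigned
        self.n_iter_ = est.n_iters
        self.final_delta_ = est.final_delta
        self.loglik_trace_ = est.loglik_trace
        return self

    def predict_proba(self, X) -> sp.csr_matrix:
        """Posterior read-to-transcript responsibilities under the fitted theta."""
        return e_step(self.theta_, X)

    def score(self, X, y=None) -> float:
        """Mean per-read log-likelihood under the fitted theta."""
        indptr, *_ = _csr_arrays(X)
        return log_likelihood(self.theta_, X) / (len(indptr) - 1)
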