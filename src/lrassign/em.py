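"""Alignment-guided EM for read-to-transcript assignment.

The model: each read r carries one unit of mass to distribute over the
transcripts it aligns to. Given fixed compatibility priors X_rt (score
decay x optional filters x optional coverage weights) and relative
transcript abundances rho, the E-step computes the expected assignment
fractions

    alpha_rt = rho_t X_rt / sum_{t' in T_r} rho_{t'} X_{rt'}

and the M-step re-estimates abundances from the summed fractions,
rho_t = rc_t / N with rc_t = sum_r alpha_rt and N the (constant) number of
assigned reads. Iterations run until the total L1 change in the read-count
vector falls below a threshold.

Two departures from naive EM make the algorithm alignment-guided: the X
priors in the E-step, and a one-shot *drop* pruning applied right after the
first E-step, which zeroes compatibility entries whose first-round fraction
falls below a per-read threshold tau'_r = (1 + f)/|T_r|. Dropped entries
stay zero forever (alpha is multiplied by X). A guard keeps each row's
argmax entry so no read is ever left without a transcript.

:class:`AlignmentGuidedEM` wraps this as a scikit-learn style estimator;
:func:`run_em` is the functional entry point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .compatibility import CompatibilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceEstimate",
    "AlignmentGuidedEM",
    "initialize_rho",
    "e_step",
    "m_step",
    "drop",
    "log_likelihood",
    "run_em",
]


@dataclass
class AbundanceEstimate:
    """Per-transcript abundance estimates from one EM fit.

    ``rho`` sums to 1 over transcripts; ``read_count`` (rc_t, fractional
    reads) sums to ``n_reads``. ``transcript_ids`` aligns positionally with
    the arrays when known.
    """

    rho: np.ndarray
    read_count: np.ndarray
    n_reads: float
    transcript_ids: list[str] | None = None

    def rho_map(self) -> dict[str, float]:
        if self.transcript_ids is None:
            raise ValueError("no transcript ids attached")
        return dict(zip(self.transcript_ids, self.rho.tolist()))

    def read_count_map(self) -> dict[str, float]:
        if self.transcript_ids is None:
            raise ValueError("no transcript ids attached")
        return dict(zip(self.transcript_ids, self.read_count.tolist()))


def _as_csr(X) -> tuple[sp.csr_matrix, list[str] | None, list[str] | None]:
    if isinstance(X, CompatibilityMatrix):
        return X.X.tocsr(), X.read_ids, X.transcript_ids
    M = sp.csr_matrix(X, dtype=np.float64)
    return M, None, None


def initialize_rho(X: sp.csr_matrix) -> np.ndarray:
    """Uniform initial abundances over transcripts with >= 1 alignment (T_A).

    Columns without any alignment get rho = 0 and never gain mass.
    """
    if X.shape[0] == 0 or X.nnz == 0:
        raise ValueError("no aligned reads: compatibility matrix is empty")
    col_nnz = X.getnnz(axis=0)
    active = col_nnz > 0
    rho = np.zeros(X.shape[1], dtype=np.float64)
    rho[active] = 1.0 / active.sum()
    return rho


def e_step(rho: np.ndarray, X: sp.csr_matrix) -> sp.csr_matrix:
    """Expected assignment fractions alpha_rt = rho_t X_rt / row normalizer."""
    alpha = X.copy()
    alpha.data = alpha.data * rho[alpha.indices]
    row_sums = np.add.reduceat(
        np.concatenate([alpha.data, [0.0]]), alpha.indptr[:-1]
    )
    # reduceat misbehaves on empty rows; recompute those as 0
    empty = np.diff(alpha.indptr) == 0
    row_sums[empty] = 0.0
    if np.any(row_sums <= 0.0):
        bad = int(np.argmax(row_sums <= 0.0))
        raise ValueError(
            f"read row {bad} has zero assignment mass (no compatible "
            "transcript with positive abundance)"
        )
    alpha.data /= np.repeat(row_sums, np.diff(alpha.indptr))
    return alpha


def m_step(alpha: sp.csr_matrix, n_reads: float) -> tuple[np.ndarray, np.ndarray]:
    """Read counts rc_t (column sums of alpha) and abundances rho = rc / N."""
    rc = np.asarray(alpha.sum(axis=0)).ravel()
    return rc, rc / n_reads


def drop(
    alpha: sp.csr_matrix, X: sp.csr_matrix, drop_fraction: float = 0.1
) -> sp.csr_matrix:
    """One-shot pruning of weak compatibilities after the first E-step.

    Entries with alpha_rt < tau'_r = (1 + f)/|T_r| are zeroed in X, where
    |T_r| is the read's current number of compatible transcripts. The row's
    maximum-alpha entry (tie: lowest column index) is always retained, so
    every read keeps at least one compatible transcript even when all its
    fractions are tied below the threshold.
    """
    if not 0.0 <= drop_fraction <= 1.0:
        raise ValueError("drop_fraction must lie in [0, 1]")
    alpha = alpha.tocsr()
    X_new = X.tocsr(copy=True)
    if alpha.nnz != X_new.nnz or alpha.shape != X_new.shape:
        raise ValueError("alpha and X must share a sparsity pattern")
    keep = np.ones(alpha.nnz, dtype=bool)
    indptr = alpha.indptr
    data = alpha.data
    for i in range(alpha.shape[0]):
        lo, hi = indptr[i], indptr[i + 1]
        n = hi - lo
        if n == 0:
            continue
        tau = (1.0 + drop_fraction) / n
        row = data[lo:hi]
        below = row < tau
        # guard: the argmax (first max, i.e. lowest column index) survives
        below[int(np.argmax(row))] = False
        keep[lo:hi] = ~below
    X_new.data[~keep] = 0.0
    X_new.eliminate_zeros()
    return X_new


def log_likelihood(rho: np.ndarray, X: sp.csr_matrix) -> float:
    """Observed-data log likelihood sum_r log(sum_t rho_t X_rt)."""
    weighted = X.copy()
    weighted.data = weighted.data * rho[weighted.indices]
    row_sums = np.asarray(weighted.sum(axis=1)).ravel()
    if np.any(row_sums <= 0.0):
        return -np.inf
    return float(np.log(row_sums).sum())


class AlignmentGuidedEM(BaseEstimator):
    """EM estimator of read-to-transcript assignments and abundances.

    Parameters
    ----------
    convergence_threshold : float, default=10.0
        Stop when the L1 change of the read-count vector between successive
        iterations falls below this absolute value. The default is sized
        for datasets with millions of reads; tighten it (e.g. 1e-6) for
        small instances or oracle comparisons.
    max_iter : int, default=5000
        Iteration cap; hitting it logs a warning but is not an error.
    drop : bool, default=True
        Apply the one-shot pruning of weak compatibilities after the first
        E-step.
    drop_fraction : float, default=0.1
        Fractional increment f of the drop threshold, tau'_r = (1+f)/|T_r|.
    track_history : bool, default=False
        Record per-iteration rho vectors and log likelihoods (small
        instances / diagnostics only).

    Attributes
    ----------
    rho_ : ndarray of shape (n_transcripts,)
        Relative abundances (sum to 1 over aligned transcripts).
    read_count_ : ndarray of shape (n_transcripts,)
        Fractional read counts rc_t (sum to the number of reads).
    assignment_ : scipy.sparse.csr_matrix
        Final fractional assignments alpha; each row sums to 1.
    X_ : scipy.sparse.csr_matrix
        Compatibility matrix actually used (post-drop).
    n_iter_ : int
        Number of completed E/M cycles.
    converged_ : bool
        Whether the threshold was reached before ``max_iter``.
    loglik_history_, rho_history_ : lists, only when ``track_history``.
    """

    def __init__(
        self,
        convergence_threshold: float = 10.0,
        max_iter: int = 5000,
        drop: bool = True,
        drop_fraction: float = 0.1,
        track_history: bool = False,
    ):
        self.convergence_threshold = convergence_threshold
        self.max_iter = max_iter
        self.drop = drop
        self.drop_fraction = drop_fraction
        self.track_history = track_history

    def fit(self, X, y=None) -> "AlignmentGuidedEM":
        """Run EM on a compatibility matrix.

        ``X`` may be a :class:`~lrassign.compatibility.CompatibilityMatrix`
        (ids are then kept on the estimator) or any nonnegative sparse/dense
        read x transcript array in which absent entries mean incompatible.
        """
        if not self.convergence_threshold > 0:
            raise ValueError("convergence_threshold must be positive")
        M, read_ids, transcript_ids = _as_csr(X)
        if M.nnz and M.data.min() < 0:
            raise ValueError("compatibility scores must be nonnegative")
        self.read_ids_ = read_ids
        self.transcript_ids_ = transcript_ids

        rho = initialize_rho(M)
        n_reads = float(M.shape[0])
        prev_rc = np.zeros(M.shape[1], dtype=np.float64)
        if self.track_history:
            self.rho_history_ = []
            self.loglik_history_ = []

        converged = False
        n_iter = 0
        alpha = None
        for n_iter in range(1, self.max_iter + 1):
            alpha = e_step(rho, M)
            if n_iter == 1 and self.drop:
                M = drop(alpha, M, self.drop_fraction)
                alpha = e_step(rho, M)
            rc, rho = m_step(alpha, n_reads)
            delta = float(np.abs(rc - prev_rc).sum())
            prev_rc = rc
            if self.track_history:
                self.rho_history_.append(rho.copy())
                self.loglik_history_.append(log_likelihood(rho, M))
            logger.debug("iteration %d: L1 read-count change %.6g", n_iter, delta)
            if delta < self.convergence_threshold:
                converged = True
                break
        if not converged:
            logger.warning(
                "EM did not converge in %d iterations (last change above %.3g)",
                self.max_iter,
                self.convergence_threshold,
            )
        self.X_ = M
        self.assignment_ = alpha
        self.read_count_ = prev_rc
        self.rho_ = rho
        self.n_reads_ = n_reads
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def fit_transform(self, X, y=None) -> sp.csr_matrix:
        """Fit and return the fractional assignment matrix alpha."""
        return self.fit(X).assignment_

    def abundance(self) -> AbundanceEstimate:
        """Package the fitted abundances as an :class:`AbundanceEstimate`."""
        if not hasattr(self, "rho_"):
            raise ValueError("estimator is not fitted")
        return AbundanceEstimate(
            rho=self.rho_,
            read_count=self.read_count_,
            n_reads=self.n_reads_,
            transcript_ids=self.transcript_ids_,
        )


def run_em(
    X,
    convergence_threshold: float = 10.0,
    max_iter: int = 5000,
    drop: bool = True,
    drop_fraction: float = 0.1,
) -> tuple[sp.csr_matrix, AbundanceEstimate, int]:
    """Functional wrapper: returns (alpha, abundance estimate, n_iterations)."""
    est = AlignmentGuidedEM(
        convergence_threshold=convergence_threshold,
        max_iter=max_iter,
        drop=drop,
        drop_fraction=drop_fraction,
    ).fit(X)
    return est.assignment_, est.abundance(), est.n_iter_
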