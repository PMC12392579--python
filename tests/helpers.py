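"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package's
own code paths: the naive EM uses dense python/numpy loops, and the
correlation/RMSE references implement the textbook formulas directly
(average ranks + Pearson product-moment) rather than calling scipy.
"""

from __future__ import annotations

import math

import numpy as np


def naive_em(X_dense: np.ndarray, n_iterations: int):
    """Textbook EM on a dense nonnegative compatibility matrix.

    Uniform initialization over columns with any alignment, E-step
    alpha = rho*X row-normalized, M-step rho = column sums / n_reads.
    Returns (list of rho after each M-step, final alpha).
    """
    X = np.asarray(X_dense, dtype=float)
    n_reads, n_tx = X.shape
    active = [j for j in range(n_tx) if any(X[i, j] > 0 for i in range(n_reads))]
    rho = np.zeros(n_tx)
    for j in active:
        rho[j] = 1.0 / len(active)
    history = []
    alpha = np.zeros_like(X)
    for _ in range(n_iterations):
        for i in range(n_reads):
            denom = sum(rho[j] * X[i, j] for j in range(n_tx))
            for j in range(n_tx):
                alpha[i, j] = rho[j] * X[i, j] / denom
        rc = alpha.sum(axis=0)
        rho = rc / n_reads
        history.append(rho.copy())
    return history, alpha


def average_ranks(values: np.ndarray) -> np.ndarray:
    """1-based ranks with ties replaced by their average rank."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_reference(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(np.sum(a * b) / math.sqrt(np.sum(a * a) * np.sum(b * b)))


def spearman_reference(a: np.ndarray, b: np.ndarray) -> float:
    return pearson_reference(average_ranks(a), average_ranks(b))


def rmse_reference(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(math.sqrt(np.mean((a - b) ** 2)))


def random_compat(rng: np.random.Generator, max_reads: int = 20, max_tx: int = 5) -> np.ndarray:
    """Random dense compatibility matrix; every row keeps >= 1 positive entry."""
    n_reads = int(rng.integers(2, max_reads + 1))
    n_tx = int(rng.integers(2, max_tx + 1))
    X = rng.random((n_reads, n_tx)) * (rng.random((n_reads, n_tx)) < 0.6)
    for i in range(n_reads):
        if not np.any(X[i] > 0):
            X[i, int(rng.integers(0, n_tx))] = rng.random() + 0.1
    return X


def true_counts(truth: dict[str, str]) -> dict[str, float]:
    counts: dict[str, float] = {}
    for tid in truth.values():
        counts[tid] = counts.get(tid, 0.0) + 1.0
    return counts


def alpha_as_dicts(alpha, read_ids, transcript_ids) -> dict[str, dict[str, float]]:
    """Sparse assignment matrix -> {read_id: {transcript_id: fraction}}."""
    alpha = alpha.tocsr()
    out: dict[str, dict[str, float]] = {}
    for i, rid in enumerate(read_ids):
        row = {}
        for k in range(alpha.indptr[i], alpha.indptr[i + 1]):
            row[transcript_ids[alpha.indices[k]]] = float(alpha.data[k])
        out[rid] = row
    return out
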