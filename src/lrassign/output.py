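"""Assignment and abundance outputs: hard assignment (push), CPM, coverage, TSVs.

The EM produces fractional assignments alpha. The *push* step converts
them into hard 1-to-1 read assignments by sampling each read's transcript
from the discrete distribution its alpha row defines (the alternative of
taking the argmax is available for comparison but loses more accuracy).
Abundance reports carry read counts rc_t, counts-per-million
CPM_t = rc_t / l * 1e6 (l = total aligned reads), and per-transcript
coverage lambda_t = sum_r alpha_rt * l(r) / l(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .em import AbundanceEstimate
from .transcriptome import TranscriptomeIndex

__all__ = [
    "HardAssignment",
    "push",
    "read_counts",
    "cpm",
    "transcript_coverage",
    "abundance_report",
    "write_outputs",
    "read_assignments_tsv",
    "read_abundance_tsv",
]


@dataclass
class HardAssignment:
    """One transcript per read: column index per alpha row, plus id lookups."""

    columns: np.ndarray
    read_ids: list[str] | None = None
    transcript_ids: list[str] | None = None

    def as_map(self) -> dict[str, str]:
        if self.read_ids is None or self.transcript_ids is None:
            raise ValueError("no ids attached to this assignment")
        return {
            rid: self.transcript_ids[j]
            for rid, j in zip(self.read_ids, self.columns.tolist())
        }


def push(
    alpha: sp.csr_matrix,
    seed: int = 0,
    strategy: str = "sample",
    read_ids: list[str] | None = None,
    transcript_ids: list[str] | None = None,
) -> tuple[HardAssignment, AbundanceEstimate]:
    """Collapse fractional assignments to hard 1-to-1 assignments.

    ``strategy="sample"`` draws each read's transcript from its alpha row
    (seeded, reproducible); ``strategy="argmax"`` takes the highest
    fraction (ties: lowest column index). Abundances are recomputed from
    the hard assignments, so the returned read counts are integers.
    """
    if strategy not in ("sample", "argmax"):
        raise ValueError(f"unknown strategy {strategy!r}")
    alpha = alpha.tocsr()
    n_reads, n_tx = alpha.shape
    rng = np.random.default_rng(seed)
    chosen = np.empty(n_reads, dtype=np.int64)
    for i in range(n_reads):
        lo, hi = alpha.indptr[i], alpha.indptr[i + 1]
        if lo == hi:
            raise ValueError(f"read row {i} has no assignment mass")
        cols = alpha.indices[lo:hi]
        probs = alpha.data[lo:hi]
        if strategy == "argmax":
            chosen[i] = cols[int(np.argmax(probs))]
        else:
            cum = np.cumsum(probs)
            u = rng.random() * cum[-1]  # renormalize against float drift
            chosen[i] = cols[int(np.searchsorted(cum, u, side="right").clip(0, len(cols) - 1))]
    rc = np.bincount(chosen, minlength=n_tx).astype(np.float64)
    est = AbundanceEstimate(
        rho=rc / n_reads,
        read_count=rc,
        n_reads=float(n_reads),
        transcript_ids=transcript_ids,
    )
    return HardAssignment(chosen, read_ids, transcript_ids), est


def read_counts(alpha: sp.csr_matrix) -> np.ndarray:
    """rc_t: column sums of the fractional assignment matrix."""
    return np.asarray(alpha.sum(axis=0)).ravel()


def cpm(read_count, total_aligned: float):
    """Counts per million: CPM_t = rc_t / l * 1e6 with l total aligned reads.

    Accepts an array or a transcript->count mapping and returns the same
    shape.
    """
    if total_aligned <= 0:
        raise ValueError("total aligned read count must be positive")
    if isinstance(read_count, Mapping):
        return {t: rc / total_aligned * 1e6 for t, rc in read_count.items()}
    return np.asarray(read_count, dtype=np.float64) / total_aligned * 1e6


def transcript_coverage(
    alpha: sp.csr_matrix,
    read_lengths: np.ndarray,
    transcript_ids: list[str],
    index: TranscriptomeIndex,
) -> np.ndarray:
    """lambda_t = (sum_r alpha_rt * l(r)) / l(t), per alpha column."""
    read_lengths = np.asarray(read_lengths, dtype=np.float64)
    if read_lengths.shape[0] != alpha.shape[0]:
        raise ValueError("one read length per alpha row is required")
    if np.any(read_lengths <= 0):
        bad = int(np.argmax(read_lengths <= 0))
        raise ValueError(f"read row {bad} has no recorded positive length")
    weighted = alpha.T @ read_lengths
    lengths = np.array([index.length(t) for t in transcript_ids], dtype=np.float64)
    return np.asarray(weighted).ravel() / lengths


def abundance_report(
    alpha: sp.csr_matrix,
    transcript_ids: list[str],
    index: TranscriptomeIndex,
    read_lengths: np.ndarray,
    read_count: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-transcript abundance table over the *whole* annotation.

    Transcripts in the index without any alignment are reported with zero
    counts rather than omitted. Columns: transcript_id, read_count, cpm,
    coverage.
    """
    rc = read_counts(alpha) if read_count is None else np.asarray(read_count, float)
    total = float(alpha.shape[0])
    cov = transcript_coverage(alpha, read_lengths, transcript_ids, index)
    cpms = cpm(rc, total)
    by_tid = {t: i for i, t in enumerate(transcript_ids)}
    rows = []
    for tid in index:
        i = by_tid.get(tid)
        if i is None:
            rows.append((tid, 0.0, 0.0, 0.0))
        else:
            rows.append((tid, rc[i], cpms[i], cov[i]))
    return pd.DataFrame(rows, columns=["transcript_id", "read_count", "cpm", "coverage"])


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_outputs(
    out_dir: str | Path,
    alpha: sp.csr_matrix,
    read_ids: list[str],
    transcript_ids: list[str],
    report: pd.DataFrame,
    hard: HardAssignment | None = None,
) -> dict[str, Path]:
    """Write assignment and abundance TSVs.

    ``assignments.tsv``: one row per positive alpha entry
    (read_id, transcript_id, fraction; 6 significant digits).
    ``abundances.tsv``: transcript_id, read_count, cpm, coverage.
    ``hard_assignments.tsv`` (when ``hard`` given): read_id, transcript_id.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {"assignments": out_dir / "assignments.tsv"}
        alpha = alpha.tocsr()
        with open(paths["assignments"], "w") as fh:
            fh.write("read_id\ttranscript_id\tfraction\n")
            for i in range(alpha.shape[0]):
                for k in range(alpha.indptr[i], alpha.indptr[i + 1]):
                    fh.write(
                        f"{read_ids[i]}\t{transcript_ids[alpha.indices[k]]}\t"
                        f"{_fmt(alpha.data[k])}\n"
                    )
        paths["abundances"] = out_dir / "abundances.tsv"
        with open(paths["abundances"], "w") as fh:
            fh.write("transcript_id\tread_count\tcpm\tcoverage\n")
            for row in report.itertuples(index=False):
                fh.write(
                    f"{row.transcript_id}\t{_fmt(row.read_count)}\t"
                    f"{_fmt(row.cpm)}\t{_fmt(row.coverage)}\n"
                )
        if hard is not None:
            paths["hard_assignments"] = out_dir / "hard_assignments.tsv"
            with open(paths["hard_assignments"], "w") as fh:
                fh.write("read_id\ttranscript_id\n")
                for rid, tid in hard.as_map().items():
                    fh.write(f"{rid}\t{tid}\n")
        return paths
    except OSError as exc:
        raise OSError(f"failed writing outputs under {out_dir}: {exc}") from exc


def read_assignments_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    """Parse an assignments TSV back into read -> {transcript: fraction}."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.read_id), {})[str(row.transcript_id)] = float(row.fraction)
    return out


def read_abundance_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
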