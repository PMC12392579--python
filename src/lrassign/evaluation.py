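"""Evaluation of read assignments and abundance estimates against ground truth.

Read-level: TP is the mass a read places on its true origin transcript,
FP the mass it places elsewhere, and FN the mass *not* on the origin
(whether misassigned or unassigned), so TP + FN always equals the number
of reads evaluated. A read assigned to a transcript set without fractions
is split evenly.
Recall uses the total number of sequenced reads as its denominator;
precision is TP / (TP + FP); F1 = 2PR/(P+R).

Abundance-level: Spearman correlation and RMSE on raw read counts, Pearson
correlation on log2(count + 1), over the union of transcripts with missing
values as zero. Spike-in (sequin) ground-truth CPM converts catalog
abundances and the sample's spike-in concentration into expected CPM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionTally",
    "AssignmentMetrics",
    "AbundanceMetrics",
    "assignment_confusion",
    "precision_recall_f1",
    "abundance_metrics",
    "sequin_cpm",
    "load_truth_tsv",
    "write_truth_tsv",
]

_TOL = 1e-9


@dataclass
class ConfusionTally:
    """Fractional TP/FP/FN mass; tp + fn equals the number of reads."""

    tp: float = 0.0
    fp: float = 0.0
    fn: float = 0.0


@dataclass
class AssignmentMetrics:
    recall: float
    precision: float
    f1: float
    precision_defined: bool = True


@dataclass
class AbundanceMetrics:
    """scc/pcc_log/rmse; correlations are None when a vector is constant."""

    scc: float | None
    pcc_log: float | None
    rmse: float
    n: int


def assignment_confusion(
    assignments: Mapping[str, Mapping[str, float] | Iterable[str] | str],
    truth: Mapping[str, str],
) -> ConfusionTally:
    """Tally TP/FP/FN mass of read assignments against known origins.

    ``assignments`` maps read_id to either {transcript: fraction}
    (fractions sum to <= 1), an iterable of transcripts (even split), or a
    single transcript id. Per read, the fraction on the origin is TP, the
    rest of the assigned mass is FP, and FN is everything not on the
    origin (1 - TP), so tp + fn equals the number of truth reads. Reads
    present in the truth but absent here contribute a full unit to FN;
    reads present here but missing from the truth are an error.
    """
    tally = ConfusionTally()
    for read_id, assigned in assignments.items():
        if read_id not in truth:
            raise KeyError(f"read {read_id!r} has assignments but no known origin")
        origin = truth[read_id]
        if isinstance(assigned, str):
            fractions = {assigned: 1.0}
        elif isinstance(assigned, Mapping):
            fractions = {t: float(v) for t, v in assigned.items()}
        else:
            members = list(assigned)
            fractions = {t: 1.0 / len(members) for t in members} if members else {}
        total = sum(fractions.values())
        if total > 1.0 + 1e-6:
            raise ValueError(
                f"read {read_id!r} has assigned fractions summing to {total:.6g} > 1"
            )
        on_origin = fractions.get(origin, 0.0)
        tally.tp += on_origin
        tally.fp += total - on_origin
        tally.fn += 1.0 - on_origin
    for read_id in truth:
        if read_id not in assignments:
            tally.fn += 1.0
    return tally


def precision_recall_f1(tally: ConfusionTally, total_reads: int) -> AssignmentMetrics:
    """Recall = TP / total sequenced reads; precision = TP/(TP+FP); F1 = 2PR/(P+R)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    recall = tally.tp / total_reads
    denom = tally.tp + tally.fp
    precision_defined = denom > _TOL
    precision = tally.tp / denom if precision_defined else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > _TOL
        else 0.0
    )
    return AssignmentMetrics(recall, precision, f1, precision_defined)


def _aligned_vectors(
    estimated: Mapping[str, float],
    truth: Mapping[str, float],
    min_count: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(set(estimated) | set(truth))
    if min_count is not None:
        keys = [k for k in keys if estimated.get(k, 0.0) >= min_count]
    est = np.array([estimated.get(k, 0.0) for k in keys], dtype=np.float64)
    tru = np.array([truth.get(k, 0.0) for k in keys], dtype=np.float64)
    return est, tru


def abundance_metrics(
    estimated: Mapping[str, float],
    truth: Mapping[str, float],
    min_count: float | None = None,
) -> AbundanceMetrics:
    """Spearman (raw), Pearson (log2(x+1)) and RMSE between count maps.

    Vectors are built over the union of transcript ids with zero fill;
    ``min_count`` optionally drops transcripts whose estimate falls below
    it before comparison (the low-abundance filter used when transcripts
    under one read are considered noise). Constant vectors make the
    correlations undefined and are reported as ``None``.
    """
    est, tru = _aligned_vectors(estimated, truth, min_count)
    if est.size < 3:
        raise ValueError("need at least 3 transcripts to compare abundances")
    rmse = float(np.sqrt(np.mean((est - tru) ** 2)))
    scc: float | None
    pcc: float | None
    if np.ptp(est) == 0.0 or np.ptp(tru) == 0.0:
        scc = pcc = None
    else:
        scc = float(stats.spearmanr(est, tru).statistic)
        log_e, log_t = np.log2(est + 1.0), np.log2(tru + 1.0)
        if np.ptp(log_e) == 0.0 or np.ptp(log_t) == 0.0:
            pcc = None
        else:
            pcc = float(stats.pearsonr(log_e, log_t).statistic)
    return AbundanceMetrics(scc=scc, pcc_log=pcc, rmse=rmse, n=est.size)


def sequin_cpm(
    raw_abundances: Mapping[str, float], spike_concentration: float
) -> dict[str, float]:
    """Ground-truth CPM for spike-in (sequin) transcripts.

    CPM_x = a_x / sum_t a_t * c_s * 1e6, where a are the catalog
    abundances and c_s is the sample's spike-in concentration.
    """
    if spike_concentration <= 0:
        raise ValueError("spike concentration must be positive")
    total = float(sum(raw_abundances.values()))
    if not total > 0:
        raise ValueError("total raw abundance must be positive")
    return {
        x: a / total * spike_concentration * 1e6 for x, a in raw_abundances.items()
    }


def load_truth_tsv(path: str | Path) -> dict[str, str]:
    """Read a (read_id, transcript_id) truth table; header optional."""
    truth: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            if line_no == 1 and parts[0] in ("read_id", "read"):
                continue
            if parts[0] in truth:
                raise ValueError(f"{path}:{line_no}: duplicate read id {parts[0]!r}")
            truth[parts[0]] = parts[1]
    return truth


def write_truth_tsv(truth: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttranscript_id\n")
        for rid, tid in truth.items():
            fh.write(f"{rid}\t{tid}\n")
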