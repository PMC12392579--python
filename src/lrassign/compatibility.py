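"""Compatibility-score construction (the "prefilter" stage).

Each retained read/transcript alignment is converted into a nonnegative
compatibility score

    X_rt = upsilon_rt * omega_rt * f_eta(r, t) * sigma_rt

combining, per pair: exponential alignment-score decay sigma (relative to
the read's best score), optional 5'/3' end-distance indicator filters
upsilon/omega taken relative to the read's primary alignment, and optional
position-specific coverage weights f_eta that favour sparsely covered
transcript positions. X is held sparsely (reads x aligned transcripts) and
stays fixed through the EM iterations that follow.

End-filter semantics: a candidate alignment passes when its end distance
exceeds the primary alignment's by at most the tolerance |beta|
(``delta_rt - delta_primary <= |beta|``); ``beta = -inf`` disables a filter.
The primary alignment always passes (difference 0), so every read keeps at
least one compatible transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .alignment_io import AlignmentRecord
from .transcriptome import TranscriptomeIndex

__all__ = [
    "CompatConfig",
    "PRESETS",
    "CoverageProfile",
    "CompatibilityMatrix",
    "end_distances",
    "end_filter_indicators",
    "score_decay",
    "coverage_profile",
    "position_weights",
    "psw_factor",
    "build_compatibility",
]


@dataclass(frozen=True)
class CompatConfig:
    """Prefilter parameters.

    lambda_decay : exponential decay rate for score gaps (default 5).
    beta_s, beta_e : 5'/3' end-distance tolerances; ``-inf`` disables the
        corresponding filter (both disabled by default).
    psw : enable position-specific coverage weights.
    """

    lambda_decay: float = 5.0
    beta_s: float = -math.inf
    beta_e: float = -math.inf
    psw: bool = False

    def __post_init__(self) -> None:
        if not self.lambda_decay > 0:
            raise ValueError("lambda_decay must be positive")


#: Recommended protocol presets for the end filters.
PRESETS: dict[str, CompatConfig] = {
    "ont-drna": CompatConfig(beta_s=-800.0, beta_e=-math.inf),
    "ont-cdna": CompatConfig(beta_s=-600.0, beta_e=-500.0),
    "pacbio": CompatConfig(beta_s=-600.0, beta_e=-500.0),
}


def end_distances(record: AlignmentRecord, transcript_length: int) -> tuple[int, int]:
    """Distances from the alignment ends to the transcript ends.

    delta_s = start (5' side), delta_e = |t| - end (3' side); both >= 0.
    """
    if record.end > transcript_length:
        raise ValueError(
            f"alignment end {record.end} beyond transcript length {transcript_length}"
        )
    return record.start, transcript_length - record.end


def end_filter_indicators(
    record: AlignmentRecord,
    primary: AlignmentRecord,
    config: CompatConfig,
    index: TranscriptomeIndex,
) -> tuple[int, int]:
    """5'/3' pass indicators (upsilon, omega) relative to the primary alignment.

    An end passes when its distance exceeds the primary's by at most the
    tolerance ``|beta|``; a ``beta`` of ``-inf`` deactivates that filter.
    """
    ds, de = end_distances(record, index.length(record.transcript_id))
    pds, pde = end_distances(primary, index.length(primary.transcript_id))
    upsilon = 1 if ds - pds <= abs(config.beta_s) else 0
    omega = 1 if de - pde <= abs(config.beta_e) else 0
    return upsilon, omega


def score_decay(
    records_for_read: Sequence[AlignmentRecord], lambda_decay: float = 5.0
) -> dict[str, float]:
    """Exponential score decay sigma_rt = exp(-(max_k x_rk - x_rt) / lambda).

    The read's max-scoring transcript gets sigma = 1; all values lie in
    (0, 1]. The maximum ranges over the read's aligned transcript set.
    """
    if not records_for_read:
        raise ValueError("score_decay needs at least one record")
    reads = {rec.read_id for rec in records_for_read}
    if len(reads) != 1:
        raise ValueError(f"records span multiple reads: {sorted(reads)}")
    best = max(rec.score for rec in records_for_read)
    return {
        rec.transcript_id: math.exp(-(best - rec.score) / lambda_decay)
        for rec in records_for_read
    }


@dataclass
class CoverageProfile:
    """Per-base and per-transcript read coverage over the transcriptome.

    ``per_base[t][k]`` counts deduplicated alignments covering base k of t;
    ``per_transcript[t]`` is total aligned bases on t divided by its length
    (i.e. the mean of the per-base counts). Transcripts with no alignments
    are all-zero.
    """

    index: TranscriptomeIndex
    per_base: dict[str, np.ndarray] = field(default_factory=dict)
    per_transcript: dict[str, float] = field(default_factory=dict)

    def base_counts(self, transcript_id: str) -> np.ndarray:
        if transcript_id in self.per_base:
            return self.per_base[transcript_id]
        return np.zeros(self.index.length(transcript_id), dtype=np.int64)

    def mean_coverage(self, transcript_id: str) -> float:
        return self.per_transcript.get(transcript_id, 0.0)


def coverage_profile(
    records: Iterable[AlignmentRecord], index: TranscriptomeIndex
) -> CoverageProfile:
    """Tally per-base alignment coverage c_k^t and mean coverage c^t.

    Expects records already deduplicated per (read, transcript) pair.
    Uses a difference-array accumulation so cost is O(records + bases).
    """
    diffs: dict[str, np.ndarray] = {}
    aligned_bases: dict[str, int] = {}
    for rec in records:
        tid = rec.transcript_id
        if tid not in diffs:
            diffs[tid] = np.zeros(index.length(tid) + 1, dtype=np.int64)
            aligned_bases[tid] = 0
        diffs[tid][rec.start] += 1
        diffs[tid][rec.end] -= 1
        aligned_bases[tid] += rec.span
    profile = CoverageProfile(index)
    for tid, diff in diffs.items():
        profile.per_base[tid] = np.cumsum(diff[:-1])
        profile.per_transcript[tid] = aligned_bases[tid] / index.length(tid)
    return profile


def position_weights(profile: CoverageProfile, transcript_id: str) -> np.ndarray | None:
    """Normalized, zero-shifted coverage-deficit weights for one transcript.

    eta_k = c^t - c_k^t (deficit relative to the transcript mean),
    eta'_k = eta_k + |min_z eta_z| (zero-shift), and the weight vector is
    eta'' = eta' / sum(eta'). Sparsely covered bases get larger weights.
    Returns ``None`` when coverage is uniform (sum of shifted deficits is
    zero), the degenerate case consumers must fall back on.
    """
    c_k = profile.base_counts(transcript_id)
    c_t = profile.mean_coverage(transcript_id)
    eta = c_t - c_k.astype(np.float64)
    eta_shifted = eta + abs(eta.min())
    total = eta_shifted.sum()
    if total <= 0.0:
        return None
    return eta_shifted / total


def psw_factor(record: AlignmentRecord, weights: np.ndarray) -> float:
    """Sum of position weights over the aligned interval [start, end)."""
    return float(weights[record.start : record.end].sum())


@dataclass
class CompatibilityMatrix:
    """Sparse read x transcript compatibility scores X.

    Rows are reads with >= 1 retained alignment, columns the transcripts
    with >= 1 alignment (T_A). Structural zeros mean "incompatible"; every
    row has at least one strictly positive entry.
    """

    X: sp.csr_matrix
    read_ids: list[str]
    transcript_ids: list[str]
    read_lengths: np.ndarray

    def __post_init__(self) -> None:
        self._row_of = {r: i for i, r in enumerate(self.read_ids)}
        self._col_of = {t: j for j, t in enumerate(self.transcript_ids)}

    @property
    def n_reads(self) -> int:
        return self.X.shape[0]

    @property
    def n_transcripts(self) -> int:
        return self.X.shape[1]

    def row(self, read_id: str) -> dict[str, float]:
        """The read's compatible transcripts with their X values."""
        i = self._row_of[read_id]
        sl = self.X[i]
        return {self.transcript_ids[j]: v for j, v in zip(sl.indices, sl.data)}

    def to_tsv(self, path: str) -> None:
        """Debug dump of the sparse matrix as (read_id, transcript_id, score)."""
        coo = self.X.tocoo()
        with open(path, "w") as fh:
            fh.write("read_id\ttranscript_id\tscore\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.read_ids[i]}\t{self.transcript_ids[j]}\t{v:.6g}\n")


def build_compatibility(
    records: Sequence[AlignmentRecord],
    index: TranscriptomeIndex,
    config: CompatConfig | None = None,
) -> CompatibilityMatrix:
    """Assemble the compatibility matrix from deduplicated alignments.

    Per read: sigma from score decay, upsilon/omega from the end filters
    (relative to the read's primary alignment), f_eta from the precomputed
    coverage weights when ``config.psw`` is on. If a read's row would be
    entirely zero under psw (all weight mass outside its alignments), the
    row is rebuilt with f_eta = 1, so no read is left unassignable.

    The coverage profile is computed once, from all deduplicated records,
    before any filtering; weights are static across EM iterations.
    """
    config = config or CompatConfig()
    if not records:
        raise ValueError("no alignment records given")

    by_read: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)

    # transcripts with >= 1 alignment, in stable index order
    aligned = {rec.transcript_id for rec in records}
    transcript_ids = [t for t in index if t in aligned]
    col_of = {t: j for j, t in enumerate(transcript_ids)}

    weights_cache: dict[str, np.ndarray | None] = {}
    profile: CoverageProfile | None = None
    if config.psw:
        profile = coverage_profile(records, index)
        for tid in transcript_ids:
            weights_cache[tid] = position_weights(profile, tid)

    read_ids = list(by_read)
    read_lengths = np.zeros(len(read_ids), dtype=np.int64)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i, rid in enumerate(read_ids):
        recs = by_read[rid]
        primaries = [r for r in recs if r.is_primary]
        if len(primaries) != 1:
            raise ValueError(
                f"read {rid!r} has {len(primaries)} primary alignments; expected 1"
            )
        primary = primaries[0]
        read_lengths[i] = primary.read_length
        sigma = score_decay(recs, config.lambda_decay)

        def row_values(use_psw: bool) -> list[tuple[int, float]]:
            out = []
            for rec in recs:
                ups, omg = end_filter_indicators(rec, primary, config, index)
                if ups == 0 or omg == 0:
                    continue
                f_eta = 1.0
                if use_psw:
                    w = weights_cache.get(rec.transcript_id)
                    f_eta = psw_factor(rec, w) if w is not None else 1.0
                x = f_eta * sigma[rec.transcript_id]
                if x > 0.0:
                    out.append((col_of[rec.transcript_id], x))
            return out

        entries = row_values(config.psw)
        if not entries and config.psw:
            # psw zero-sum fallback: drop the weights for this read only
            entries = row_values(False)
        if not entries:
            raise AssertionError(
                f"read {rid!r} lost all compatible transcripts; the primary "
                "alignment must always pass the filters (implementation bug)"
            )
        for j, x in entries:
            rows.append(i)
            cols.append(j)
            vals.append(x)

    X = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(read_ids), len(transcript_ids)),
        dtype=np.float64,
    )
    X.sort_indices()
    return CompatibilityMatrix(X, read_ids, transcript_ids, read_lengths)
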