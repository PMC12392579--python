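"""Synthetic transcriptome, reads and aligner-like records for end-to-end runs.

The generator emulates the situation the assignment problem arises from:
gene loci whose isoforms share sequence (here: a common 3' suffix with
distinct 5' extensions, the alternative-start structure typical of
multi-isoform loci), reads drawn from transcripts in proportion to a true
abundance vector, 5' truncation (3'-anchored for direct-RNA-like libraries,
uniform placement otherwise), and per-base substitution errors.

The companion "aligner" is score-faithful rather than sequence-faithful:
it derives each candidate alignment's coordinates and score from the known
read geometry (match reward x aligned length minus an error penalty per
sequencing error in the aligned portion) instead of re-running dynamic
programming. Reads falling inside a shared suffix therefore produce
multiple equally plausible records exactly as a real aligner would, while
reads extending into a unique 5' region give their origin a strictly
higher expected score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_io import AlignmentRecord
from .transcriptome import TranscriptomeIndex

__all__ = [
    "SimConfig",
    "SimRead",
    "ToyTranscriptome",
    "default_config",
    "unambiguous_config",
    "make_toy_transcriptome",
    "simulate_reads",
    "simulate_alignments",
    "simulate_dataset",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults give 50 transcripts in 10 loci with shared 3' suffixes,
    10,000 reads with 70% 3'-anchored truncation and 2% substitution
    errors; the score model mirrors minimap2's match reward of 2.
    """

    n_loci: int = 10
    isoforms_per_locus: int = 5
    unique_prefix_range: tuple[int, int] = (100, 800)
    shared_suffix_range: tuple[int, int] = (200, 400)
    n_reads: int = 10_000
    rho_true: tuple[float, ...] | None = None
    rho_concentration: float = 0.5
    three_prime_fraction: float = 0.7
    min_read_fraction: float = 0.3
    error_rate: float = 0.02
    match_reward: int = 2
    error_penalty: int = 6
    min_aln_len: int = 50
    unambiguous: bool = False
    unambiguous_margin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho_true is not None:
            total = sum(self.rho_true)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"rho_true sums to {total}, expected 1")
            if len(self.rho_true) != self.n_loci * self.isoforms_per_locus:
                raise ValueError("rho_true length must equal the transcript count")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.unique_prefix_range[0] < 1 or self.shared_suffix_range[0] < 0:
            raise ValueError("lengths must be positive")


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The standard 10,000-read / 50-transcript simulation conditions."""
    return replace(SimConfig(seed=seed), **overrides)


def unambiguous_config(seed: int = 0, **overrides) -> SimConfig:
    """Conditions under which every read is resolvable exactly.

    Error-free reads forced to extend at least ``unambiguous_margin`` bases
    into their origin's unique 5' region, so the origin's alignment score is
    strictly maximal for every read.
    """
    base = SimConfig(
        n_loci=5,
        isoforms_per_locus=3,
        n_reads=300,
        error_rate=0.0,
        unambiguous=True,
        seed=seed,
    )
    return replace(base, **overrides)


@dataclass
class ToyTranscriptome:
    """Synthetic transcriptome plus the shared-structure geometry.

    ``prefix_len[t]`` is the length of t's unique 5' region; bases from
    there to the end are the locus-wide shared suffix.
    """

    index: TranscriptomeIndex
    locus_of: dict[str, int]
    prefix_len: dict[str, int]
    shared_len: dict[int, int]

    def isoforms(self, locus: int) -> list[str]:
        return [t for t, l in self.locus_of.items() if l == locus]


@dataclass
class SimRead:
    read_id: str
    origin: str
    start: int  # interval on the origin transcript, 0-based half-open
    end: int
    sequence: str
    error_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def length(self) -> int:
        return self.end - self.start


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_toy_transcriptome(config: SimConfig) -> ToyTranscriptome:
    """Build a multi-isoform toy transcriptome, deterministic given the seed.

    Each locus has one shared 3' suffix; isoform k of a locus is a unique
    random 5' prefix joined to that suffix, so any read contained in the
    suffix is compatible with every isoform of its locus.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    locus_of: dict[str, int] = {}
    prefix_len: dict[str, int] = {}
    shared_len: dict[int, int] = {}
    for locus in range(config.n_loci):
        s_len = int(rng.integers(config.shared_suffix_range[0], config.shared_suffix_range[1] + 1))
        shared = _random_seq(rng, s_len)
        shared_len[locus] = s_len
        for k in range(config.isoforms_per_locus):
            u_len = int(rng.integers(config.unique_prefix_range[0], config.unique_prefix_range[1] + 1))
            tid = f"tx{locus:02d}.{k}"
            seq = _random_seq(rng, u_len) + shared
            lengths[tid] = len(seq)
            sequences[tid] = seq
            locus_of[tid] = locus
            prefix_len[tid] = u_len
    return ToyTranscriptome(TranscriptomeIndex(lengths, sequences), locus_of, prefix_len, shared_len)


def _true_rho(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.rho_true is not None:
        return np.asarray(config.rho_true, dtype=np.float64)
    rho = rng.dirichlet(np.full(n, config.rho_concentration))
    # Dirichlet can return exact zeros at tiny concentrations; keep support full
    rho = np.maximum(rho, 1e-6)
    return rho / rho.sum()


def simulate_reads(
    toy: ToyTranscriptome, config: SimConfig
) -> tuple[list[SimRead], dict[str, str], np.ndarray]:
    """Draw reads from transcripts with truncation and substitution errors.

    Returns (reads, truth table read_id -> origin, true rho vector). Origins
    are multinomial in the true abundances; a 3'-anchored read ends at the
    transcript's 3' end (direct-RNA-like), others are placed uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    tids = toy.index.ids
    rho_true = _true_rho(config, len(tids), rng)
    origins = rng.choice(len(tids), size=config.n_reads, p=rho_true)
    reads: list[SimRead] = []
    truth: dict[str, str] = {}
    for i, oi in enumerate(origins):
        tid = tids[int(oi)]
        L = toy.index.length(tid)
        u = toy.prefix_len[tid]
        min_len = max(config.min_aln_len, int(config.min_read_fraction * L))
        read_len = int(rng.integers(min_len, L + 1))
        if rng.random() < config.three_prime_fraction:
            start, end = L - read_len, L
        else:
            start = int(rng.integers(0, L - read_len + 1))
            end = start + read_len
        if config.unambiguous:
            # force the read to cover unique 5' sequence so scores resolve it
            anchor = max(0, u - config.unambiguous_margin)
            if start > anchor:
                start = anchor
            end = max(end, min(L, start + config.min_aln_len))
        seq = np.frombuffer(
            toy.index.sequence(tid)[start:end].encode(), dtype="S1"
        ).astype("U1")
        n_err = rng.binomial(len(seq), config.error_rate)
        err_pos = np.sort(rng.choice(len(seq), size=n_err, replace=False)) if n_err else np.empty(0, dtype=np.int64)
        for p in err_pos:
            alternatives = [b for b in "ACGT" if b != seq[p]]
            seq[p] = alternatives[int(rng.integers(0, 3))]
        rid = f"read{i:06d}"
        reads.append(SimRead(rid, tid, start, end, "".join(seq), err_pos))
        truth[rid] = tid
    return reads, truth, rho_true


def simulate_alignments(
    reads: Sequence[SimRead], toy: ToyTranscriptome, config: SimConfig
) -> list[AlignmentRecord]:
    """Aligner-like records: origin plus same-locus isoforms sharing sequence.

    The origin transcript always gets a record spanning the whole read.
    Another isoform of the same locus gets one when at least
    ``min_aln_len`` bases of the read fall inside the locus' shared suffix;
    its aligned interval is the shared portion translated onto that
    isoform's coordinates and the rest of the read is (implicitly) clipped.
    Scores are match_reward x aligned length minus error_penalty per
    simulated error inside the aligned portion, so with no errors the
    origin's score is strictly maximal whenever the read covers unique
    sequence. The max-score record is flagged primary (ties: first
    transcript id).
    """
    records: list[AlignmentRecord] = []
    for read in reads:
        origin = read.origin
        locus = toy.locus_of[origin]
        u_o = toy.prefix_len[origin]
        cands: list[AlignmentRecord] = []
        n_err_total = int(read.error_positions.size)
        score_o = config.match_reward * read.length - config.error_penalty * n_err_total
        cands.append(
            AlignmentRecord(
                read_id=read.read_id,
                transcript_id=origin,
                score=float(score_o),
                start=read.start,
                end=read.end,
                is_primary=False,
                read_length=read.length,
            )
        )
        # portion of the read inside the shared suffix, in read offsets
        shared_off = max(0, u_o - read.start)
        shared_span = read.length - shared_off
        if shared_span >= config.min_aln_len:
            p0 = max(read.start, u_o) - u_o  # shared-suffix coordinates
            p1 = read.end - u_o
            n_err_shared = int((read.error_positions >= shared_off).sum())
            for tid in toy.isoforms(locus):
                if tid == origin:
                    continue
                u2 = toy.prefix_len[tid]
                score = config.match_reward * (p1 - p0) - config.error_penalty * n_err_shared
                cands.append(
                    AlignmentRecord(
                        read_id=read.read_id,
                        transcript_id=tid,
                        score=float(score),
                        start=u2 + p0,
                        end=u2 + p1,
                        is_primary=False,
                        read_length=read.length,
                    )
                )
        best = min(range(len(cands)), key=lambda i: (-cands[i].score, cands[i].transcript_id))
        cands[best] = replace(cands[best], is_primary=True)
        records.extend(cands)
    return records


def simulate_dataset(
    config: SimConfig,
) -> tuple[ToyTranscriptome, list[SimRead], dict[str, str], np.ndarray, list[AlignmentRecord]]:
    """Transcriptome + reads + truth + true rho + alignment records, in one call."""
    toy = make_toy_transcriptome(config)
    reads, truth, rho_true = simulate_reads(toy, config)
    records = simulate_alignments(reads, toy, config)
    return toy, reads, truth, rho_true, records


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * read.length}\n")
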