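"""Transcriptomic alignment I/O: SAM/BAM/PAF parsing, per-pair dedup, aligner wrapper.

Internal coordinate convention is 0-based half-open on the transcript.
SAM's 1-based inclusive POS and PAF's native 0-based half-open target
coordinates are both converted at this boundary, so everything downstream
speaks a single convention.

Alignment scores are taken from the ``ms`` tag (minimap2's DP score of the
max-scoring segment) with ``AS`` as a fallback when ``ms`` is absent.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .transcriptome import TranscriptomeIndex

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "ParseStats",
    "parse_alignments",
    "dedupe_best_per_pair",
    "write_sam",
    "build_aligner_command",
    "run_aligner",
]

DEFAULT_N_SECONDARY = 181  # deepest annotated locus in human RefSeq


@dataclass(frozen=True)
class AlignmentRecord:
    """One read <-> transcript alignment.

    ``start``/``end`` are 0-based half-open on the transcript; ``score`` is
    the aligner's alignment score for this segment; exactly one retained
    record per read carries ``is_primary``.
    """

    read_id: str
    transcript_id: str
    score: float
    start: int
    end: int
    is_primary: bool
    read_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"read {self.read_id!r} on {self.transcript_id!r}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ParseStats:
    """Bookkeeping emitted alongside parsed records."""

    n_records: int = 0
    n_unmapped: int = 0
    n_missing_score: int = 0
    n_reverse_discarded: int = 0
    score_tag: str | None = None


def _get_score(tags: dict[str, float]) -> tuple[float | None, str | None]:
    if "ms" in tags:
        return float(tags["ms"]), "ms"
    if "AS" in tags:
        return float(tags["AS"]), "AS"
    return None, None


def parse_alignments(
    path: str | Path,
    index: TranscriptomeIndex,
    dialect: str | None = None,
    keep_reverse: bool = False,
) -> tuple[list[AlignmentRecord], ParseStats]:
    """Parse transcriptomic alignments into :class:`AlignmentRecord` objects.

    Parameters
    ----------
    path
        SAM/BAM/PAF file of reads aligned to transcript sequences.
    index
        The target transcriptome; every mapped record must reference a
        transcript in it (hard error otherwise).
    dialect
        ``"sam"``, ``"bam"`` or ``"paf"``; inferred from the suffix when
        omitted.
    keep_reverse
        Reads are expected on the sense strand of transcripts; reverse-strand
        hits are discarded (and counted) unless this is set.

    Returns
    -------
    (records, stats)
        Records in file order with 0-based half-open coordinates, plus skip
        counters. Supplementary alignments are treated as secondary. Records
        missing a score tag are skipped and counted; if *every* mapped record
        lacks one, that is a hard error.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".sam": "sam", ".bam": "bam", ".paf": "paf"}.get(suffix)
        if dialect is None:
            raise ValueError(f"cannot infer alignment dialect from {path.name!r}")
    if dialect == "paf":
        return _parse_paf(path, index, keep_reverse)
    if dialect not in ("sam", "bam"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return _parse_sam_bam(path, index, dialect, keep_reverse)


def _parse_sam_bam(
    path: Path, index: TranscriptomeIndex, dialect: str, keep_reverse: bool
) -> tuple[list[AlignmentRecord], ParseStats]:
    mode = "rb" if dialect == "bam" else "r"
    stats = ParseStats()
    records: list[AlignmentRecord] = []
    n_mapped = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            stats.n_records += 1
            if aln.is_unmapped:
                stats.n_unmapped += 1
                continue
            n_mapped += 1
            tid = aln.reference_name
            if tid not in index:
                raise ValueError(
                    f"alignment of read {aln.query_name!r} references unknown "
                    f"transcript {tid!r} (record {stats.n_records} in {path.name})"
                )
            tags = dict(aln.get_tags())
            score, tag = _get_score(tags)
            if score is None:
                stats.n_missing_score += 1
                continue
            if stats.score_tag is None:
                stats.score_tag = tag
                logger.info("using %s tag for alignment scores", tag)
            if aln.is_reverse and not keep_reverse:
                stats.n_reverse_discarded += 1
                continue
            start = aln.reference_start  # pysam is already 0-based
            end = aln.reference_end  # exclusive (POS + reference span)
            if end is None or end > index.length(tid):
                raise ValueError(
                    f"alignment of read {aln.query_name!r} exceeds transcript "
                    f"{tid!r} length {index.length(tid)}"
                )
            read_len = aln.infer_read_length() or aln.query_length
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    transcript_id=tid,
                    score=score,
                    start=start,
                    end=end,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                    read_length=int(read_len or 0),
                    strand="-" if aln.is_reverse else "+",
                )
            )
    if n_mapped > 0 and stats.n_missing_score == n_mapped:
        raise ValueError(f"no record in {path.name} carries an ms/AS score tag")
    if stats.n_missing_score:
        logger.warning("%d records without ms/AS tag skipped", stats.n_missing_score)
    return records, stats


def _parse_paf(
    path: Path, index: TranscriptomeIndex, keep_reverse: bool
) -> tuple[list[AlignmentRecord], ParseStats]:
    stats = ParseStats()
    records: list[AlignmentRecord] = []
    n_mapped = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path.name}:{line_no}: PAF line has <12 columns")
            stats.n_records += 1
            tid = fields[5]
            if tid == "*":
                stats.n_unmapped += 1
                continue
            n_mapped += 1
            if tid not in index:
                raise ValueError(
                    f"{path.name}:{line_no}: unknown transcript {tid!r} "
                    f"for read {fields[0]!r}"
                )
            tags: dict[str, float] = {}
            is_primary = True
            for tag in fields[12:]:
                name, typ, value = tag.split(":", 2)
                if name in ("ms", "AS") and typ in ("i", "f"):
                    tags[name] = float(value)
                elif name == "tp" and typ == "A":
                    is_primary = value == "P"
            score, tag_used = _get_score(tags)
            if score is None:
                stats.n_missing_score += 1
                continue
            if stats.score_tag is None:
                stats.score_tag = tag_used
            strand = fields[4]
            if strand == "-" and not keep_reverse:
                stats.n_reverse_discarded += 1
                continue
            start, end = int(fields[7]), int(fields[8])  # already 0-based half-open
            if end > index.length(tid):
                raise ValueError(
                    f"{path.name}:{line_no}: interval [{start},{end}) exceeds "
                    f"transcript {tid!r} length {index.length(tid)}"
                )
            records.append(
                AlignmentRecord(
                    read_id=fields[0],
                    transcript_id=tid,
                    score=score,
                    start=start,
                    end=end,
                    is_primary=is_primary,
                    read_length=int(fields[1]),
                    strand=strand,
                )
            )
    if n_mapped > 0 and stats.n_missing_score == n_mapped:
        raise ValueError(f"no record in {path.name} carries an ms/AS score tag")
    return records, stats


def dedupe_best_per_pair(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep, per (read, transcript) pair, only the maximum-score alignment.

    Ties break deterministically on smaller start, then smaller end. After
    dedup, any read whose primary record was eliminated has its best
    surviving record promoted to primary, so the "exactly one primary per
    read" invariant holds for the retained set.
    """
    best: dict[tuple[str, str], AlignmentRecord] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.read_id, rec.transcript_id)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            order.append(key)
        elif (-rec.score, rec.start, rec.end) < (-cur.score, cur.start, cur.end):
            # keep the primary flag if either candidate carried it
            if cur.is_primary and not rec.is_primary:
                rec = replace(rec, is_primary=False)
            best[key] = rec
    out = [best[k] for k in order]
    return _repair_primaries(out)


def _repair_primaries(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Guarantee exactly one primary per read (promote/demote as needed)."""
    by_read: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_read.setdefault(rec.read_id, []).append(i)
    for idxs in by_read.values():
        primaries = [i for i in idxs if records[i].is_primary]
        if len(primaries) == 1:
            continue
        # pick best by (score desc, start, end, transcript id) deterministically
        winner = min(
            idxs,
            key=lambda i: (
                -records[i].score,
                records[i].start,
                records[i].end,
                records[i].transcript_id,
            ),
        )
        for i in idxs:
            if records[i].is_primary != (i == winner):
                records[i] = replace(records[i], is_primary=(i == winner))
    return records


def write_sam(
    records: Sequence[AlignmentRecord],
    index: TranscriptomeIndex,
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write records as a SAM file against the index's transcripts.

    Round-trips (read_id, transcript_id, start, end, score, is_primary,
    read_length) through :func:`parse_alignments`. When a read is longer
    than its aligned span, the surplus is written as a leading soft clip so
    the read length is recoverable from the CIGAR. Scores go to ``ms:i``.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": tid, "LN": index.length(tid)} for tid in index],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = index.index_of(rec.transcript_id)
            a.reference_start = rec.start
            a.mapping_quality = 60 if rec.is_primary else 0
            flag = 0
            if not rec.is_primary:
                flag |= 0x100
            if rec.strand == "-":
                flag |= 0x10
            a.flag = flag
            span = rec.span
            clip = max(0, rec.read_length - span)
            cigar = ([(4, clip)] if clip else []) + [(0, span)]
            a.cigartuples = cigar
            if sequences is not None and rec.read_id in sequences:
                seq = sequences[rec.read_id]
                if len(seq) == clip + span:
                    a.query_sequence = seq
            a.set_tag("ms", int(round(rec.score)), "i")
            out.write(a)


def build_aligner_command(
    reads: str | Path,
    transcriptome: str | Path,
    out_path: str | Path,
    n_secondary: int = DEFAULT_N_SECONDARY,
    preset: str = "map-ont",
    extra_args: Sequence[str] = (),
) -> list[str]:
    """Construct the minimap2 invocation for non-spliced transcriptomic alignment."""
    if n_secondary < 0:
        raise ValueError("n_secondary must be >= 0")
    return [
        "minimap2",
        "-a",
        "-x",
        preset,
        "-N",
        str(n_secondary),
        *extra_args,
        "-o",
        str(out_path),
        str(transcriptome),
        str(reads),
    ]


def run_aligner(
    reads: str | Path,
    transcriptome: str | Path,
    out_path: str | Path,
    n_secondary: int = DEFAULT_N_SECONDARY,
    preset: str = "map-ont",
    extra_args: Sequence[str] = (),
) -> Path:
    """Align reads to the transcriptome with minimap2 (``-N`` secondaries).

    Raises an actionable error when minimap2 is not installed; in that case
    supply a precomputed SAM/BAM/PAF to :func:`parse_alignments` instead.
    """
    if shutil.which("minimap2") is None:
        raise RuntimeError(
            "minimap2 not found on PATH; install it or supply precomputed "
            "alignments (SAM/BAM/PAF with ms/AS score tags) instead"
        )
    cmd = build_aligner_command(reads, transcriptome, out_path, n_secondary, preset, extra_args)
    logger.info("running: %s", " ".join(cmd))
    subprocess.run(cmd, check=True)
    return Path(out_path)
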