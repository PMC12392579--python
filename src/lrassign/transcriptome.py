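"""Transcriptome index: the set of target transcripts all reads are assigned to.

A :class:`TranscriptomeIndex` maps transcript identifiers to their lengths
(and optionally sequences) and fixes a stable integer index per transcript,
which downstream sparse matrices use as column coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

__all__ = ["TranscriptomeIndex"]


@dataclass
class TranscriptomeIndex:
    """Transcript identifiers, lengths, and a stable 0-based integer ordering.

    Parameters
    ----------
    lengths
        Mapping transcript_id -> length in nucleotides (>= 1). Insertion
        order defines the integer index of each transcript.
    sequences
        Optional mapping transcript_id -> nucleotide sequence. When given,
        ``len(sequences[t]) == lengths[t]`` must hold.
    """

    lengths: dict[str, int]
    sequences: dict[str, str] | None = None
    _order: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for tid, length in self.lengths.items():
            if length < 1:
                raise ValueError(f"transcript {tid!r} has non-positive length {length}")
        if self.sequences is not None:
            for tid, seq in self.sequences.items():
                if tid not in self.lengths:
                    raise ValueError(f"sequence for unknown transcript {tid!r}")
                if len(seq) != self.lengths[tid]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{self.lengths[tid]} for transcript {tid!r}"
                    )
        self._order = {tid: i for i, tid in enumerate(self.lengths)}

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self.lengths)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    @property
    def ids(self) -> list[str]:
        return list(self.lengths)

    def length(self, transcript_id: str) -> int:
        return self.lengths[transcript_id]

    def index_of(self, transcript_id: str) -> int:
        return self._order[transcript_id]

    def sequence(self, transcript_id: str) -> str:
        if self.sequences is None:
            raise ValueError("index was built without sequences")
        return self.sequences[transcript_id]

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path, keep_sequences: bool = True) -> "TranscriptomeIndex":
        """Build an index from a transcript FASTA (lengths from sequences)."""
        lengths: dict[str, int] = {}
        sequences: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in lengths:
                raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
            lengths[rec.id] = len(rec.seq)
            if keep_sequences:
                sequences[rec.id] = str(rec.seq).upper()
        if not lengths:
            raise ValueError(f"no sequences found in {path}")
        return cls(lengths, sequences if keep_sequences else None)

    @classmethod
    def from_gtf(cls, gtf_path: str | Path, fasta_path: str | Path) -> "TranscriptomeIndex":
        """Build an index from a GTF annotation plus a transcript FASTA.

        The GTF restricts and orders the transcript set; lengths and
        sequences come from the FASTA (transcript coordinates, not genomic).
        Exon lines are used to recover transcript ids; a transcript present
        in the GTF but absent from the FASTA is an error.
        """
        import gffutils

        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
        wanted: list[str] = []
        seen: set[str] = set()
        for feat in db.all_features():
            tid = feat.attributes.get("transcript_id", [None])[0]
            if tid is not None and tid not in seen:
                seen.add(tid)
                wanted.append(tid)
        full = cls.from_fasta(fasta_path)
        missing = [t for t in wanted if t not in full]
        if missing:
            raise ValueError(f"transcripts in GTF but not in FASTA: {missing[:5]}")
        lengths = {t: full.lengths[t] for t in wanted}
        seqs = {t: full.sequences[t] for t in wanted} if full.sequences else None
        return cls(lengths, seqs)

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        if self.sequences is None:
            raise ValueError("index holds no sequences to write")
        with open(path, "w") as fh:
            for tid in self.lengths:
                fh.write(f">{tid}\n")
                seq = self.sequences[tid]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def as_mapping(self) -> Mapping[str, int]:
        return dict(self.lengths)
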