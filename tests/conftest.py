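import numpy as np
import pytest

from lrassign.alignment_io import AlignmentRecord
from lrassign.transcriptome import TranscriptomeIndex


@pytest.fixture
def toy_index() -> TranscriptomeIndex:
    return TranscriptomeIndex({"t1": 1000, "t2": 800, "t3": 500})


def make_record(
    read_id="r1",
    transcript_id="t1",
    score=900.0,
    start=0,
    end=100,
    is_primary=True,
    read_length=None,
):
    return AlignmentRecord(
        read_id=read_id,
        transcript_id=transcript_id,
        score=score,
        start=start,
        end=end,
        is_primary=is_primary,
        read_length=read_length if read_length is not None else end - start,
    )


@pytest.fixture
def record_factory():
    return make_record


def random_records(seed: int, index: TranscriptomeIndex, n_reads: int = 15):
    """Random deduplicated records with exactly one primary per read."""
    rng = np.random.default_rng(seed)
    tids = index.ids
    records = []
    for i in range(n_reads):
        chosen = rng.choice(len(tids), size=int(rng.integers(1, len(tids) + 1)), replace=False)
        scores = rng.integers(500, 1000, size=len(chosen))
        best = int(np.argmax(scores))
        for k, j in enumerate(chosen):
            tid = tids[int(j)]
            L = index.length(tid)
            start = int(rng.integers(0, L - 50))
            end = int(rng.integers(start + 50, L + 1))
            records.append(
                make_record(
                    read_id=f"r{i}",
                    transcript_id=tid,
                    score=float(scores[k]),
                    start=start,
                    end=end,
                    is_primary=(k == best),
                    read_length=end - start,
                )
            )
    return records


@pytest.fixture
def random_record_factory(toy_index):
    return lambda seed, n_reads=15: random_records(seed, toy_index, n_reads)
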