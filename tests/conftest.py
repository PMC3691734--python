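"""Shared fixtures: small random transcriptomes and read factories."""

import numpy as np
import pytest

BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_transcriptome(rng):
    """20 random 2 kb transcripts, one gene each."""
    seqs = {f"t{i}": random_seq(rng, 2000) for i in range(20)}
    genes = {tid: tid.replace("t", "g") for tid in seqs}
    return seqs, genes


def brute_force_hits(seqs: dict, query: str, max_mm: int):
    """Exhaustive Hamming-scan placements of a query on both strands.

    Independent oracle for the seeded aligner: slides the query (and its
    reverse complement) across every offset of every transcript.
    """
    from fusionq._seq import revcomp

    hits = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        qa = np.frombuffer(q.encode(), dtype="S1")
        for tid, seq in seqs.items():
            if len(seq) < len(q):
                continue
            sa = np.frombuffer(seq.encode(), dtype="S1")
            windows = np.lib.stride_tricks.sliding_window_view(sa, len(q))
            mm = (windows != qa).sum(axis=1)
            # N never matches anything, including N vs N:
            mm = mm + ((windows == b"N") & (qa == b"N")).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                hits.add((tid, int(pos), strand, int(mm[pos])))
    return hits
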