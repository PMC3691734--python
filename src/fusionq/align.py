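"""Seeded transcriptome alignment, pair classification, insert modelling.

A k-mer index over the forward strand of every transcript answers
substitution-only alignment queries for both strands.  Seeding uses
non-overlapping k-mer windows: a query of length L carries
``floor(L / k)`` windows, so every placement with at most
``floor(L / k) - 1`` mismatches is guaranteed to be found (pigeonhole).
With the defaults (k = 12) that covers full 50 bp reads at <= 3 mismatches
and 25 bp half-reads at <= 1 — both stricter than the configured caps.

Pair classification follows transcript-space geometry: a pair is
concordant when some hit pair shares a transcript with proper forward /
reverse-complement orientation and an implied fragment length within
``mean +/- insert_sd_multiplier * sd`` of the insert model; discordant
gene pairs become spanning evidence; a pair with exactly one mapped end
nominates its unmapped end as a candidate split read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping, Sequence

from ._seq import revcomp
from .formats import ReadPair

log = logging.getLogger(__name__)

DEFAULT_INSERT_PRIOR = (164.0, 48.0)


@dataclass(frozen=True)
class AlignmentHit:
    """One placement of a query on a transcript.

    ``position`` is the 0-based offset of the query's first base on the
    transcript's forward strand; for a reverse-complement hit the query's
    reverse complement starts there.
    """

    transcript_id: str
    position: int
    strand: Literal["+", "-"]
    mismatches: int


@dataclass
class InsertModel:
    """Empirical normal model of the cDNA fragment (mate-pair) length."""

    mean: float
    sd: float
    n_observations: int = 0

    @classmethod
    def prior(cls) -> "InsertModel":
        return cls(*DEFAULT_INSERT_PRIOR, n_observations=0)


PairLabel = Literal["concordant", "spanning", "one_end_unmapped", "both_unmapped"]


@dataclass
class PairClass:
    """Classification of one read pair with its supporting alignments.

    ``evidence`` holds (end1_hit, end2_hit) tuples for concordant/spanning
    labels; for ``one_end_unmapped`` it holds the mapped end's hits.
    """

    label: PairLabel
    evidence: list = field(default_factory=list)
    unmapped_end: int | None = None  # 1 or 2 for one_end_unmapped


def _mismatch_count(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit past ``limit``; N matches nothing."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


class TranscriptIndex:
    """Exact k-mer index of transcript forward strands.

    Postings map each k-mer to ``(transcript_id, offset)`` pairs.  Reverse
    strand queries are handled by reverse-complementing the query, never
    the index.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 12):
        if k < 4:
            raise ValueError("k must be at least 4")
        self.k = k
        self.sequences = dict(sequences)
        index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.sequences.items():
            for off in range(len(seq) - k + 1):
                index.setdefault(seq[off : off + k], []).append((tid, off))
        self._index = index

    def postings(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])

    def _candidates(self, seq: str) -> set[tuple[str, int]]:
        """Candidate (transcript, query-start) placements via seeding."""
        k, n = self.k, len(seq)
        offsets = list(range(0, n - k + 1, k))
        if offsets and offsets[-1] != n - k:
            offsets.append(n - k)  # tail window for lengths not divisible by k
        cands: set[tuple[str, int]] = set()
        for off in offsets:
            for tid, tpos in self._index.get(seq[off : off + k], ()):
                start = tpos - off
                if start >= 0 and start + n <= len(self.sequences[tid]):
                    cands.add((tid, start))
        return cands

    def align(self, seq: str, max_mismatch: int) -> list[AlignmentHit]:
        """All placements of ``seq`` on both strands with <= ``max_mismatch``
        substitutions.  Complete whenever the true placement contains at
        least one exact seed window (guaranteed up to
        ``floor(len(seq)/k) - 1`` mismatches)."""
        if len(seq) < self.k:
            return []
        hits: list[AlignmentHit] = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for tid, start in sorted(self._candidates(query)):
                mm = _mismatch_count(
                    query, self.sequences[tid][start : start + len(query)], max_mismatch
                )
                if mm <= max_mismatch:
                    hits.append(AlignmentHit(tid, start, strand, mm))
        return hits


def concordant_placements(
    hits1: Sequence[AlignmentHit],
    hits2: Sequence[AlignmentHit],
    len1: int,
    len2: int,
    insert: InsertModel,
    sd_multiplier: float = 3.0,
) -> list[tuple[AlignmentHit, AlignmentHit, int]]:
    """Hit pairs on a shared transcript in proper FR orientation whose
    implied fragment length falls within ``mean +/- sd_multiplier*sd``.

    Returns ``(hit1, hit2, fragment_length)`` triples.
    """
    lo = insert.mean - sd_multiplier * insert.sd
    hi = insert.mean + sd_multiplier * insert.sd
    out = []
    for h1 in hits1:
        for h2 in hits2:
            if h1.transcript_id != h2.transcript_id or h1.strand == h2.strand:
                continue
            fwd, rc = (h1, h2) if h1.strand == "+" else (h2, h1)
            rc_len = len2 if rc is h2 else len1
            frag = rc.position + rc_len - fwd.position
            if frag >= max(len1, len2) and lo <= frag <= hi:
                out.append((h1, h2, frag))
    return out


def classify_pair(
    pair: ReadPair,
    hits1: Sequence[AlignmentHit],
    hits2: Sequence[AlignmentHit],
    insert: InsertModel,
    gene_of: Mapping[str, str],
    index: TranscriptIndex | None = None,
    max_mismatch_seed: int = 1,
    sd_multiplier: float = 3.0,
) -> PairClass:
    """Label a read pair as concordant / spanning / one_end_unmapped /
    both_unmapped.

    Concordance takes precedence.  Spanning requires some hit pair mapping
    the two ends to *different genes* with opposite strands.  When neither
    full end maps and an ``index`` is supplied, both ends are halved and a
    half-read hit pair to different genes still counts as spanning (the
    half-read rescue).  A pair with exactly one unmapped end nominates that
    end as a candidate split read.
    """
    conc = concordant_placements(
        hits1, hits2, len(pair.end1_seq), len(pair.end2_seq), insert, sd_multiplier
    )
    if conc:
        return PairClass("concordant", [(h1, h2) for h1, h2, _ in conc])

    spanning = [
        (h1, h2)
        for h1 in hits1
        for h2 in hits2
        if gene_of[h1.transcript_id] != gene_of[h2.transcript_id]
        and h1.strand != h2.strand
    ]
    if spanning:
        return PairClass("spanning", spanning)

    if hits1 and not hits2:
        return PairClass("one_end_unmapped", list(hits1), unmapped_end=2)
    if hits2 and not hits1:
        return PairClass("one_end_unmapped", list(hits2), unmapped_end=1)
    if hits1 and hits2:
        # Both map but only within one gene in incompatible geometry;
        # treat as unusable for fusion evidence.
        return PairClass("both_unmapped")

    if index is not None:
        rescued = _half_read_rescue(pair, index, gene_of, max_mismatch_seed)
        if rescued:
            return PairClass("spanning", rescued)
    return PairClass("both_unmapped")


def _half_read_rescue(
    pair: ReadPair,
    index: TranscriptIndex,
    gene_of: Mapping[str, str],
    max_mismatch_seed: int,
) -> list[tuple[AlignmentHit, AlignmentHit]]:
    halves1 = _halves(pair.end1_seq)
    halves2 = _halves(pair.end2_seq)
    hits1 = [h for half in halves1 for h in index.align(half, max_mismatch_seed)]
    hits2 = [h for half in halves2 for h in index.align(half, max_mismatch_seed)]
    return [
        (h1, h2)
        for h1 in hits1
        for h2 in hits2
        if gene_of[h1.transcript_id] != gene_of[h2.transcript_id]
        and h1.strand != h2.strand
    ]


def _halves(seq: str) -> tuple[str, str]:
    mid = len(seq) // 2
    return seq[:mid], seq[mid:]


def remove_duplicates(pairs: Iterable[ReadPair]) -> Iterator[ReadPair]:
    """Drop exact PCR duplicates, keeping the first pair of each
    ``(end1_seq, end2_seq)`` tuple; order is otherwise preserved."""
    seen: set[tuple[str, str]] = set()
    for pair in pairs:
        key = (pair.end1_seq, pair.end2_seq)
        if key not in seen:
            seen.add(key)
            yield pair


def estimate_insert_model(
    fragment_lengths: Sequence[float],
    prior: tuple[float, float] = DEFAULT_INSERT_PRIOR,
) -> InsertModel:
    """Mean and sample SD of observed concordant fragment lengths.

    With fewer than two observations the configured prior is returned with
    a logged warning.
    """
    n = len(fragment_lengths)
    if n < 2:
        log.warning(
            "only %d concordant fragment(s); falling back to prior insert model %s",
            n,
            prior,
        )
        return InsertModel(prior[0], prior[1], n_observations=n)
    mean = sum(fragment_lengths) / n
    var = sum((x - mean) ** 2 for x in fragment_lengths) / (n - 1)
    return InsertModel(mean, math.sqrt(var), n_observations=n)
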