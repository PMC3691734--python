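"""False-positive filters and candidate ranking.

Three filters run after candidate assembly, in this order:

1. *Read-number filter* — minimum split reads, spanning pairs, and total
   supporting reads.
2. *Similarity filter* — Smith-Waterman local alignment between the
   partner isoforms; paralog pairs whose similarity exceeds 50% are
   discarded as likely misalignment artifacts.
3. *Distribution filter* — a two-sample Kolmogorov-Smirnov test compares
   each side's spanning-read positions against pooled "background
   positions" from ordinary transcripts; a fusion whose p-value falls
   below the empirical low quantile of a null p-value distribution (built
   from the background transcripts themselves) is discarded.

Each filter is a pure predicate on the candidate, so keep/discard
decisions are order-independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from scipy import stats

from .detect import FusionCandidate

log = logging.getLogger(__name__)


@dataclass
class FilterThresholds:
    """Filter settings.  Defaults mirror a conservative short-read run:
    more than one split read and one spanning pair, more than three
    supporting reads in total, 50% partner similarity cap, and a 0.025
    significance level for the position-distribution test."""

    min_split: int = 2
    min_span: int = 2
    min_total: int = 4
    similarity_max: float = 0.50
    ks_alpha: float = 0.025
    n_background_transcripts: int = 200

    def __post_init__(self) -> None:
        if min(self.min_split, self.min_span, self.min_total) < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0.0 <= self.similarity_max <= 1.0:
            raise ValueError("similarity_max must lie in [0, 1]")
        if not 0.0 < self.ks_alpha < 0.5:
            raise ValueError("ks_alpha must lie in (0, 0.5)")


@dataclass
class BackgroundPositions:
    """Pooled, length-normalised read start positions from ordinary
    transcripts — the reference distribution for the K-S filter."""

    positions: np.ndarray
    source_count: int


@dataclass
class PValueNull:
    """Empirical null distribution of K-S p-values for real transcripts."""

    pvalues: np.ndarray

    def low_quantile(self, alpha: float) -> float:
        return float(np.quantile(self.pvalues, alpha))


def read_number_filter(
    candidates: Sequence[FusionCandidate], thresholds: FilterThresholds
) -> list[FusionCandidate]:
    """Keep candidates with ``n_split >= min_split``, ``n_span >= min_span``
    and ``n_split + n_span >= min_total``."""
    kept = [
        c
        for c in candidates
        if c.n_split >= thresholds.min_split
        and c.n_span >= thresholds.min_span
        and c.n_split + c.n_span >= thresholds.min_total
    ]
    log.info("read-number filter: %d -> %d candidates", len(candidates), len(kept))
    return kept


_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=5.0,
    mismatch_score=-4.0,
    open_gap_score=-10.5,
    extend_gap_score=-0.5,
)


def local_alignment_score(seq_a: str, seq_b: str) -> float:
    """Smith-Waterman local alignment score (match +5, mismatch -4, gap of
    length L costs 10 + 0.5*L)."""
    return float(_ALIGNER.score(seq_a, seq_b))


def pairwise_similarity(seq_a: str, seq_b: str) -> float:
    """Sequence similarity between two transcripts in [0, 1].

    The best local alignment is computed under the scoring above;
    similarity is the number of identical aligned positions divided by
    ``max(alignment_length, min(len_a, len_b))``.  The denominator floor
    keeps a short perfect repeat inside two long, otherwise unrelated
    sequences from dominating: only alignments covering most of the
    shorter sequence can approach 1.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    aln_len = counts.gaps + counts.identities + counts.mismatches
    denom = max(aln_len, min(len(seq_a), len(seq_b)))
    return counts.identities / denom if denom else 0.0


def similarity_filter(
    candidates: Sequence[FusionCandidate],
    sequences_by_gene: Mapping[str, Sequence[tuple[str, str]]],
    thresholds: FilterThresholds,
) -> list[FusionCandidate]:
    """Discard candidates whose partner isoforms exceed ``similarity_max``
    (strictly).  The maximum over all reported isoform pairs is stored on
    the candidate.  Candidates with a missing partner sequence are kept
    and flagged with NaN similarity."""
    kept = []
    for cand in candidates:
        isos5 = sequences_by_gene.get(cand.gene5, [])
        isos3 = sequences_by_gene.get(cand.gene3, [])
        if not isos5 or not isos3:
            log.warning(
                "similarity filter: missing partner sequence for %s-%s; kept",
                cand.gene5,
                cand.gene3,
            )
            cand.similarity = float("nan")
            kept.append(cand)
            continue
        cand.similarity = max(
            pairwise_similarity(s5, s3) for _, s5 in isos5 for _, s3 in isos3
        )
        if cand.similarity <= thresholds.similarity_max:
            kept.append(cand)
    log.info("similarity filter: %d -> %d candidates", len(candidates), len(kept))
    return kept


def build_background(
    positions_by_transcript: Mapping[str, Sequence[float]],
    transcript_lengths: Mapping[str, int],
    n: int,
    rng_seed: int = 0,
    min_reads: int = 5,
) -> tuple[BackgroundPositions, PValueNull]:
    """Sample ``n`` well-covered transcripts, pool their length-normalised
    read start positions, and record each sampled transcript's own K-S
    p-value against the pool (itself excluded) as the empirical p-value
    null.  Deterministic under a fixed seed."""
    eligible = sorted(
        tid
        for tid, pos in positions_by_transcript.items()
        if len(pos) >= min_reads
    )
    rng = np.random.default_rng(rng_seed)
    if len(eligible) < n:
        log.info(
            "only %d transcripts with >= %d mapped pairs (requested %d); using all",
            len(eligible),
            min_reads,
            n,
        )
        sampled = eligible
    else:
        sampled = sorted(rng.choice(eligible, size=n, replace=False).tolist())
    per_tid = {
        tid: np.asarray(positions_by_transcript[tid], dtype=float)
        / transcript_lengths[tid]
        for tid in sampled
    }
    pooled = (
        np.concatenate(list(per_tid.values())) if per_tid else np.empty(0)
    )
    pvalues = []
    offset = 0
    for tid in sampled:
        own = per_tid[tid]
        others = np.concatenate([pooled[:offset], pooled[offset + len(own) :]])
        if len(own) >= 2 and len(others) >= 2:
            pvalues.append(stats.ks_2samp(own, others).pvalue)
        offset += len(own)
    if len(sampled) < 2:
        log.warning("background built from %d transcript(s); K-S filter degenerate", len(sampled))
    return (
        BackgroundPositions(positions=pooled, source_count=len(sampled)),
        PValueNull(pvalues=np.asarray(pvalues)),
    )


def distribution_filter(
    positions5: Sequence[float],
    positions3: Sequence[float],
    background: BackgroundPositions,
    null: PValueNull,
    thresholds: FilterThresholds,
) -> tuple[bool, float, float]:
    """K-S test each side's normalised spanning-read positions against the
    background pool.

    Returns ``(keep, p5, p3)``.  Discard when either p-value falls below
    the empirical ``ks_alpha`` quantile of the p-value null.  With fewer
    than two positions on a side (or a degenerate background) the filter
    abstains on that side and keeps the candidate.
    """
    if len(background.positions) < 2 or len(null.pvalues) < 2:
        return True, float("nan"), float("nan")
    threshold = null.low_quantile(thresholds.ks_alpha)
    ps = []
    for pos in (positions5, positions3):
        if len(pos) < 2:
            ps.append(float("nan"))
        else:
            ps.append(float(stats.ks_2samp(np.asarray(pos, float), background.positions).pvalue))
    keep = all(math.isnan(p) or p >= threshold for p in ps)
    return keep, ps[0], ps[1]


def score_candidate(candidate: FusionCandidate) -> float:
    """Ranking score: ``log2(1 + n_split) + log2(1 + n_span) + min(p5, p3)``.

    Monotone in each component; used only to order the report.  Sides
    where the distribution filter abstained contribute no p-value term.
    """
    ps = [p for p in (candidate.ks_p5, candidate.ks_p3) if not math.isnan(p)]
    p_term = min(ps) if ps else 0.0
    return math.log2(1 + candidate.n_split) + math.log2(1 + candidate.n_span) + p_term
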