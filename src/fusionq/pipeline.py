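"""End-to-end orchestration: dedup -> align -> classify -> detect ->
filter -> quantify -> report, plus the evaluation utilities.

Every stage logs its candidate counts.  The run is deterministic for a
fixed configuration and seed: the only stochastic step (background
transcript sampling for the distribution filter) draws from a seeded
generator, and all reductions iterate in insertion order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import (
    InsertModel,
    PairClass,
    TranscriptIndex,
    classify_pair,
    concordant_placements,
    estimate_insert_model,
    remove_duplicates,
)
from .detect import (
    BreakpointCall,
    DetectConfig,
    FusionCandidate,
    assemble_candidates,
    canonicalize_junction,
    construct_chimeric_structures,
    detect_split_read,
)
from .filters import (
    FilterThresholds,
    build_background,
    distribution_filter,
    read_number_filter,
    score_candidate,
    similarity_filter,
)
from .formats import (
    FusionRecord,
    ReadPair,
    Transcript,
    read_fasta,
    read_fastq_pairs,
    read_gtf,
    write_fusion_report,
)
from .quantify import (
    FragmentAlignment,
    build_quant_model,
    expression_filter,
    run_em,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, outputs, and every module's knobs for one run."""

    transcripts_fasta: str | Path
    annotation_gtf: str | Path
    reads1: str | Path
    reads2: str | Path
    out_dir: str | Path
    k: int = 12
    max_mismatch_read: int = 2
    insert_sd_multiplier: float = 3.0
    detect: DetectConfig = field(default_factory=DetectConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    lam: float = 1.0
    em_tol: float = 1e-6
    em_max_iter: int = 1000
    expression_epsilon: float | None = None
    seed: int = 0
    threads: int = 1


@dataclass
class EvalResult:
    """Detection quality against a truth manifest.

    ``specificity`` keeps the precision-like definition used in fusion
    benchmarking: true detected / all detected.
    """

    sensitivity: float
    specificity: float
    n_true: int
    n_detected: int
    n_matched: int
    n_breakpoint_exact: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def breakpoint_exact_rate(self) -> float:
        return self.n_breakpoint_exact / self.n_detected if self.n_detected else 0.0


def run_pipeline(config: PipelineConfig) -> list[FusionRecord]:
    """Execute the full detection and quantification pipeline and write
    ``fusions.tsv`` into the output directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    transcripts = read_gtf(config.annotation_gtf, dict(read_fasta(config.transcripts_fasta)))
    sequences = {t.transcript_id: t.sequence for t in transcripts}
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    by_gene: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    index = TranscriptIndex(sequences, k=config.k)

    pairs = list(remove_duplicates(read_fastq_pairs(config.reads1, config.reads2)))
    log.info("deduplicated input: %d pairs", len(pairs))
    if not pairs:
        write_fusion_report([], out_dir / "fusions.tsv")
        return []
    read_len = len(pairs[0].end1_seq)

    hits = [
        (
            index.align(p.end1_seq, config.max_mismatch_read),
            index.align(p.end2_seq, config.max_mismatch_read),
        )
        for p in pairs
    ]

    # Insert model from a first classification pass under the prior.
    prior = InsertModel.prior()
    frag_lens = []
    for p, (h1, h2) in zip(pairs, hits):
        for _, _, frag in concordant_placements(
            h1, h2, len(p.end1_seq), len(p.end2_seq), prior, config.insert_sd_multiplier
        ):
            frag_lens.append(frag)
            break
    insert = estimate_insert_model(frag_lens)
    log.info(
        "insert model: mean %.1f sd %.1f from %d concordant pairs",
        insert.mean,
        insert.sd,
        insert.n_observations,
    )

    classes: list[PairClass] = [
        classify_pair(
            p,
            h1,
            h2,
            insert,
            gene_of,
            index=index,
            max_mismatch_seed=config.detect.max_mismatch_seed,
            sd_multiplier=config.insert_sd_multiplier,
        )
        for p, (h1, h2) in zip(pairs, hits)
    ]
    n_by_label: dict[str, int] = {}
    for c in classes:
        n_by_label[c.label] = n_by_label.get(c.label, 0) + 1
    log.info("pair classes: %s", n_by_label)

    # Background position pool from concordant pairs (forward end start).
    positions_by_tid: dict[str, list[int]] = {}
    for p, (h1, h2), cls in zip(pairs, hits, classes):
        if cls.label != "concordant":
            continue
        e1, e2 = cls.evidence[0]
        fwd = e1 if e1.strand == "+" else e2
        positions_by_tid.setdefault(fwd.transcript_id, []).append(fwd.position)

    # Unmapped pool for residual sequence extension: non-candidate unmapped
    # ends (both orientations of both ends of both_unmapped pairs).
    unmapped_pool: list[str] = []
    for p, cls in zip(pairs, classes):
        if cls.label == "both_unmapped":
            unmapped_pool.extend((p.end1_seq, p.end2_seq))

    calls: list[BreakpointCall] = []
    for p, (h1, h2), cls in zip(pairs, hits, classes):
        if cls.label != "one_end_unmapped":
            continue
        if cls.unmapped_end == 2:
            candidate_seq, mate_hits = p.end2_seq, h1
        else:
            candidate_seq, mate_hits = p.end1_seq, h2
        mate_genes = frozenset(gene_of[h.transcript_id] for h in mate_hits)
        calls.extend(
            detect_split_read(
                f"{p.pair_id}/{cls.unmapped_end}",
                candidate_seq,
                index,
                gene_of,
                unmapped_pool,
                mate_genes,
                config.detect,
            )
        )
    log.info("breakpoint calls: %d", len(calls))

    spanning = [c for c in classes if c.label == "spanning"]
    candidates = assemble_candidates(
        calls,
        spanning,
        sequences,
        gene_of,
        insert,
        read_len,
        config.detect,
        config.insert_sd_multiplier,
    )
    log.info("assembled candidates: %d", len(candidates))

    candidates = read_number_filter(candidates, config.thresholds)

    seqs_by_gene = {
        g: [(t.transcript_id, t.sequence) for t in ts] for g, ts in by_gene.items()
    }
    candidates = similarity_filter(candidates, seqs_by_gene, config.thresholds)

    background, null = build_background(
        positions_by_tid,
        {tid: len(seq) for tid, seq in sequences.items()},
        config.thresholds.n_background_transcripts,
        rng_seed=config.seed,
    )
    survivors = []
    for cand in candidates:
        pos5, pos3 = spanning_side_positions(cand, read_len, insert)
        keep, p5, p3 = distribution_filter(
            pos5, pos3, background, null, config.thresholds
        )
        cand.ks_p5, cand.ks_p3 = p5, p3
        if keep:
            survivors.append(cand)
    log.info("distribution filter: %d -> %d candidates", len(candidates), len(survivors))
    candidates = survivors

    for cand in candidates:
        cand.structures = construct_chimeric_structures(cand, by_gene)

    records = _quantify_and_report(
        candidates, pairs, hits, classes, index, insert, read_len, config
    )
    write_fusion_report(records, out_dir / "fusions.tsv")
    return records


def spanning_side_positions(
    cand: FusionCandidate, read_len: int, insert: InsertModel
) -> tuple[list[float], list[float]]:
    """Spanning-read positions on each partner, mapped to [0, 1].

    A spanning end sits at a junction distance ``d`` (bases between the
    read's junction-proximal edge and the breakpoint) whose distribution
    under a genuine fusion follows from the insert model: given fragment
    length ``f``, ``d`` is uniform on ``[0, f - 2*read_len]``.  Applying
    the corresponding CDF (a probability integral transform) makes
    true-fusion positions ~uniform on [0, 1] — the same scale as the
    pooled background — while misalignment artifacts stacked at one
    position stay degenerate and fail the K-S test."""
    pos5, pos3 = [], []
    for _, p5, p3 in cand.spanning_pairs:
        d5 = max(cand.break5 + 1 - read_len - p5, 0)
        d3 = max(p3 - cand.break3, 0)
        pos5.append(_junction_distance_cdf(d5, insert, read_len))
        pos3.append(_junction_distance_cdf(d3, insert, read_len))
    return pos5, pos3


def _junction_distance_cdf(d: float, insert: InsertModel, read_len: int) -> float:
    """CDF of the junction distance of a spanning end.

    With fragment length X ~ N(mean, sd) and the junction uniform within
    the insert, P(D <= d) = (E[(X-a)+] - E[(X-a-d)+]) / E[(X-a)+] with
    a = 2*read_len, using E[(X-t)+] = sd*phi(z) + (mean-t)*(1-Phi(z))."""

    def partial_expectation(t: float) -> float:
        z = (t - insert.mean) / max(insert.sd, 1e-9)
        return float(
            insert.sd * stats.norm.pdf(z) + (insert.mean - t) * stats.norm.sf(z)
        )

    a = 2.0 * read_len
    total = partial_expectation(a)
    if total <= 0.0:
        return 0.5
    return min(max((total - partial_expectation(a + d)) / total, 0.0), 1.0)


def _quantify_and_report(
    candidates: Sequence[FusionCandidate],
    pairs: Sequence[ReadPair],
    hits,
    classes: Sequence[PairClass],
    index: TranscriptIndex,
    insert: InsertModel,
    read_len: int,
    config: PipelineConfig,
) -> list[FusionRecord]:
    """Phase III: append chimeric transcripts to the transcript set,
    enumerate concordant fragments for every read, run penalized EM, apply
    the expression filter, and emit report records."""
    chimera_seqs: dict[str, str] = {}
    chimera_junction: dict[str, int] = {}
    structures_by_cand: dict[int, list[str]] = {}
    for ci, cand in enumerate(candidates):
        ids = []
        for s in cand.structures:
            cid = f"chim_{cand.gene5}_{cand.gene3}_{cand.break5}_{s.name}"
            if cid not in chimera_seqs:
                chimera_seqs[cid] = s.sequence
                chimera_junction[cid] = cand.break5 + 1
            ids.append(cid)
        structures_by_cand[ci] = ids

    if not candidates:
        return []

    chim_index = TranscriptIndex(chimera_seqs, k=config.k) if chimera_seqs else None
    read_fragments: list[list[FragmentAlignment]] = []
    for p, (h1, h2) in zip(pairs, hits):
        frags: list[FragmentAlignment] = []
        seen: set[tuple[str, int]] = set()
        for e1, e2, frag in concordant_placements(
            h1, h2, len(p.end1_seq), len(p.end2_seq), insert, config.insert_sd_multiplier
        ):
            fwd = e1 if e1.strand == "+" else e2
            key = (e1.transcript_id, fwd.position)
            if key not in seen:
                seen.add(key)
                frags.append(
                    FragmentAlignment(
                        e1.transcript_id, frag, e1.mismatches + e2.mismatches, False
                    )
                )
        if chim_index is not None:
            c1 = chim_index.align(p.end1_seq, config.max_mismatch_read)
            c2 = chim_index.align(p.end2_seq, config.max_mismatch_read)
            for e1, e2, frag in concordant_placements(
                c1, c2, len(p.end1_seq), len(p.end2_seq), insert, config.insert_sd_multiplier
            ):
                fwd = e1 if e1.strand == "+" else e2
                key = (e1.transcript_id, fwd.position)
                if key in seen:
                    continue
                seen.add(key)
                junction = chimera_junction[e1.transcript_id]
                crosses = fwd.position < junction < fwd.position + frag
                frags.append(
                    FragmentAlignment(
                        e1.transcript_id, frag, e1.mismatches + e2.mismatches, crosses
                    )
                )
        read_fragments.append(frags)
    read_fragments = [f for f in read_fragments if f]

    transcripts_for_quant = [(tid, len(seq)) for tid, seq in index.sequences.items()]
    transcripts_for_quant += [(cid, len(seq)) for cid, seq in chimera_seqs.items()]
    model = build_quant_model(
        read_fragments,
        transcripts_for_quant,
        list(chimera_seqs),
        insert,
        lam=config.lam,
        read_length=read_len,
    )
    state = run_em(model, tol=config.em_tol, max_iter=config.em_max_iter)
    log.info("EM: %d iterations, loglik %.2f", state.iteration, state.loglik)

    kept_keys, abundances = expression_filter(
        structures_by_cand, model, state, config.expression_epsilon
    )
    log.info("expression filter: %d -> %d candidates", len(candidates), len(kept_keys))

    records = []
    for ci in kept_keys:
        cand = candidates[ci]
        cand.abundance = abundances[ci]
        cand.score = score_candidate(cand)
        records.append(
            FusionRecord(
                gene5=cand.gene5,
                gene3=cand.gene3,
                breakpoint5=cand.break5,
                breakpoint3=cand.break3,
                n_split=cand.n_split,
                n_span=cand.n_span,
                similarity=cand.similarity,
                ks_p5=cand.ks_p5,
                ks_p3=cand.ks_p3,
                score=cand.score,
                abundance=cand.abundance,
                structures=[s.format_chain() for s in cand.structures],
            )
        )
    return records


def evaluate_against_truth(
    records: Sequence[FusionRecord],
    truth: pd.DataFrame,
    sequences: Mapping[str, str] | None = None,
    transcript5_of: Mapping[str, str] | None = None,
    tolerance: int = 2,
) -> EvalResult:
    """Compare a fusion report against a simulation truth manifest.

    A detected fusion matches a true one when the gene pair agrees and
    both breakpoints are within ``tolerance``.  When partner ``sequences``
    are supplied (keyed by transcript id, with ``transcript5_of`` /
    mapping columns in the truth table), truth junctions are first shifted
    to their rightmost equivalent representation so micro-homology at the
    junction does not count as an offset error.
    """
    truth_rows = []
    for row in truth.itertuples(index=False):
        b5, b3 = int(row.break5), int(row.break3)
        if sequences is not None:
            b5, b3 = canonicalize_junction(
                sequences[row.transcript5], sequences[row.transcript3], b5, b3
            )
        truth_rows.append((row.gene5, row.gene3, b5, b3))

    matched_truth: set[int] = set()
    n_matched = n_exact = 0
    for rec in records:
        best = None
        for ti, (g5, g3, b5, b3) in enumerate(truth_rows):
            if rec.gene5 == g5 and rec.gene3 == g3:
                if abs(rec.breakpoint5 - b5) <= tolerance and abs(rec.breakpoint3 - b3) <= tolerance:
                    best = (ti, b5, b3)
                    break
        if best is not None:
            n_matched += 1
            matched_truth.add(best[0])
            if rec.breakpoint5 == best[1] and rec.breakpoint3 == best[2]:
                n_exact += 1

    n_true = len(truth_rows)
    n_detected = len(records)
    sensitivity = len(matched_truth) / n_true if n_true else 0.0
    specificity = n_matched / n_detected if n_detected else 0.0
    return EvalResult(
        sensitivity=sensitivity,
        specificity=specificity,
        n_true=n_true,
        n_detected=n_detected,
        n_matched=n_matched,
        n_breakpoint_exact=n_exact,
    )


def compute_quantile_roc(
    scores: Sequence[float],
    truth_labels: Sequence[bool],
    n_quantiles: int = 50,
) -> list[tuple[float, float]]:
    """Quantile-tail ROC: sort reported fusions ascending by score; for
    k = 1..n_quantiles take the top-k/n tail and count TP/FP there,
    FN/TN in the remainder.  Quantile boundaries fall on ranks (rounded)
    when there are fewer fusions than quantiles.  Empty denominators use
    the convention TPR = FPR = 1 at the full list."""
    order = np.argsort(np.asarray(scores, dtype=float), kind="stable")
    labels = np.asarray(truth_labels, dtype=bool)[order]
    n = len(labels)
    total_true = int(labels.sum())
    total_false = n - total_true
    points = []
    for k in range(1, n_quantiles + 1):
        tail = round(n * k / n_quantiles)
        tail_labels = labels[n - tail :] if tail else labels[:0]
        tp = int(tail_labels.sum())
        fp = tail - tp
        tpr = tp / total_true if total_true else 1.0
        fpr = fp / total_false if total_false else 1.0
        points.append((fpr, tpr))
    return points
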