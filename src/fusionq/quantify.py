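"""EM abundance estimation with an L1 sparsity penalty on fusion
transcripts.

The generative model is the standard RNA-Seq mixture: a paired-end read
``x_n`` arises from transcript ``i`` with probability proportional to
``theta_i / l_i`` times a fragment likelihood
``P(x_n | Z_nij = 1) = P(end1) * P(end2) * P(d) * P(psi)`` where the end
terms multiply per-base ``1 - e`` on matches and ``e / 3`` on mismatches
(``e`` from base quality), ``P(d)`` is the normal density of the implied
fragment length under the empirical insert model, and ``P(psi)`` is the
empirical probability that an alignment crosses a chimeric junction
(1 for fragments that do not touch one).

``theta`` is the read-fraction parameter (sums to 1); the
transcript-fraction (length-normalised) vector ``tau_i \\propto
theta_i / l_i`` is also reported.  The M-step applies soft-thresholding to
the expected counts of fusion transcripts — ``c_k <- max(0, c_k -
lambda)`` — which yields exact zeros for artifact chimeras whose reads are
better explained by reference transcripts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import InsertModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentAlignment:
    """One candidate fragment (concordant placement) of a read pair."""

    transcript_id: str
    insert_len: int
    n_mismatch: int
    crosses_junction: bool = False


@dataclass
class QuantModel:
    """Flattened fragment sets ready for vectorised EM."""

    transcript_ids: list[str]
    lengths: np.ndarray
    is_fusion: np.ndarray
    frag_transcript: np.ndarray  # transcript index per fragment
    frag_prob: np.ndarray  # P(x_n | Z_nij = 1) per fragment
    read_ptr: np.ndarray  # CSR-style offsets: fragments of read r are [ptr[r], ptr[r+1])
    lam: float
    n_reads: int
    psi: float = 1.0

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)


@dataclass
class EMState:
    theta: np.ndarray
    transcript_fraction: np.ndarray
    expected_counts: np.ndarray
    loglik: float
    penalized_trace: list[float] = field(default_factory=list)
    iteration: int = 0
    converged: bool = False


def build_quant_model(
    read_fragments: Sequence[Sequence[FragmentAlignment]],
    transcripts: Sequence[tuple[str, int]],
    fusion_ids: Sequence[str],
    insert_model: InsertModel,
    lam: float = 1.0,
    base_error: float = 1e-4,
    read_length: int = 50,
) -> QuantModel:
    """Assemble the EM model from per-read fragment sets.

    ``base_error`` is the per-base error probability implied by the base
    qualities (constant quality assumed; 1e-4 corresponds to Phred 40).
    Reads whose fragment probabilities are all zero are dropped with a
    warning.  The junction-crossing probability ``psi`` is estimated as
    the fraction of fusion-transcript fragments that cross a junction.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    tindex = {tid: i for i, (tid, _) in enumerate(transcripts)}
    lengths = np.array([ln for _, ln in transcripts], dtype=float)
    is_fusion = np.array([tid in set(fusion_ids) for tid, _ in transcripts])

    on_fusion = crossing = 0
    for frags in read_fragments:
        for f in frags:
            if is_fusion[tindex[f.transcript_id]]:
                on_fusion += 1
                crossing += f.crosses_junction
    psi = crossing / on_fusion if on_fusion else 1.0

    sd = max(insert_model.sd, 1e-6)
    norm_const = 1.0 / (sd * math.sqrt(2 * math.pi))
    match_p = (1.0 - base_error) ** (2 * read_length)
    err_ratio = (base_error / 3.0) / max(1.0 - base_error, 1e-12)

    frag_t: list[int] = []
    frag_p: list[float] = []
    ptr = [0]
    dropped = 0
    for frags in read_fragments:
        row_t, row_p = [], []
        for f in frags:
            d = (f.insert_len - insert_model.mean) / sd
            p = (
                match_p
                * err_ratio ** f.n_mismatch
                * norm_const
                * math.exp(-0.5 * d * d)
            )
            if f.crosses_junction:
                p *= psi
            if p > 0.0:
                row_t.append(tindex[f.transcript_id])
                row_p.append(p)
        if row_p:
            frag_t.extend(row_t)
            frag_p.extend(row_p)
            ptr.append(len(frag_t))
        else:
            dropped += 1
    if dropped:
        log.warning("dropped %d read(s) with zero total fragment probability", dropped)
    return QuantModel(
        transcript_ids=[tid for tid, _ in transcripts],
        lengths=lengths,
        is_fusion=is_fusion,
        frag_transcript=np.asarray(frag_t, dtype=np.int64),
        frag_prob=np.asarray(frag_p, dtype=float),
        read_ptr=np.asarray(ptr, dtype=np.int64),
        lam=lam,
        n_reads=len(ptr) - 1,
        psi=psi,
    )


def _read_sums(model: QuantModel, values: np.ndarray) -> np.ndarray:
    """Sum fragment values within each read."""
    return np.add.reduceat(values, model.read_ptr[:-1]) if model.n_reads else np.empty(0)


def e_step(model: QuantModel, theta: np.ndarray) -> np.ndarray:
    """Responsibilities E[Z_nij]: ``(theta_i / l_i) * P(x_n|Z_nij=1)``
    normalised over each read's fragment set.  Reads with an all-zero
    numerator get zero responsibilities (excluded this iteration)."""
    weights = (theta / model.lengths)[model.frag_transcript] * model.frag_prob
    totals = _read_sums(model, weights)
    denom = np.repeat(np.where(totals > 0.0, totals, 1.0), np.diff(model.read_ptr))
    resp = weights / denom
    resp[np.repeat(totals == 0.0, np.diff(model.read_ptr))] = 0.0
    return resp


def m_step(model: QuantModel, responsibilities: np.ndarray) -> np.ndarray:
    """Expected-count update with L1 soft-thresholding on fusion
    transcripts: ``c_k <- max(0, c_k - lambda)`` before renormalising."""
    counts = np.bincount(
        model.frag_transcript, weights=responsibilities, minlength=model.n_transcripts
    )
    counts = np.where(model.is_fusion, np.maximum(0.0, counts - model.lam), counts)
    total = counts.sum()
    if total <= 0.0:
        raise ValueError(
            "all expected counts shrank to zero; lambda is too large for this dataset"
        )
    return counts / total


_THETA_FLOOR = 1e-12


def _objective(model: QuantModel, theta: np.ndarray) -> tuple[float, float]:
    """(data log-likelihood, penalized objective).

    The count-space soft-threshold M-step ``c_k <- max(0, c_k - lambda)``
    is the exact maximiser of ``sum_i c_i log theta_i - lambda *
    sum_{k in F} log theta_k`` on the simplex, so the objective this EM
    ascends is the log-likelihood minus ``lambda * sum_{k in F} log
    theta_k`` (a MAP objective with a log prior pushing fusion abundances
    to zero; abundances at exactly zero contribute the floored constant).
    Reads with zero likelihood are excluded from the sum, matching their
    exclusion from the E-step."""
    weights = (theta / model.lengths)[model.frag_transcript] * model.frag_prob
    totals = _read_sums(model, weights)
    positive = totals > 0.0
    loglik = float(np.log(totals[positive]).sum())
    penalty = model.lam * float(
        np.log(np.maximum(theta[model.is_fusion], _THETA_FLOOR)).sum()
    )
    return loglik, loglik - penalty


def run_em(
    model: QuantModel,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> EMState:
    """Iterate E/M from uniform theta until the relative change of the
    penalized objective drops below ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    m = model.n_transcripts
    theta = np.full(m, 1.0 / m)
    trace: list[float] = []
    converged = False
    it = 0
    prev = -np.inf
    for it in range(1, max_iter + 1):
        resp = e_step(model, theta)
        theta = m_step(model, resp)
        loglik, penalized = _objective(model, theta)
        if not np.isfinite(penalized):
            raise FloatingPointError("non-finite penalized objective during EM")
        trace.append(penalized)
        if prev > -np.inf and abs(penalized - prev) <= tol * max(1.0, abs(prev)):
            converged = True
            break
        prev = penalized
    resp = e_step(model, theta)
    counts = np.bincount(
        model.frag_transcript, weights=resp, minlength=model.n_transcripts
    )
    loglik, _ = _objective(model, theta)
    with np.errstate(invalid="ignore"):
        tau = theta / model.lengths
    tau = tau / tau.sum() if tau.sum() > 0 else tau
    return EMState(
        theta=theta,
        transcript_fraction=tau,
        expected_counts=counts,
        loglik=loglik,
        penalized_trace=trace,
        iteration=it,
        converged=converged,
    )


def abundance_rpk(model: QuantModel, state: EMState, transcript_id: str) -> float:
    """Expected reads per kilobase of transcript — the report's expression
    scale."""
    i = model.transcript_ids.index(transcript_id)
    return float(state.expected_counts[i] / (model.lengths[i] / 1000.0))


def expression_filter(
    structure_ids_by_candidate: Mapping[int, Sequence[str]],
    model: QuantModel,
    state: EMState,
    epsilon: float | None = None,
) -> tuple[list[int], dict[int, float]]:
    """Final filter: candidates whose chimeric structures carry (summed)
    abundance at or below ``epsilon`` are disregarded as artifacts of
    misalignment.

    ``epsilon`` is in theta units; the default is the theta equivalent of
    one expected read.  Returns the surviving candidate keys and an
    abundance (reads per kilobase) for every candidate.
    """
    if epsilon is None:
        epsilon = 1.0 / max(model.n_reads, 1)
    index = {tid: i for i, tid in enumerate(model.transcript_ids)}
    kept: list[int] = []
    abundances: dict[int, float] = {}
    for key, tids in structure_ids_by_candidate.items():
        ids = [index[t] for t in tids if t in index]
        theta_sum = float(state.theta[ids].sum()) if ids else 0.0
        abundances[key] = float(
            sum(state.expected_counts[i] / (model.lengths[i] / 1000.0) for i in ids)
        )
        if theta_sum > epsilon:
            kept.append(key)
    return kept, abundances
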