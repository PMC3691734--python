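"""Split-read breakpoint detection and fusion candidate assembly.

A candidate split read (the unmapped end of a pair whose mate maps) is
split in the middle; each half that aligns with at most one mismatch is a
*seed*.  Seeds are extended base by base toward the unmapped side until
extension no longer matches the seed transcript; the stop point is the
fusion breakpoint and the unextended remainder the *residual sequence*.
Because the residual is short (< half a read), its gene is resolved by
*residual sequence extension*: a 20 bp contig around the junction fishes
overlapping unmapped reads out of the dataset, the reads are merged into a
longer consensus, and the merged residual side is realigned.

Candidates are assembled by grouping concordant breakpoint calls, checking
each split read's mate against the partner genes, and attaching spanning
pairs whose geometry is feasible under the insert model.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._seq import revcomp
from .align import AlignmentHit, InsertModel, PairClass, TranscriptIndex
from .formats import Transcript

log = logging.getLogger(__name__)


@dataclass
class DetectConfig:
    """Tunable knobs of split-read detection.

    ``min_residual`` — each fusion partner must contribute at least this
    many bases to a split read (default 5).
    ``mismatch_anchor`` — a mismatch consumed during seed extension must be
    followed by at least this many matching bases, else extension stops
    before it; this keeps sequencing-error tolerance from pushing the
    breakpoint past the true junction.
    ``max_residual_gene_hits`` — residual placements hitting more than this
    many genes are discarded as unresolvable (specificity guard).
    """

    min_read_len: int = 50
    max_mismatch_seed: int = 1
    mismatch_anchor: int = 4
    min_residual: int = 5
    max_residual_gene_hits: int = 3
    breakpoint_collapse_bp: int = 2
    contig_len: int = 20
    contig_mid_min_residual: int = 10


@dataclass
class Seed:
    """A mapped half of a candidate split read (<= 1 mismatch)."""

    read_id: str
    half: str  # "left" or "right"
    orientation: str  # "+" if the read maps forward as sequenced, "-" if reverse-complemented
    sequence: str
    hits: list[AlignmentHit]


@dataclass
class BreakpointCall:
    """One split read's breakpoint assertion after extension and residual
    resolution.

    Positions are transcript coordinates: ``break5`` is the last base of
    the 5' partner, ``break3`` the first base of the 3' partner.
    ``split_offset`` counts the read bases assigned to the seed side.
    """

    read_id: str
    gene5: str
    gene3: str
    transcript5: str
    transcript3: str
    break5: int
    break3: int
    split_offset: int
    residual_seq: str
    merged_sequence: str = ""
    mate_genes: frozenset[str] = frozenset()


@dataclass
class Contig:
    """The 20 bp window around the fusion point used to fish for
    overlapping reads."""

    sequence: str
    fusion_offset: int  # junction position within the contig
    read_start: int  # contig start offset within the oriented read


@dataclass
class ChimericStructure:
    name: str
    exon_chain: list[tuple[str, int, int, str]]
    sequence: str

    def format_chain(self) -> str:
        return ",".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in self.exon_chain)


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    transcript5: str
    transcript3: str
    break5: int
    break3: int
    split_reads: list[BreakpointCall] = field(default_factory=list)
    spanning_pairs: list[tuple[PairClass, int, int]] = field(default_factory=list)
    merged_sequences: list[str] = field(default_factory=list)
    structures: list[ChimericStructure] = field(default_factory=list)
    similarity: float = float("nan")
    ks_p5: float = float("nan")
    ks_p3: float = float("nan")
    score: float = float("nan")
    abundance: float = 0.0

    @property
    def n_split(self) -> int:
        return len({c.read_id for c in self.split_reads})

    @property
    def n_span(self) -> int:
        return len(self.spanning_pairs)


def split_candidate_read(read_seq: str, min_len: int = 50) -> tuple[str, str]:
    """Split a candidate split read in the middle: first floor(L/2) bases
    and the remainder.  Reads below ``min_len`` are rejected."""
    if len(read_seq) < min_len:
        raise ValueError(f"read of {len(read_seq)} bp is below the {min_len} bp minimum")
    mid = len(read_seq) // 2
    return read_seq[:mid], read_seq[mid:]


def find_seeds(
    read_id: str,
    read_seq: str,
    index: TranscriptIndex,
    config: DetectConfig | None = None,
) -> list[Seed]:
    """Align both halves of the read in both orientations (<= 1 mismatch).

    Orientation is canonicalised: each seed records whether the read was
    reverse-complemented, and its hits are forward-strand placements of the
    oriented read's half, so extension always proceeds on a forward string.
    """
    config = config or DetectConfig()
    seeds = []
    for orientation, oriented in (("+", read_seq), ("-", revcomp(read_seq))):
        left, right = split_candidate_read(oriented, config.min_read_len)
        for half_name, half_seq in (("left", left), ("right", right)):
            hits = [
                h
                for h in index.align(half_seq, config.max_mismatch_seed)
                if h.strand == "+"
            ]
            if hits:
                seeds.append(Seed(read_id, half_name, orientation, half_seq, hits))
    return seeds


def _extend_right(
    read: str, start: int, transcript: str, tpos: int, budget: int, anchor: int
) -> int:
    """Extend rightwards from read index ``start`` along ``transcript`` at
    ``tpos``; returns the number of bases extended."""
    i, t = start, tpos
    n, m = len(read), len(transcript)
    while i < n and t < m:
        if read[i] == transcript[t] and read[i] != "N":
            i += 1
            t += 1
        elif budget > 0 and _anchored_right(read, i, transcript, t, anchor):
            budget -= 1
            i += 1
            t += 1
        else:
            break
    return i - start


def _anchored_right(read: str, i: int, transcript: str, t: int, anchor: int) -> bool:
    nxt_r, nxt_t = read[i + 1 : i + 1 + anchor], transcript[t + 1 : t + 1 + anchor]
    return len(nxt_r) == anchor and nxt_r == nxt_t and "N" not in nxt_r


def _extend_left(
    read: str, start: int, transcript: str, tpos: int, budget: int, anchor: int
) -> int:
    """Extend leftwards from read index ``start`` (inclusive) backwards."""
    i, t = start, tpos
    while i >= 0 and t >= 0:
        if read[i] == transcript[t] and read[i] != "N":
            i -= 1
            t -= 1
        elif budget > 0 and _anchored_left(read, i, transcript, t, anchor):
            budget -= 1
            i -= 1
            t -= 1
        else:
            break
    return start - i


def _anchored_left(read: str, i: int, transcript: str, t: int, anchor: int) -> bool:
    prv_r, prv_t = read[max(0, i - anchor) : i], transcript[max(0, t - anchor) : t]
    return len(prv_r) == anchor and prv_r == prv_t and "N" not in prv_r


@dataclass
class Extension:
    """Raw outcome of extending one seed: the junction as seen from the
    seed side, before the residual gene is resolved."""

    read_id: str
    orientation: str
    seed_half: str
    transcript_id: str
    seed_break_pos: int  # last 5'-partner base (left seed) / first 3'-partner base (right seed)
    split_offset: int  # read bases assigned to the seed side
    residual_seq: str
    oriented_read: str


def extend_seed(
    seed: Seed,
    oriented_read: str,
    sequences: Mapping[str, str],
    config: DetectConfig | None = None,
) -> list[Extension]:
    """Extend a seed nucleotide by nucleotide toward the unmapped side.

    The seed's <= 1 mismatch budget covers the extended prefix too.  For
    each hit the extension stop point is computed; the maximal extension
    over all hits defines the breakpoint.  Ties across transcripts emit one
    extension each (reconciled at assembly).  Returns an empty list when
    the seed extends through the whole read (no junction) or the residual
    is shorter than ``min_residual``.
    """
    config = config or DetectConfig()
    h = len(seed.sequence)
    L = len(oriented_read)
    results: dict[str, Extension] = {}
    best = -1
    for hit in seed.hits:
        transcript = sequences[hit.transcript_id]
        budget = config.max_mismatch_seed - hit.mismatches
        if seed.half == "left":
            ext = _extend_right(
                oriented_read, h, transcript, hit.position + h, budget, config.mismatch_anchor
            )
            split_offset = h + ext
            residual = oriented_read[split_offset:]
            seed_break = hit.position + split_offset - 1
        else:
            first = L - h  # read index of the seed's first base
            ext = _extend_left(
                oriented_read, first - 1, transcript, hit.position - 1, budget, config.mismatch_anchor
            )
            split_offset = h + ext
            residual = oriented_read[: L - split_offset]
            seed_break = hit.position - ext
        if split_offset >= L or len(residual) < config.min_residual:
            continue
        if split_offset > best:
            best = split_offset
            results = {}
        if split_offset == best:
            results.setdefault(
                hit.transcript_id,
                Extension(
                    read_id=seed.read_id,
                    orientation=seed.orientation,
                    seed_half=seed.half,
                    transcript_id=hit.transcript_id,
                    seed_break_pos=seed_break,
                    split_offset=split_offset,
                    residual_seq=residual,
                    oriented_read=oriented_read,
                ),
            )
    return list(results.values())


def build_contig(
    read_seq: str,
    split_offset: int,
    residual_len: int,
    residual_side: str = "right",
    config: DetectConfig | None = None,
) -> Contig:
    """The 20 bp window with the fusion point in the middle — or, when the
    residual is shorter than 10 bp, the 20 bp window containing the whole
    residual.  Windows falling off the read are clamped to its boundary."""
    config = config or DetectConfig()
    clen = config.contig_len
    half = clen // 2
    L = len(read_seq)
    if L < clen:
        raise ValueError("read shorter than contig length")
    if residual_len < 1:
        raise ValueError("residual must be non-empty")
    junction = split_offset if residual_side == "right" else residual_len
    if residual_len >= config.contig_mid_min_residual:
        start = junction - half
    elif residual_side == "right":
        start = L - clen  # window ending at the residual-side read end
    else:
        start = 0
    start = max(0, min(start, L - clen))
    return Contig(
        sequence=read_seq[start : start + clen],
        fusion_offset=junction - start,
        read_start=start,
    )


def collect_reference_reads(contig: Contig, unmapped_reads: Sequence[str]) -> list[str]:
    """All unmapped, non-candidate reads containing the contig exactly as a
    substring, orientation-normalised to the contig's strand."""
    rc_contig = revcomp(contig.sequence)
    out = []
    for seq in unmapped_reads:
        if contig.sequence in seq:
            out.append(seq)
        elif rc_contig in seq:
            out.append(revcomp(seq))
    return out


def merge_reference_reads(
    split_read: str,
    reference_reads: Sequence[str],
    contig: Contig,
) -> tuple[str, int]:
    """Merge the split read with its reference reads into one consensus.

    Reads are anchored by their (first) contig occurrence on a common
    axis; columns with a unique majority base join the consensus, which is
    trimmed at the first conflicting column on each side of the contig.
    Returns ``(merged_sequence, split_read_offset)`` where the offset is
    the position of the split read's first base within the merged
    sequence.  With no reference reads the merged sequence is the split
    read itself.
    """
    layouts = [(split_read, -contig.read_start)]
    for ref in reference_reads:
        idx = ref.find(contig.sequence)
        if idx >= 0:
            layouts.append((ref, -idx))
    columns: dict[int, Counter] = {}
    for seq, shift in layouts:
        for i, base in enumerate(seq):
            columns.setdefault(shift + i, Counter())[base] += 1

    def consensus_at(col: int) -> str | None:
        counter = columns.get(col)
        if not counter:
            return None
        (base, n), *rest = counter.most_common(2)
        if rest and rest[0][1] == n:
            return None  # tied column: conflict
        return base

    lo = 0
    while consensus_at(lo - 1) is not None:
        lo -= 1
    hi = len(contig.sequence)
    while consensus_at(hi) is not None:
        hi += 1
    merged = "".join(consensus_at(c) for c in range(lo, hi))
    split_read_offset = -contig.read_start - lo
    return merged, split_read_offset


def resolve_residual_gene(
    residual_query: str,
    index: TranscriptIndex,
    gene_of: Mapping[str, str],
    config: DetectConfig | None = None,
) -> AlignmentHit | None:
    """Place the (merged) residual-side sequence and pick its gene.

    Forward-strand placements only (chimeras concatenate sense-strand
    partner sequences).  A unique best gene wins; hits spread over more
    than ``max_residual_gene_hits`` genes, ambiguous placements, or
    queries too short to index are unresolved (``None``)."""
    config = config or DetectConfig()
    if len(residual_query) < index.k:
        return None
    hits = [
        h
        for h in index.align(residual_query, config.max_mismatch_seed)
        if h.strand == "+"
    ]
    if not hits:
        return None
    genes = {gene_of[h.transcript_id] for h in hits}
    if len(genes) > config.max_residual_gene_hits:
        return None
    best_mm = min(h.mismatches for h in hits)
    best = [h for h in hits if h.mismatches == best_mm]
    best_genes = {gene_of[h.transcript_id] for h in best}
    if len(best_genes) != 1:
        return None
    if len({(h.transcript_id, h.position) for h in best}) != 1:
        return None  # repeat within the gene: breakpoint would be ambiguous
    return best[0]


def resolve_call(
    ext: Extension,
    index: TranscriptIndex,
    gene_of: Mapping[str, str],
    unmapped_pool: Sequence[str],
    mate_genes: frozenset[str],
    config: DetectConfig | None = None,
) -> BreakpointCall | None:
    """Residual sequence extension for one seed extension: contig, fish for
    reference reads, merge, realign the merged residual side, and emit a
    full breakpoint call — or ``None`` when the residual stays unresolved."""
    config = config or DetectConfig()
    read = ext.oriented_read
    residual_side = "right" if ext.seed_half == "left" else "left"
    residual_len = len(ext.residual_seq)
    contig = build_contig(read, ext.split_offset, residual_len, residual_side, config)
    refs = collect_reference_reads(contig, unmapped_pool)
    merged, read_offset = merge_reference_reads(read, refs, contig)
    if residual_side == "right":
        junction_in_merged = read_offset + ext.split_offset
        query = merged[junction_in_merged:]
    else:
        junction_in_merged = read_offset + residual_len
        query = merged[:junction_in_merged]
    hit = resolve_residual_gene(query, index, gene_of, config)
    if hit is None:
        return None
    if residual_side == "right":
        gene5, t5, b5 = gene_of[ext.transcript_id], ext.transcript_id, ext.seed_break_pos
        gene3, t3, b3 = gene_of[hit.transcript_id], hit.transcript_id, hit.position
    else:
        gene5, t5 = gene_of[hit.transcript_id], hit.transcript_id
        b5 = hit.position + len(query) - 1
        gene3, t3, b3 = gene_of[ext.transcript_id], ext.transcript_id, ext.seed_break_pos
    if gene5 == gene3:
        return None  # both sides in one gene: no fusion
    return BreakpointCall(
        read_id=ext.read_id,
        gene5=gene5,
        gene3=gene3,
        transcript5=t5,
        transcript3=t3,
        break5=b5,
        break3=b3,
        split_offset=ext.split_offset,
        residual_seq=ext.residual_seq,
        merged_sequence=merged,
        mate_genes=mate_genes,
    )


def detect_split_read(
    read_id: str,
    read_seq: str,
    index: TranscriptIndex,
    gene_of: Mapping[str, str],
    unmapped_pool: Sequence[str],
    mate_genes: frozenset[str] = frozenset(),
    config: DetectConfig | None = None,
) -> list[BreakpointCall]:
    """Full split-read treatment of one candidate read: seeds, extension,
    residual sequence extension.  Returns zero or more breakpoint calls."""
    config = config or DetectConfig()
    if len(read_seq) < config.min_read_len:
        log.debug("read %s rejected: %d bp < %d", read_id, len(read_seq), config.min_read_len)
        return []
    calls = []
    for seed in find_seeds(read_id, read_seq, index, config):
        oriented = read_seq if seed.orientation == "+" else revcomp(read_seq)
        for ext in extend_seed(seed, oriented, index.sequences, config):
            call = resolve_call(ext, index, gene_of, unmapped_pool, mate_genes, config)
            if call is not None:
                calls.append(call)
    return calls


def canonicalize_junction(
    seq5: str, seq3: str, break5: int, break3: int
) -> tuple[int, int]:
    """Shift a junction to its rightmost equivalent representation.

    When the first base after the junction on the 5' partner equals the
    first retained base of the 3' partner the chimera sequence is identical
    under a one-base right shift; such micro-homology makes the breakpoint
    a closed interval, reported here at its right edge."""
    while (
        break5 + 1 < len(seq5)
        and break3 + 1 <= len(seq3) - 1
        and seq5[break5 + 1] == seq3[break3]
    ):
        break5 += 1
        break3 += 1
    return break5, break3


def assemble_candidates(
    calls: Sequence[BreakpointCall],
    spanning_pairs: Sequence[PairClass],
    sequences: Mapping[str, str],
    gene_of: Mapping[str, str],
    insert: InsertModel,
    read_len: int,
    config: DetectConfig | None = None,
    sd_multiplier: float = 3.0,
) -> list[FusionCandidate]:
    """Group concordant breakpoint calls into fusion candidates and attach
    geometrically consistent spanning pairs.

    A split read whose mate maps to neither partner gene is discarded; a
    spanning pair attaches when its forward-strand end lies upstream of
    ``break5`` and its reverse end downstream of ``break3``, both within
    ``mean + sd_multiplier*sd`` of the junction.  No split read contributes
    to more than one candidate."""
    config = config or DetectConfig()
    usable = []
    for call in calls:
        b5, b3 = canonicalize_junction(
            sequences[call.transcript5], sequences[call.transcript3], call.break5, call.break3
        )
        call.break5, call.break3 = b5, b3
        if call.mate_genes and not (call.mate_genes & {call.gene5, call.gene3}):
            continue  # mate-consistency rule
        usable.append(call)

    grouped: dict[tuple[str, str, str, str], list[BreakpointCall]] = {}
    for call in usable:
        grouped.setdefault(
            (call.gene5, call.gene3, call.transcript5, call.transcript3), []
        ).append(call)

    candidates = []
    used_reads: set[str] = set()
    for (gene5, gene3, t5, t3), group in grouped.items():
        remaining = [c for c in group]
        while remaining:
            mode_bp, _ = Counter((c.break5, c.break3) for c in remaining).most_common(1)[0]
            tol = config.breakpoint_collapse_bp
            members = [
                c
                for c in remaining
                if abs(c.break5 - mode_bp[0]) <= tol and abs(c.break3 - mode_bp[1]) <= tol
            ]
            remaining = [c for c in remaining if c not in members]
            members = [c for c in members if c.read_id not in used_reads]
            if not members:
                continue
            used_reads.update(c.read_id for c in members)
            candidates.append(
                FusionCandidate(
                    gene5=gene5,
                    gene3=gene3,
                    transcript5=t5,
                    transcript3=t3,
                    break5=mode_bp[0],
                    break3=mode_bp[1],
                    split_reads=members,
                    merged_sequences=sorted({c.merged_sequence for c in members}),
                )
            )

    window = insert.mean + sd_multiplier * insert.sd
    for cand in candidates:
        for pair in spanning_pairs:
            attach = _spanning_attachment(pair, cand, gene_of, read_len, window)
            if attach is not None:
                cand.spanning_pairs.append((pair, attach[0], attach[1]))
    return candidates


def _spanning_attachment(
    pair: PairClass,
    cand: FusionCandidate,
    gene_of: Mapping[str, str],
    read_len: int,
    window: float,
) -> tuple[int, int] | None:
    """Positions (on 5' and 3' partners) if the pair supports the
    candidate's junction, else None.  The forward-strand hit belongs to the
    5' side (the left end of the fragment in chimera coordinates)."""
    for h1, h2 in pair.evidence:
        fwd, rc = (h1, h2) if h1.strand == "+" else (h2, h1)
        if gene_of[fwd.transcript_id] != cand.gene5 or gene_of[rc.transcript_id] != cand.gene3:
            continue
        ok5 = ok3 = True
        if fwd.transcript_id == cand.transcript5:
            dist5 = cand.break5 + 1 - fwd.position
            ok5 = fwd.position + read_len - 1 <= cand.break5 and dist5 <= window
        if rc.transcript_id == cand.transcript3:
            dist3 = rc.position + read_len - cand.break3
            ok3 = rc.position >= cand.break3 and dist3 <= window
        if ok5 and ok3:
            return fwd.position, rc.position
    return None


def construct_chimeric_structures(
    candidate: FusionCandidate,
    transcripts_by_gene: Mapping[str, Sequence[Transcript]],
) -> list[ChimericStructure]:
    """All chimeric transcript structures compatible with the breakpoints:
    one per isoform pair, with the 5' isoform's exon chain truncated at
    ``break5`` and concatenated with the 3' isoform's chain from
    ``break3``.  Isoforms too short to contain the breakpoint are skipped;
    isoforms without exon annotation yield a sequence-only structure."""
    structures = []
    for iso5 in transcripts_by_gene.get(candidate.gene5, []):
        if candidate.break5 >= iso5.length:
            continue
        for iso3 in transcripts_by_gene.get(candidate.gene3, []):
            if candidate.break3 >= iso3.length:
                continue
            seq = iso5.sequence[: candidate.break5 + 1] + iso3.sequence[candidate.break3 :]
            chain = _truncate_chain_5p(iso5, candidate.break5 + 1) + _truncate_chain_3p(
                iso3, candidate.break3
            )
            structures.append(
                ChimericStructure(
                    name=f"{iso5.transcript_id}|{iso3.transcript_id}",
                    exon_chain=chain,
                    sequence=seq,
                )
            )
    return structures


def _truncate_chain_5p(t: Transcript, keep: int) -> list[tuple[str, int, int, str]]:
    """First ``keep`` transcript bases of the exon chain, in genomic
    coordinates."""
    chain = []
    remaining = keep
    for chrom, start, end in t.exons:
        width = end - start
        take = min(width, remaining)
        if take <= 0:
            break
        if t.strand == "+":
            chain.append((chrom, start, start + take, "+"))
        else:
            chain.append((chrom, end - take, end, "-"))
        remaining -= take
    return chain


def _truncate_chain_3p(t: Transcript, skip: int) -> list[tuple[str, int, int, str]]:
    """Exon chain with the first ``skip`` transcript bases removed."""
    chain = []
    to_skip = skip
    for chrom, start, end in t.exons:
        width = end - start
        if to_skip >= width:
            to_skip -= width
            continue
        if t.strand == "+":
            chain.append((chrom, start + to_skip, end, "+"))
        else:
            chain.append((chrom, start, end - to_skip, "-"))
        to_skip = 0
    return chain
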