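"""Split-read detection: halving, seed extension (vs a brute-force
oracle), contigs, reference-read merging, residual resolution, assembly,
and chimeric structure construction."""

import numpy as np
import pytest

from conftest import random_seq
from fusionq._seq import revcomp
from fusionq.align import AlignmentHit, InsertModel, PairClass, TranscriptIndex
from fusionq.detect import (
    BreakpointCall,
    Contig,
    DetectConfig,
    assemble_candidates,
    build_contig,
    canonicalize_junction,
    collect_reference_reads,
    construct_chimeric_structures,
    detect_split_read,
    extend_seed,
    find_seeds,
    merge_reference_reads,
    split_candidate_read,
)
from fusionq.formats import Transcript


@pytest.fixture
def two_genes(rng):
    seqs = {"tA": random_seq(rng, 1200), "tB": random_seq(rng, 1400)}
    genes = {"tA": "gA", "tB": "gB"}
    idx = TranscriptIndex(seqs, k=12)
    return seqs, genes, idx


def junction_read(seqs, n5, n3, at5=400, at3=700):
    """Error-free split read: last n5 bases of gA up to at5, first n3 of gB
    from at3."""
    return seqs["tA"][at5 - n5 : at5] + seqs["tB"][at3 : at3 + n3]


class TestSplitCandidateRead:
    @pytest.mark.parametrize("length,left,right", [(50, 25, 25), (51, 25, 26)])
    def test_floor_ceil_halving(self, length, left, right):
        l, r = split_candidate_read("A" * length)
        assert (len(l), len(r)) == (left, right)

    def test_short_read_rejected(self):
        with pytest.raises(ValueError):
            split_candidate_read("A" * 40)


class TestFindSeeds:
    def test_junction_read_yields_one_seed_per_half(self, two_genes):
        seqs, genes, idx = two_genes
        read = junction_read(seqs, 25, 25)
        seeds = find_seeds("r", read, idx)
        halves = {(s.half, s.orientation) for s in seeds}
        assert ("left", "+") in halves and ("right", "+") in halves

    def test_reverse_complement_read_canonicalised(self, two_genes):
        seqs, genes, idx = two_genes
        read = revcomp(junction_read(seqs, 25, 25))
        seeds = find_seeds("r", read, idx)
        assert seeds and all(s.orientation == "-" for s in seeds)
        assert all(h.strand == "+" for s in seeds for h in s.hits)

    def test_half_with_two_mismatches_is_not_a_seed(self, two_genes):
        seqs, genes, idx = two_genes
        half = list(seqs["tA"][200:225])
        half[3] = "ACGT"[("ACG".find(half[3]) + 1) % 4]
        half[19] = "ACGT"[("ACG".find(half[19]) + 1) % 4]
        read = "".join(half) + random_seq(np.random.default_rng(0), 25)
        seeds = find_seeds("r", read, idx)
        assert all(s.half != "left" or not s.hits for s in seeds) or not any(
            h.transcript_id == "tA" and h.position == 200 for s in seeds for h in s.hits
        )


def brute_force_max_extension(read, half, transcript, pos, budget, anchor):
    """Oracle for extension: tries every stop point and returns the longest
    prefix (suffix) consistent with the mismatch budget and anchor rule by
    replaying the greedy definition position by position."""
    if half == "left":
        i, t = 25, pos + 25
        used = 0
        while i < len(read) and t < len(transcript):
            if read[i] == transcript[t]:
                i += 1
                t += 1
                continue
            nxt_r = read[i + 1 : i + 1 + anchor]
            nxt_t = transcript[t + 1 : t + 1 + anchor]
            if used < budget and len(nxt_r) == anchor and nxt_r == nxt_t:
                used += 1
                i += 1
                t += 1
            else:
                break
        return i
    raise NotImplementedError


class TestExtendSeed:
    def test_left_seed_stops_exactly_at_junction(self, two_genes):
        seqs, genes, idx = two_genes
        read = junction_read(seqs, 30, 20)
        seeds = [s for s in find_seeds("r", read, idx) if s.half == "left"]
        exts = extend_seed(seeds[0], read, seqs)
        assert len(exts) == 1
        ext = exts[0]
        # allow micro-homology: extension may run past the junction only
        # while gB's bases coincide with gA's continuation
        shift = ext.split_offset - 30
        assert shift >= 0
        assert seqs["tA"][400 : 400 + shift] == seqs["tB"][700 : 700 + shift]
        assert ext.seed_break_pos == 400 - 30 + ext.split_offset - 1 + 0

    def test_right_seed_stops_exactly_at_junction(self, two_genes):
        seqs, genes, idx = two_genes
        read = junction_read(seqs, 20, 30)
        seeds = [s for s in find_seeds("r", read, idx) if s.half == "right"]
        exts = extend_seed(seeds[0], read, seqs)
        assert len(exts) == 1
        shift = 20 - (len(read) - exts[0].split_offset)
        assert shift >= 0  # leftward extension can pass micro-homology only
        assert exts[0].residual_seq == read[: len(read) - exts[0].split_offset]

    def test_read_within_one_transcript_has_no_breakpoint(self, two_genes):
        seqs, genes, idx = two_genes
        read = seqs["tA"][100:150]
        for seed in find_seeds("r", read, idx):
            assert extend_seed(seed, read, seqs) == []

    def test_scattered_errors_do_not_fake_a_junction(self, two_genes):
        # A read from one gene with 3 scattered errors: unmapped as a whole,
        # but extension should not produce a call for another gene.
        seqs, genes, idx = two_genes
        read = list(seqs["tA"][500:550])
        for p in (5, 27, 45):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        read = "".join(read)
        calls = detect_split_read("r", read, idx, genes, [], frozenset({"gA"}))
        assert calls == []

    def test_matches_brute_force_stop_point(self, two_genes, rng):
        seqs, genes, idx = two_genes
        cfg = DetectConfig()
        for _ in range(20):
            n5 = int(rng.integers(25, 40))
            read = junction_read(seqs, n5, 50 - n5, at5=int(rng.integers(100, 1000)))
            seeds = [s for s in find_seeds("r", read, idx) if s.half == "left"]
            if not seeds:
                continue
            for hit in seeds[0].hits:
                oracle = brute_force_max_extension(
                    read, "left", seqs[hit.transcript_id], hit.position,
                    cfg.max_mismatch_seed - hit.mismatches, cfg.mismatch_anchor,
                )
                exts = extend_seed(seeds[0], read, seqs, cfg)
                if exts and exts[0].transcript_id == hit.transcript_id:
                    assert exts[0].split_offset == oracle


class TestBuildContig:
    def test_fusion_point_in_the_middle(self):
        read = "".join("ACGT"[i % 4] for i in range(50))
        c = build_contig(read, 30, 20)
        assert c.sequence == read[20:40]
        assert c.fusion_offset == 10

    def test_short_residual_window_contains_it(self):
        read = "".join("ACGT"[i % 4] for i in range(50))
        c = build_contig(read, 42, 8)
        assert c.sequence == read[30:50]
        assert c.fusion_offset == 12

    def test_residual_exactly_ten_uses_middle_rule(self):
        read = "".join("ACGT"[i % 4] for i in range(50))
        c = build_contig(read, 40, 10)
        assert c.sequence == read[30:50]
        assert c.fusion_offset == 10

    def test_window_clamped_at_read_boundary(self):
        read = "".join("ACGT"[i % 4] for i in range(50))
        c = build_contig(read, 6, 44, residual_side="right")
        assert len(c.sequence) == 20
        assert c.read_start == 0
        assert c.fusion_offset == 6


class TestReferenceReads:
    def test_overlapping_junction_reads_collected(self, two_genes, rng):
        seqs, genes, idx = two_genes
        chimera = seqs["tA"][:400] + seqs["tB"][700:]
        contig = Contig(sequence=chimera[390:410], fusion_offset=10, read_start=0)
        pool = [chimera[i : i + 50] for i in (360, 370, 375, 385, 390)]
        pool += [random_seq(rng, 50) for _ in range(5)]
        got = collect_reference_reads(contig, pool)
        assert len(got) == 5

    def test_reverse_complement_reads_normalised(self, two_genes):
        seqs, genes, idx = two_genes
        chimera = seqs["tA"][:400] + seqs["tB"][700:]
        contig = Contig(sequence=chimera[390:410], fusion_offset=10, read_start=0)
        got = collect_reference_reads(contig, [revcomp(chimera[380:430])])
        assert got == [chimera[380:430]]

    def test_no_containing_reads_gives_empty_list(self, two_genes):
        seqs, genes, idx = two_genes
        contig = Contig(sequence=seqs["tA"][0:20], fusion_offset=10, read_start=0)
        assert collect_reference_reads(contig, ["T" * 50]) == []


class TestMergeReferenceReads:
    def test_staggered_reads_reconstruct_chimeric_window(self, two_genes):
        seqs, genes, idx = two_genes
        chimera = seqs["tA"][:400] + seqs["tB"][700:]
        split_read = chimera[370:420]
        contig = Contig(sequence=chimera[390:410], fusion_offset=10, read_start=20)
        refs = [chimera[360:410], chimera[385:435], chimera[375:425]]
        merged, offset = merge_reference_reads(split_read, refs, contig)
        assert merged == chimera[360:435]
        assert merged[offset : offset + 50] == split_read

    def test_single_read_merges_to_itself(self, two_genes):
        seqs, genes, idx = two_genes
        read = seqs["tA"][100:150]
        contig = Contig(sequence=read[20:40], fusion_offset=10, read_start=20)
        merged, offset = merge_reference_reads(read, [], contig)
        assert merged == read and offset == 0

    def test_majority_vote_overrides_single_error(self, two_genes):
        seqs, genes, idx = two_genes
        chimera = seqs["tA"][:400] + seqs["tB"][700:]
        split_read = chimera[370:420]
        contig = Contig(sequence=chimera[390:410], fusion_offset=10, read_start=20)
        bad = list(chimera[385:435])
        bad[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[40]]  # error at chimera[425]
        refs = [chimera[385:435], chimera[380:430], "".join(bad)]
        merged, _ = merge_reference_reads(split_read, refs, contig)
        assert chimera[425] in merged
        assert merged == chimera[370:435]


class TestResolveAndAssemble:
    def test_full_split_read_call_matches_construction(self, two_genes):
        seqs, genes, idx = two_genes
        read = junction_read(seqs, 30, 20)
        calls = detect_split_read("r", read, idx, genes, [], frozenset({"gA"}))
        assert calls
        call = calls[0]
        assert (call.gene5, call.gene3) == ("gA", "gB")
        b5, b3 = canonicalize_junction(seqs["tA"], seqs["tB"], 399, 700)
        assert (call.break5, call.break3) == (b5, b3)

    def test_short_residual_without_references_unresolved(self, two_genes):
        seqs, genes, idx = two_genes
        read = junction_read(seqs, 44, 6)
        calls = detect_split_read("r", read, idx, genes, [], frozenset({"gA"}))
        assert calls == []

    def test_short_residual_rescued_by_reference_reads(self, two_genes):
        seqs, genes, idx = two_genes
        chimera = seqs["tA"][:400] + seqs["tB"][700:]
        read = chimera[356:406]  # junction at read offset 44, residual 6 bp
        pool = [chimera[i : i + 50] for i in (370, 380, 390, 400)]
        calls = detect_split_read("r", read, idx, genes, pool, frozenset({"gA"}))
        assert calls
        assert {(c.gene5, c.gene3) for c in calls} == {("gA", "gB")}

    def test_residual_mapping_to_many_genes_dropped(self, rng):
        # Same 30 bp block planted in five genes: residual is unresolvable.
        block = random_seq(rng, 30)
        seqs = {f"t{i}": random_seq(rng, 500) + block + random_seq(rng, 470) for i in range(5)}
        seqs["tS"] = random_seq(rng, 1000)
        genes = {tid: tid.replace("t", "g") for tid in seqs}
        idx = TranscriptIndex(seqs, k=12)
        read = seqs["tS"][200:230] + block[:20]
        calls = detect_split_read("r", read, idx, genes, [], frozenset({"gS"}))
        assert calls == []

    def _call(self, read_id, b5=399, b3=700, mate=frozenset({"gA"})):
        return BreakpointCall(
            read_id=read_id, gene5="gA", gene3="gB", transcript5="tA", transcript3="tB",
            break5=b5, break3=b3, split_offset=30, residual_seq="X" * 20, mate_genes=mate,
        )

    def test_grouping_counts_and_spanning_attachment(self, two_genes):
        seqs, genes, idx = two_genes
        insert = InsertModel(164.0, 48.0, 10)
        calls = [self._call(f"r{i}") for i in range(3)]
        b5, b3 = canonicalize_junction(seqs["tA"], seqs["tB"], 399, 700)
        spans = [
            PairClass("spanning", [(AlignmentHit("tA", b5 - 200 + 1, "+", 0),
                                    AlignmentHit("tB", b3 + 60, "-", 0))])
            for _ in range(5)
        ]
        cands = assemble_candidates(calls, spans, seqs, genes, insert, 50)
        assert len(cands) == 1
        assert cands[0].n_split == 3 and cands[0].n_span == 5

    def test_mate_on_third_gene_excluded(self, two_genes):
        seqs, genes, idx = two_genes
        insert = InsertModel(164.0, 48.0, 10)
        calls = [self._call("r0"), self._call("r1", mate=frozenset({"gZ"}))]
        cands = assemble_candidates(calls, [], seqs, genes, insert, 50)
        assert len(cands) == 1 and cands[0].n_split == 1

    def test_distant_spanning_pair_not_attached(self, two_genes):
        seqs, genes, idx = two_genes
        insert = InsertModel(164.0, 48.0, 10)
        calls = [self._call("r0")]
        b5, _ = canonicalize_junction(seqs["tA"], seqs["tB"], 399, 700)
        far = PairClass("spanning", [(AlignmentHit("tA", b5 - 400, "+", 0),
                                      AlignmentHit("tB", 760, "-", 0))])
        cands = assemble_candidates(calls, [far], seqs, genes, insert, 50)
        assert cands[0].n_span == 0

    def test_breakpoints_within_tolerance_collapse_to_mode(self, two_genes):
        seqs, genes, idx = two_genes
        insert = InsertModel(164.0, 48.0, 10)
        # choose a junction with no micro-homology so canonicalisation is a no-op
        b5 = 399
        while seqs["tA"][b5 + 1] == seqs["tB"][700]:
            b5 += 1
        calls = [self._call("r0", b5=b5), self._call("r1", b5=b5), self._call("r2", b5=b5 - 30)]
        # make the near-call canonicalisation-stable too
        cands = assemble_candidates(calls, [], seqs, genes, insert, 50)
        assert any(c.n_split == 2 for c in cands)


class TestCanonicalize:
    def test_shifts_through_micro_homology(self):
        seq5 = "AAAACCGGTT"
        seq3 = "GGTTAAACCC"
        # junction 5'[:4] + 3'[4:]; 5' continuation "CCGG" vs 3' first kept
        b5, b3 = canonicalize_junction(seq5, seq3, 3, 4)
        chim_before = seq5[:4] + seq3[4:]
        chim_after = seq5[: b5 + 1] + seq3[b3:]
        assert chim_before == chim_after

    def test_no_homology_is_identity(self):
        assert canonicalize_junction("AAAA", "CCCC", 1, 2) == (1, 2)


class TestStructures:
    def _transcripts(self):
        t5 = Transcript("tA", "gA", "A" * 100, [("chr1", 0, 60), ("chr1", 100, 140)], "+")
        t3 = Transcript("tB", "gB", "C" * 80, [("chr2", 200, 280)], "+")
        return {"gA": [t5], "gB": [t3]}

    def test_single_isoform_pair_single_structure(self):
        from fusionq.detect import FusionCandidate

        cand = FusionCandidate("gA", "gB", "tA", "tB", break5=69, break3=10)
        structs = construct_chimeric_structures(cand, self._transcripts())
        assert len(structs) == 1
        s = structs[0]
        assert s.sequence == "A" * 70 + "C" * 70
        assert s.exon_chain == [
            ("chr1", 0, 60, "+"),
            ("chr1", 100, 110, "+"),
            ("chr2", 210, 280, "+"),
        ]

    def test_isoform_combinations_multiply(self):
        from fusionq.detect import FusionCandidate

        txs = self._transcripts()
        txs["gA"].append(Transcript("tA2", "gA", "A" * 90, [("chr1", 0, 90)], "+"))
        txs["gB"].append(Transcript("tB2", "gB", "C" * 60, [("chr2", 200, 260)], "+"))
        cand = FusionCandidate("gA", "gB", "tA", "tB", break5=69, break3=10)
        assert len(construct_chimeric_structures(cand, txs)) == 4

    def test_chimera_length_arithmetic(self):
        from fusionq.detect import FusionCandidate

        cand = FusionCandidate("gA", "gB", "tA", "tB", break5=39, break3=20)
        (s,) = construct_chimeric_structures(cand, self._transcripts())
        assert len(s.sequence) == 40 + (80 - 20)

    def test_minus_strand_truncation(self):
        from fusionq.detect import FusionCandidate

        t5 = Transcript("tA", "gA", "A" * 100, [("chr1", 0, 100)], "+")
        t3 = Transcript("tB", "gB", "C" * 100, [("chr3", 500, 600)], "-")
        cand = FusionCandidate("gA", "gB", "tA", "tB", break5=49, break3=30)
        (s,) = construct_chimeric_structures(cand, {"gA": [t5], "gB": [t3]})
        # minus-strand 3' partner: skip the first 30 transcript bases =
        # genomically rightmost 30
        assert s.exon_chain[-1] == ("chr3", 500, 570, "-")
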