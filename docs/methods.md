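# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `fusionq`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

Input is a reference transcriptome (spliced transcript FASTA plus
exon-level GTF) and paired-end RNA-Seq reads (two FASTQ files, Phred+33,
read length ≥ 50 bp, pairs matched by record order). The caller assumes:

- fusions preserve transcript sense (5' piece of one gene joined to a 3'
  piece of another, both read in transcription direction);
- each split read harbours at most one fusion point;
- sequencing noise is substitution-only (no indels) — alignment is
  therefore substitution-only Hamming matching;
- fragment (mate-pair) lengths are approximately normal.

All internal coordinates are 0-based half-open; GTF's 1-based closed
convention is converted at the parsing boundary only. A fusion is
reported as `(gene5, gene3, breakpoint5, breakpoint3)` where
`breakpoint5` is the last retained base of the 5' partner and
`breakpoint3` the first retained base of the 3' partner, on their
transcripts.

## Alignment

A k-mer index (default `k = 12`) over transcript forward strands seeds
alignment; queries are verified by full Hamming comparison, with the
reverse strand handled by reverse-complementing the query. Seeds are
non-overlapping windows, so a query of length L is guaranteed complete up
to `floor(L/k) − 1` mismatches: 3 for full 50 bp reads (cap 2 is used,
"fewer than three"), 1 for 25 bp half reads (the cap for seeds). `N`
never matches any base, including `N`.

Pair classification: *concordant* requires a shared transcript, proper
forward/reverse orientation and an implied fragment length within
`mean ± 3·sd` of the insert model (the 3·sd window is a conventional
choice; the concordance window is not otherwise principled). *Spanning*
requires opposite-strand hits in different genes. A pair with exactly one
unmapped end nominates that end as a candidate split read; pairs with
neither end mapped get one rescue attempt from half-read alignments
before being discarded. PCR duplicates are removed before alignment by
exact `(end1, end2)` sequence identity — read-level QC, deliberately
independent of alignment.

The insert model is estimated from concordant fragment lengths found
under the prior (164, 48); with fewer than two observations the prior is
kept. Note the ±3·sd acceptance window truncates the tails, so the
estimated sd is biased slightly low (≈ 44 when the truth is 48); this is
accepted because the model is used only for windows and densities, where
the effect is negligible.

## Breakpoint detection

Candidate split reads are split in the middle (floor/ceil for odd
lengths). Each half aligning with ≤ 1 mismatch is a seed; extension
proceeds base by base toward the unmapped side against each seed hit's
transcript. The mismatch budget (1, shared with the seed) may be consumed
during extension only when the mismatch is followed by at least
`mismatch_anchor = 4` matching bases. Without the anchor rule, the first
chimeric base consumes the budget whenever it happens to differ from the
5' continuation and extension then drifts past the true junction;
requiring 4 subsequent matches bounds the per-junction probability of an
overshoot by about `(1/4)^4`. The maximal extension over all hits defines
the split offset and breakpoint; reads extending to their full length
carry no junction.

Junction micro-homology (the first bases of the 3' piece equal the 5'
continuation) makes the breakpoint a closed interval of equivalent
representations; all junctions — called and simulated truth alike — are
canonicalised to the rightmost representation, so "breakpoint exact"
comparisons are well defined.

### Residual sequence extension

The residual (the unextended remainder, required ≥ 5 bp per partner) is
usually too short to place uniquely. A 20 bp contig is taken around the
junction — centred when the residual is ≥ 10 bp, otherwise the 20 bp
window containing the whole residual — and all *other* unmapped,
non-candidate reads containing the contig exactly (either strand) are
collected as reference reads. They are anchored at their contig
occurrence, merged by per-column strict majority (the consensus is
trimmed at conflicting columns), and the merged residual side is
realigned. The gene is accepted when the best placements fall in a single
gene, with at most 3 genes hit overall (residuals hitting more genes are
unresolvable repeats; the candidate is dropped). Contig matching is exact
because 20-mer exactness keeps the search specific and indexable.

### Assembly

Calls are grouped by gene pair and transcript pair; breakpoints within
±2 bp collapse to the modal pair (the tolerance absorbs ≤ 1 bp mismatch
wobble at junctions). A split read whose mapped mate belongs to neither
partner gene is discarded; no read supports two candidates. Spanning
pairs attach when their forward-strand end lies upstream of `break5` and
their reverse end downstream of `break3`, each within `mean + 3·sd` of
the junction.

## Filters

1. **Read numbers** — keep iff `n_split ≥ 2`, `n_span ≥ 2` and
   `n_split + n_span ≥ 4` ("more than one of each, more than three in
   total"); all three are configurable.
2. **Similarity** — Smith–Waterman local alignment between every pair of
   partner isoforms (match +5, mismatch −4, gap of length L costs
   10 + 0.5·L). Similarity = identities / max(alignment length,
   min(sequence lengths)); the denominator floor keeps a short perfect
   repeat inside long unrelated sequences from scoring 1. Discard when
   similarity exceeds 0.50 strictly (0.50 exactly is kept).
3. **Position distribution** — background positions are the
   length-normalised starts of concordant reads on up to 200 sampled
   well-covered transcripts (≥ 5 pairs each); each sampled transcript's
   own K-S p-value against the pool (itself excluded) forms an empirical
   p-value null. For a candidate, each side's spanning-read *junction
   distances* are first mapped through their model-implied CDF: with
   fragment length X ~ N(mean, sd) and the junction uniform in the
   insert, the distance d of a spanning end from the junction has CDF
   `(E[(X−a)+] − E[(X−a−d)+]) / E[(X−a)+]`, `a = 2·read_len`. This
   probability integral transform makes genuine fusions' positions
   ~uniform on [0, 1] — the background's scale — whereas raw
   length-normalised positions would cluster within one insert length of
   the junction and fail the test precisely when coverage is good.
   Stacked artifact positions remain degenerate and are discarded. The
   candidate is discarded when either side's p-value falls below the
   empirical 2.5% quantile of the null; with fewer than two spanning
   positions on a side the filter abstains. Sample-size mismatch between
   null transcripts and candidates leaves a mild residual miscalibration;
   the suite verifies calibration with matched sizes.

Each filter is a pure predicate, so filter order affects logs only.

The ranking score is `log2(1 + n_split) + log2(1 + n_span) +
min(ks_p5, ks_p3)` — a documented, monotone reconstruction used only for
ordering the report; any ranking-monotone alternative would do.

## Quantification

Chimeric structures are built for every isoform pair compatible with the
breakpoints (5' exon chain truncated at `break5`, 3' chain from
`break3`) and appended to the transcript set, so junction reads align
concordantly to them. For each read pair, all concordant placements on
references and chimeras form its fragment set, with fragment likelihood

    P(x | Z) = P(end1) · P(end2) · N(d; mean, sd) · P(ψ),

where the end terms multiply `1 − e` per matching base and `e/3` per
mismatch (`e` from base quality; constant Phred 40 in simulation, so
`e = 1e-4`), `d` is the implied fragment length, and `P(ψ)` — applied
only to junction-crossing fragments — is the empirical fraction of
fusion-transcript fragments that cross a junction.

EM starts from uniform `θ` (the read-fraction parameter, Σθ = 1; the
length-normalised transcript fraction `τ_i ∝ θ_i / l_i` is also
reported). The M-step computes expected counts and soft-thresholds
fusion transcripts, `c_k ← max(0, c_k − λ)`, before renormalising;
`λ = 1` expected read by default, shared across fusions. Plain transcript
length `l_i` is used rather than an effective length; this biases
absolute abundances of short transcripts slightly but cancels in the
fusion-vs-zero decisions the pipeline makes.

The soft-threshold update is the exact simplex maximiser of
`Σ c_i log θ_i − λ Σ_{k∈F} log θ_k`, i.e. the count-space L1 shrinkage
and the log-penalty formulation are the same M-step; MAP-EM therefore
ascends the penalized objective `loglik − λ Σ_{k∈F} log max(θ_k, 1e−12)`
(the floor makes exact zeros finite), which is the monotonicity invariant
the suite asserts. Convergence is declared when the relative change of
this objective drops below 1e-6 (1000 iterations cap). Reads whose
fragment probabilities are all zero are excluded with a warning.

The expression filter removes candidates whose structures' summed `θ`
does not exceed ε (default: one expected read, `1/N`); reported abundance
is expected reads per kilobase.

## Synthetic data

The generator emulates a short-insert paired-end library: background
transcripts of uniform length 500–3000 bp with i.i.d. uniform bases (each
its own gene, 1–3 exons on a private synthetic chromosome, ~20% minus
strand); fusions between disjoint partner pairs with breakpoints uniform
in the middle 80% of each partner ("broken-exon" breakpoints, blind to
exon boundaries); fragments of length `round(N(164, 48²))` clipped to
`[2·read_len, transcript length]` and uniform start, `ceil(cov·len/100)`
fragments per source; end 1 is the fragment's first 50 bp, end 2 the
reverse complement of its last 50 bp; substitutions at 1e-4 per base;
constant Phred 40. Note the lower clip truncates the fragment-length
distribution, so its true mean is ≈ 166, not 164; tests assert against
the analytic truncated mean. Output is bit-identical for a fixed seed,
and the manifest records every fragment's source and coordinates so
junction-read offsets are recoverable exactly.

What the generator does **not** model — and hence what passing tests do
not certify about real data: sequencing indels, quality ramps and
miscalibration, coverage bias (GC, positional), real paralog families and
repeat structure (background sequences are random, so the similarity and
residual-ambiguity guards face much easier instances than a real
transcriptome), incomplete or wrong annotation, and fusion classes that
break sense-preserving concatenation (antisense partners, internal
inversions). Background reads here come from the synthetic transcriptome
rather than a real fusion-free library.

## Problem sizes and defaults

The shipped verification runs use desk-scale instances chosen to exercise
every stage with comfortable statistical margins: 20 fusions at coverage
20 (or a 1–50 ladder) over 100 background transcripts at coverage 4
(≈ 14 k pairs), 25 replicate seeds for the coverage-trend check, 2000
Monte-Carlo trials for filter calibration, 20 k reads for EM recovery.
Key defaults: `k = 12`, read mismatch cap 2, seed cap 1, anchor 4,
`min_residual = 5`, residual ambiguity cap 3 genes, collapse ±2 bp,
contig 20 bp, thresholds 2/2/4, similarity 0.50, `ks_alpha = 0.025`,
`λ = 1`, `em_tol = 1e-6`, ε = one read. The `threads` knob is accepted
for interface compatibility but the implementation is single-threaded;
all reductions are order-stable, so results never depend on it.

## Known limitations

- Substitution-only alignment: an indel near a junction shifts or loses
  the call.
- Breakpoints are reported on partner transcripts, not lifted to genomic
  coordinates.
- The spanning-position CDF transform assumes the normal insert model;
  heavily non-normal libraries would miscalibrate the distribution
  filter.
- `specificity` in reports and evaluation keeps the precision-like
  definition (true detected / all detected) used in fusion benchmarking,
  not the TN-based one.
- The similarity metric (identities over the floored local-alignment
  length) is one reasonable formalisation of "percent similarity"; the
  50% threshold is meaningful only relative to it.
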