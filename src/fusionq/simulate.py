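"""Synthetic fusion transcriptomes and paired-end reads with ground truth.

The generator produces the study conditions every downstream module is
tested under: random background transcripts, chimeric transcripts joined at
"broken-exon" breakpoints (positions chosen without regard to splice
sites), and 50 bp paired-end reads drawn from cDNA fragments whose lengths
follow N(164, 48^2), with a per-base substitution rate of 1e-4 and constant
Phred-40 base qualities.  Fragment counts per source follow
``ceil(coverage * length / (2 * read_length))``.

Every dataset carries a truth manifest so breakpoint-exactness and
sensitivity can be measured read-for-read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .formats import Transcript, write_fasta, write_fastq, write_gtf

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults reflect a typical short-insert paired-end RNA-Seq library:
    50 bp reads, fragment length ~ N(164 bp, 48 bp), substitution error
    1e-4 per base.
    """

    n_background_transcripts: int = 100
    n_fusions: int = 20
    coverage_per_fusion: list[int] = field(default_factory=list)
    background_coverage: int = 5
    read_length: int = 50
    fragment_mean: float = 164.0
    fragment_sd: float = 48.0
    error_rate: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 50:
            raise ValueError("read_length must be at least 50 bp")
        if self.fragment_mean <= self.read_length:
            raise ValueError("fragment_mean must exceed read_length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if not self.coverage_per_fusion:
            self.coverage_per_fusion = [
                max(1, round(c))
                for c in np.linspace(1, 50, self.n_fusions)
            ] if self.n_fusions else []
        if len(self.coverage_per_fusion) != self.n_fusions:
            raise ValueError("coverage_per_fusion must have n_fusions entries")


@dataclass
class GroundTruthFusion:
    """A simulated fusion: 5'/3' partners, breakpoints, chimera sequence.

    ``break5`` is the last base of the 5' partner kept in the chimera
    (0-based transcript position); ``break3`` the first base kept from the
    3' partner.  ``chimera_sequence == seq5[:break5+1] + seq3[break3:]``.
    """

    fusion_id: str
    gene5: str
    gene3: str
    transcript5: str
    transcript3: str
    break5: int
    break3: int
    chimera_sequence: str
    coverage: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_transcriptome(config: SimConfig, rng: np.random.Generator | None = None) -> list[Transcript]:
    """Generate random background transcripts, one gene each.

    Lengths are uniform in [500, 3000] bp with i.i.d. uniform bases.  Each
    transcript gets its own synthetic genomic locus with 1-3 exons so that
    chimeric structure construction has annotation to work on.
    """
    if config.n_background_transcripts < 2:
        raise ValueError("need at least 2 background transcripts")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    transcripts = []
    for i in range(config.n_background_transcripts):
        length = int(rng.integers(500, 3001))
        seq = _random_sequence(rng, length)
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False).tolist())
        widths = np.diff([0, *cuts, length]).tolist()
        strand = "+" if rng.random() < 0.8 else "-"
        chrom = f"chrS{i}"
        pos, exons = 100, []
        for w in widths:
            exons.append((chrom, pos, pos + int(w)))
            pos += int(w) + int(rng.integers(50, 500))
        if strand == "-":
            exons = exons[::-1]  # transcription order: 5' exon first
        transcripts.append(
            Transcript(
                transcript_id=f"t{i:04d}",
                gene_id=f"g{i:04d}",
                sequence=seq,
                exons=exons,
                strand=strand,
            )
        )
    return transcripts


def make_fusions(
    transcripts: Sequence[Transcript],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[GroundTruthFusion]:
    """Pick disjoint partner pairs and join them at broken-exon breakpoints.

    Breakpoints are uniform within the middle 80% of each partner, so both
    chimera flanks exceed the read length for transcripts >= 500 bp.
    """
    if len(transcripts) < 2 * config.n_fusions:
        raise ValueError("need at least 2 transcripts per fusion")
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    order = rng.permutation(len(transcripts))
    fusions = []
    for i in range(config.n_fusions):
        t5 = transcripts[order[2 * i]]
        t3 = transcripts[order[2 * i + 1]]
        len5, len3 = t5.length, t3.length
        break5 = int(rng.integers(int(0.1 * len5), int(0.9 * len5)))
        break3 = int(rng.integers(int(0.1 * len3), int(0.9 * len3)))
        chimera = t5.sequence[: break5 + 1] + t3.sequence[break3:]
        fusions.append(
            GroundTruthFusion(
                fusion_id=f"fusion{i:03d}",
                gene5=t5.gene_id,
                gene3=t3.gene_id,
                transcript5=t5.transcript_id,
                transcript3=t3.transcript_id,
                break5=break5,
                break3=break3,
                chimera_sequence=chimera,
                coverage=config.coverage_per_fusion[i],
            )
        )
    return fusions


def simulate_pairs(
    sources: Sequence[tuple[str, str, int]],
    config: SimConfig,
    fastq1: str | Path,
    fastq2: str | Path,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw paired-end reads from ``(source_id, sequence, coverage)`` triples.

    Fragment lengths are ``round(N(fragment_mean, fragment_sd^2))`` clipped
    to ``[2*read_length, len(sequence)]``; fragment starts are uniform.
    End 1 is the first ``read_length`` bases of the fragment, end 2 the
    reverse complement of the last ``read_length`` bases.  Substitution
    errors hit each base independently with probability ``error_rate``.
    Qualities are constant Phred 40.

    Returns the truth manifest: one row per fragment with its source and
    coordinates, enough to recover the breakpoint offset of every junction
    read.  Output is bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(config.rng_seed + 2) if rng is None else rng
    rl = config.read_length
    qual = "I" * rl  # Phred 40 at +33
    rows = []
    fq1: list[tuple[str, str, str]] = []
    fq2: list[tuple[str, str, str]] = []
    for source_id, seq, coverage in sources:
        if len(seq) < 2 * rl:
            log.warning("skipping %s: %d bp is shorter than 2*read_length", source_id, len(seq))
            continue
        n_frags = math.ceil(coverage * len(seq) / (2 * rl))
        lengths = np.clip(
            np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n_frags)),
            2 * rl,
            len(seq),
        ).astype(int)
        for j, frag_len in enumerate(lengths):
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
            end1 = _with_errors(frag[:rl], config.error_rate, rng)
            end2 = _with_errors(revcomp(frag[-rl:]), config.error_rate, rng)
            pair_id = f"{source_id}_f{j}"
            fq1.append((f"{pair_id}/1", end1, qual))
            fq2.append((f"{pair_id}/2", end2, qual))
            rows.append(
                {
                    "pair_id": pair_id,
                    "source_id": source_id,
                    "fragment_start": start,
                    "fragment_length": int(frag_len),
                }
            )
    write_fastq(fq1, fastq1)
    write_fastq(fq2, fastq2)
    return pd.DataFrame(rows, columns=["pair_id", "source_id", "fragment_start", "fragment_length"])


def _with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class SimulatedDataset:
    """File paths and in-memory truth for one simulated dataset."""

    fasta: Path
    gtf: Path
    fastq1: Path
    fastq2: Path
    truth: pd.DataFrame
    manifest: pd.DataFrame
    transcripts: list[Transcript]
    fusions: list[GroundTruthFusion]


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> SimulatedDataset:
    """Generate a complete dataset: transcriptome FASTA + GTF, paired FASTQ
    with background and fusion reads, truth manifest TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    transcripts = make_transcriptome(config, rng)
    fusions = make_fusions(transcripts, config, rng)

    fasta = out / "transcriptome.fa"
    gtf = out / "transcriptome.gtf"
    write_fasta([(t.transcript_id, t.sequence) for t in transcripts], fasta)
    write_gtf(transcripts, gtf)

    sources = [
        (t.transcript_id, t.sequence, config.background_coverage) for t in transcripts
    ] + [(f.fusion_id, f.chimera_sequence, f.coverage) for f in fusions]
    fastq1, fastq2 = out / "reads_1.fastq", out / "reads_2.fastq"
    manifest = simulate_pairs(sources, config, fastq1, fastq2, rng)

    truth = pd.DataFrame(
        [
            {
                "fusion_id": f.fusion_id,
                "gene5": f.gene5,
                "gene3": f.gene3,
                "transcript5": f.transcript5,
                "transcript3": f.transcript3,
                "break5": f.break5,
                "break3": f.break3,
                "coverage": f.coverage,
            }
            for f in fusions
        ],
        columns=[
            "fusion_id",
            "gene5",
            "gene3",
            "transcript5",
            "transcript3",
            "break5",
            "break3",
            "coverage",
        ],
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return SimulatedDataset(
        fasta=fasta,
        gtf=gtf,
        fastq1=fastq1,
        fastq2=fastq2,
        truth=truth,
        manifest=manifest,
        transcripts=transcripts,
        fusions=fusions,
    )
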