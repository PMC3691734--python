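"""Readers and writers for the standard formats the pipeline touches.

The module owns the three domain containers that cross module boundaries
(:class:`Transcript`, :class:`ReadPair`, :class:`FusionRecord`) and the I/O
for transcript FASTA, paired FASTQ, exon-level GTF annotation, and the
tab-separated fusion report.

All internal coordinates are 0-based half-open; conversion from GTF's
1-based closed convention happens here and only here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Transcript:
    """A transcript sequence with optional exon structure.

    Attributes
    ----------
    transcript_id, gene_id : str
        Identifiers; several transcripts may share a ``gene_id``.
    sequence : str
        Spliced transcript sequence, 5'->3', uppercase A/C/G/T/N.
    exons : list of (chrom, start, end)
        Genomic intervals, 0-based half-open, ordered in transcription
        direction (index 0 is the 5' exon; reversed genomic order on the
        minus strand).
    strand : str
        "+" or "-".
    """

    transcript_id: str
    gene_id: str
    sequence: str = ""
    exons: list[tuple[str, int, int]] = field(default_factory=list)
    strand: str = "+"

    @property
    def length(self) -> int:
        if self.sequence:
            return len(self.sequence)
        return sum(e - s for _, s, e in self.exons)

    def __post_init__(self) -> None:
        if self.sequence and self.exons:
            exon_len = sum(e - s for _, s, e in self.exons)
            if exon_len != len(self.sequence):
                raise FormatError(
                    f"transcript {self.transcript_id}: exon widths sum to "
                    f"{exon_len} but sequence is {len(self.sequence)} bp"
                )


@dataclass
class ReadPair:
    """One paired-end read: two sequenced ends plus Phred qualities."""

    pair_id: str
    end1_seq: str
    end2_seq: str
    end1_qual: list[int]
    end2_qual: list[int]

    def __post_init__(self) -> None:
        if not self.end1_seq or not self.end2_seq:
            raise FormatError(f"pair {self.pair_id}: empty end sequence")
        if len(self.end1_qual) != len(self.end1_seq) or len(self.end2_qual) != len(
            self.end2_seq
        ):
            raise FormatError(
                f"pair {self.pair_id}: quality length does not match sequence"
            )


@dataclass
class FusionRecord:
    """One row of the fusion report.

    ``breakpoint5`` is the transcript position of the last base of the 5'
    partner (0-based); ``breakpoint3`` the first base of the 3' partner.
    ``structures`` holds one formatted exon-chain string per chimeric
    transcript structure.
    """

    gene5: str
    gene3: str
    breakpoint5: int
    breakpoint3: int
    n_split: int
    n_span: int
    similarity: float
    ks_p5: float
    ks_p3: float
    score: float
    abundance: float
    structures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_split < 0 or self.n_span < 0:
            raise ValueError("read counts must be non-negative")
        if not (math.isnan(self.similarity) or 0.0 <= self.similarity <= 1.0):
            raise ValueError("similarity must lie in [0, 1]")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record_id, uppercase_sequence), ...]``.

    Multi-line records are joined.  A file whose first non-blank content is
    not a header, or a record with an empty sequence, raises
    :class:`FormatError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"{path}: record '{rec.id}' has an empty sequence")
            records.append((rec.id, seq))
    except ValueError as exc:  # Biopython signals malformed FASTA this way
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files, pairing records by order.

    Qualities are decoded Phred+33 by the parser.  Unequal record counts
    raise :class:`FormatError` when the shorter file runs out.
    """
    _SENTINEL = object()
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    i = 0
    while True:
        r1 = next(it1, _SENTINEL)
        r2 = next(it2, _SENTINEL)
        if r1 is _SENTINEL and r2 is _SENTINEL:
            return
        if r1 is _SENTINEL or r2 is _SENTINEL:
            short = path1 if r1 is _SENTINEL else path2
            raise FormatError(
                f"{short}: ran out of records at pair {i}; FASTQ files are not "
                "equally sized"
            )
        yield ReadPair(
            pair_id=str(r1.id),
            end1_seq=str(r1.seq).upper(),
            end2_seq=str(r2.seq).upper(),
            end1_qual=list(r1.letter_annotations["phred_quality"]),
            end2_qual=list(r2.letter_annotations["phred_quality"]),
        )
        i += 1


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write ``(id, sequence, quality_string)`` triples as FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_gtf(path: str | Path, sequences: Mapping[str, str] | None = None) -> list[Transcript]:
    """Parse exon features from a GTF file into :class:`Transcript` records.

    GTF 1-based closed exon coordinates become 0-based half-open.  Exons are
    ordered 5'->3' in transcription direction (reversed genomic order for
    minus-strand transcripts).  When ``sequences`` maps transcript ids to
    spliced sequences, each transcript is filled from it and the exon-width
    invariant is checked.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tid: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        try:
            tid = exon["transcript_id"][0]
            gid = exon["gene_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"{path}: exon at {exon.seqid}:{exon.start}-{exon.end} lacks "
                f"attribute {exc}"
            ) from exc
        entry = by_tid.setdefault(tid, {"gene": gid, "strand": exon.strand, "exons": []})
        # GTF is 1-based closed; internal convention is 0-based half-open.
        entry["exons"].append((exon.seqid, exon.start - 1, exon.end))
    transcripts = []
    for tid, entry in by_tid.items():
        exons = sorted(entry["exons"], key=lambda e: e[1])
        if entry["strand"] == "-":
            exons = exons[::-1]
        seq = "" if sequences is None else sequences.get(tid, "")
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=entry["gene"],
                sequence=seq,
                exons=exons,
                strand=entry["strand"],
            )
        )
    return transcripts


def write_gtf(transcripts: Sequence[Transcript], path: str | Path, source: str = "fusionq") -> None:
    """Write exon features for each transcript (GTF, 1-based closed)."""
    with open(path, "w") as fh:
        for t in transcripts:
            exons = t.exons if t.strand == "+" else t.exons[::-1]
            for chrom, start, end in exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


REPORT_COLUMNS = [
    "gene5",
    "gene3",
    "breakpoint5",
    "breakpoint3",
    "n_split",
    "n_span",
    "similarity",
    "ks_p5",
    "ks_p3",
    "score",
    "abundance",
    "structures",
]


def write_fusion_report(records: Sequence[FusionRecord], path: str | Path) -> None:
    """Write fusion records as TSV, sorted by descending abundance with
    ties broken lexicographically on (gene5, gene3)."""
    ordered = sorted(records, key=lambda r: (-r.abundance, r.gene5, r.gene3))
    rows = [
        {
            "gene5": r.gene5,
            "gene3": r.gene3,
            "breakpoint5": r.breakpoint5,
            "breakpoint3": r.breakpoint3,
            "n_split": r.n_split,
            "n_span": r.n_span,
            "similarity": f"{r.similarity:.6g}",
            "ks_p5": f"{r.ks_p5:.6g}",
            "ks_p3": f"{r.ks_p3:.6g}",
            "score": f"{r.score:.6g}",
            "abundance": f"{r.abundance:.6g}",
            "structures": ";".join(r.structures),
        }
        for r in ordered
    ]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fusion_report(path: str | Path) -> list[FusionRecord]:
    """Parse a fusion report written by :func:`write_fusion_report`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene5": str, "gene3": str, "structures": str})
    records = []
    for row in df.itertuples(index=False):
        structures = [] if pd.isna(row.structures) or row.structures == "" else str(
            row.structures
        ).split(";")
        records.append(
            FusionRecord(
                gene5=row.gene5,
                gene3=row.gene3,
                breakpoint5=int(row.breakpoint5),
                breakpoint3=int(row.breakpoint3),
                n_split=int(row.n_split),
                n_span=int(row.n_span),
                similarity=float(row.similarity),
                ks_p5=float(row.ks_p5),
                ks_p3=float(row.ks_p3),
                score=float(row.score),
                abundance=float(row.abundance),
                structures=structures,
            )
        )
    return records
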