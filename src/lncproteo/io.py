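"""Domain types and readers/writers for the standard interchange formats.

The pipeline exchanges data as FASTA (sequences, protein databases), GTF
(gene models) and TSV (count tables, peptide lists, transition tables).
Sequence I/O goes through Biopython, gene models through gffutils, tables
through pandas; this module only adds the validation the pipeline relies
on (duplicate accessions, coordinate conventions, controlled vocabularies).

Coordinate convention: GTF stays 1-based inclusive at the file boundary;
everything internal is 0-based half-open.  The two conversion helpers are
the single crossing point and are inverses of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lncproteo")

LIBRARY_TYPES = ("mRNA", "RNC", "RFP")
BIOTYPES = ("coding", "lncRNA")
PE_STATUSES = ("PE1", "PE2", "PE3", "PE4", "PE5", "none")


# ---------------------------------------------------------------------------
# coordinate conversion (the only place 1-based and 0-based meet)

def gtf_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive GTF interval -> 0-based half-open internal interval."""
    if start < 1 or end < start:
        raise ValueError(f"invalid GTF interval ({start}, {end})")
    return start - 1, end


def internal_to_gtf(start: int, end: int) -> tuple[int, int]:
    """0-based half-open internal interval -> 1-based inclusive GTF interval."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid internal interval ({start}, {end})")
    return start + 1, end


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Transcript:
    """A spliced transcript with its gene model annotation.

    ``sequence`` is the sense-strand, already-spliced transcript sequence in
    the canonical DNA alphabet (T, not U); strand only annotates genomic
    placement and never affects ORF scanning.  ``exons`` are genomic
    intervals, 1-based inclusive as in GTF, ordered 5'->3' on the transcript.
    """

    transcript_id: str
    gene_id: str
    chromosome: str = "chrU"
    strand: str = "+"
    biotype: str = "lncRNA"
    sequence: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)
    pe_status: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.pe_status not in PE_STATUSES:
            raise ValueError(f"unknown PE status {self.pe_status!r}")
        self.sequence = normalize_sequence(self.sequence)
        if self.exons:
            exon_len = sum(e - s + 1 for s, e in self.exons)
            if self.sequence and exon_len != len(self.sequence):
                raise ValueError(
                    f"{self.transcript_id}: exon length {exon_len} != "
                    f"sequence length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        if self.sequence:
            return len(self.sequence)
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons) if self.exons else 1


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene read count (and RPKM) for one library of one sample."""

    gene_id: str
    sample_id: str
    library: str
    read_count: int
    rpkm: float = float("nan")

    def __post_init__(self) -> None:
        if self.library not in LIBRARY_TYPES:
            raise ValueError(f"unknown library tag {self.library!r}")
        if self.read_count < 0 or int(self.read_count) != self.read_count:
            raise ValueError(f"read_count must be a non-negative integer, got {self.read_count!r}")


def normalize_sequence(seq: str, rna_to_dna: bool = True) -> str:
    """Uppercase and (optionally) map U->T into the canonical DNA alphabet."""
    seq = seq.upper()
    if rna_to_dna:
        seq = seq.replace("U", "T")
    return seq


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, rna_to_dna: bool = True) -> list[tuple[str, str, str]]:
    """Read FASTA into (id, description, sequence) triples, order preserved.

    Sequences are uppercased; U->T normalization is applied unless
    ``rna_to_dna`` is False (protein FASTA must pass False).  Duplicate
    identifiers and empty records are rejected.
    """
    records: list[tuple[str, str, str]] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), rna_to_dna=rna_to_dna)
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append((rec.id, desc, seq))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate FASTA identifiers in {path}: {dupes}")
    return records


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, description, sequence) triples; round-trips with read_fasta."""
    seq_records = []
    for rid, desc, seq in records:
        if not seq:
            raise ValueError(f"refusing to write empty record {rid!r}")
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: str | Path) -> dict[str, Transcript]:
    """Read exon features of a GTF into Transcript models (no sequence).

    Coordinates are kept 1-based inclusive as in the file.  Exons are
    ordered 5'->3' on the transcript (reversed genomic order on the minus
    strand).  A transcript mixing strands, or an exon without a
    transcript_id attribute, is an error.
    """
    text = Path(path).read_text()
    if not text.strip():
        logger.warning("GTF %s is empty; returning no gene models", path)
        return {}
    db = gffutils.create_db(
        text, ":memory:", from_string=True, force=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    transcripts: dict[str, Transcript] = {}
    exon_lists: dict[str, list[tuple[int, int]]] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if "transcript_id" not in feat.attributes:
            raise ValueError(f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks transcript_id")
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        biotype = feat.attributes.get("gene_biotype", ["lncRNA"])[0]
        if tid not in transcripts:
            transcripts[tid] = Transcript(
                transcript_id=tid, gene_id=gid, chromosome=feat.seqid,
                strand=feat.strand, biotype=biotype,
            )
            exon_lists[tid] = []
        else:
            if transcripts[tid].strand != feat.strand:
                raise ValueError(f"transcript {tid} mixes strands")
            if transcripts[tid].chromosome != feat.seqid:
                raise ValueError(f"transcript {tid} spans chromosomes")
        exon_lists[tid].append((feat.start, feat.end))
    for tid, exons in exon_lists.items():
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"transcript {tid} has overlapping exons")
        if transcripts[tid].strand == "-":
            exons.reverse()
        transcripts[tid].exons = exons
    return transcripts


def write_gtf(transcripts: Iterable[Transcript], path: str | Path, source: str = "lncproteo") -> None:
    """Write exon features for each transcript, 1-based inclusive."""
    with open(path, "w") as handle:
        for t in transcripts:
            exons = t.exons or [(1, t.length)]
            for start, end in sorted(exons):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{t.biotype}";'
                )
                handle.write(
                    f"{t.chromosome}\t{source}\texon\t{start}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# count tables

def read_count_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV of per-gene counts into ExpressionRecords.

    Required columns: gene_id, sample_id, library, read_count; rpkm is
    optional (recomputed downstream when absent).  Malformed numeric cells
    are rejected with their line number; unknown library tags are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "sample_id", "library", "read_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} lacks columns {missing}")
    records: list[ExpressionRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        lib = row["library"]
        if lib not in LIBRARY_TYPES:
            raise ValueError(f"line {line_no}: unknown library tag {lib!r}")
        try:
            count = int(row["read_count"])
        except (TypeError, ValueError):
            raise ValueError(f"line {line_no}: malformed read_count {row['read_count']!r}")
        rpkm = float("nan")
        if "rpkm" in df.columns and pd.notna(row["rpkm"]):
            try:
                rpkm = float(row["rpkm"])
            except (TypeError, ValueError):
                raise ValueError(f"line {line_no}: malformed rpkm {row['rpkm']!r}")
        records.append(ExpressionRecord(row["gene_id"], row["sample_id"], lib, count, rpkm))
    return records


def write_count_table(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "sample_id": [r.sample_id for r in records],
            "library": [r.library for r in records],
            "read_count": [r.read_count for r in records],
            "rpkm": [r.rpkm for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Generic TSV reader (peptide lists, transition tables, truth tables)."""
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
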