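"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  The only place a
conversion happens is at the SAM boundary (SAM text is 1-based); pysam
performs that conversion for us.  Parsers stream where the format
allows it, and reject malformed intervals with the offending line
number.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tescan")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open stranded interval with an optional score.

    ``start`` is 0-based inclusive, ``end`` exclusive.  Strand ``.``
    (unstranded, the usual case for ChIP peaks) is treated as ``+``
    wherever an orientation is needed.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class AlignmentRecord:
    """A single read placement on genome or consensus space.

    ``mapq`` is the aligner's mapping quality (0-60), used downstream
    as a uniqueness surrogate (e.g. the MAPQ>20 filter at repeats).
    """

    read_id: str
    ref: str
    start: int
    length: int
    strand: str = "+"
    mapq: int = 42

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("alignment start must be >= 0")
        if not (0 <= self.mapq <= 60):
            raise ValueError(f"mapq {self.mapq} outside [0, 60]")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def midpoint(self) -> int:
        return self.start + self.length // 2


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS/TES anchors and exon intervals.

    TSS is upstream of TES in strand orientation: for ``+`` genes
    tss < tes, for ``-`` genes tes < tss.  Exons are half-open
    intervals within the gene span.
    """

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + gene needs tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise ValueError(f"{self.gene_id}: - gene needs tes < tss")
        lo, hi = self.span_start, self.span_end
        for s, e in self.exons:
            if not (lo <= s < e <= hi):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside span")

    @property
    def span_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def span_end(self) -> int:
        return max(self.tss, self.tes)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Sequences are uppercased.  Duplicate ids and empty records are
    rejected.
    """
    seqs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    del width  # Biopython wraps at 60 columns


# ---------------------------------------------------------------------------
# SAM


def read_sam(path) -> Iterator[AlignmentRecord]:
    """Stream alignments from a SAM file.

    SAM 1-based positions become 0-based internal starts (pysam does
    this).  Unmapped records are skipped; the count is logged.  A mapq
    of 255 ("unavailable") is mapped to 0 so the MAPQ filter fails
    safe.
    """
    skipped = 0
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped:
                skipped += 1
                continue
            mapq = rec.mapping_quality
            if mapq == 255:
                mapq = 0
            yield AlignmentRecord(
                read_id=rec.query_name,
                ref=rec.reference_name,
                start=rec.reference_start,
                length=rec.query_length or (rec.reference_end - rec.reference_start),
                strand="-" if rec.is_reverse else "+",
                mapq=min(mapq, 60),
            )
    if skipped:
        logger.info("read_sam: skipped %d unmapped records", skipped)


def write_sam(
    records: Iterable[AlignmentRecord], references: Mapping[str, int], path
) -> None:
    """Write alignments as text SAM with the given reference lengths."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = out.header.references.index(rec.ref)
            a.reference_start = rec.start
            a.mapping_quality = rec.mapq
            a.cigarstring = f"{rec.length}M"
            out.write(a)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list:
    """Read BED3/BED6 into GenomicIntervals (half-open, as BED is)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            out.append(
                GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Repeat instance and gene tables (TSV)

INSTANCE_COLUMNS = ["chrom", "start", "end", "strand", "class_id"]


def read_repeat_instances(path):
    """Read a RepeatMasker-style instance table (TSV, half-open coords).

    Returns a pandas DataFrame with columns chrom, start, end, strand,
    class_id.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "class_id": str})
    missing = set(INSTANCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"instance table missing columns: {sorted(missing)}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"instance table row {bad[0] + 2}: start >= end")
    return df[INSTANCE_COLUMNS]


def write_repeat_instances(df, path) -> None:
    df[INSTANCE_COLUMNS].to_csv(path, sep="\t", index=False)


def _format_exons(exons) -> str:
    return ",".join(f"{s}-{e}" for s, e in exons) or "."


def _parse_exons(text: str):
    if text in (".", "", None):
        return ()
    return tuple(
        (int(a), int(b)) for a, b in (part.split("-") for part in text.split(","))
    )


def read_gene_table(path) -> list:
    """Read a gene annotation TSV into GeneModel objects."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                tss=int(row.tss),
                tes=int(row.tes),
                strand=row.strand,
                exons=_parse_exons(getattr(row, "exons", ".")),
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\ttes\tstrand\texons\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.tes}\t{g.strand}\t"
                f"{_format_exons(g.exons)}\n"
            )
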