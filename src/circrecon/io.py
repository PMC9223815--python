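"""Readers and writers for every external file the pipeline touches.

All coordinates are normalized here, and only here, to 1-based inclusive
``[start, end]`` intervals.  Dialects with other conventions (BED12 and
CIRCexplorer-style BED, 0-based half-open) are converted on read; BED
dumps are converted back on write.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"^(?:\d+[MNSHDI])+$")


class FormatError(ValueError):
    """An input file does not conform to its declared dialect."""


class CoordinateError(ValueError):
    """A genomic coordinate falls outside the sequence it refers to."""


@dataclass
class CircRNARecord:
    """One circRNA locus, identified by its back-splice junction (BSJ).

    ``start`` and ``end`` are the 1-based inclusive BSJ coordinates (the
    5' and 3' boundary of the circularized interval on the genome).
    ``read_names`` holds the identifiers of the spanning reads — the
    chimeric reads whose alignment crosses the BSJ.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    read_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"circRNA start {self.start} > end {self.end} on {self.chrom}"
            )

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"

    def add_reads(self, names: Iterable[str]) -> None:
        seen = set(self.read_names)
        for name in names:
            if name not in seen:
                self.read_names.append(name)
                seen.add(name)


@dataclass
class AlignmentSegment:
    """One chimeric alignment line: a read piece mapped to the genome.

    ``pos`` is the 1-based leftmost reference coordinate (SAM POS);
    ``cigar`` is restricted to the {M, N, S, H, D, I} alphabet this
    method consumes.
    """

    read_name: str
    chrom: str
    pos: int
    cigar: str
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"alignment POS must be >= 1, got {self.pos}")
        if not _CIGAR_RE.match(self.cigar):
            raise ValueError(f"malformed CIGAR string: {self.cigar!r}")


@dataclass(frozen=True)
class AnnotatedExon:
    """An exon from the reference annotation, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")


@dataclass(frozen=True)
class ChimericJunction:
    """One chimeric junction call: the two breakpoints of a split read."""

    chrom_donor: str
    pos_donor: int
    chrom_acceptor: str
    pos_acceptor: int
    read_name: str


# ---------------------------------------------------------------------------
# circRNA list


def _parse_circ_id(text: str) -> tuple[str, int, int]:
    if ":" not in text or "|" not in text:
        raise FormatError(f"malformed circRNA identifier {text!r}: expected 'chrom:start|end'")
    chrom, _, coords = text.partition(":")
    left, _, right = coords.partition("|")
    try:
        return chrom, int(left), int(right)
    except ValueError as exc:
        raise FormatError(f"non-numeric coordinate in circRNA identifier {text!r}") from exc


def read_circ_list(path: str | Path, zero_based: bool = False) -> list[CircRNARecord]:
    """Read a two-column circRNA list: ``chrom:start|end`` then comma-joined read names.

    Coordinates are taken as written (1-based inclusive).  Set
    ``zero_based=True`` for lists derived from CIRCexplorer's BED output,
    whose start is 0-based half-open; the start is then shifted by +1.
    A line with an empty second column yields a record with no reads and
    a warning.
    """
    records: list[CircRNARecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) > 2:
                raise FormatError(f"line {lineno}: expected 2 columns, got {len(fields)}")
            try:
                chrom, start, end = _parse_circ_id(fields[0])
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if zero_based:
                start += 1
            reads = [r for r in fields[1].split(",") if r] if len(fields) == 2 else []
            if not reads:
                logger.warning("line %d: circRNA %s has no spanning reads listed", lineno, fields[0])
            records.append(CircRNARecord(chrom, start, end, read_names=reads))
    return records


def write_circ_list(records: Sequence[CircRNARecord], path: str | Path) -> None:
    """Write records in the two-column dialect :func:`read_circ_list` reads."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"{rec.circ_id}\t{','.join(rec.read_names)}\n")


# ---------------------------------------------------------------------------
# chimeric alignments (SAM/BAM)


def _segments_from_headerless_sam(path: str | Path) -> list[AlignmentSegment]:
    # 11 mandatory SAM columns (+ optional tags), no header: the tabular
    # per-circRNA dump dialect.  Column 3 is the chromosome as plain text.
    segments: list[AlignmentSegment] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise FormatError(f"line {lineno}: expected >= 11 SAM columns, got {len(cols)}")
            qname, flag, rname, pos, _, cigar = cols[0], int(cols[1]), cols[2], int(cols[3]), cols[4], cols[5]
            if flag & 0x4 or rname == "*":
                continue
            if cigar == "*":
                logger.warning("line %d: read %s has no CIGAR, skipped", lineno, qname)
                continue
            segments.append(AlignmentSegment(qname, rname, pos, cigar, bool(flag & 0x10)))
    return segments


def read_chimeric_alignments(path: str | Path) -> list[AlignmentSegment]:
    """Read chimeric read alignments from SAM or BAM.

    Every mapped record yields one :class:`AlignmentSegment` (both pieces
    of a chimeric pair are retained, sharing their QNAME); unmapped
    records and records without a CIGAR are skipped.  A headerless
    tab-separated SAM dump is accepted as a fallback dialect.
    """
    path = Path(path)
    try:
        mode = "rb" if path.suffix == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
            segments: list[AlignmentSegment] = []
            for rec in af:
                if rec.is_unmapped or rec.reference_name is None:
                    continue
                if rec.cigarstring is None:
                    logger.warning("read %s has no CIGAR, skipped", rec.query_name)
                    continue
                segments.append(
                    AlignmentSegment(
                        read_name=rec.query_name,
                        chrom=rec.reference_name,
                        pos=rec.reference_start + 1,
                        cigar=rec.cigarstring,
                        is_reverse=rec.is_reverse,
                    )
                )
            return segments
    except (ValueError, NotImplementedError):
        # pysam needs a header; fall back to the headerless tabular dialect
        try:
            return _segments_from_headerless_sam(path)
        except (OSError, FormatError, ValueError) as exc:
            raise FormatError(f"cannot parse {path} as SAM/BAM: {exc}") from exc


# ---------------------------------------------------------------------------
# chimeric junction table (STAR Chimeric.out.junction dialect)


def read_chimeric_junctions(path: str | Path) -> list[ChimericJunction]:
    """Read a STAR-style chimeric junction table.

    Uses columns 1-2 (donor chromosome / breakpoint), 4-5 (acceptor
    chromosome / breakpoint) and 10 (read name); the strand, junction
    type and repeat-length columns are ignored.  Comment lines and the
    header line of newer STAR versions are skipped.
    """
    junctions: list[ChimericJunction] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chr_donorA"):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(f"junction line has {len(cols)} columns, expected >= 10")
            junctions.append(
                ChimericJunction(
                    chrom_donor=cols[0],
                    pos_donor=int(cols[1]),
                    chrom_acceptor=cols[3],
                    pos_acceptor=int(cols[4]),
                    read_name=cols[9],
                )
            )
    return junctions


# ---------------------------------------------------------------------------
# annotation (GTF / BED12)


def _exons_from_gtf(path: str | Path) -> list[AnnotatedExon]:
    tx_re = re.compile(r'transcript_id "([^"]+)"')
    exons: list[AnnotatedExon] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns, got {len(cols)}")
            if cols[2] != "exon":
                continue
            m = tx_re.search(cols[8])
            exons.append(
                AnnotatedExon(
                    chrom=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    transcript_id=m.group(1) if m else "",
                )
            )
    return exons


def _exons_from_bed12(path: str | Path) -> list[AnnotatedExon]:
    exons: list[AnnotatedExon] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise FormatError(f"line {lineno}: expected 12 BED columns, got {len(cols)}")
            chrom, chrom_start, name = cols[0], int(cols[1]), cols[3]
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets):
                raise FormatError(f"line {lineno}: blockSizes/blockStarts length mismatch")
            for size, offset in zip(sizes, offsets):
                # 0-based half-open block -> 1-based inclusive exon
                start = chrom_start + offset + 1
                exons.append(AnnotatedExon(chrom, start, start + size - 1, name))
    return exons


def read_annotation_exons(path: str | Path, dialect: str | None = None) -> list[AnnotatedExon]:
    """Read exon intervals from a GTF or BED12 annotation.

    GTF exon features are 1-based inclusive and kept unchanged; BED12
    blocks are converted from 0-based half-open.  ``dialect`` is
    ``"gtf"`` or ``"bed12"``; when omitted it is inferred from the file
    extension.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower().lstrip(".")
        if suffix in ("gtf", "gff"):
            dialect = "gtf"
        elif suffix == "bed":
            dialect = "bed12"
    if dialect == "gtf":
        return _exons_from_gtf(path)
    if dialect == "bed12":
        return _exons_from_bed12(path)
    raise FormatError(f"unknown annotation dialect {dialect!r} (expected 'gtf' or 'bed12')")


# ---------------------------------------------------------------------------
# genome FASTA


def load_genome(path: str | Path) -> Fasta:
    """Open an indexed genome FASTA (the .fai index is built on first use)."""
    return Fasta(str(path), sequence_always_upper=True)


def fetch_genome_subsequence(
    genome: Fasta | Mapping[str, str], chrom: str, start: int, end: int
) -> str:
    """Return the uppercase genome bases of ``[start, end]``, 1-based inclusive."""
    if chrom not in genome:
        raise CoordinateError(f"chromosome {chrom!r} not present in genome")
    record = genome[chrom]
    length = len(record)
    if not (1 <= start <= end <= length):
        raise CoordinateError(
            f"interval [{start}, {end}] out of range for {chrom} (length {length})"
        )
    piece = record[start - 1 : end]
    seq = piece if isinstance(piece, str) else piece.seq
    return seq.upper()


# ---------------------------------------------------------------------------
# reconstructed-sequence FASTA


def write_fulllength_fasta(results: Sequence, path: str | Path) -> None:
    """Write reconstructed sequences as FASTA, one record per result.

    Headers are the circRNA identifier ``chrom:start|end``; bodies are
    wrapped at 60 columns.  An empty result list produces a valid empty
    file and a warning.
    """
    if not results:
        logger.warning("writing empty full-length FASTA to %s", path)
    records = [
        SeqRecord(Seq(res.sequence), id=res.circ_id, description="") for res in results
    ]
    for res, rec in zip(results, records):
        if not res.sequence:
            raise ValueError(f"result {res.circ_id} has an empty sequence")
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{identifier: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
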