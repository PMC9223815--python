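"""Clip final exons to the back-splice junction and assemble full-length sequences.

Per circRNA the pipeline is: collect spanning-read alignments, decompose
each CIGAR into exon/intron blocks, snap exons to the annotation, pool
evidence across reads, detect and subtract skip exons, clip the result
to the BSJ interval, and concatenate the genomic sequence of the
surviving exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .exons import (
    AnnotationIndex,
    Interval,
    IntervalSet,
    detect_skip_exons,
    merge_intervals,
    parse_cigar_segments,
    subtract_skip_exons,
)
from .io import (
    AlignmentSegment,
    AnnotatedExon,
    CircRNARecord,
    CoordinateError,
    fetch_genome_subsequence,
)
from .spanning import extract_spanning_alignments

logger = logging.getLogger(__name__)


@dataclass
class ReconstructionConfig:
    """Tunable knobs of the reconstruction pipeline.

    snap_bp
        Maximum distance (bases) between the outermost exon evidence and
        the BSJ coordinate for the terminal exon to be forced flush with
        the BSJ.  Read ends are ragged; 10 bp absorbs that.
    d_advances_reference
        CIGAR D handling: by default deletions are ignored like S/H/I;
        set True for strict SAM semantics (D consumes reference).
    revcomp_minus
        Reverse-complement the assembled sequence of minus-strand
        circRNAs.  Off by default: genome-forward output keeps
        coordinate-space comparison against long-read FASTA trivial.
    """

    snap_bp: int = 10
    d_advances_reference: bool = False
    revcomp_minus: bool = False


@dataclass
class FullLengthResult:
    """A reconstructed circRNA: its final exon chain and assembled sequence."""

    circ_id: str
    chrom: str
    exons: list[Interval]
    sequence: str
    n_spanning_reads: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != sum(e - s + 1 for s, e in self.exons):
            raise ValueError(
                f"{self.circ_id}: sequence length {len(self.sequence)} != exon span"
            )


@dataclass
class RunReport:
    """Aggregate tallies of one reconstruction run."""

    attempted: int = 0
    assembled: int = 0
    rows: list[dict] = field(default_factory=list)

    @property
    def abandoned(self) -> int:
        return self.attempted - self.assembled

    @property
    def reconstruction_rate_pct(self) -> float | None:
        if self.attempted == 0:
            return None
        return 100.0 * self.assembled / self.attempted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["circ_id", "n_reads", "n_exons", "length", "status"]
        )


def clip_exons_to_circ(
    exons: IntervalSet, circ: CircRNARecord, snap_bp: int = 10
) -> IntervalSet:
    """Intersect the final exon set with the BSJ interval ``[start, end]``.

    Exons wholly outside are dropped.  When the outermost retained
    evidence reaches within ``snap_bp`` of a BSJ coordinate, the
    terminal exon is forced flush with it (circRNA sequences start and
    end exactly at the back-splice junction).
    """
    clipped = [
        (max(s, circ.start), min(e, circ.end))
        for s, e in exons.intervals
        if s <= circ.end and e >= circ.start
    ]
    if clipped:
        first_s, first_e = clipped[0]
        if 0 < first_s - circ.start <= snap_bp:
            clipped[0] = (circ.start, first_e)
        last_s, last_e = clipped[-1]
        if 0 < circ.end - last_e <= snap_bp:
            clipped[-1] = (last_s, circ.end)
    return IntervalSet(exons.chrom, clipped, "exon")


def assemble_full_length(
    circ: CircRNARecord,
    final_exons: IntervalSet,
    genome,
    revcomp_minus: bool = False,
) -> FullLengthResult:
    """Concatenate the genomic sequence of the final exons in coordinate order."""
    if not final_exons.intervals:
        raise ValueError(f"{circ.circ_id}: no final exons to assemble")
    parts = [
        fetch_genome_subsequence(genome, final_exons.chrom, s, e)
        for s, e in sorted(final_exons.intervals)
    ]
    sequence = "".join(parts)
    if revcomp_minus and circ.strand == "-":
        sequence = str(Seq(sequence).reverse_complement())
    return FullLengthResult(
        circ_id=circ.circ_id,
        chrom=final_exons.chrom,
        exons=sorted(final_exons.intervals),
        sequence=sequence,
        n_spanning_reads=len(circ.read_names),
    )


def infer_final_exons(
    circ: CircRNARecord,
    segments: Sequence[AlignmentSegment],
    annotation: AnnotationIndex,
    config: ReconstructionConfig,
) -> IntervalSet:
    """Run CIGAR decomposition, annotation snap and skip-exon removal for one circRNA.

    Exon and intron evidence is pooled (union) across all spanning
    reads, so an intron gap observed in any read can veto exon bases
    supported only by another — that veto is the skip-exon rule.
    """
    exon_sets: list[IntervalSet] = []
    intron_sets: list[IntervalSet] = []
    for seg in segments:
        blocks = parse_cigar_segments(seg.pos, seg.cigar, config.d_advances_reference)
        exon_ivs: list[Interval] = []
        intron_ivs: list[Interval] = []
        for block in blocks:
            if block.opcode == "M":
                snapped, _ = annotation.snap(seg.chrom, block.interval)
                exon_ivs.append(snapped)
            else:
                intron_ivs.append(block.interval)
        if exon_ivs:
            exon_sets.append(IntervalSet(seg.chrom, exon_ivs, "exon"))
        if intron_ivs:
            intron_sets.append(IntervalSet(seg.chrom, intron_ivs, "intron"))
    if not exon_sets:
        return IntervalSet(circ.chrom, [], "exon")
    exons = merge_intervals(exon_sets)
    if intron_sets:
        introns = merge_intervals(intron_sets)
        skips = detect_skip_exons(exons, introns)
        exons = subtract_skip_exons(exons, skips)
    return exons


def reconstruct_all(
    circs: Sequence[CircRNARecord],
    segments: Sequence[AlignmentSegment],
    annotation: Sequence[AnnotatedExon] | AnnotationIndex,
    genome,
    config: ReconstructionConfig | None = None,
) -> tuple[list[FullLengthResult], RunReport]:
    """Reconstruct every circRNA; return results plus a per-circRNA run report.

    Failures are per-circRNA, never fatal: a circRNA with no exon
    evidence inside its BSJ interval is reported as not assembled and
    counts against the reconstruction rate (assembled / attempted).
    """
    config = config or ReconstructionConfig()
    index = annotation if isinstance(annotation, AnnotationIndex) else AnnotationIndex(annotation)
    assignments = extract_spanning_alignments(circs, segments)
    results: list[FullLengthResult] = []
    report = RunReport()
    for circ in circs:
        report.attempted += 1
        segs = assignments.get(circ.circ_id, [])
        row = {
            "circ_id": circ.circ_id,
            "n_reads": len({s.read_name for s in segs}),
            "n_exons": 0,
            "length": 0,
            "status": "no_spanning_reads",
        }
        if segs:
            try:
                final = clip_exons_to_circ(
                    infer_final_exons(circ, segs, index, config), circ, config.snap_bp
                )
                if final.intervals:
                    result = assemble_full_length(circ, final, genome, config.revcomp_minus)
                    results.append(result)
                    report.assembled += 1
                    row.update(
                        n_exons=len(result.exons),
                        length=len(result.sequence),
                        status="assembled",
                    )
                else:
                    row["status"] = "no_exons_in_bsj_interval"
            except CoordinateError as exc:
                logger.error("%s: genome fetch failed: %s", circ.circ_id, exc)
                row["status"] = "genome_fetch_failed"
        report.rows.append(row)
    logger.info(
        "reconstructed %d/%d circRNAs (%.2f%%)",
        report.assembled,
        report.attempted,
        report.reconstruction_rate_pct or 0.0,
    )
    return results, report
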