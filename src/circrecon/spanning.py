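"""Assign chimeric alignments to the circRNAs their reads span.

A spanning read is one whose chimeric junction breakpoints coincide with
a circRNA's back-splice junction.  Assignment is by read name: both
pieces of a split read are kept, and a read shared by two circRNAs is
copied to both.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

from .io import AlignmentSegment, ChimericJunction, CircRNARecord

logger = logging.getLogger(__name__)


def map_junctions_to_circrnas(
    junctions: Sequence[ChimericJunction],
    circs: Sequence[CircRNARecord],
    tolerance: int = 0,
) -> list[CircRNARecord]:
    """Populate each circRNA's spanning-read set from a chimeric junction table.

    A junction's read is assigned to a circRNA when both breakpoints are
    on the circRNA's chromosome and each falls within ``tolerance``
    bases of one BSJ coordinate (the lower breakpoint against the BSJ
    start, the higher against the BSJ end — chimeric callers report
    donor/acceptor in either order).  Assigned reads are unioned with
    any reads already listed; records are modified in place and returned.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_chrom: dict[str, list[CircRNARecord]] = {}
    for circ in circs:
        by_chrom.setdefault(circ.chrom, []).append(circ)
    for jct in junctions:
        if jct.chrom_donor != jct.chrom_acceptor:
            continue
        lo = min(jct.pos_donor, jct.pos_acceptor)
        hi = max(jct.pos_donor, jct.pos_acceptor)
        for circ in by_chrom.get(jct.chrom_donor, []):
            if abs(lo - circ.start) <= tolerance and abs(hi - circ.end) <= tolerance:
                circ.add_reads([jct.read_name])
    return list(circs)


def extract_spanning_alignments(
    circs: Sequence[CircRNARecord], segments: Sequence[AlignmentSegment]
) -> dict[str, list[AlignmentSegment]]:
    """Collect, per circRNA, the alignment segments of its spanning reads.

    A segment belongs to a circRNA when its read name is in the
    circRNA's spanning-read set *and* it maps to the circRNA's
    chromosome.  Per-circRNA order is input order; segments are never
    invented or deduplicated, so a read shared by two circRNAs appears
    under both.
    """
    out: dict[str, list[AlignmentSegment]] = {circ.circ_id: [] for circ in circs}
    by_name: dict[str, list[AlignmentSegment]] = {}
    order: dict[int, int] = {}
    for idx, seg in enumerate(segments):
        by_name.setdefault(seg.read_name, []).append(seg)
        order[id(seg)] = idx
    for circ in circs:
        picked = [
            seg
            for name in circ.read_names
            for seg in by_name.get(name, [])
            if seg.chrom == circ.chrom
        ]
        # restore global input order (reads were grouped by name above)
        picked.sort(key=lambda seg: order[id(seg)])
        out[circ.circ_id] = picked
        if not picked:
            logger.warning("circRNA %s has no spanning alignment segments", circ.circ_id)
    return out


def write_spanning_dumps(
    assignments: dict[str, list[AlignmentSegment]], outdir: str | Path
) -> list[Path]:
    """Write one TSV per circRNA with its spanning alignments in SAM column order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for circ_id, segs in assignments.items():
        path = outdir / (circ_id.replace(":", "_").replace("|", "_") + ".tsv")
        with open(path, "w") as handle:
            for seg in segs:
                flag = 16 if seg.is_reverse else 0
                handle.write(
                    f"{seg.read_name}\t{flag}\t{seg.chrom}\t{seg.pos}\t255\t{seg.cigar}\t*\t0\t0\t*\t*\n"
                )
        written.append(path)
    return written
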