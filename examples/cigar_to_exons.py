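"""Decompose a chimeric alignment's CIGAR string into exon and intron intervals.

A spanning read aligned at POS=125314967 with CIGAR
67M8354N57M7713N81M44S carries three exon blocks (M) separated by two
intron gaps (N); the trailing 44S soft clip is the piece of the read
that maps on the other side of the back-splice junction and does not
consume reference.  Exons are then snapped to the annotation: if an
annotated exon intersects a CIGAR exon, the annotated coordinates win.
"""

from circrecon import AnnotatedExon, parse_cigar_segments, snap_exon_to_annotation

segments = parse_cigar_segments(125314967, "67M8354N57M7713N81M44S")
print("op  length      start        end")
for seg in segments:
    print(f"{seg.opcode:>2} {seg.n:>7} {seg.start:>10} {seg.end:>10}")

annotated = [
    AnnotatedExon("chr7", 125323308, 125323444, "NM_021964"),
    AnnotatedExon("chr7", 125331157, 125331238, "NM_021964"),
]
print("\nannotation snap (CIGAR exon -> final exon):")
for seg in segments:
    if seg.opcode == "M":
        final, provenance = snap_exon_to_annotation(seg.interval, annotated)
        print(f"  {seg.interval} -> {final}  [{provenance}]")
# The middle and last exons intersect annotated exons and adopt their
# coordinates; the first has no annotated partner and is kept as read.
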