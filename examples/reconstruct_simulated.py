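"""Reconstruct full-length circRNA sequences from a simulated input bundle.

Generates a ground-truthed bundle (genome, annotation, circRNA list,
chimeric SAM, junction table), runs the full reconstruction pipeline
and compares every assembled sequence with the planted truth.  On
noise-free input every circRNA should be recovered exactly.
"""

import tempfile

from circrecon import (
    SimConfig,
    load_genome,
    read_annotation_exons,
    read_chimeric_alignments,
    read_circ_list,
    reconstruct_all,
    simulate_bundle,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = simulate_bundle(SimConfig(seed=1, n_circ=20, skip_probability=0.3), tmp)
    circs = read_circ_list(bundle.circ_list)
    segments = read_chimeric_alignments(bundle.alignments)
    annotation = read_annotation_exons(bundle.annotation)
    genome = load_genome(bundle.genome)

    results, report = reconstruct_all(circs, segments, annotation, genome)
    exact = sum(r.sequence == bundle.truth_sequences[r.circ_id] for r in results)

    print(f"assembled {report.assembled}/{report.attempted} circRNAs "
          f"(reconstruction rate {report.reconstruction_rate_pct:.2f}%)")
    print(f"exact truth recoveries: {exact}/{len(results)}")
    first = results[0]
    print(f"example: {first.circ_id}  exons={len(first.exons)}  "
          f"length={len(first.sequence)} nt  reads={first.n_spanning_reads}")
# The rate is assembled/attempted; an exact recovery means the
# assembled sequence is byte-identical to the planted exon chain with
# skip exons removed.
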