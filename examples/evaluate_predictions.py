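"""Score reconstructed sequences against a long-read-style reference set.

Uses the simulator's truth FASTA as the stand-in for a long-read
reference, the pipeline's own output as the current method, and a
deliberately degraded copy (one circRNA dropped, one sequence
corrupted) as the competing method, so that TP, FP and FN are all
exercised.
"""

import tempfile

import numpy as np

from circrecon import (
    SimConfig,
    classify,
    load_genome,
    metrics,
    mutate_sequence,
    read_annotation_exons,
    read_chimeric_alignments,
    read_circ_list,
    read_fasta_sequences,
    reconstruct_all,
    simulate_bundle,
)

with tempfile.TemporaryDirectory() as tmp:
    bundle = simulate_bundle(SimConfig(seed=7, n_circ=12, skip_probability=0.3), tmp)
    circs = read_circ_list(bundle.circ_list)
    segments = read_chimeric_alignments(bundle.alignments)
    annotation = read_annotation_exons(bundle.annotation)
    genome = load_genome(bundle.genome)
    results, report = reconstruct_all(circs, segments, annotation, genome)

    reference = read_fasta_sequences(bundle.truth_fasta)
    current = {r.circ_id: r.sequence for r in results}
    # competitor: drops one circRNA, corrupts another beyond the 95% bar
    other = dict(current)
    dropped = sorted(other)[0]
    other.pop(dropped)
    rng = np.random.default_rng(0)
    corrupt_id = sorted(other)[0]
    other[corrupt_id] = mutate_sequence(other[corrupt_id], 0.2, rng)

    for name, predictions in (("current", current), ("competitor", other)):
        counts = classify(predictions, reference,
                          other if name == "current" else current)
        rep = metrics(counts, n_candidates=len(circs)).rounded()
        print(f"{name:>10}: NRS={counts.n_reconstructed} TP={counts.tp} "
              f"FP={counts.fp} FN={counts.fn} precision={rep['precision_pct']}% "
              f"sensitivity={rep['sensitivity_pct']}% F1={rep['f1']}")
# A prediction is a TP when it passes both similarity criteria against
# a reference sequence (>95% identity and match count within 10 of the
# mean length); an FN is a circRNA the other method got verified but
# this method never assembled.
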