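"""Ground-truthed synthetic input bundles for the whole pipeline.

The generator plants multi-exon circRNA loci on a random genome and
emits every file the reconstruction pipeline consumes — genome FASTA,
GTF annotation, circRNA list, chimeric SAM, junction table — plus the
planted truth (full-length sequences of the non-skipped exon chains).

Each spanning read realizes the full planted exon/intron structure as a
chimeric pair: two SAM lines sharing a QNAME, one per side of the
back-splice junction, with the far side soft-clipped.  When a circRNA
carries a planted skip exon, half of its reads include that exon as an
M block and the other half span it inside an N gap, so the skip-exon
veto is actually exercised.  Terminal read ends are left slightly
ragged (a few bases short of the exon boundary) so annotation snapping
has work to do.

The generator emulates alignment *structure*, not sequencing physics:
base qualities, sequencer-specific error profiles and fragment-length
variation are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle.

    Defaults describe a small but structurally complete experiment:
    20 circRNAs of 2-5 exons (60-200 bp) separated by 80-500 bp
    introns on two 100 kb chromosomes, 4 spanning reads per circRNA,
    internal exons skipped with probability 0.3, error-free bases.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_circ: int = 20
    exons_per_circ: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (60, 200)
    intron_length: tuple[int, int] = (80, 500)
    skip_probability: float = 0.3
    coverage: int = 4
    base_error_rate: float = 0.0
    end_trim_max: int = 4
    locus_gap: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.skip_probability <= 1.0:
            raise ValueError("skip_probability must be in [0, 1]")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be in [0, 1]")
        for name in ("n_chroms", "chrom_length", "coverage"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantedCirc:
    """Truth for one simulated circRNA locus (1-based inclusive intervals)."""

    chrom: str
    exons: list[tuple[int, int]]
    skipped: list[bool]
    read_names: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}|{self.end}"

    @property
    def kept_exons(self) -> list[tuple[int, int]]:
        return [iv for iv, sk in zip(self.exons, self.skipped) if not sk]


@dataclass
class SimBundle:
    """Paths of one generated bundle plus its in-memory truth."""

    outdir: Path
    genome: Path
    annotation: Path
    circ_list: Path
    alignments: Path
    junctions: Path
    truth_fasta: Path
    truth_table: Path
    truth_sequences: dict[str, str]
    circs: list[PlantedCirc]


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Replace each base with probability ``rate`` by a uniform draw from ACGT.

    The draw may return the original base, so at rate 1 the expected
    identity to the input is 25% on long sequences.
    """
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    arr[hit] = rng.choice(_BASES, size=int(hit.sum()))
    return "".join(arr)


def _plant_loci(config: SimConfig, rng: np.random.Generator) -> list[PlantedCirc]:
    loci: list[PlantedCirc] = []
    cursors = {f"chr{i + 1}": 1_000 for i in range(config.n_chroms)}
    chrom_names = list(cursors)
    for idx in range(config.n_circ):
        k = int(rng.integers(config.exons_per_circ[0], config.exons_per_circ[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=k)
        intron_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, size=max(k - 1, 0)
        )
        span = int(exon_lens.sum() + intron_lens.sum())
        chrom = chrom_names[idx % config.n_chroms]
        start = cursors[chrom]
        if start + span + config.locus_gap > config.chrom_length:
            raise ValueError(
                f"configuration infeasible: circRNA {idx} does not fit on {chrom} "
                f"(needs {span} bp at {start}, chrom_length={config.chrom_length})"
            )
        exons: list[tuple[int, int]] = []
        pos = start
        for j in range(k):
            exons.append((pos, pos + int(exon_lens[j]) - 1))
            pos += int(exon_lens[j])
            if j < k - 1:
                pos += int(intron_lens[j])
        cursors[chrom] = pos + config.locus_gap
        # only internal exons may be skipped: the BSJ pins the terminal ones
        skipped = [False] * k
        for j in range(1, k - 1):
            skipped[j] = bool(rng.random() < config.skip_probability)
        loci.append(PlantedCirc(chrom, exons, skipped))
    return loci


def _read_blocks(
    circ: PlantedCirc, include_skipped: bool
) -> list[tuple[str, int, int]]:
    """(op, start, end) M/N chain over the genome for one read variant."""
    kept = [iv for iv, sk in zip(circ.exons, circ.skipped) if include_skipped or not sk]
    blocks: list[tuple[str, int, int]] = []
    for i, (s, e) in enumerate(kept):
        if i > 0:
            blocks.append(("N", kept[i - 1][1] + 1, s - 1))
        blocks.append(("M", s, e))
    return blocks


def _blocks_to_cigar(blocks: list[tuple[str, int, int]]) -> str:
    return "".join(f"{e - s + 1}{op}" for op, s, e in blocks)


def _exonic_seq(blocks: list[tuple[str, int, int]], chrom_seq: str) -> str:
    return "".join(chrom_seq[s - 1 : e] for op, s, e in blocks if op == "M")


def simulate_bundle(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Write a complete, deterministic input bundle under ``outdir``.

    Emits ``genome.fa``, ``annotation.gtf``, ``circ_list.tsv``,
    ``chimeric.sam``, ``junctions.tsv``, ``truth.fa`` and ``truth.tsv``.
    Byte-identical output for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {
        name: "".join(rng.choice(_BASES, size=config.chrom_length)) for name in chrom_names
    }
    circs = _plant_loci(config, rng)

    # reads: alternate exon-skipping / exon-inclusive structural variants
    sam_records: list[tuple] = []  # (qname, flag, chrom, pos, cigar, seq)
    junction_rows: list[str] = []
    for ci, circ in enumerate(circs):
        has_skip = any(circ.skipped)
        for r in range(config.coverage):
            qname = f"read_c{ci}_{r}"
            circ.read_names.append(qname)
            include_skipped = has_skip and (r % 2 == 1)
            blocks = _read_blocks(circ, include_skipped)
            # a BSJ-crossing read is a suffix+prefix of the circle: segment A
            # realizes the exon chain's tail, segment B the chain from the BSJ
            # start through the whole structure, so every N gap is observed
            m_idx = [i for i, b in enumerate(blocks) if b[0] == "M"]
            part_a, part_b = blocks[m_idx[len(m_idx) // 2] :], list(blocks)
            # ragged outer ends: trim a few bases off the outermost M blocks
            t1 = int(rng.integers(0, config.end_trim_max + 1))
            t2 = int(rng.integers(0, config.end_trim_max + 1))
            op0, s0, e0 = part_b[0]
            if e0 - (s0 + t1) + 1 >= 20:
                part_b = [(op0, s0 + t1, e0)] + part_b[1:]
            opz, sz, ez = part_a[-1]
            if (ez - t2) - sz + 1 >= 20:
                part_a = part_a[:-1] + [(opz, sz, ez - t2)]
            seq_a = _exonic_seq(part_a, genome[circ.chrom])
            seq_b = _exonic_seq(part_b, genome[circ.chrom])
            full_seq = seq_a + seq_b
            if config.base_error_rate > 0:
                full_seq = mutate_sequence(full_seq, config.base_error_rate, rng)
            cigar_a = _blocks_to_cigar(part_a) + f"{len(seq_b)}S"
            cigar_b = f"{len(seq_a)}S" + _blocks_to_cigar(part_b)
            sam_records.append((qname, 0, circ.chrom, part_a[0][1], cigar_a, full_seq))
            sam_records.append((qname, 2048, circ.chrom, part_b[0][1], cigar_b, full_seq))
            junction_rows.append(
                f"{circ.chrom}\t{circ.end}\t+\t{circ.chrom}\t{circ.start}\t+\t0\t0\t0\t{qname}"
            )

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for name in chrom_names:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        for ci, circ in enumerate(circs):
            tx = f"tx{ci}"
            for s, e in circ.exons:
                attrs = f'gene_id "g{ci}"; transcript_id "{tx}";'
                fh.write(f"{circ.chrom}\tsim\texon\t{s}\t{e}\t.\t+\t.\t{attrs}\n")

    circ_path = outdir / "circ_list.tsv"
    with open(circ_path, "w") as fh:
        for circ in circs:
            fh.write(f"{circ.circ_id}\t{','.join(circ.read_names)}\n")

    sam_path = outdir / "chimeric.sam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": config.chrom_length} for name in chrom_names],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for qname, flag, chrom, pos, cigar, seq in sam_records:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = qname
            rec.flag = flag
            rec.reference_name = chrom
            rec.reference_start = pos - 1
            rec.mapping_quality = 255
            rec.cigarstring = cigar
            rec.query_sequence = seq
            sam.write(rec)

    junction_path = outdir / "junctions.tsv"
    junction_path.write_text("".join(row + "\n" for row in junction_rows))

    truth_sequences = {
        circ.circ_id: "".join(
            genome[circ.chrom][s - 1 : e] for s, e in circ.kept_exons
        )
        for circ in circs
    }
    truth_fa = outdir / "truth.fa"
    with open(truth_fa, "w") as fh:
        for circ_id, seq in truth_sequences.items():
            fh.write(f">{circ_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    truth_tsv = outdir / "truth.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("circ_id\texons\tskipped\tlength\n")
        for circ in circs:
            structure = ",".join(f"{s}-{e}" for s, e in circ.exons)
            flags = ",".join("1" if sk else "0" for sk in circ.skipped)
            fh.write(
                f"{circ.circ_id}\t{structure}\t{flags}\t{len(truth_sequences[circ.circ_id])}\n"
            )

    return SimBundle(
        outdir=outdir,
        genome=genome_path,
        annotation=gtf_path,
        circ_list=circ_path,
        alignments=sam_path,
        junctions=junction_path,
        truth_fasta=truth_fa,
        truth_table=truth_tsv,
        truth_sequences=truth_sequences,
        circs=circs,
    )


def corrupt_reads(bundle: SimBundle, substitution_rate: float, seed: int = 0) -> SimBundle:
    """Return a bundle whose SAM SEQ fields carry seeded base substitutions.

    Coordinates and CIGARs are untouched, so the alignment structure —
    and therefore the reconstruction — is preserved; only the
    read-derived base evidence degrades.  A rate of 0 returns the input
    bundle unchanged.
    """
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must be in [0, 1]")
    if substitution_rate == 0.0:
        return bundle
    rng = np.random.default_rng(seed)
    out_path = bundle.alignments.with_name("chimeric.corrupted.sam")
    with open(bundle.alignments) as src, open(out_path, "w") as dst:
        for line in src:
            if line.startswith("@"):
                dst.write(line)
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[9] != "*":
                cols[9] = mutate_sequence(cols[9], substitution_rate, rng)
            dst.write("\t".join(cols) + "\n")
    return SimBundle(
        **{
            **bundle.__dict__,
            "alignments": out_path,
        }
    )
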