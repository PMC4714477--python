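"""Synthetic toy study with planted ground truth.

Generates a random genome with gene models and exclusion tracks, plants
editing sites (sense-strand A positions inside genes) and germline SNPs,
and simulates multi-sample RNA/DNA alignments: RNA reads are drawn from
mature transcripts (splice gaps as CIGAR N) plus a per-tissue
intron-retention fraction, DNA reads uniformly from the genome. All
randomness flows from one seed; the same seed yields byte-identical output
files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from .intervals import IntervalSet
from .io_formats import (
    AlignedRead,
    ExclusionTracks,
    GeneModel,
    GenomeSequence,
    write_bed,
    write_fasta,
    write_gff3,
)
from .snv_calling import detect_homopolymers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


# ---------------------------------------------------------------------------
# Configuration and truth


@dataclass
class SampleSpec:
    sample_id: str
    tissue: str
    kind: str  # "RNA" or "DNA"
    depth: float
    read_length: int = 75


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 40
    exons_per_gene: int = 5
    exon_length: int = 300
    intron_length: int = 150
    utr_length: int = 150
    samples: List[SampleSpec] = field(default_factory=list)
    n_edits: int = 200
    n_snps: int = 100
    edit_freq_min: float = 0.1
    edit_freq_max: float = 1.0
    intronic_edit_fraction: float = 0.15
    tissue_active_prob: float = 0.6
    expressed_fraction: float = 0.9
    intron_retention: Dict[str, float] = field(default_factory=dict)
    default_intron_retention: float = 0.05
    base_error_rate: float = 0.001
    het_fraction: float = 0.8
    n_track_intervals: int = 4
    track_interval_length: int = 400
    n_homopolymer_runs: int = 10
    homopolymer_run_length: int = 8
    multimap_read_fraction: float = 0.002
    lowqual_read_fraction: float = 0.002

    def retention(self, tissue: str) -> float:
        return self.intron_retention.get(tissue, self.default_intron_retention)

    def rna_samples(self) -> List[SampleSpec]:
        return [s for s in self.samples if s.kind == "RNA"]

    def dna_samples(self) -> List[SampleSpec]:
        return [s for s in self.samples if s.kind == "DNA"]

    def tissues(self) -> List[str]:
        seen: List[str] = []
        for s in self.rna_samples():
            if s.tissue not in seen:
                seen.append(s.tissue)
        return seen

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        data["samples"] = [SampleSpec(**s) for s in data.get("samples", [])]
        return cls(**data)


def default_config(seed: int = 0) -> SimulationConfig:
    """The default toy study: 6 RNA tissues + 2 pooled DNA samples."""
    tissues = ["brain", "liver", "heart", "kidney", "spleen", "testis"]
    depths = [40, 15, 20, 25, 30, 35]
    samples = [
        SampleSpec(f"{t}_rna", t, "RNA", d) for t, d in zip(tissues, depths)
    ] + [
        SampleSpec("brain_dna", "brain", "DNA", 20),
        SampleSpec("spleen_dna", "spleen", "DNA", 20),
    ]
    return SimulationConfig(
        seed=seed,
        samples=samples,
        intron_retention={"brain": 0.4},
    )


def small_config(seed: int = 0) -> SimulationConfig:
    """A minimal configuration for fast unit and determinism tests."""
    cfg = default_config(seed)
    cfg.n_chroms = 1
    cfg.chrom_length = 60_000
    cfg.n_genes = 6
    cfg.n_edits = 20
    cfg.n_snps = 10
    cfg.samples = [
        SampleSpec("brain_rna", "brain", "RNA", 30),
        SampleSpec("liver_rna", "liver", "RNA", 25),
        SampleSpec("brain_dna", "brain", "DNA", 30),
    ]
    return cfg


@dataclass
class PlantedEdit:
    chrom: str
    pos: int
    strand: str
    gene_id: str
    context: str  # "exon" or "intron"
    genomic_ref: str
    genomic_alt: str
    freq: Dict[str, float]  # per tissue design frequency


@dataclass
class PlantedSnp:
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" or "hom"


@dataclass
class GroundTruth:
    edits: List[PlantedEdit] = field(default_factory=list)
    snps: List[PlantedSnp] = field(default_factory=list)
    expression: Dict[Tuple[str, str], float] = field(default_factory=dict)
    # filled during read simulation: sample -> (chrom, donor, acceptor) -> mean
    junction_means: Dict[str, Dict[Tuple[str, int, int], float]] = field(
        default_factory=dict
    )


# ---------------------------------------------------------------------------
# Genome simulation


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[GenomeSequence, List[GeneModel], ExclusionTracks]:
    """Random genome with placed genes, planted homopolymer runs and
    exclusion-track intervals. The homopolymer track is recomputed from the
    final sequence so it also covers chance runs."""
    rng = np.random.default_rng([config.seed, 0])
    arrays: Dict[str, np.ndarray] = {}
    for i in range(config.n_chroms):
        arrays[f"chr{i + 1}"] = _random_sequence(rng, config.chrom_length).copy()

    gene_span = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    genes: List[GeneModel] = []
    chrom_names = list(arrays)
    per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    gidx = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        if n_here == 0:
            continue
        pitch = config.chrom_length // (n_here + 1)
        if pitch <= gene_span:
            raise ValueError(
                f"{n_here} genes of span {gene_span} do not fit on a "
                f"{config.chrom_length} bp chromosome"
            )
        for k in range(n_here):
            start = (k + 1) * pitch - gene_span // 2
            exons = []
            pos = start
            for _ in range(config.exons_per_gene):
                exons.append((pos, pos + config.exon_length))
                pos += config.exon_length + config.intron_length
            strand = "+" if gidx % 2 == 0 else "-"
            mature = config.exons_per_gene * config.exon_length
            cds_len = 3 * ((mature - 2 * config.utr_length) // 3)
            gene = GeneModel(
                f"gene{gidx:03d}", f"tx{gidx:03d}", chrom, strand, exons
            )
            cds = gene.transcript_blocks(
                config.utr_length, config.utr_length + cds_len
            )
            genes.append(
                GeneModel(
                    f"gene{gidx:03d}", f"tx{gidx:03d}", chrom, strand, exons, cds
                )
            )
            gidx += 1

    # plant homopolymer runs in intergenic space
    gene_spans = IntervalSet.from_tuples(
        [(g.chrom, g.span[0], g.span[1]) for g in genes]
    )
    run_len = config.homopolymer_run_length
    for _ in range(config.n_homopolymer_runs):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        arr = arrays[chrom]
        for _attempt in range(50):
            p = int(rng.integers(1, len(arr) - run_len - 1))
            if not gene_spans.overlaps(chrom, p - 1, p + run_len + 1):
                base = _BASES[int(rng.integers(0, 4))]
                arr[p : p + run_len] = base
                others = [b for b in _BASES if b != base]
                arr[p - 1] = others[int(rng.integers(0, 3))]
                arr[p + run_len] = others[int(rng.integers(0, 3))]
                break

    # alignability tracks at random positions (may overlap genes)
    track_ivs: Dict[str, List[Tuple[str, int, int]]] = {
        "repeat_masker": [],
        "multimap": [],
        "self_chain": [],
    }
    for name in track_ivs:
        for _ in range(config.n_track_intervals):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = int(
                rng.integers(0, config.chrom_length - config.track_interval_length)
            )
            track_ivs[name].append(
                (chrom, start, start + config.track_interval_length)
            )

    genome = GenomeSequence(
        {name: arr.tobytes().decode() for name, arr in arrays.items()}
    )
    tracks = ExclusionTracks(
        homopolymer=detect_homopolymers(genome, min_run=5),
        repeat_masker=IntervalSet.from_tuples(track_ivs["repeat_masker"]),
        multimap=IntervalSet.from_tuples(track_ivs["multimap"]),
        self_chain=IntervalSet.from_tuples(track_ivs["self_chain"]),
    )
    return genome, genes, tracks


# ---------------------------------------------------------------------------
# Truth design


def _sense_ref_alt(strand: str) -> Tuple[str, str]:
    # sense A -> G reads as genomic A->G on '+', T->C on '-'
    return ("A", "G") if strand == "+" else ("T", "C")


def design_truth(
    config: SimulationConfig,
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    tracks: ExclusionTracks,
) -> GroundTruth:
    """Choose edit and SNP positions plus per-tissue expression weights.

    Edits land on sense-strand A positions inside genes, clear of exclusion
    tracks, genomic homopolymers and splice boundaries, so that only
    evidence-level effects decide their recovery.
    """
    rng = np.random.default_rng([config.seed, 1])
    tissues = config.tissues()
    truth = GroundTruth()

    for g in genes:
        for t in tissues:
            expressed = rng.random() < config.expressed_fraction
            weight = float(rng.uniform(0.5, 1.5)) if expressed else 0.0
            truth.expression[(g.gene_id, t)] = weight

    margin = 8
    used: Set[Tuple[str, int]] = set()

    def _ok_position(chrom: str, pos: int, want_base: str) -> bool:
        if (chrom, pos) in used:
            return False
        if genome.base(chrom, pos) != want_base:
            return False
        for _, track in tracks.items():
            if track.contains(chrom, pos):
                return False
        return all(abs(pos - p) >= 10 for c, p in used if c == chrom)

    n_intronic = int(round(config.n_edits * config.intronic_edit_fraction))
    plan = ["intron"] * n_intronic + ["exon"] * (config.n_edits - n_intronic)
    for context in plan:
        for _attempt in range(500):
            g = genes[int(rng.integers(0, len(genes)))]
            regions = g.introns if context == "intron" else g.exons
            if not regions:
                continue
            s, e = regions[int(rng.integers(0, len(regions)))]
            if e - s <= 2 * margin:
                continue
            pos = int(rng.integers(s + margin, e - margin))
            want_ref, want_alt = _sense_ref_alt(g.strand)
            if not _ok_position(g.chrom, pos, want_ref):
                continue
            active = [t for t in tissues if rng.random() < config.tissue_active_prob]
            if not active:
                active = [tissues[int(rng.integers(0, len(tissues)))]]
            f = float(rng.uniform(config.edit_freq_min, config.edit_freq_max))
            truth.edits.append(
                PlantedEdit(
                    chrom=g.chrom,
                    pos=pos,
                    strand=g.strand,
                    gene_id=g.gene_id,
                    context=context,
                    genomic_ref=want_ref,
                    genomic_alt=want_alt,
                    freq={t: (f if t in active else 0.0) for t in tissues},
                )
            )
            used.add((g.chrom, pos))
            break
        else:
            raise RuntimeError("could not place a planted edit; config too dense")

    for _ in range(config.n_snps):
        for _attempt in range(500):
            exonic = rng.random() < 0.7
            if exonic and genes:
                g = genes[int(rng.integers(0, len(genes)))]
                s, e = g.exons[int(rng.integers(0, len(g.exons)))]
                chrom = g.chrom
                pos = int(rng.integers(s + margin, e - margin))
            else:
                chrom = genome.chrom_names[
                    int(rng.integers(0, len(genome.chrom_names)))
                ]
                pos = int(rng.integers(margin, genome.length(chrom) - margin))
            ref = genome.base(chrom, pos)
            if ref not in "ACGT" or (chrom, pos) in used:
                continue
            if any(abs(pos - p) < 10 for c, p in used if c == chrom):
                continue
            alt = _BASE_STR[int(rng.integers(0, 4))]
            while alt == ref:
                alt = _BASE_STR[int(rng.integers(0, 4))]
            genotype = "het" if rng.random() < config.het_fraction else "hom"
            truth.snps.append(PlantedSnp(chrom, pos, ref, alt, genotype))
            used.add((chrom, pos))
            break
        else:
            raise RuntimeError("could not place a planted SNP; config too dense")
    return truth


# ---------------------------------------------------------------------------
# Read simulation


def _sam_header(genome: GenomeSequence) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": name, "LN": genome.length(name)}
                for name in genome.chrom_names
            ],
        }
    )


def _cigar_from_blocks(blocks: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    cigar: List[Tuple[int, int]] = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            if gap > 0:
                cigar.append((3, gap))  # N
        cigar.append((0, e - s))  # M
    return cigar


class _ReadEmitter:
    """Applies planted substitutions and sequencing errors, writes SAM."""

    def __init__(
        self,
        out: pysam.AlignmentFile,
        header: pysam.AlignmentHeader,
        genome: GenomeSequence,
        config: SimulationConfig,
        rng: np.random.Generator,
        sample_id: str,
    ):
        self.out = out
        self.header = header
        self.genome = genome
        self.config = config
        self.rng = rng
        self.sample_id = sample_id
        self.counter = 0

    def emit(
        self,
        chrom: str,
        blocks: Sequence[Tuple[int, int]],
        substitutions: Mapping[int, Tuple[str, float]],
    ) -> None:
        """Write one read. ``substitutions`` maps genomic pos -> (alt base,
        probability of carrying it)."""
        rng = self.rng
        parts = [self.genome.fetch(chrom, s, e) for s, e in blocks]
        seq = list("".join(parts))
        length = len(seq)
        # genomic pos -> query offset
        offset = 0
        qpos_of: Dict[int, int] = {}
        for s, e in blocks:
            for gpos, (alt, prob) in substitutions.items():
                if s <= gpos < e:
                    qpos_of[gpos] = offset + (gpos - s)
            offset += e - s
        for gpos, q in qpos_of.items():
            alt, prob = substitutions[gpos]
            if prob >= 1.0 or rng.random() < prob:
                seq[q] = alt
        quals = np.full(length, 30, dtype=np.uint8)
        n_err = rng.binomial(length, self.config.base_error_rate)
        if n_err:
            err_pos = rng.choice(length, size=n_err, replace=False)
            for q in err_pos:
                cur = seq[q]
                repl = _BASE_STR[int(rng.integers(0, 4))]
                while repl == cur:
                    repl = _BASE_STR[int(rng.integers(0, 4))]
                seq[q] = repl
                quals[q] = rng.integers(10, 36)
        nh = 1
        if rng.random() < self.config.multimap_read_fraction:
            nh = 2
        if rng.random() < self.config.lowqual_read_fraction:
            n_low = int(0.4 * length)
            low_pos = rng.choice(length, size=n_low, replace=False)
            quals[low_pos] = 10
        rec = pysam.AlignedSegment(self.header)
        rec.query_name = f"{self.sample_id}.r{self.counter}"
        self.counter += 1
        rec.flag = 0
        rec.reference_id = self.header.get_tid(chrom)
        rec.reference_start = blocks[0][0]
        rec.mapping_quality = 60
        rec.cigartuples = _cigar_from_blocks(blocks)
        rec.query_sequence = "".join(seq)
        rec.query_qualities = quals.tolist()
        rec.set_tags([("NH", nh)])
        self.out.write(rec)


def simulate_reads(
    config: SimulationConfig,
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    out_dir: str,
) -> Dict[str, str]:
    """Write one SAM file per sample; returns sample_id -> path.

    RNA reads come from mature transcripts of expressed genes (plus a
    per-tissue intron-retention fraction from the unspliced span); DNA reads
    are uniform over the genome. Expected junction-spanning read counts are
    recorded in ``truth.junction_means``.
    """
    os.makedirs(out_dir, exist_ok=True)
    header = _sam_header(genome)
    paths: Dict[str, str] = {}
    edits_by_gene: Dict[str, List[PlantedEdit]] = {}
    for e in truth.edits:
        edits_by_gene.setdefault(e.gene_id, []).append(e)
    snps_by_chrom: Dict[str, List[PlantedSnp]] = {}
    for s in truth.snps:
        snps_by_chrom.setdefault(s.chrom, []).append(s)
    for lst in snps_by_chrom.values():
        lst.sort(key=lambda s: s.pos)

    for sample_index, spec in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, 2, sample_index])
        path = os.path.join(out_dir, f"{spec.sample_id}.sam")
        paths[spec.sample_id] = path
        with pysam.AlignmentFile(path, "w", header=header) as out:
            emitter = _ReadEmitter(out, header, genome, config, rng, spec.sample_id)
            if spec.kind == "RNA":
                truth.junction_means.setdefault(spec.sample_id, {})
                _simulate_rna_sample(
                    config, genome, genes, truth, spec, rng, emitter,
                    edits_by_gene, snps_by_chrom,
                )
            else:
                _simulate_dna_sample(config, genome, spec, rng, emitter, snps_by_chrom)
    return paths


def _snp_substitutions(
    snps_by_chrom: Mapping[str, List[PlantedSnp]],
    chrom: str,
    start: int,
    end: int,
) -> Dict[int, Tuple[str, float]]:
    from bisect import bisect_left, bisect_right

    snps = snps_by_chrom.get(chrom, [])
    positions = [s.pos for s in snps]
    subs: Dict[int, Tuple[str, float]] = {}
    for i in range(bisect_left(positions, start), bisect_right(positions, end - 1)):
        snp = snps[i]
        subs[snp.pos] = (snp.alt, 0.5 if snp.genotype == "het" else 1.0)
    return subs


def _simulate_rna_sample(
    config: SimulationConfig,
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    spec: SampleSpec,
    rng: np.random.Generator,
    emitter: _ReadEmitter,
    edits_by_gene: Mapping[str, List[PlantedEdit]],
    snps_by_chrom: Mapping[str, List[PlantedSnp]],
) -> None:
    length = spec.read_length
    rho = config.retention(spec.tissue)
    for gene in genes:
        weight = truth.expression.get((gene.gene_id, spec.tissue), 0.0)
        if weight == 0.0:
            continue
        mature = gene.mature_length
        pre = gene.pre_length
        if mature < length or pre < length:
            continue
        n_mean = spec.depth * weight * mature / length
        n_reads = int(rng.poisson(n_mean))
        # expected junction-spanning counts for this design
        n_spliced_mean = n_mean * (1.0 - rho)
        jm = truth.junction_means[spec.sample_id]
        boundary = 0
        exon_order = gene.exons if gene.strand == "+" else gene.exons[::-1]
        for i, (s, e) in enumerate(exon_order[:-1]):
            boundary += e - s
            lo = max(boundary - length + 1, 0)
            hi = min(boundary - 1, mature - length)
            n_positions = max(hi - lo + 1, 0)
            # junction key is genomic (donor, acceptor) of the skipped intron
            if gene.strand == "+":
                intron = (gene.exons[i][1], gene.exons[i + 1][0])
            else:
                ridx = len(gene.exons) - 1 - i
                intron = (gene.exons[ridx - 1][1], gene.exons[ridx][0])
            jm[(gene.chrom, intron[0], intron[1])] = jm.get(
                (gene.chrom, intron[0], intron[1]), 0.0
            ) + n_spliced_mean * n_positions / (mature - length + 1)

        gene_edits = edits_by_gene.get(gene.gene_id, [])
        span = gene.span
        for _ in range(n_reads):
            if rng.random() < rho:
                start = span[0] + int(rng.integers(0, pre - length + 1))
                blocks = [(start, start + length)]
            else:
                t = int(rng.integers(0, mature - length + 1))
                blocks = [(s, e) for s, e in gene.transcript_blocks(t, t + length)]
            subs = _snp_substitutions(
                snps_by_chrom, gene.chrom, blocks[0][0], blocks[-1][1]
            )
            for edit in gene_edits:
                f = edit.freq.get(spec.tissue, 0.0)
                if f > 0.0:
                    subs[edit.pos] = (edit.genomic_alt, f)
            emitter.emit(gene.chrom, blocks, subs)


def _simulate_dna_sample(
    config: SimulationConfig,
    genome: GenomeSequence,
    spec: SampleSpec,
    rng: np.random.Generator,
    emitter: _ReadEmitter,
    snps_by_chrom: Mapping[str, List[PlantedSnp]],
) -> None:
    length = spec.read_length
    for chrom in genome.chrom_names:
        chrom_len = genome.length(chrom)
        n_reads = int(rng.poisson(spec.depth * chrom_len / length))
        starts = rng.integers(0, chrom_len - length + 1, size=n_reads)
        for start in starts:
            start = int(start)
            subs = _snp_substitutions(snps_by_chrom, chrom, start, start + length)
            emitter.emit(chrom, [(start, start + length)], subs)


# ---------------------------------------------------------------------------
# Whole-study convenience + truth serialization


def write_truth(truth: GroundTruth, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "edits.tsv"), "w") as fh:
        tissues = sorted({t for e in truth.edits for t in e.freq})
        fh.write(
            "chrom\tpos\tstrand\tgene_id\tcontext\tgenomic_ref\tgenomic_alt\t"
            + "\t".join(f"freq.{t}" for t in tissues)
            + "\n"
        )
        for e in sorted(truth.edits, key=lambda e: (e.chrom, e.pos)):
            fh.write(
                f"{e.chrom}\t{e.pos + 1}\t{e.strand}\t{e.gene_id}\t{e.context}\t"
                f"{e.genomic_ref}\t{e.genomic_alt}\t"
                + "\t".join(repr(e.freq.get(t, 0.0)) for t in tissues)
                + "\n"
            )
    with open(os.path.join(out_dir, "edits.bed"), "w") as fh:
        for e in sorted(truth.edits, key=lambda e: (e.chrom, e.pos)):
            fh.write(f"{e.chrom}\t{e.pos}\t{e.pos + 1}\t{e.gene_id}\t0\t{e.strand}\n")
    with open(os.path.join(out_dir, "snps.tsv"), "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgenotype\n")
        for s in sorted(truth.snps, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.ref}\t{s.alt}\t{s.genotype}\n")
    with open(os.path.join(out_dir, "expression.tsv"), "w") as fh:
        fh.write("gene_id\ttissue\tweight\n")
        for (gid, tissue), w in sorted(truth.expression.items()):
            fh.write(f"{gid}\t{tissue}\t{repr(w)}\n")


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: GenomeSequence
    genes: List[GeneModel]
    tracks: ExclusionTracks
    truth: GroundTruth
    sam_paths: Dict[str, str]
    genome_path: str
    gff3_path: str
    track_paths: Dict[str, str]


def simulate_study(config: SimulationConfig, out_dir: str) -> SimulatedStudy:
    """Generate and write a full study (FASTA, GFF3, BED tracks, SAMs, truth)."""
    os.makedirs(out_dir, exist_ok=True)
    genome, genes, tracks = simulate_genome(config)
    truth = design_truth(config, genome, genes, tracks)
    sam_paths = simulate_reads(
        config, genome, genes, truth, os.path.join(out_dir, "samples")
    )
    genome_path = os.path.join(out_dir, "genome.fa")
    write_fasta(genome, genome_path)
    gff3_path = os.path.join(out_dir, "genes.gff3")
    write_gff3(genes, gff3_path)
    track_dir = os.path.join(out_dir, "tracks")
    os.makedirs(track_dir, exist_ok=True)
    track_paths = {}
    by_field = {
        "homopolymer": tracks.homopolymer,
        "repeat_masker": tracks.repeat_masker,
        "multimap": tracks.multimap,
        "self_chain": tracks.self_chain,
    }
    for name, iset in by_field.items():
        path = os.path.join(track_dir, f"{name}.bed")
        write_bed(iset, path, name=name)
        track_paths[name] = path
    write_truth(truth, os.path.join(out_dir, "truth"))
    return SimulatedStudy(
        config=config,
        genome=genome,
        genes=genes,
        tracks=tracks,
        truth=truth,
        sam_paths=sam_paths,
        genome_path=genome_path,
        gff3_path=gff3_path,
        track_paths=track_paths,
    )


# ---------------------------------------------------------------------------
# Matrix-level correlation study (enzyme-driven vs null editing sites)


def simulate_correlation_study(
    seed: int,
    n_true: int = 5,
    n_null: int = 100,
    n_samples: int = 8,
    noise_sd: float = 0.05,
    coverage: int = 30,
    min_cov: int = 10,
):
    """Editing matrix with ``n_true`` sites whose frequency is linear in a
    single enzyme's expression plus noise, among ``n_null`` independent sites.

    Returns (EditingMatrix, enzyme_expression frame, set of true site ids).
    Null frequencies are Gaussian around 0.5 and independent of the enzyme,
    so the one-sided positive-correlation test is exactly at its nominal
    level on them.
    """
    import pandas as pd

    from .quantification import EditingMatrix

    rng = np.random.default_rng([seed, 7])
    samples = [f"s{i}" for i in range(n_samples)]
    expr = rng.uniform(5.0, 50.0, size=n_samples)
    site_ids = [f"true{i}" for i in range(n_true)] + [
        f"null{i}" for i in range(n_null)
    ]
    freq = np.empty((n_true + n_null, n_samples))
    scaled = (expr - expr.min()) / (expr.max() - expr.min())
    for i in range(n_true):
        freq[i] = np.clip(0.1 + 0.8 * scaled + rng.normal(0, noise_sd, n_samples), 0, 1)
    for i in range(n_null):
        freq[n_true + i] = np.clip(rng.normal(0.5, 0.15, n_samples), 0, 1)
    freq_df = pd.DataFrame(freq, index=site_ids, columns=samples)
    cov_df = pd.DataFrame(coverage, index=site_ids, columns=samples, dtype=int)
    called_df = pd.DataFrame(True, index=site_ids, columns=samples, dtype=bool)
    matrix = EditingMatrix(
        freq=freq_df,
        coverage=cov_df,
        called=called_df,
        mask=cov_df < min_cov,
        min_cov=min_cov,
    )
    enzyme = pd.DataFrame([expr], index=["Adar"], columns=samples)
    return matrix, enzyme, {f"true{i}" for i in range(n_true)}


# ---------------------------------------------------------------------------
# Filter gauntlet


@dataclass
class GauntletSite:
    name: str
    chrom: str
    pos: int
    ref: str
    alt: str
    rule: str  # designed violation, or "clean"


@dataclass
class GauntletFixture:
    genome: GenomeSequence
    genes: List[GeneModel]
    tracks: ExclusionTracks
    rna_reads: Dict[str, List[AlignedRead]]
    dna_reads: Dict[str, List[AlignedRead]]
    sites: List[GauntletSite]

    @property
    def expected_survivors(self) -> Set[Tuple[str, int, str]]:
        return {
            (s.chrom, s.pos, s.alt) for s in self.sites if s.rule == "clean"
        }


def _mem_read(
    chrom: str,
    start: int,
    genome_seq: str,
    sample_id: str,
    rid: str,
    length: int = 50,
    subs: Optional[Mapping[int, str]] = None,
    qual_overrides: Optional[Mapping[int, int]] = None,
    unique: bool = True,
) -> AlignedRead:
    seq = list(genome_seq[start : start + length])
    quals = [30] * length
    for gpos, base in (subs or {}).items():
        seq[gpos - start] = base
    for gpos, q in (qual_overrides or {}).items():
        quals[gpos - start] = q
    return AlignedRead(
        read_id=rid,
        sample_id=sample_id,
        chrom=chrom,
        strand="+",
        start=start,
        blocks=((start, start + length, 0, length),),
        junctions=(),
        bases="".join(seq),
        quals=tuple(quals),
        unique=unique,
    )


def make_filter_gauntlet() -> GauntletFixture:
    """A deterministic fixture with one site per filter rule plus clean sites.

    Each non-clean site is constructed to violate exactly one rule of the
    cascade; the designed survivor set is exactly the clean sites.
    """
    chrom = "chr1"
    chrom_len = 20_000
    rng = np.random.default_rng(987654321)
    seq = list(_random_sequence(rng, chrom_len).tobytes().decode())

    sites = [
        GauntletSite("low_coverage", chrom, 1700, "A", "G", "low_coverage"),
        GauntletSite("few_alt_reads", chrom, 1900, "A", "G", "few_alt_reads"),
        GauntletSite("low_base_qual", chrom, 2100, "A", "G", "low_base_qual"),
        GauntletSite("read_end_only", chrom, 2300, "A", "G", "read_end_only"),
        GauntletSite("homopolymer", chrom, 2500, "A", "G", "homopolymer"),
        GauntletSite("repeat", chrom, 2700, "A", "G", "repeat"),
        GauntletSite("multimap", chrom, 2900, "A", "G", "multimap"),
        GauntletSite("splice_proximal", chrom, 3003, "A", "G", "splice_proximal"),
        GauntletSite("self_chain", chrom, 3250, "A", "G", "self_chain"),
        GauntletSite("clean_intron", chrom, 3300, "A", "G", "clean"),
        GauntletSite("dna_support", chrom, 4000, "A", "G", "dna_support"),
        GauntletSite("dna_low_cov", chrom, 4200, "A", "G", "dna_low_cov"),
        GauntletSite("clean_cds_1", chrom, 4400, "A", "G", "clean"),
        GauntletSite("clean_cds_2", chrom, 4600, "A", "G", "clean"),
        GauntletSite("intergenic", chrom, 9500, "A", "G", "intergenic"),
        GauntletSite("clean_minus", chrom, 11000, "T", "C", "clean"),
        GauntletSite("strand_ambiguous", chrom, 14200, "A", "G", "strand_ambiguous"),
    ]
    site_positions = {s.pos for s in sites}
    for s in sites:
        seq[s.pos] = s.ref

    # plant the homopolymer run (AAAAAA around 2500), flanked by non-A
    for p in range(2498, 2504):
        seq[p] = "A"
    seq[2497] = "C"
    seq[2504] = "G"
    protected = set(range(2497, 2505))

    # break every other run of >= 5 identical bases
    def _break_runs() -> None:
        i = 0
        while i < chrom_len:
            j = i
            while j < chrom_len and seq[j] == seq[i]:
                j += 1
            if j - i >= 5 and i not in protected:
                for p in range(i, j):
                    if p not in site_positions and p not in protected:
                        old = seq[p]
                        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
                        break
            i = j

    for _ in range(4):
        _break_runs()

    genome = GenomeSequence({chrom: "".join(seq)})
    genome_seq = genome.sequence(chrom)

    g1_exons = [(1000, 3000), (3500, 6000), (6500, 9000)]
    g1_cds = [(1500, 3000), (3500, 6000), (6500, 8002)]
    genes = [
        GeneModel("G1", "G1.t1", chrom, "+", g1_exons, g1_cds),
        GeneModel("G2", "G2.t1", chrom, "-", [(10000, 12000)]),
        GeneModel("G3", "G3.t1", chrom, "+", [(13000, 14500)]),
        GeneModel("G4", "G4.t1", chrom, "-", [(14000, 15500)]),
    ]
    tracks = ExclusionTracks(
        homopolymer=detect_homopolymers(genome, min_run=5),
        repeat_masker=IntervalSet({chrom: [(2650, 2750)]}),
        multimap=IntervalSet({chrom: [(2850, 2950)]}),
        self_chain=IntervalSet({chrom: [(3200, 3300)]}),
    )

    rna: List[AlignedRead] = []
    rid = [0]

    def _next_rid() -> str:
        rid[0] += 1
        return f"rna.r{rid[0]}"

    def default_site_reads(
        pos: int, alt: str, n_total: int = 30, n_alt: int = 8
    ) -> None:
        # alt reads first (offsets 35..): site sits mid-read, distinct starts
        for i in range(n_total):
            subs = {pos: alt} if i < n_alt else None
            rna.append(
                _mem_read(chrom, pos - 35 + i, genome_seq, "rna", _next_rid(), subs=subs)
            )

    by_name = {s.name: s for s in sites}

    s = by_name["low_coverage"]
    for i in range(9):
        subs = {s.pos: s.alt} if i < 5 else None
        rna.append(_mem_read(chrom, s.pos - 35 + i, genome_seq, "rna", _next_rid(), subs=subs))

    s = by_name["few_alt_reads"]
    for i in range(28):
        rna.append(_mem_read(chrom, s.pos - 35 + i, genome_seq, "rna", _next_rid()))
    for _ in range(2):  # two alt reads sharing one alignment start
        rna.append(
            _mem_read(chrom, s.pos - 20, genome_seq, "rna", _next_rid(), subs={s.pos: s.alt})
        )

    s = by_name["low_base_qual"]
    for i in range(27):
        rna.append(_mem_read(chrom, s.pos - 35 + i, genome_seq, "rna", _next_rid()))
    for i in range(3):  # alt support exists but below the quality threshold
        rna.append(
            _mem_read(
                chrom,
                s.pos - 20 - i,
                genome_seq,
                "rna",
                _next_rid(),
                subs={s.pos: s.alt},
                qual_overrides={s.pos: 22},
            )
        )

    s = by_name["read_end_only"]
    for i in range(26):
        rna.append(_mem_read(chrom, s.pos - 35 + i, genome_seq, "rna", _next_rid()))
    for i in range(4):  # alt base always within 10 bp of the read start
        rna.append(
            _mem_read(
                chrom, s.pos - 5 - i, genome_seq, "rna", _next_rid(), subs={s.pos: s.alt}
            )
        )

    for name in (
        "homopolymer",
        "repeat",
        "multimap",
        "splice_proximal",
        "self_chain",
        "clean_intron",
        "dna_support",
        "dna_low_cov",
        "clean_cds_1",
        "clean_cds_2",
        "intergenic",
        "clean_minus",
        "strand_ambiguous",
    ):
        s = by_name[name]
        default_site_reads(s.pos, s.alt)

    dna: List[AlignedRead] = []
    did = [0]

    def _next_did() -> str:
        did[0] += 1
        return f"dna.r{did[0]}"

    for s in sites:
        n = 20 if s.rule == "dna_low_cov" else 30
        for i in range(n):
            subs = None
            if s.rule == "dna_support" and i == 0:
                subs = {s.pos: s.alt}
            dna.append(
                _mem_read(
                    chrom, s.pos - 40 + i, genome_seq, "dna", _next_did(),
                    length=60, subs=subs,
                )
            )

    return GauntletFixture(
        genome=genome,
        genes=genes,
        tracks=tracks,
        rna_reads={"rna": rna},
        dna_reads={"dna": dna},
        sites=sites,
    )
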