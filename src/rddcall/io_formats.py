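"""Readers/writers for FASTA, GFF3, SAM and BED, plus the pipeline's own tables.

Internal convention: every coordinate in memory is 0-based half-open.
SAM (1-based POS) and GFF3 (1-based closed) are converted at the boundary;
output tables use 1-based positions.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pysam

from .intervals import Interval, IntervalSet, merge_intervals, subtract_intervals

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes accepted on input; anything not ACGT becomes N.
_IUPAC = set("ACGTNRYSWKMBDHVU")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class GeneModelError(ValueError):
    """Raised when a transcript model violates its structural invariants."""


# ---------------------------------------------------------------------------
# Genome


class GenomeSequence:
    """An in-memory reference genome: ordered chromosomes of A/C/G/T/N."""

    def __init__(self, chroms: Dict[str, str]):
        for name, seq in chroms.items():
            if not seq:
                raise FormatError(f"chromosome {name!r} has an empty sequence")
        self._chroms = dict(chroms)

    @property
    def chrom_names(self) -> List[str]:
        return list(self._chroms)

    def sequence(self, chrom: str) -> str:
        return self._chroms[chrom]

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self._chroms[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        return self._chroms[chrom][pos]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self._chroms.items())


def read_fasta(path: str) -> GenomeSequence:
    """Load a FASTA file; sequences are uppercased, ambiguity codes become N."""
    chroms: Dict[str, str] = {}
    name: Optional[str] = None
    parts: List[str] = []
    n_line = 0
    saw_any = False

    def _flush():
        if name is None:
            return
        if name in chroms:
            raise FormatError(f"duplicate sequence name {name!r} in {path}")
        chroms[name] = "".join(parts).upper()

    with open(path) as fh:
        for line in fh:
            n_line += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{n_line}: empty FASTA header")
                name = header.split()[0]
                parts = []
                saw_any = True
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{n_line}: sequence data before any FASTA header"
                    )
                bad = set(line.upper()) - _IUPAC
                if bad:
                    raise FormatError(
                        f"{path}:{n_line}: non-IUPAC characters {sorted(bad)}"
                    )
                parts.append(line)
        _flush()

    if not saw_any:
        warnings.warn(f"FASTA file {path} is empty; returning empty genome")
        return _empty_genome()
    cleaned = {
        n: "".join(c if c in "ACGTN" else "N" for c in s) for n, s in chroms.items()
    }
    return GenomeSequence(cleaned)


def _empty_genome() -> GenomeSequence:
    g = GenomeSequence.__new__(GenomeSequence)
    g._chroms = {}
    return g


def write_fasta(genome: GenomeSequence, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models


class GeneModel:
    """A stranded transcript with exon/CDS structure and derived UTRs/introns.

    Coordinates are genomic, 0-based half-open, exons sorted. For coding
    transcripts the 5' UTR is the exonic sequence upstream of the CDS in the
    direction of transcription.
    """

    __slots__ = (
        "gene_id",
        "transcript_id",
        "chrom",
        "strand",
        "exons",
        "cds",
        "utr5",
        "utr3",
        "introns",
    )

    def __init__(
        self,
        gene_id: str,
        transcript_id: str,
        chrom: str,
        strand: str,
        exons: Sequence[Interval],
        cds: Sequence[Interval] = (),
    ):
        if strand not in "+-":
            raise GeneModelError(f"{transcript_id}: bad strand {strand!r}")
        exons = sorted(tuple(e) for e in exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise GeneModelError(f"{transcript_id}: overlapping exons")
        for s, e in exons:
            if s >= e:
                raise GeneModelError(f"{transcript_id}: empty exon ({s},{e})")
        cds = sorted(tuple(c) for c in cds)
        exonic = merge_intervals(exons)
        if cds and subtract_intervals(cds, exonic):
            raise GeneModelError(f"{transcript_id}: CDS outside exons")
        # CDS length % 3 == 0 is required only where translation happens
        # (predict_consequence); partial CDS annotations are tolerated here.
        self.gene_id = gene_id
        self.transcript_id = transcript_id
        self.chrom = chrom
        self.strand = strand
        self.exons = tuple(exons)
        self.cds = tuple(cds)
        self.introns = tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:]) if s2 > e1
        )
        if cds:
            utr = subtract_intervals(exonic, cds)
            cds_start, cds_end = cds[0][0], cds[-1][1]
            left = tuple(iv for iv in utr if iv[1] <= cds_start)
            right = tuple(iv for iv in utr if iv[0] >= cds_end)
            self.utr5 = left if strand == "+" else right
            self.utr3 = right if strand == "+" else left
        else:
            self.utr5 = ()
            self.utr3 = ()

    # -- geometry -----------------------------------------------------------

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def pre_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e

    def transcript_blocks(self, tstart: int, tend: int) -> List[Interval]:
        """Genomic intervals (sorted) covered by mature-transcript slice [tstart, tend)."""
        if not (0 <= tstart <= tend <= self.mature_length):
            raise ValueError("transcript slice out of range")
        exon_order = self.exons if self.strand == "+" else self.exons[::-1]
        blocks: List[Interval] = []
        offset = 0
        for s, e in exon_order:
            length = e - s
            lo, hi = max(tstart - offset, 0), min(tend - offset, length)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + lo, s + hi))
                else:
                    blocks.append((e - hi, e - lo))
            offset += length
        return sorted(blocks)

    def cds_positions(self) -> List[int]:
        """Genomic positions of CDS bases in translation (5'→3') order."""
        positions: List[int] = []
        for s, e in self.cds:
            positions.extend(range(s, e))
        if self.strand == "-":
            positions.reverse()
        return positions

    def __repr__(self) -> str:
        return (
            f"GeneModel({self.gene_id}/{self.transcript_id} {self.chrom}"
            f"{self.strand} exons={len(self.exons)} cds={len(self.cds)})"
        )


class TranscriptIndex:
    """Point-overlap lookup over transcript spans, per chromosome."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._by_chrom: Dict[str, List[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: Dict[str, List[int]] = {}
        self._maxend: Dict[str, List[int]] = {}
        for chrom, lst in self._by_chrom.items():
            lst.sort(key=lambda g: g.span)
            self._starts[chrom] = [g.span[0] for g in lst]
            maxend: List[int] = []
            cur = 0
            for g in lst:
                cur = max(cur, g.span[1])
                maxend.append(cur)
            self._maxend[chrom] = maxend

    def overlapping(self, chrom: str, pos: int) -> List[GeneModel]:
        lst = self._by_chrom.get(chrom)
        if not lst:
            return []
        i = bisect_right(self._starts[chrom], pos) - 1
        hits: List[GeneModel] = []
        while i >= 0 and self._maxend[chrom][i] > pos:
            g = lst[i]
            if g.span[0] <= pos < g.span[1]:
                hits.append(g)
            i -= 1
        hits.reverse()
        return hits

    def all(self) -> List[GeneModel]:
        return [g for lst in self._by_chrom.values() for g in lst]


def read_gff3(path: str) -> List[GeneModel]:
    """Parse gene/mRNA/exon/CDS features linked by Parent into GeneModels.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Transcripts whose CDS violates the model invariants are rejected with a
    warning; orphan exon/CDS features are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    models: List[GeneModel] = []
    n_orphans = 0
    tx_types = {"mRNA", "transcript", "ncRNA"}
    known_parents = set()
    for tx in db.all_features():
        if tx.featuretype not in tx_types:
            continue
        known_parents.add(tx.id)
        gene_id = tx.attributes.get("Parent", [tx.id])[0]
        exons = []
        cds = []
        for child in db.children(tx.id):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
        if not exons:
            warnings.warn(f"transcript {tx.id} has no exons; skipped")
            continue
        try:
            models.append(
                GeneModel(gene_id, tx.id, tx.seqid, tx.strand, exons, cds)
            )
        except GeneModelError as exc:
            warnings.warn(f"rejected transcript model: {exc}")
    for feat in db.all_features():
        if feat.featuretype in ("exon", "CDS"):
            parents = feat.attributes.get("Parent", [])
            if not parents or all(p not in known_parents for p in parents):
                n_orphans += 1
    if n_orphans:
        warnings.warn(f"{path}: skipped {n_orphans} orphan exon/CDS features")
    models.sort(key=lambda g: (g.chrom, g.span, g.transcript_id))
    return models


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Write transcripts as gene/mRNA/exon/CDS GFF3 (1-based closed)."""
    by_gene: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_gene.setdefault(g.gene_id, []).append(g)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id in sorted(by_gene):
            txs = by_gene[gene_id]
            start = min(t.span[0] for t in txs)
            end = max(t.span[1] for t in txs)
            chrom, strand = txs[0].chrom, txs[0].strand
            fh.write(
                f"{chrom}\trddcall\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for t in sorted(txs, key=lambda t: t.transcript_id):
                s, e = t.span
                fh.write(
                    f"{chrom}\trddcall\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                for i, (xs, xe) in enumerate(t.exons, 1):
                    fh.write(
                        f"{chrom}\trddcall\texon\t{xs + 1}\t{xe}\t.\t{strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                for i, (cs, ce) in enumerate(t.cds, 1):
                    fh.write(
                        f"{chrom}\trddcall\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t0\t"
                        f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Aligned reads


@dataclass
class AlignedRead:
    """One aligned read with CIGAR-derived genomic blocks.

    ``blocks`` pairs genomic with read-offset intervals; splice gaps (CIGAR N)
    between consecutive blocks are recorded in ``junctions`` as (donor,
    acceptor) = the 0-based half-open genomic span of the skipped intron.
    ``qa_start``/``qa_end`` bound the aligned (non-soft-clipped) part of the
    read; per-base end distances are measured within that span.
    """

    read_id: str
    sample_id: str
    chrom: str
    strand: str
    start: int
    blocks: Tuple[Tuple[int, int, int, int], ...]  # (gstart, gend, qstart, qend)
    junctions: Tuple[Interval, ...]
    bases: str
    quals: Tuple[int, ...]
    unique: bool

    @property
    def qa_start(self) -> int:
        return self.blocks[0][2]

    @property
    def qa_end(self) -> int:
        return self.blocks[-1][3]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def end_distance(self, qpos: int) -> int:
        """Distance (bp) of query position from the nearer aligned read end."""
        return min(qpos - self.qa_start, self.qa_end - 1 - qpos)


_QUERY_OPS = {0, 1, 4, 7, 8}  # M, I, S, =, X consume query
_REF_OPS = {0, 2, 3, 7, 8}  # M, D, N, =, X consume reference


def blocks_from_cigar(
    start: int, cigartuples: Sequence[Tuple[int, int]]
) -> Tuple[Tuple[Tuple[int, int, int, int], ...], Tuple[Interval, ...]]:
    """Walk a CIGAR into (genomic, query) blocks and N-gap junctions."""
    g = start
    q = 0
    blocks: List[Tuple[int, int, int, int]] = []
    junctions: List[Interval] = []
    for op, length in cigartuples:
        if op in (0, 7, 8):  # aligned
            blocks.append((g, g + length, q, q + length))
            g += length
            q += length
        elif op == 1:  # insertion: bases never enter pileups
            q += length
        elif op == 2:  # deletion: genomic gap, no junction
            g += length
        elif op == 3:  # splice
            junctions.append((g, g + length))
            g += length
        elif op == 4:  # soft clip
            q += length
        elif op == 5:  # hard clip
            pass
        else:
            raise FormatError(f"unsupported CIGAR op {op}")
    return tuple(blocks), tuple(junctions)


def read_sam(
    path: str,
    sample_id: str,
    mapq_unique_threshold: int = 20,
) -> Iterator[AlignedRead]:
    """Stream aligned reads from a SAM file.

    Uniqueness comes from the NH tag when present (NH == 1), otherwise from
    MAPQ >= ``mapq_unique_threshold``. Unmapped reads are skipped; reads whose
    CIGAR and SEQ lengths disagree are rejected and counted in the log.
    """
    n_rejected = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        it = iter(sam)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except OSError as exc:  # htslib aborts on malformed records
                n_rejected += 1
                logger.warning("%s: malformed SAM record rejected (%s)", path, exc)
                break
            if rec.is_unmapped or rec.cigartuples is None or rec.query_sequence is None:
                continue
            expected = sum(l for op, l in rec.cigartuples if op in _QUERY_OPS)
            if expected != len(rec.query_sequence):
                n_rejected += 1
                continue
            blocks, junctions = blocks_from_cigar(rec.reference_start, rec.cigartuples)
            if not blocks:
                continue
            if rec.has_tag("NH"):
                unique = rec.get_tag("NH") == 1
            else:
                unique = rec.mapping_quality >= mapq_unique_threshold
            quals = rec.query_qualities
            yield AlignedRead(
                read_id=rec.query_name,
                sample_id=sample_id,
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                start=rec.reference_start,
                blocks=blocks,
                junctions=junctions,
                bases=rec.query_sequence.upper(),
                quals=tuple(quals) if quals is not None else (30,) * len(rec.query_sequence),
                unique=unique,
            )
    if n_rejected:
        logger.warning("%s: rejected %d reads with CIGAR/SEQ mismatch", path, n_rejected)


# ---------------------------------------------------------------------------
# BED / exclusion tracks


def read_bed(path: str) -> IntervalSet:
    """Read a >=3 column BED (0-based half-open) into a merged IntervalSet."""
    tuples: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                warnings.warn(f"{path}:{i}: fewer than 3 columns; line skipped")
                continue
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                warnings.warn(f"{path}:{i}: start >= end; line skipped")
                continue
            tuples.append((chrom, start, end))
    return IntervalSet.from_tuples(tuples)


def write_bed(intervals: IntervalSet, path: str, name: str | None = None) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.intervals():
            if name:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass
class ExclusionTracks:
    """Named positional blacklists applied to candidate variants."""

    homopolymer: IntervalSet = field(default_factory=IntervalSet)
    repeat_masker: IntervalSet = field(default_factory=IntervalSet)
    multimap: IntervalSet = field(default_factory=IntervalSet)
    self_chain: IntervalSet = field(default_factory=IntervalSet)

    # filter names as they appear in SnvCall.filters_failed
    def items(self) -> List[Tuple[str, IntervalSet]]:
        return [
            ("homopolymer", self.homopolymer),
            ("repeat", self.repeat_masker),
            ("multimap", self.multimap),
            ("self_chain", self.self_chain),
        ]


# ---------------------------------------------------------------------------
# RDD table


RDD_TABLE_COMMENT = (
    "# RNA-DNA difference sites. pos is 1-based; ref/alt are genome-strand "
    "bases; sense_ref/sense_alt are transcript-strand bases; per-sample "
    "columns are <sample>.freq (edited-read fraction), <sample>.cov (RNA "
    "read depth) and <sample>.called (1 if the site independently passed "
    "all RNA-side filters in that sample)."
)


def write_rdd_table(rdds: Sequence, path: str) -> None:
    """Serialize RddSite records to a TSV (stable order: chrom, pos, alt)."""
    sample_ids: List[str] = []
    for site in rdds:
        for sid in site.samples:
            if sid not in sample_ids:
                sample_ids.append(sid)
    cols = [
        "chrom",
        "pos",
        "genomic_ref",
        "genomic_alt",
        "strand",
        "sense_ref",
        "sense_alt",
        "edit_class",
        "canonical",
        "gene_ids",
    ]
    for sid in sample_ids:
        cols += [f"{sid}.freq", f"{sid}.cov", f"{sid}.called"]
    with open(path, "w") as fh:
        fh.write(RDD_TABLE_COMMENT + "\n")
        fh.write("\t".join(cols) + "\n")
        for site in sorted(rdds, key=lambda s: (s.chrom, s.pos, s.genomic_alt)):
            row = [
                site.chrom,
                str(site.pos + 1),
                site.genomic_ref,
                site.genomic_alt,
                site.strand,
                site.sense_ref,
                site.sense_alt,
                site.edit_class,
                "1" if site.canonical else "0",
                ",".join(site.gene_ids),
            ]
            for sid in sample_ids:
                stats = site.samples.get(sid)
                if stats is None or stats.coverage == 0:
                    row += ["NA", "0", "0"]
                else:
                    freq = "NA" if stats.frequency is None else repr(stats.frequency)
                    row += [freq, str(stats.coverage), "1" if stats.called else "0"]
            fh.write("\t".join(row) + "\n")


def read_rdd_table(path: str) -> List:
    """Round-trip reader for :func:`write_rdd_table` output."""
    from .rdd_calling import RddSite, SampleSiteStats

    sites: List[RddSite] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                sample_ids = [
                    c[: -len(".freq")] for c in header if c.endswith(".freq")
                ]
                continue
            vals = dict(zip(header, line.split("\t")))
            samples = {}
            for sid in sample_ids:
                cov = int(vals[f"{sid}.cov"])
                if cov == 0:
                    continue
                freq_s = vals[f"{sid}.freq"]
                samples[sid] = SampleSiteStats(
                    frequency=None if freq_s == "NA" else float(freq_s),
                    coverage=cov,
                    called=vals[f"{sid}.called"] == "1",
                )
            sites.append(
                RddSite(
                    chrom=vals["chrom"],
                    pos=int(vals["pos"]) - 1,
                    genomic_ref=vals["genomic_ref"],
                    genomic_alt=vals["genomic_alt"],
                    strand=vals["strand"],
                    sense_ref=vals["sense_ref"],
                    sense_alt=vals["sense_alt"],
                    edit_class=vals["edit_class"],
                    canonical=vals["canonical"] == "1",
                    gene_ids=tuple(g for g in vals["gene_ids"].split(",") if g),
                    samples=samples,
                )
            )
    return sites
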