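"""Read filtering, pileup construction and candidate RNA SNV calling.

Evidence model: coverage at a site counts every aligned A/C/G/T base from a
read that passed the read-level filters, regardless of base quality; calling
evidence for an alternate base additionally requires base quality >= 23.
The pileup keeps dense per-chromosome coverage arrays and per-read metadata
only at mismatch positions, which is all downstream filters consult.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Set, Tuple

import numpy as np

from .intervals import IntervalSet
from .io_formats import AlignedRead, ExclusionTracks, GenomeSequence, TranscriptIndex

logger = logging.getLogger(__name__)

# filter names, in the order they are audited
FILTER_LOW_COVERAGE = "low_coverage"
FILTER_FEW_ALT_READS = "few_alt_reads"
FILTER_READ_END_ONLY = "read_end_only"
FILTER_SPLICE = "splice_proximal"


class Evidence(NamedTuple):
    """Per-read support for one base at one site."""

    qual: int
    end_dist: int  # distance from the nearer aligned read end
    aln_start: int
    unique: bool


@dataclass
class SiteCounts:
    """Nucleotide evidence at one genomic position for one sample.

    Per-read metadata is retained for bases that disagree with the reference;
    reference-matching reads contribute to counts and coverage only.
    """

    chrom: str
    pos: int
    counts: Dict[str, int]
    evidence: Dict[str, List[Evidence]]

    @property
    def total_coverage(self) -> int:
        return sum(self.counts.values())


@dataclass
class SnvCall:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    alt_count: int
    total_coverage: int
    frequency: float
    sample_id: str
    filters_failed: Set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.filters_failed

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_base)


def filter_reads(
    reads: Iterable[AlignedRead],
    min_qual: int = 23,
    min_fraction: float = 0.7,
    stats: Optional[Dict[str, int]] = None,
) -> Iterator[AlignedRead]:
    """Yield reads that are uniquely mapped and have >= ``min_fraction`` of
    cycles at Phred >= ``min_qual`` (boundary inclusive)."""
    eps = 1e-9
    for read in reads:
        if not read.unique:
            if stats is not None:
                stats["read_not_unique"] = stats.get("read_not_unique", 0) + 1
            continue
        n = len(read.quals)
        n_good = sum(1 for q in read.quals if q >= min_qual)
        if n == 0 or n_good / n < min_fraction - eps:
            if stats is not None:
                stats["read_low_quality"] = stats.get("read_low_quality", 0) + 1
            continue
        if stats is not None:
            stats["read_kept"] = stats.get("read_kept", 0) + 1
        yield read


_BASE_BY_CODE = {65: "A", 67: "C", 71: "G", 84: "T", 78: "N"}


class Pileup:
    """Per-sample pileup: dense coverage plus mismatch evidence.

    Coverage excludes read bases of 'N' and anything under a splice (N) gap,
    insertion or deletion.
    """

    def __init__(self, genome: GenomeSequence, sample_id: str = ""):
        self.genome = genome
        self.sample_id = sample_id
        self._ref_arrays: Dict[str, np.ndarray] = {}
        self._cov: Dict[str, np.ndarray] = {}
        # (chrom, pos) -> base -> [Evidence]
        self._evidence: Dict[Tuple[str, int], Dict[str, List[Evidence]]] = {}
        self.n_reads = 0

    def _ref(self, chrom: str) -> np.ndarray:
        arr = self._ref_arrays.get(chrom)
        if arr is None:
            arr = np.frombuffer(self.genome.sequence(chrom).encode(), dtype=np.uint8)
            self._ref_arrays[chrom] = arr
            self._cov[chrom] = np.zeros(len(arr), dtype=np.int32)
        return arr

    def add_read(self, read: AlignedRead) -> None:
        ref = self._ref(read.chrom)
        cov = self._cov[read.chrom]
        qarr = np.frombuffer(read.bases.encode(), dtype=np.uint8)
        self.n_reads += 1
        for gs, ge, qs, qe in read.blocks:
            cov[gs:ge] += 1
            mism = np.nonzero(ref[gs:ge] != qarr[qs:qe])[0]
            for off in mism:
                off = int(off)
                gpos = gs + off
                qpos = qs + off
                base = _BASE_BY_CODE.get(qarr[qpos], "N")
                if base == "N":
                    cov[gpos] -= 1  # N bases carry no evidence
                    continue
                site = self._evidence.setdefault((read.chrom, gpos), {})
                site.setdefault(base, []).append(
                    Evidence(
                        qual=read.quals[qpos],
                        end_dist=read.end_distance(qpos),
                        aln_start=read.start,
                        unique=read.unique,
                    )
                )

    def coverage(self, chrom: str, pos: int) -> int:
        cov = self._cov.get(chrom)
        if cov is None or not (0 <= pos < len(cov)):
            return 0
        return int(cov[pos])

    def alt_count(self, chrom: str, pos: int, base: str) -> int:
        site = self._evidence.get((chrom, pos))
        if not site:
            return 0
        return len(site.get(base, ()))

    def alt_evidence(self, chrom: str, pos: int, base: str) -> List[Evidence]:
        site = self._evidence.get((chrom, pos))
        if not site:
            return []
        return list(site.get(base, ()))

    def site(self, chrom: str, pos: int) -> SiteCounts:
        evid = self._evidence.get((chrom, pos), {})
        counts = {b: len(ev) for b, ev in evid.items()}
        total = self.coverage(chrom, pos)
        ref_base = self.genome.base(chrom, pos)
        n_alt = sum(counts.values())
        n_ref = max(total - n_alt, 0)
        if ref_base in "ACGT" and n_ref:
            counts[ref_base] = counts.get(ref_base, 0) + n_ref
        return SiteCounts(chrom=chrom, pos=pos, counts=counts, evidence=evid)

    def positions(self) -> List[Tuple[str, int]]:
        """Sorted positions holding at least one mismatching read base."""
        return sorted(self._evidence)

    def merge(self, other: "Pileup") -> None:
        """Pool another pileup's evidence into this one (DNA-sample pooling)."""
        for chrom, cov in other._cov.items():
            self._ref(chrom)
            self._cov[chrom] += cov
        for key, bases in other._evidence.items():
            mine = self._evidence.setdefault(key, {})
            for base, evs in bases.items():
                mine.setdefault(base, []).extend(evs)
        self.n_reads += other.n_reads


def build_pileup(
    reads: Iterable[AlignedRead],
    genome: GenomeSequence,
    sample_id: str = "",
    region: Optional[Tuple[str, int, int]] = None,
) -> Pileup:
    """Accumulate filtered reads into a Pileup (optionally restricted to a region)."""
    pileup = Pileup(genome, sample_id=sample_id)
    for read in reads:
        if region is not None:
            chrom, start, end = region
            if read.chrom != chrom or read.end <= start or read.start >= end:
                continue
        pileup.add_read(read)
    return pileup


def call_snvs(
    pileup: Pileup,
    genome: GenomeSequence,
    min_cov: int = 10,
    min_alt_reads: int = 2,
    min_base_qual: int = 23,
    end_exclusion_bp: int = 10,
    unique_mode: str = "distinct_starts",
) -> List[SnvCall]:
    """Emit candidate SNVs at every mismatch position, annotating failures.

    A candidate passes when total coverage >= ``min_cov``, at least
    ``min_alt_reads`` unique supporting reads carry the alternate base at
    quality >= ``min_base_qual`` ("unique" = distinct alignment starts by
    default), and at least one such read supports it more than
    ``end_exclusion_bp`` from both read ends. Reference positions of N are
    skipped.
    """
    if unique_mode not in ("distinct_starts", "any"):
        raise ValueError(f"unknown unique_mode {unique_mode!r}")
    calls: List[SnvCall] = []
    for chrom, pos in pileup.positions():
        ref_base = genome.base(chrom, pos)
        if ref_base not in "ACGT":
            continue
        total = pileup.coverage(chrom, pos)
        site_evid = pileup._evidence[(chrom, pos)]
        for alt_base in sorted(site_evid):
            if alt_base == ref_base:
                continue
            all_support = site_evid[alt_base]
            evidence = [e for e in all_support if e.qual >= min_base_qual and e.unique]
            failed: Set[str] = set()
            if total < min_cov:
                failed.add(FILTER_LOW_COVERAGE)
            if unique_mode == "distinct_starts":
                n_unique = len({e.aln_start for e in evidence})
            else:
                n_unique = len(evidence)
            if n_unique < min_alt_reads:
                failed.add(FILTER_FEW_ALT_READS)
            if not any(e.end_dist > end_exclusion_bp for e in evidence):
                failed.add(FILTER_READ_END_ONLY)
            alt_count = len(all_support)
            calls.append(
                SnvCall(
                    chrom=chrom,
                    pos=pos,
                    ref_base=ref_base,
                    alt_base=alt_base,
                    alt_count=alt_count,
                    total_coverage=total,
                    frequency=alt_count / total if total else 0.0,
                    sample_id=pileup.sample_id,
                    filters_failed=failed,
                )
            )
    return calls


def apply_region_filters(
    calls: Iterable[SnvCall],
    tracks: ExclusionTracks,
    tx_index: TranscriptIndex,
    splice_buffer_bp: int = 5,
) -> List[SnvCall]:
    """Add positional exclusion filters to each call (idempotent, set semantics).

    A call gains a track's filter name when its position lies in that track,
    and ``splice_proximal`` when it is intronic in some overlapping transcript
    and within ``splice_buffer_bp`` bases (inclusive) of that intron's edge.
    The splice rule never applies through an exonic placement: only intronic
    positions of a transcript are tested against that transcript's introns.
    """
    out: List[SnvCall] = []
    for call in calls:
        for name, track in tracks.items():
            if track.contains(call.chrom, call.pos):
                call.filters_failed.add(name)
        for gene in tx_index.overlapping(call.chrom, call.pos):
            for s, e in gene.introns:
                if s <= call.pos < e and min(call.pos - s, e - 1 - call.pos) < splice_buffer_bp:
                    call.filters_failed.add(FILTER_SPLICE)
        out.append(call)
    return out


def detect_homopolymers(genome: GenomeSequence, min_run: int = 5) -> IntervalSet:
    """Maximal single-nucleotide runs of length >= ``min_run`` (N excluded)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) == 0:
            continue
        change = np.nonzero(arr[1:] != arr[:-1])[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        runs = [
            (int(s), int(e))
            for s, e in zip(starts, ends)
            if e - s >= min_run and chr(arr[s]) in "ACGT"
        ]
        if runs:
            by_chrom[chrom] = runs
    return IntervalSet(by_chrom)
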