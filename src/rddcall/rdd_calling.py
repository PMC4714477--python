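"""Genomic subtraction and RNA-DNA difference classification.

Composes the per-sample SNV calls with DNA evidence: a surviving RNA variant
becomes an RDD when the pooled whole-genome data covers the site at more than
``dna_min_cov`` reads with zero reads supporting the edited base. Sites are
strand-resolved from overlapping gene models; an A->G change on the sense
strand is the canonical A-to-I class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .io_formats import (
    AlignedRead,
    ExclusionTracks,
    GeneModel,
    GenomeSequence,
    TranscriptIndex,
    revcomp,
)
from .snv_calling import (
    Pileup,
    SnvCall,
    apply_region_filters,
    build_pileup,
    call_snvs,
    filter_reads,
)

logger = logging.getLogger(__name__)

REASON_INTERGENIC = "intergenic"
REASON_STRAND_AMBIGUOUS = "strand_ambiguous"
REASON_DNA_LOW_COV = "dna_low_cov"
REASON_DNA_SUPPORT = "dna_support"


@dataclass
class SampleSiteStats:
    frequency: Optional[float]  # None when coverage == 0
    coverage: int
    called: bool


@dataclass
class RddSite:
    """A strand-resolved RNA-DNA difference with per-sample observations."""

    chrom: str
    pos: int
    genomic_ref: str
    genomic_alt: str
    strand: str
    sense_ref: str
    sense_alt: str
    edit_class: str
    canonical: bool
    gene_ids: Tuple[str, ...]
    samples: Dict[str, SampleSiteStats] = field(default_factory=dict)

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.pos, self.genomic_alt)

    def called_samples(self) -> List[str]:
        return [sid for sid, s in self.samples.items() if s.called]


def infer_strand(
    call: SnvCall, tx_index: TranscriptIndex
) -> Tuple[Optional[str], Optional[str], Tuple[str, ...]]:
    """Resolve the transcript strand of a call from overlapping gene models.

    Returns (strand, rejection_reason, gene_ids). Sites outside every gene are
    rejected as intergenic; sites inside genes on both strands are rejected as
    strand-ambiguous. Multiple same-strand genes are allowed.
    """
    genes = tx_index.overlapping(call.chrom, call.pos)
    if not genes:
        return None, REASON_INTERGENIC, ()
    strands = {g.strand for g in genes}
    if len(strands) > 1:
        return None, REASON_STRAND_AMBIGUOUS, ()
    gene_ids = tuple(sorted({g.gene_id for g in genes}))
    return strands.pop(), None, gene_ids


def genomic_subtraction(
    call: SnvCall, dna_pileup: Pileup, min_dna_cov: int = 20
) -> Tuple[bool, Optional[str]]:
    """Pass iff DNA coverage is strictly greater than ``min_dna_cov`` and no
    DNA read supports the edited base."""
    cov = dna_pileup.coverage(call.chrom, call.pos)
    if cov <= min_dna_cov:
        return False, REASON_DNA_LOW_COV
    if dna_pileup.alt_count(call.chrom, call.pos, call.alt_base) > 0:
        return False, REASON_DNA_SUPPORT
    return True, None


def classify_edit(call: SnvCall, strand: str, gene_ids: Tuple[str, ...] = ()) -> RddSite:
    """Strand-correct the change and assign its edit class.

    Sense bases are the reverse complement of the genomic bases on '-' strand
    transcripts; a sense A->G change is the canonical A-to-I event (inosine
    reads as guanosine).
    """
    if strand == "-":
        sense_ref = revcomp(call.ref_base)
        sense_alt = revcomp(call.alt_base)
    else:
        sense_ref = call.ref_base
        sense_alt = call.alt_base
    canonical = sense_ref == "A" and sense_alt == "G"
    edit_class = "A-to-I" if canonical else f"{sense_ref}-to-{sense_alt}"
    return RddSite(
        chrom=call.chrom,
        pos=call.pos,
        genomic_ref=call.ref_base,
        genomic_alt=call.alt_base,
        strand=strand,
        sense_ref=sense_ref,
        sense_alt=sense_alt,
        edit_class=edit_class,
        canonical=canonical,
        gene_ids=gene_ids,
    )


@dataclass
class RddCallConfig:
    min_cov: int = 10
    min_alt_reads: int = 2
    min_base_qual: int = 23
    end_exclusion_bp: int = 10
    splice_buffer_bp: int = 5
    dna_min_cov: int = 20
    read_min_qual: int = 23
    read_min_fraction: float = 0.7
    unique_mode: str = "distinct_starts"
    canonical_only: bool = False


@dataclass
class RddCallResult:
    sites: List[RddSite]
    filter_stats: Dict[str, Dict[str, int]]  # per sample audit counts
    pileups: Dict[str, Pileup]
    dna_pileup: Pileup


def call_rdds(
    rna_samples: Mapping[str, Iterable[AlignedRead]],
    dna_samples: Mapping[str, Iterable[AlignedRead]],
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    tracks: ExclusionTracks,
    config: RddCallConfig = RddCallConfig(),
) -> RddCallResult:
    """Run the full RNA-side filter cascade plus genomic subtraction.

    ``rna_samples``/``dna_samples`` map sample ids to aligned-read streams.
    DNA samples are pooled (counts summed) before subtraction. Output sites
    are ordered by (chrom, pos, alt); each carries per-sample frequency,
    coverage and a called flag (true when the site independently survived all
    RNA-side filters in that sample).
    """
    if not dna_samples:
        raise ValueError("genomic subtraction requires at least one DNA sample")
    tx_index = TranscriptIndex(genes)

    dna_pileup = Pileup(genome, sample_id="DNA_pooled")
    for sid, reads in dna_samples.items():
        stats: Dict[str, int] = {}
        sub = build_pileup(
            filter_reads(reads, stats=stats), genome, sample_id=sid
        )
        logger.info("DNA sample %s: %s", sid, stats)
        dna_pileup.merge(sub)

    filter_stats: Dict[str, Dict[str, int]] = {}
    pileups: Dict[str, Pileup] = {}
    passing: Dict[str, Set[Tuple[str, int, str]]] = {}
    candidates: Dict[Tuple[str, int, str], SnvCall] = {}

    for sid in rna_samples:
        stats = {}
        pileup = build_pileup(
            filter_reads(
                rna_samples[sid],
                min_qual=config.read_min_qual,
                min_fraction=config.read_min_fraction,
                stats=stats,
            ),
            genome,
            sample_id=sid,
        )
        pileups[sid] = pileup
        calls = call_snvs(
            pileup,
            genome,
            min_cov=config.min_cov,
            min_alt_reads=config.min_alt_reads,
            min_base_qual=config.min_base_qual,
            end_exclusion_bp=config.end_exclusion_bp,
            unique_mode=config.unique_mode,
        )
        stats["snv_candidates"] = len(calls)
        calls = apply_region_filters(
            calls, tracks, tx_index, splice_buffer_bp=config.splice_buffer_bp
        )
        passed = {c.key for c in calls if c.passed}
        stats["snv_passed_rna_filters"] = len(passed)
        for c in calls:
            for reason in c.filters_failed:
                stats[f"snv_failed_{reason}"] = stats.get(f"snv_failed_{reason}", 0) + 1
            if c.passed and c.key not in candidates:
                candidates[c.key] = c
        passing[sid] = passed
        filter_stats[sid] = stats

    sites: List[RddSite] = []
    union_stats: Dict[str, int] = {"candidate_sites": len(candidates)}
    for key in sorted(candidates):
        call = candidates[key]
        strand, reason, gene_ids = infer_strand(call, tx_index)
        if strand is None:
            union_stats[reason] = union_stats.get(reason, 0) + 1
            continue
        ok, reason = genomic_subtraction(call, dna_pileup, min_dna_cov=config.dna_min_cov)
        if not ok:
            union_stats[reason] = union_stats.get(reason, 0) + 1
            continue
        site = classify_edit(call, strand, gene_ids)
        for sid, pileup in pileups.items():
            cov = pileup.coverage(site.chrom, site.pos)
            if cov == 0 and key not in passing[sid]:
                continue
            altc = pileup.alt_count(site.chrom, site.pos, site.genomic_alt)
            site.samples[sid] = SampleSiteStats(
                frequency=altc / cov if cov else None,
                coverage=cov,
                called=key in passing[sid],
            )
        sites.append(site)
    union_stats["rdd_sites"] = len(sites)
    if config.canonical_only:
        sites = [s for s in sites if s.canonical]
        union_stats["rdd_sites_canonical"] = len(sites)
    filter_stats["__union__"] = union_stats
    return RddCallResult(
        sites=sites, filter_stats=filter_stats, pileups=pileups, dna_pileup=dna_pileup
    )
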