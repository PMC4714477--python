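"""Genic context, coding consequence and sequence context of edited sites."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, GenomeSequence, TranscriptIndex, revcomp
from .rdd_calling import RddSite

CONTEXT_PRIORITY = ["cds", "utr5", "utr3", "noncoding_exon", "intron"]


@dataclass
class SiteAnnotation:
    context: str
    consequence: str = "NA"
    ref_codon: str = ""
    alt_codon: str = ""
    ref_aa: str = ""
    alt_aa: str = ""
    transcript_id: str = ""


def transcript_context(pos: int, gene: GeneModel) -> Optional[str]:
    """Context of a position within one transcript, or None if outside it."""
    if not gene.contains(pos):
        return None
    for s, e in gene.cds:
        if s <= pos < e:
            return "cds"
    for s, e in gene.utr5:
        if s <= pos < e:
            return "utr5"
    for s, e in gene.utr3:
        if s <= pos < e:
            return "utr3"
    for s, e in gene.exons:
        if s <= pos < e:
            return "noncoding_exon"
    return "intron"


def classify_context(pos: int, genes: Sequence[GeneModel]) -> str:
    """Resolve a site's genic context across transcripts.

    Per-transcript labels are combined with priority
    cds > utr5 > utr3 > noncoding_exon > intron.
    """
    labels = {c for c in (transcript_context(pos, g) for g in genes) if c}
    if not labels:
        raise ValueError(f"position {pos} lies outside all supplied transcripts")
    for label in CONTEXT_PRIORITY:
        if label in labels:
            return label
    raise AssertionError("unreachable")


def coding_transcript_for(pos: int, genes: Sequence[GeneModel]) -> Optional[GeneModel]:
    """The transcript used for consequence prediction: CDS-context transcripts
    only, longest CDS wins (deterministic tie-break on transcript id)."""
    coding = [g for g in genes if transcript_context(pos, g) == "cds"]
    if not coding:
        return None
    return max(coding, key=lambda g: (g.cds_length, g.transcript_id))


def predict_consequence(
    pos: int, genomic_alt: str, transcript: GeneModel, genome: GenomeSequence
) -> SiteAnnotation:
    """Translate the codon containing the site before and after the change.

    The CDS is spliced and reverse-complemented for '-' strand transcripts;
    the standard genetic code applies, with stop gain/loss labelled
    separately.
    """
    positions = transcript.cds_positions()
    if len(positions) % 3 != 0:
        raise ValueError(
            f"{transcript.transcript_id}: CDS length {len(positions)} is not a "
            "multiple of 3; cannot translate"
        )
    try:
        idx = positions.index(pos)
    except ValueError:
        raise ValueError(
            f"position {pos} is not within the CDS of {transcript.transcript_id}"
        )
    chrom = transcript.chrom
    codon_idx = idx // 3
    within = idx % 3
    codon_positions = positions[codon_idx * 3 : codon_idx * 3 + 3]
    if transcript.strand == "+":
        ref_codon = "".join(genome.base(chrom, p) for p in codon_positions)
        alt_base = genomic_alt
    else:
        ref_codon = "".join(revcomp(genome.base(chrom, p)) for p in codon_positions)
        alt_base = revcomp(genomic_alt)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gain"
    elif ref_aa == "*":
        consequence = "stop_loss"
    else:
        consequence = "nonsynonymous"
    return SiteAnnotation(
        context="cds",
        consequence=consequence,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        transcript_id=transcript.transcript_id,
    )


def annotate_site(
    site: RddSite, tx_index: TranscriptIndex, genome: GenomeSequence
) -> SiteAnnotation:
    """Full annotation of one RDD site against its own-strand transcripts."""
    genes = [
        g
        for g in tx_index.overlapping(site.chrom, site.pos)
        if g.strand == site.strand
    ]
    if not genes:
        raise ValueError(
            f"site {site.chrom}:{site.pos} has no transcript on strand {site.strand}"
        )
    context = classify_context(site.pos, genes)
    if context != "cds":
        return SiteAnnotation(context=context)
    transcript = coding_transcript_for(site.pos, genes)
    assert transcript is not None
    ann = predict_consequence(site.pos, site.genomic_alt, transcript, genome)
    return ann


def annotate_sites(
    sites: Sequence[RddSite], genes: Sequence[GeneModel], genome: GenomeSequence
) -> pd.DataFrame:
    """Annotation table (one row per site, indexed like the site list)."""
    tx_index = TranscriptIndex(genes)
    rows = []
    for site in sites:
        ann = annotate_site(site, tx_index, genome)
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos + 1,
                "strand": site.strand,
                "edit_class": site.edit_class,
                "gene_ids": ",".join(site.gene_ids),
                "context": ann.context,
                "consequence": ann.consequence,
                "ref_codon": ann.ref_codon,
                "alt_codon": ann.alt_codon,
                "ref_aa": ann.ref_aa,
                "alt_aa": ann.alt_aa,
                "transcript_id": ann.transcript_id,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ContextMatrix:
    """Base composition around edited sites, strand-corrected.

    ``freq`` has shape (4, 2k+1), rows in A,C,G,T order; columns sum to 1.
    """

    k: int
    counts: np.ndarray
    n_sites: int
    n_dropped: int

    @property
    def freq(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def to_frame(self) -> pd.DataFrame:
        cols = list(range(-self.k, self.k + 1))
        return pd.DataFrame(self.freq, index=list("ACGT"), columns=cols)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def context_matrix(
    sites: Iterable[RddSite],
    genome: GenomeSequence,
    k: int = 5,
    group_by: Optional[Callable[[RddSite], str]] = None,
) -> Dict[str, ContextMatrix]:
    """Position-frequency matrices of the +/-k window around sites.

    Windows on '-' strand sites are reverse complemented so that position 0
    reads the sense reference base. Sites within k of a chromosome end are
    dropped (counted in ``n_dropped``). Returns one matrix per group ("all"
    when no grouping function is given).
    """
    grouped: Dict[str, ContextMatrix] = {}
    for site in sites:
        key = group_by(site) if group_by else "all"
        mat = grouped.get(key)
        if mat is None:
            mat = ContextMatrix(k=k, counts=np.zeros((4, 2 * k + 1)), n_sites=0, n_dropped=0)
            grouped[key] = mat
        start, end = site.pos - k, site.pos + k + 1
        if start < 0 or end > genome.length(site.chrom):
            mat.n_dropped += 1
            continue
        window = genome.fetch(site.chrom, start, end)
        if site.strand == "-":
            window = revcomp(window)
        mat.n_sites += 1
        for j, base in enumerate(window):
            if base in _BASE_INDEX:
                mat.counts[_BASE_INDEX[base], j] += 1
    return grouped


def category_enrichment(
    edited_genes: Set[str],
    expressed_genes: Set[str],
    category_map: Mapping[str, Set[str]],
    min_odds_ratio: float = 10.0,
    min_edited: int = 2,
) -> pd.DataFrame:
    """Fisher-exact category enrichment of edited genes over an expressed universe.

    For each category, the 2x2 table (edited/not x in-category/not) is tested
    over ``expressed_genes``; odds ratios use a Haldane 0.5 correction when a
    cell is zero. p-values are BH-adjusted over all tested categories, then
    the table is filtered to odds ratio > ``min_odds_ratio`` and at least
    ``min_edited`` edited genes per category.
    """
    if not expressed_genes:
        raise ValueError("expressed-gene universe is empty")
    edited = edited_genes & expressed_genes
    rows = []
    for category in sorted(category_map):
        members = category_map[category] & expressed_genes
        a = len(edited & members)
        b = len(edited - members)
        c = len(members - edited)
        d = len(expressed_genes) - a - b - c
        _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append(
            {
                "category": category,
                "n_edited_in_category": a,
                "n_edited_total": len(edited),
                "n_category_expressed": len(members),
                "n_universe": len(expressed_genes),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["p_adjusted"] = []
        return table
    table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table[
        (table["odds_ratio"] > min_odds_ratio)
        & (table["n_edited_in_category"] >= min_edited)
    ]
    return table.sort_values("p_adjusted").reset_index(drop=True)
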