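"""Expression, junction and editing quantification plus cross-sample statistics.

RPKM is computed over the union of coding exons per gene; junction usage is
exact-match counting of CIGAR N gaps, normalized as log2(FPKM + 1) with each
junction treated as a fixed feature of one read length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet, merge_intervals
from .io_formats import AlignedRead, GeneModel, TranscriptIndex
from .rdd_calling import RddSite


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionTable:
    rpkm: pd.DataFrame  # genes x samples; NaN for genes without CDS
    counts: pd.DataFrame  # genes x samples, raw read counts
    sample_meta: pd.DataFrame  # total_reads, read_length, analyzed_bases


def _sample_meta(reads_by_sample: Mapping[str, Sequence[AlignedRead]]) -> pd.DataFrame:
    rows = {}
    for sid, reads in reads_by_sample.items():
        n = len(reads)
        read_length = len(reads[0].bases) if n else 0
        rows[sid] = {
            "total_reads": n,
            "read_length": read_length,
            "analyzed_bases": n * read_length,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compute_rpkm(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    genes: Sequence[GeneModel],
) -> ExpressionTable:
    """Per-gene RPKM over the union of CDS exons of the gene's transcripts.

    A read counts toward a gene when any aligned block overlaps the gene's
    CDS union; reads overlapping the CDS of several genes count toward each.
    RPKM = count / (CDS-kb x mapped-reads-in-millions); genes with no CDS get
    NaN.
    """
    cds_by_gene: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    chrom_of_gene: Dict[str, str] = {}
    for g in genes:
        chrom_of_gene[g.gene_id] = g.chrom
        cds_by_gene.setdefault(g.gene_id, {}).setdefault(g.chrom, []).extend(g.cds)
    gene_ids = sorted(cds_by_gene)
    cds_sets = {
        gid: IntervalSet({c: ivs for c, ivs in by_chrom.items()})
        for gid, by_chrom in cds_by_gene.items()
    }
    cds_len = {
        gid: sum(
            e - s for c, ivs in by_chrom.items() for s, e in merge_intervals(ivs)
        )
        for gid, by_chrom in cds_by_gene.items()
    }
    tx_index = TranscriptIndex(genes)

    counts = pd.DataFrame(0, index=gene_ids, columns=list(reads_by_sample), dtype=int)
    for sid, reads in reads_by_sample.items():
        col = counts[sid].to_dict()
        for read in reads:
            hit: Set[str] = set()
            for gs, ge, _, _ in read.blocks:
                for g in tx_index.overlapping(read.chrom, gs):
                    hit.add(g.gene_id)
                for g in tx_index.overlapping(read.chrom, ge - 1):
                    hit.add(g.gene_id)
            for gid in hit:
                cds = cds_sets[gid]
                if any(cds.overlaps(read.chrom, gs, ge) for gs, ge, _, _ in read.blocks):
                    col[gid] += 1
        counts[sid] = pd.Series(col)

    meta = _sample_meta(reads_by_sample)
    rpkm = pd.DataFrame(index=gene_ids, columns=list(reads_by_sample), dtype=float)
    for sid in reads_by_sample:
        millions = meta.loc[sid, "total_reads"] / 1e6
        for gid in gene_ids:
            kb = cds_len[gid] / 1000.0
            if kb == 0 or millions == 0:
                rpkm.loc[gid, sid] = np.nan
            else:
                rpkm.loc[gid, sid] = counts.loc[gid, sid] / (kb * millions)
    return ExpressionTable(rpkm=rpkm, counts=counts, sample_meta=meta)


# ---------------------------------------------------------------------------
# Junctions


class Junction(NamedTuple):
    chrom: str
    donor: int  # 0-based start of the skipped intron
    acceptor: int  # 0-based end (half-open) of the skipped intron
    label: str
    strand: str


@dataclass
class JunctionMatrix:
    counts: pd.DataFrame  # junction label x sample, raw read counts
    normalized: pd.DataFrame  # log2(FPKM + 1)
    catalog: List[Junction]


def read_junction_catalog(path: str) -> List[Junction]:
    """BED-like 6-column catalog: chrom, donor, acceptor, label, score, strand."""
    catalog = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, donor, acceptor, label, _, strand = line.split("\t")[:6]
            catalog.append(Junction(chrom, int(donor), int(acceptor), label, strand))
    return catalog


def write_junction_catalog(catalog: Sequence[Junction], path: str) -> None:
    with open(path, "w") as fh:
        for j in catalog:
            fh.write(f"{j.chrom}\t{j.donor}\t{j.acceptor}\t{j.label}\t0\t{j.strand}\n")


def quantify_junctions(
    reads_by_sample: Mapping[str, Sequence[AlignedRead]],
    catalog: Sequence[Junction],
) -> JunctionMatrix:
    """Count reads whose splice gap exactly matches each catalog junction.

    Normalization treats each junction as a fixed-length feature of one read
    length: FPKM = count / (read_length-kb x mapped-reads-in-millions), and
    the reported value is log2(FPKM + 1) (0 iff the count is 0).
    """
    labels = [j.label for j in catalog]
    lookup = {(j.chrom, j.donor, j.acceptor): j.label for j in catalog}
    counts = pd.DataFrame(0, index=labels, columns=list(reads_by_sample), dtype=int)
    for sid, reads in reads_by_sample.items():
        for read in reads:
            for d, a in read.junctions:
                label = lookup.get((read.chrom, d, a))
                if label is not None:
                    counts.loc[label, sid] += 1
    meta = _sample_meta(reads_by_sample)
    normalized = pd.DataFrame(index=labels, columns=list(reads_by_sample), dtype=float)
    for sid in reads_by_sample:
        millions = meta.loc[sid, "total_reads"] / 1e6
        kb = meta.loc[sid, "read_length"] / 1000.0
        denom = kb * millions
        fpkm = counts[sid] / denom if denom > 0 else counts[sid] * 0.0
        normalized[sid] = np.log2(fpkm + 1.0)
    return JunctionMatrix(counts=counts, normalized=normalized, catalog=list(catalog))


# ---------------------------------------------------------------------------
# Editing matrix


def site_id(site: RddSite) -> str:
    return f"{site.chrom}:{site.pos + 1}:{site.genomic_alt}"


@dataclass
class EditingMatrix:
    """Sites x samples grid of (frequency, coverage, called) with masking.

    ``mask`` is True where coverage is below the threshold; masked cells are
    excluded from all downstream statistics. ``freq`` is NaN where coverage
    is zero.
    """

    freq: pd.DataFrame
    coverage: pd.DataFrame
    called: pd.DataFrame
    mask: pd.DataFrame
    min_cov: int

    @property
    def sites(self) -> List[str]:
        return list(self.freq.index)

    @property
    def samples(self) -> List[str]:
        return list(self.freq.columns)


def editing_matrix(
    rdds: Sequence[RddSite],
    sample_ids: Optional[Sequence[str]] = None,
    min_cov: int = 10,
) -> EditingMatrix:
    if sample_ids is None:
        seen: List[str] = []
        for site in rdds:
            for sid in site.samples:
                if sid not in seen:
                    seen.append(sid)
        sample_ids = seen
    index = [site_id(s) for s in rdds]
    freq = pd.DataFrame(np.nan, index=index, columns=list(sample_ids))
    cov = pd.DataFrame(0, index=index, columns=list(sample_ids), dtype=int)
    called = pd.DataFrame(False, index=index, columns=list(sample_ids), dtype=bool)
    for site in rdds:
        sid_row = site_id(site)
        for sid, stats in site.samples.items():
            if sid not in freq.columns:
                continue
            cov.loc[sid_row, sid] = stats.coverage
            called.loc[sid_row, sid] = stats.called
            if stats.frequency is not None:
                freq.loc[sid_row, sid] = stats.frequency
    mask = cov < min_cov
    return EditingMatrix(freq=freq, coverage=cov, called=called, mask=mask, min_cov=min_cov)


def heatmap_sites(matrix: EditingMatrix, min_cov: int = 10, min_freq: float = 0.4) -> List[str]:
    """Sites with >= ``min_cov`` coverage and frequency > ``min_freq`` in >= 1 sample."""
    ok = (matrix.coverage >= min_cov) & (matrix.freq > min_freq)
    return list(matrix.freq.index[ok.any(axis=1)])


def variable_sites(matrix: EditingMatrix, min_cov: int = 10) -> List[str]:
    """Sites with >= ``min_cov`` coverage in >= 2 samples and called in >= 1."""
    enough_cov = (matrix.coverage >= min_cov).sum(axis=1) >= 2
    any_called = matrix.called.any(axis=1)
    return list(matrix.freq.index[enough_cov & any_called])


# ---------------------------------------------------------------------------
# Sharing


def sharing_stats(
    called: pd.DataFrame,
    strata: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Binary recurrence statistics over the union of called sites.

    ``called`` is a sites x samples boolean frame. For each stratum (a named
    subset of site ids; "all" is always included) the fractions of sites
    called in >= 2 samples and in all samples are reported, over the sites of
    that stratum called in >= 1 sample.
    """
    if called.shape[1] < 2:
        raise ValueError("sharing statistics require at least 2 samples")
    all_strata: Dict[str, Sequence[str]] = {"all": list(called.index)}
    if strata:
        all_strata.update(strata)
    n_samples = called.shape[1]
    rows = []
    for name, site_ids in all_strata.items():
        sub = called.loc[[s for s in site_ids if s in called.index]]
        n_called = sub.sum(axis=1)
        universe = sub[n_called >= 1]
        n = len(universe)
        n_any = int((universe.sum(axis=1) >= 2).sum())
        n_all = int((universe.sum(axis=1) == n_samples).sum())
        rows.append(
            {
                "stratum": name,
                "n_sites": n,
                "shared_any_fraction": n_any / n if n else np.nan,
                "shared_all_fraction": n_all / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RDD counts vs analyzed bases


def overlaps_intron(site: RddSite, tx_index: TranscriptIndex) -> bool:
    for g in tx_index.overlapping(site.chrom, site.pos):
        for s, e in g.introns:
            if s <= site.pos < e:
                return True
    return False


def rdd_counts_by_depth(
    rdds: Sequence[RddSite],
    genes: Sequence[GeneModel],
    sample_meta: pd.DataFrame,
    canonical_only: bool = True,
) -> pd.DataFrame:
    """Per sample: analyzed bases and called A-to-I site counts, with and
    without sites that overlap an intron of any overlapping transcript."""
    tx_index = TranscriptIndex(genes)
    sites = [s for s in rdds if s.canonical or not canonical_only]
    intronic = {site_id(s) for s in sites if overlaps_intron(s, tx_index)}
    rows = []
    for sid in sample_meta.index:
        called_here = [s for s in sites if s.samples.get(sid) and s.samples[sid].called]
        n_all = len(called_here)
        n_no_intron = sum(1 for s in called_here if site_id(s) not in intronic)
        rows.append(
            {
                "sample_id": sid,
                "analyzed_bases": int(sample_meta.loc[sid, "analyzed_bases"]),
                "n_rdds": n_all,
                "n_rdds_excluding_intronic": n_no_intron,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Enzyme-expression correlation


def correlate_editing_enzymes(
    matrix: EditingMatrix,
    enzyme_expression: pd.DataFrame,
    min_cov: int = 10,
    min_pairs: int = 3,
    method: str = "pearson",
    site_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per site x enzyme one-sided tests for positive correlation.

    ``enzyme_expression`` is enzymes x samples. Only samples with coverage >=
    ``min_cov`` at the site enter a test; tests with fewer than ``min_pairs``
    pairs, or a constant frequency or expression vector, are recorded as
    untested. BH adjustment runs across all performed tests; rows are sorted
    by adjusted p.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if site_ids is None:
        site_ids = variable_sites(matrix, min_cov=min_cov)
    shared = [s for s in matrix.samples if s in enzyme_expression.columns]
    rows = []
    for sid_site in site_ids:
        covered = [
            s for s in shared if matrix.coverage.loc[sid_site, s] >= min_cov
        ]
        freqs = matrix.freq.loc[sid_site, covered].to_numpy(dtype=float)
        for enzyme in enzyme_expression.index:
            expr = enzyme_expression.loc[enzyme, covered].to_numpy(dtype=float)
            keep = ~(np.isnan(freqs) | np.isnan(expr))
            x, y = freqs[keep], expr[keep]
            n = len(x)
            row = {
                "site": sid_site,
                "enzyme": enzyme,
                "n": n,
                "r": np.nan,
                "p_value": np.nan,
                "tested": False,
                "reason": "",
            }
            if n < min_pairs:
                row["reason"] = "too_few_pairs"
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                row["reason"] = "constant"
            else:
                if method == "pearson":
                    res = pearsonr(x, y, alternative="greater")
                else:
                    res = spearmanr(x, y, alternative="greater")
                row["r"] = float(res.statistic)
                row["p_value"] = float(res.pvalue)
                row["tested"] = True
            rows.append(row)
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    tested = table["tested"]
    if tested.any():
        table.loc[tested, "p_adjusted"] = multipletests(
            table.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return table.sort_values(
        ["p_adjusted", "p_value", "site", "enzyme"], na_position="last"
    ).reset_index(drop=True)
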