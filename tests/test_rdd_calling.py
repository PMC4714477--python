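"""RDD calling: strand inference, subtraction, classification, full cascade.

The gauntlet test re-checks every rule with an independent brute-force
oracle that works directly from the raw reads, without using the pileup or
call machinery under test.
"""

import pytest

from rddcall.io_formats import GeneModel, GenomeSequence, TranscriptIndex, revcomp
from rddcall.rdd_calling import (
    RddCallConfig,
    call_rdds,
    classify_edit,
    genomic_subtraction,
    infer_strand,
)
from rddcall.snv_calling import Pileup, SnvCall, build_pileup

from conftest import make_genome
from test_snv_calling import mk_read


def _call(chrom="chr1", pos=50, ref="A", alt="G"):
    return SnvCall(
        chrom=chrom, pos=pos, ref_base=ref, alt_base=alt,
        alt_count=5, total_coverage=20, frequency=0.25, sample_id="s",
    )


# ---------------------------------------------------------------------------
# strand inference


def test_infer_strand_single_plus_gene():
    idx = TranscriptIndex([GeneModel("g", "t", "chr1", "+", [(0, 100)])])
    strand, reason, gene_ids = infer_strand(_call(), idx)
    assert strand == "+" and reason is None and gene_ids == ("g",)


def test_infer_strand_opposite_overlap_rejected():
    idx = TranscriptIndex(
        [
            GeneModel("a", "a.t", "chr1", "+", [(0, 100)]),
            GeneModel("b", "b.t", "chr1", "-", [(40, 140)]),
        ]
    )
    strand, reason, _ = infer_strand(_call(), idx)
    assert strand is None and reason == "strand_ambiguous"


def test_infer_strand_two_minus_genes_allowed():
    idx = TranscriptIndex(
        [
            GeneModel("a", "a.t", "chr1", "-", [(0, 100)]),
            GeneModel("b", "b.t", "chr1", "-", [(40, 140)]),
        ]
    )
    strand, reason, gene_ids = infer_strand(_call(), idx)
    assert strand == "-" and reason is None and gene_ids == ("a", "b")


def test_infer_strand_intergenic():
    strand, reason, _ = infer_strand(_call(), TranscriptIndex([]))
    assert strand is None and reason == "intergenic"


# ---------------------------------------------------------------------------
# genomic subtraction


def _dna_pileup(n_ref, n_alt, pos=50):
    genome = make_genome("A" * 200)
    reads = [mk_read(pos - 30 + i, "A" * 60, rid=f"d{i}") for i in range(n_ref)]
    for i in range(n_alt):
        off = 25 + i
        bases = "A" * off + "G" + "A" * (60 - off - 1)
        reads.append(mk_read(pos - off, bases, rid=f"a{i}"))
    return build_pileup(reads, genome)


def test_subtraction_pass_at_25x_clean():
    ok, reason = genomic_subtraction(_call(), _dna_pileup(25, 0))
    assert ok and reason is None


def test_subtraction_requires_strictly_more_than_20x():
    ok, reason = genomic_subtraction(_call(), _dna_pileup(20, 0))
    assert not ok and reason == "dna_low_cov"


def test_subtraction_fails_on_any_alt_support():
    ok, reason = genomic_subtraction(_call(), _dna_pileup(39, 1))
    assert not ok and reason == "dna_support"


def test_subtraction_site_absent_from_dna():
    empty = Pileup(make_genome("A" * 200))
    ok, reason = genomic_subtraction(_call(), empty)
    assert not ok and reason == "dna_low_cov"


# ---------------------------------------------------------------------------
# classification


def test_classify_minus_strand_tc_is_a_to_i():
    site = classify_edit(_call(ref="T", alt="C"), "-")
    assert site.sense_ref == "A" and site.sense_alt == "G"
    assert site.edit_class == "A-to-I" and site.canonical


def test_classify_minus_strand_ag_is_noncanonical():
    site = classify_edit(_call(ref="A", alt="G"), "-")
    assert site.edit_class == "T-to-C" and not site.canonical


def test_classify_plus_strand_ct_noncanonical():
    site = classify_edit(_call(ref="C", alt="T"), "+")
    assert site.edit_class == "C-to-T" and not site.canonical


@pytest.mark.parametrize("base", "ACGT")
def test_strand_correction_is_involution(base):
    assert revcomp(revcomp(base)) == base


# ---------------------------------------------------------------------------
# gauntlet: brute-force per-rule oracle, independent of the pileup machinery


def oracle_survivors(fixture, cfg: RddCallConfig):
    """Re-derive the survivor set by checking every rule from raw reads."""
    genome = fixture.genome
    genes = fixture.genes

    def kept(read):
        good = sum(1 for q in read.quals if q >= cfg.read_min_qual)
        return read.unique and good / len(read.quals) >= cfg.read_min_fraction

    rna = [r for reads in fixture.rna_reads.values() for r in reads if kept(r)]
    dna = [r for reads in fixture.dna_reads.values() for r in reads if kept(r)]

    def base_at(read, chrom, pos):
        if read.chrom != chrom:
            return None
        for gs, ge, qs, qe in read.blocks:
            if gs <= pos < ge:
                q = qs + (pos - gs)
                return read.bases[q], read.quals[q], read.end_distance(q), read.start
        return None

    survivors = set()
    for site in fixture.sites:
        chrom, pos, alt = site.chrom, site.pos, site.alt
        rna_obs = [o for o in (base_at(r, chrom, pos) for r in rna) if o]
        coverage = sum(1 for b, *_ in rna_obs if b != "N")
        support = [o for o in rna_obs if o[0] == alt]
        evidence = [o for o in support if o[1] >= cfg.min_base_qual]
        if coverage < cfg.min_cov:
            continue
        if len({start for _, _, _, start in evidence}) < cfg.min_alt_reads:
            continue
        if not any(d > cfg.end_exclusion_bp for _, _, d, _ in evidence):
            continue
        if any(t.contains(chrom, pos) for _, t in fixture.tracks.items()):
            continue
        splice_fail = False
        for g in genes:
            for s, e in g.introns:
                if s <= pos < e and min(pos - s, e - 1 - pos) < cfg.splice_buffer_bp:
                    splice_fail = True
        if splice_fail:
            continue
        strands = {g.strand for g in genes if g.span[0] <= pos < g.span[1]}
        if len(strands) != 1:
            continue
        dna_obs = [o for o in (base_at(r, chrom, pos) for r in dna) if o]
        dna_cov = sum(1 for b, *_ in dna_obs if b != "N")
        dna_alt = sum(1 for b, *_ in dna_obs if b == alt)
        if dna_cov <= cfg.dna_min_cov or dna_alt > 0:
            continue
        survivors.add((chrom, pos, alt))
    return survivors


@pytest.fixture(scope="module")
def gauntlet_result(gauntlet):
    return call_rdds(
        gauntlet.rna_reads,
        gauntlet.dna_reads,
        gauntlet.genome,
        gauntlet.genes,
        gauntlet.tracks,
        RddCallConfig(),
    )


def test_gauntlet_survivors_match_design(gauntlet, gauntlet_result):
    assert {s.key for s in gauntlet_result.sites} == gauntlet.expected_survivors


def test_gauntlet_matches_brute_force_oracle(gauntlet, gauntlet_result):
    assert {s.key for s in gauntlet_result.sites} == oracle_survivors(
        gauntlet, RddCallConfig()
    )


def test_gauntlet_audit_records_each_designed_failure(gauntlet, gauntlet_result):
    stats = gauntlet_result.filter_stats
    rna_stats = stats["rna"]
    union = stats["__union__"]
    # rules surfaced at the SNV stage (low_base_qual manifests as missing
    # qualifying evidence, i.e. few_alt_reads)
    assert rna_stats["snv_failed_low_coverage"] >= 1
    assert rna_stats["snv_failed_few_alt_reads"] >= 2
    assert rna_stats["snv_failed_read_end_only"] >= 1
    for name in ("homopolymer", "repeat", "multimap", "self_chain", "splice_proximal"):
        assert rna_stats[f"snv_failed_{name}"] == 1
    for name in ("intergenic", "strand_ambiguous", "dna_support", "dna_low_cov"):
        assert union[name] == 1


def test_gauntlet_minus_strand_survivor_classified(gauntlet_result):
    (minus,) = [s for s in gauntlet_result.sites if s.strand == "-"]
    assert minus.genomic_ref == "T" and minus.genomic_alt == "C"
    assert minus.edit_class == "A-to-I" and minus.canonical


def test_no_dna_samples_raises(gauntlet):
    with pytest.raises(ValueError, match="DNA"):
        call_rdds(
            gauntlet.rna_reads, {}, gauntlet.genome, gauntlet.genes, gauntlet.tracks
        )


def test_rdd_sites_never_have_dna_support(gauntlet, gauntlet_result):
    dna = gauntlet_result.dna_pileup
    for site in gauntlet_result.sites:
        assert dna.coverage(site.chrom, site.pos) > 20
        assert dna.alt_count(site.chrom, site.pos, site.genomic_alt) == 0


# ---------------------------------------------------------------------------
# planted truth, small scale


def test_small_study_no_rdds_at_snp_sites(small_study):
    from rddcall.io_formats import read_sam

    cfg = small_study.config
    rna = {
        s.sample_id: read_sam(small_study.sam_paths[s.sample_id], s.sample_id)
        for s in cfg.rna_samples()
    }
    dna = {
        s.sample_id: read_sam(small_study.sam_paths[s.sample_id], s.sample_id)
        for s in cfg.dna_samples()
    }
    result = call_rdds(
        rna, dna, small_study.genome, small_study.genes, small_study.tracks
    )
    snp_positions = {(s.chrom, s.pos) for s in small_study.truth.snps}
    called_positions = {(s.chrom, s.pos) for s in result.sites}
    assert not (snp_positions & called_positions)
    # most called positions are planted edits
    edit_positions = {(e.chrom, e.pos) for e in small_study.truth.edits}
    assert len(called_positions & edit_positions) >= 1
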