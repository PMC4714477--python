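import itertools

import numpy as np
import pandas as pd
import pytest

from rddcall.io_formats import GeneModel
from rddcall.quantification import (
    Junction,
    compute_rpkm,
    correlate_editing_enzymes,
    editing_matrix,
    heatmap_sites,
    quantify_junctions,
    rdd_counts_by_depth,
    sharing_stats,
    site_id,
    variable_sites,
)
from rddcall.rdd_calling import RddSite, SampleSiteStats

from test_snv_calling import mk_read


# ---------------------------------------------------------------------------
# RPKM


def _rpkm_fixture(n_gene_reads=1000, n_total=1_000_000):
    gene = GeneModel("g1", "g1.t", "chr1", "+", [(0, 1000)], [(0, 999)])
    reads = [mk_read(10, "A" * 50, rid=f"g{i}") for i in range(n_gene_reads)]
    # filler reads elsewhere on the chromosome
    reads += [
        mk_read(5000, "A" * 50, rid=f"f{i}") for i in range(n_total - n_gene_reads)
    ]
    return gene, reads


def test_rpkm_closed_form():
    gene = GeneModel("g1", "g1.t", "chr1", "+", [(0, 1000)], [(0, 999)])
    # 999 bp CDS is not 1 kb; use a CDS of exactly 1000 bp via two exons
    gene = GeneModel("g1", "g1.t", "chr1", "+", [(0, 600), (700, 1200)], [(0, 600), (700, 1100)])
    assert gene.cds_length == 1000
    reads = [mk_read(10, "A" * 50, rid=f"g{i}") for i in range(1000)]
    reads += [mk_read(5000, "A" * 50, rid=f"f{i}") for i in range(999_000)]
    table = compute_rpkm({"s": reads}, [gene])
    assert table.rpkm.loc["g1", "s"] == pytest.approx(1000.0)
    assert table.sample_meta.loc["s", "analyzed_bases"] == 1_000_000 * 50


def test_rpkm_zero_reads_and_scale_property():
    gene = GeneModel("g1", "g1.t", "chr1", "+", [(0, 1000)], [(0, 600)])
    filler = [mk_read(5000, "A" * 50, rid=f"f{i}") for i in range(1000)]
    table = compute_rpkm({"s": filler}, [gene])
    assert table.rpkm.loc["g1", "s"] == 0.0
    gene_reads = [mk_read(10, "A" * 50, rid=f"g{i}") for i in range(10)]
    t1 = compute_rpkm({"s": gene_reads + filler}, [gene])
    t2 = compute_rpkm({"s": gene_reads + filler * 2}, [gene])
    ratio = t1.rpkm.loc["g1", "s"] / t2.rpkm.loc["g1", "s"]
    assert ratio == pytest.approx(2010 / 1010)


def test_rpkm_gene_without_cds_is_na():
    gene = GeneModel("nc", "nc.t", "chr1", "+", [(0, 1000)])
    table = compute_rpkm({"s": [mk_read(10, "A" * 50)]}, [gene])
    assert np.isnan(table.rpkm.loc["nc", "s"])


# ---------------------------------------------------------------------------
# junctions


def _spliced_read(rid="r1"):
    return mk_read(
        9,
        "AAAAAA",
        blocks=((9, 12, 0, 3), (112, 115, 3, 6)),
        junctions=((12, 112),),
        rid=rid,
    )


def test_junction_exact_match_counting():
    catalog = [
        Junction("chr1", 12, 112, "J1", "+"),
        Junction("chr1", 12, 113, "J_near_miss", "+"),
        Junction("chr1", 11, 112, "J_near_miss2", "+"),
    ]
    jm = quantify_junctions({"s": [_spliced_read()]}, catalog)
    assert jm.counts.loc["J1", "s"] == 1
    assert jm.counts.loc["J_near_miss", "s"] == 0
    assert jm.counts.loc["J_near_miss2", "s"] == 0


def test_junction_normalization_zero_iff_zero_count():
    catalog = [Junction("chr1", 12, 112, "J1", "+"), Junction("chr1", 500, 600, "J2", "+")]
    reads = [_spliced_read(f"r{i}") for i in range(4)]
    jm = quantify_junctions({"s": reads}, catalog)
    assert jm.normalized.loc["J2", "s"] == 0.0
    assert jm.normalized.loc["J1", "s"] > 0.0
    # closed form: count / (read_len_kb * millions)
    fpkm = 4 / ((6 / 1000) * (4 / 1e6))
    assert jm.normalized.loc["J1", "s"] == pytest.approx(np.log2(fpkm + 1))


# ---------------------------------------------------------------------------
# editing matrix and selectors


def _site(pos, per_sample, chrom="chr1"):
    return RddSite(
        chrom=chrom, pos=pos, genomic_ref="A", genomic_alt="G", strand="+",
        sense_ref="A", sense_alt="G", edit_class="A-to-I", canonical=True,
        gene_ids=("g",),
        samples={
            sid: SampleSiteStats(frequency=f, coverage=c, called=k)
            for sid, (f, c, k) in per_sample.items()
        },
    )


def test_editing_matrix_masking():
    site = _site(10, {"a": (0.5, 12, True), "b": (0.2, 5, False)})
    m = editing_matrix([site], min_cov=10)
    sid = site_id(site)
    assert not m.mask.loc[sid, "a"]
    assert m.mask.loc[sid, "b"]


def test_heatmap_selector_spec_examples():
    in_site = _site(10, {"a": (0.41, 12, True), "b": (0.1, 30, False)})
    out_site = _site(50, {"a": (0.9, 9, False), "b": (0.9, 9, False)})
    m = editing_matrix([in_site, out_site], min_cov=10)
    assert heatmap_sites(m) == [site_id(in_site)]


def test_heatmap_selector_boundary_freq_exactly_04_excluded():
    site = _site(10, {"a": (0.4, 12, True)})
    m = editing_matrix([site])
    assert heatmap_sites(m) == []


def test_variable_selector_spec_example():
    in_site = _site(10, {"a": (0.5, 10, True), "b": (0.0, 10, False), "c": (0.0, 3, False)})
    only_one_cov = _site(50, {"a": (0.5, 10, True), "b": (0.0, 3, False)})
    uncalled = _site(90, {"a": (0.5, 15, False), "b": (0.0, 15, False)})
    m = editing_matrix([in_site, only_one_cov, uncalled], min_cov=10)
    assert variable_sites(m) == [site_id(in_site)]


# ---------------------------------------------------------------------------
# sharing


def test_sharing_worked_example():
    called = pd.DataFrame(
        {
            "A": [True, True, True],
            "B": [False, True, True],
            "C": [False, False, True],
        },
        index=["s1", "s2", "s3"],
    )
    table = sharing_stats(called).set_index("stratum")
    assert table.loc["all", "shared_any_fraction"] == pytest.approx(2 / 3)
    assert table.loc["all", "shared_all_fraction"] == pytest.approx(1 / 3)


def test_sharing_all_singletons_and_all_shared():
    called = pd.DataFrame({"A": [True, False], "B": [False, True]}, index=["s1", "s2"])
    table = sharing_stats(called).set_index("stratum")
    assert table.loc["all", "shared_any_fraction"] == 0.0
    called = pd.DataFrame({"A": [True], "B": [True]}, index=["s1"])
    table = sharing_stats(called).set_index("stratum")
    assert table.loc["all", "shared_any_fraction"] == 1.0
    assert table.loc["all", "shared_all_fraction"] == 1.0


def test_sharing_single_sample_errors():
    called = pd.DataFrame({"A": [True]}, index=["s1"])
    with pytest.raises(ValueError):
        sharing_stats(called)


def sharing_oracle(mat: np.ndarray):
    """Exhaustive enumeration oracle for shared-any / shared-all fractions."""
    n_sites, n_samples = mat.shape
    union = [i for i in range(n_sites) if mat[i].sum() >= 1]
    if not union:
        return np.nan, np.nan
    any2 = sum(1 for i in union if mat[i].sum() >= 2) / len(union)
    alln = sum(1 for i in union if mat[i].sum() == n_samples) / len(union)
    return any2, alln


def test_sharing_matches_enumeration_oracle_random():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n_sites = int(rng.integers(1, 13))
        n_samples = int(rng.integers(2, 6))
        mat = rng.random((n_sites, n_samples)) < 0.4
        called = pd.DataFrame(
            mat,
            index=[f"s{i}" for i in range(n_sites)],
            columns=[f"c{j}" for j in range(n_samples)],
        )
        expected_any, expected_all = sharing_oracle(mat)
        row = sharing_stats(called).set_index("stratum").loc["all"]
        if np.isnan(expected_any):
            assert np.isnan(row["shared_any_fraction"])
        else:
            assert row["shared_any_fraction"] == pytest.approx(expected_any)
            assert row["shared_all_fraction"] == pytest.approx(expected_all)


# ---------------------------------------------------------------------------
# counts by depth


def test_rdd_counts_by_depth_intron_exclusion():
    gene = GeneModel("g", "t", "chr1", "+", [(0, 100), (200, 300)])
    intronic = _site(150, {"a": (0.5, 20, True)})
    exonic = _site(50, {"a": (0.5, 20, True)})
    meta = pd.DataFrame({"total_reads": [100], "read_length": [50], "analyzed_bases": [5000]}, index=["a"])
    table = rdd_counts_by_depth([intronic, exonic], [gene], meta)
    assert table.loc["a", "n_rdds"] == 2
    assert table.loc["a", "n_rdds_excluding_intronic"] == 1
    table = rdd_counts_by_depth([intronic], [gene], meta)
    assert table.loc["a", "n_rdds_excluding_intronic"] == 0


def test_rdd_counts_monotone_under_exclusion():
    # subset property: excluding introns never increases counts
    gene = GeneModel("g", "t", "chr1", "+", [(0, 100), (200, 300)])
    sites = [_site(p, {"a": (0.5, 20, True)}) for p in (50, 150, 250)]
    meta = pd.DataFrame({"total_reads": [1], "read_length": [1], "analyzed_bases": [1]}, index=["a"])
    table = rdd_counts_by_depth(sites, [gene], meta)
    assert (table["n_rdds_excluding_intronic"] <= table["n_rdds"]).all()


# ---------------------------------------------------------------------------
# correlation


def _matrix_from_freqs(freqs: dict, coverage=30):
    samples = sorted({s for d in freqs.values() for s in d})
    idx = list(freqs)
    freq = pd.DataFrame(
        [[freqs[i][s] for s in samples] for i in idx], index=idx, columns=samples
    )
    cov = pd.DataFrame(coverage, index=idx, columns=samples, dtype=int)
    called = pd.DataFrame(True, index=idx, columns=samples)
    from rddcall.quantification import EditingMatrix

    return EditingMatrix(freq=freq, coverage=cov, called=called, mask=cov < 10, min_cov=10)


def test_correlation_perfect_positive():
    samples = [f"s{i}" for i in range(6)]
    expr = pd.DataFrame([np.arange(1.0, 7.0)], index=["Adar"], columns=samples)
    m = _matrix_from_freqs({"x": {s: 0.1 * (i + 1) for i, s in enumerate(samples)}})
    table = correlate_editing_enzymes(m, expr, site_ids=["x"])
    row = table.iloc[0]
    assert row["r"] == pytest.approx(1.0)
    assert row["tested"]
    assert row["p_value"] < 1e-8


def test_correlation_constant_untested():
    samples = [f"s{i}" for i in range(6)]
    expr = pd.DataFrame([np.arange(1.0, 7.0)], index=["Adar"], columns=samples)
    m = _matrix_from_freqs({"x": {s: 0.5 for s in samples}})
    table = correlate_editing_enzymes(m, expr, site_ids=["x"])
    assert not table.iloc[0]["tested"]
    assert table.iloc[0]["reason"] == "constant"


def test_correlation_too_few_pairs_untested():
    samples = ["s0", "s1"]
    expr = pd.DataFrame([[1.0, 2.0]], index=["Adar"], columns=samples)
    m = _matrix_from_freqs({"x": {"s0": 0.1, "s1": 0.9}})
    table = correlate_editing_enzymes(m, expr, site_ids=["x"])
    assert table.iloc[0]["reason"] == "too_few_pairs"


def test_correlation_masks_low_coverage_samples():
    samples = [f"s{i}" for i in range(6)]
    expr = pd.DataFrame([np.arange(1.0, 7.0)], index=["Adar"], columns=samples)
    freqs = {"x": {s: 0.1 * (i + 1) for i, s in enumerate(samples)}}
    m = _matrix_from_freqs(freqs)
    m.coverage.loc["x", "s5"] = 5  # below threshold: excluded from the test
    table = correlate_editing_enzymes(m, expr, site_ids=["x"])
    assert table.iloc[0]["n"] == 5
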