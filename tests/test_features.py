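import numpy as np
import pandas as pd
import pytest

from haplocis import features
from haplocis.config import factor_registry

SIZES = {"chr1": 100_000}


def _gene(start=10_000, end=13_000, strand="+", gid="g1"):
    return pd.DataFrame({"gene_id": [gid], "chrom": ["chr1"],
                         "start": [start], "end": [end], "strand": [strand]})


def test_plus_strand_promoter_geometry():
    reg = features.assign_regions(_gene(), pd.DataFrame(columns=[
        "acr_id", "chrom", "start", "end"]), SIZES)
    prom = reg[reg.region == "promoter"].iloc[0]
    assert (prom.start, prom.end) == (9_000, 10_000)
    # no ACR anywhere: regulatory regions absent
    assert set(reg.region) == {"genic", "promoter"}


def test_minus_strand_geometry_is_mirrored():
    reg = features.assign_regions(_gene(strand="-"), pd.DataFrame({
        "acr_id": ["a1"], "chrom": ["chr1"], "start": [14_500], "end": [15_000],
    }), SIZES)
    prom = reg[reg.region == "promoter"].iloc[0]
    assert (prom.start, prom.end) == (13_000, 14_000)   # downstream in genome coords
    up = reg[reg.region == "upstream_reg"]
    assert len(up) == 1 and up.start.iloc[0] == 14_500


def test_upstream_region_requires_acr_in_window():
    acrs = pd.DataFrame({"acr_id": ["near", "far"], "chrom": ["chr1"] * 2,
                         "start": [5_000, 1_000], "end": [5_400, 1_200]})
    reg = features.assign_regions(_gene(), acrs, SIZES)
    up = reg[reg.region == "upstream_reg"]
    assert list(up.start) == [5_000]    # within [4,000, 9,000); 1,000 is not


def test_regions_clip_at_chromosome_edge():
    reg = features.assign_regions(_gene(start=400, end=1_400), pd.DataFrame(
        columns=["acr_id", "chrom", "start", "end"]), SIZES)
    prom = reg[reg.region == "promoter"].iloc[0]
    assert prom.start == 0 and prom.end == 400


@pytest.mark.parametrize("a_start,a_end,expected", [
    (11_000, 11_300, "genic"),       # inside the gene span (intronic counts)
    (14_500, 14_800, "proximal"),    # gap 1,500
    (15_500, 15_800, "distal"),      # gap 2,500
    (13_000, 13_200, "genic"),       # touching start-of-gap still overlaps? no:
])
def test_acr_classification(a_start, a_end, expected):
    acrs = pd.DataFrame({"acr_id": ["a"], "chrom": ["chr1"],
                         "start": [a_start], "end": [a_end]})
    got = features.classify_acr(acrs, _gene())  # gene [10,000, 13,000)
    if (a_start, a_end) == (13_000, 13_200):
        expected = "proximal"       # touching = gap 0, not overlapping
    assert got.iloc[0] == expected


def test_classify_acr_empty_gene_set_all_distal():
    acrs = pd.DataFrame({"acr_id": ["a"], "chrom": ["chr1"],
                         "start": [0], "end": [10]})
    got = features.classify_acr(acrs, _gene().iloc[:0])
    assert (got == "distal").all()


@pytest.fixture
def matrix_inputs():
    genes = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"], "chrom": ["chr1"] * 3,
        "start": [10_000, 30_000, 50_000], "end": [13_000, 33_000, 53_000],
        "strand": ["+"] * 3,
    })
    acrs = pd.DataFrame(columns=["acr_id", "chrom", "start", "end"])
    regions = features.assign_regions(genes, acrs, SIZES)
    rng = np.random.default_rng(0)

    def snps_for(gene_start, n, mat, pat):
        return [(f"s{gene_start}_{i}", "chr1", gene_start + 100 + i * 50, mat, pat)
                for i in range(n)]

    rows = (snps_for(10_000, 4, 20, 20) + snps_for(30_000, 4, 20, 20)
            + snps_for(50_000, 4, 60, 2))   # g3: extreme WGS imbalance
    wgs = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                      "maternal_count", "paternal_count"])
    atac = wgs.assign(maternal_count=15, paternal_count=5)
    return genes, regions, {"WGS": wgs, "ATAC": atac}


def test_matrix_has_full_registry_and_na_for_empty_regions(matrix_inputs):
    genes, regions, counts = matrix_inputs
    X, sidecar = features.build_matrix(genes, regions, counts, None, None,
                                       wgs_outlier_iqr=np.inf)
    assert list(X.columns) == factor_registry()
    assert sidecar["n_chromatin_factors"] == 56
    # no SNPs in promoters: promoter allelic cells must be NA, never 0
    assert X["WGS:promoter:allelic"].isna().all()
    assert X["ATAC:genic:allelic"].notna().all()
    assert X.loc["g1", "ATAC:genic:allelic"] == pytest.approx(
        np.log2(61 / 21))


def test_wgs_outlier_genes_dropped():
    n = 8
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)], "chrom": ["chr1"] * n,
        "start": np.arange(n) * 10_000, "end": np.arange(n) * 10_000 + 3_000,
        "strand": ["+"] * n,
    })
    sizes = {"chr1": 200_000}
    regions = features.assign_regions(genes, pd.DataFrame(
        columns=["acr_id", "chrom", "start", "end"]), sizes)
    rows = []
    for i in range(n):
        mat, pat = (60, 2) if i == 7 else (20, 20)   # one strongly biased gene
        rows.append((f"s{i}", "chr1", i * 10_000 + 100, mat, pat))
    wgs = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                      "maternal_count", "paternal_count"])
    X, sidecar = features.build_matrix(genes, regions, {"WGS": wgs},
                                       None, None, percentile=0.0)
    assert sidecar["n_wgs_outliers_dropped"] == 1
    assert "g7" not in X.index


def test_percentile_filter_blanks_lowest_coverage_cells():
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(10)], "chrom": ["chr1"] * 10,
        "start": np.arange(10) * 10_000, "end": np.arange(10) * 10_000 + 3_000,
        "strand": ["+"] * 10,
    })
    sizes = {"chr1": 200_000}
    regions = features.assign_regions(genes, pd.DataFrame(
        columns=["acr_id", "chrom", "start", "end"]), sizes)
    rows = []
    for i in range(10):
        depth = 5 if i == 0 else 50   # gene 0 far below the 10th percentile
        rows.append((f"s{i}", "chr1", i * 10_000 + 100, depth, depth))
    wgs = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                      "maternal_count", "paternal_count"])
    X, _ = features.build_matrix(genes, regions, {"WGS": wgs}, None, None,
                                 percentile=10.0, wgs_outlier_iqr=np.inf)
    assert np.isnan(X.loc["g0", "WGS:genic:allelic"])
    assert X.loc["g1", "WGS:genic:allelic"] == pytest.approx(0.0)


def test_promoter_deletion_indicators_and_dnds():
    genes = _gene()
    regions = features.assign_regions(genes, pd.DataFrame(
        columns=["acr_id", "chrom", "start", "end"]), SIZES)
    sv = pd.DataFrame({"gene_id": ["g1"], "parent": ["maternal"]})
    dnds = pd.DataFrame({"gene_id": ["g1"], "dnds": [0.3]})
    X, _ = features.build_matrix(genes, regions, {}, None, None,
                                 promoter_svs=sv, dnds=dnds)
    assert X.loc["g1", "maternal_promoter_deletion"] == 1.0
    assert X.loc["g1", "paternal_promoter_deletion"] == 0.0
    assert X.loc["g1", "dnds"] == 0.3
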