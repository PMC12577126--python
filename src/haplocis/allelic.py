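"""Per-SNP allelic counts to filtered, feature-aggregated allelic quantities.

The filter order is fixed: the per-SNP coverage filter (total < 10 removed)
runs before the >= 2-SNPs-per-feature rule. Feature log2 fold changes use a
pseudocount of 1 on each haplotype sum. Haplotype counts are re-keyed to
maternal/paternal through the block-ancestry table before aggregation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats as sps


def filter_snp_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Remove SNPs covered by fewer than ``min_total`` reads (strict: a total
    of exactly ``min_total`` is retained)."""
    total = counts["hap1_count"] + counts["hap2_count"]
    return counts[total >= min_total].reset_index(drop=True)


def rekey_to_parent(counts: pd.DataFrame, ancestry: pd.DataFrame) -> pd.DataFrame:
    """Convert hap1/hap2 counts to maternal/paternal using SNP ancestry.

    SNPs whose ancestry is unknown are dropped (they cannot enter
    parent-of-origin analyses).
    """
    anc = ancestry.set_index("snp_id")["hap1_ancestry"]
    df = counts.copy()
    df["hap1_ancestry"] = df["snp_id"].map(anc)
    df = df[df["hap1_ancestry"].isin(["maternal", "paternal"])]
    mat_is_h1 = df["hap1_ancestry"] == "maternal"
    df["maternal_count"] = np.where(mat_is_h1, df["hap1_count"], df["hap2_count"])
    df["paternal_count"] = np.where(mat_is_h1, df["hap2_count"], df["hap1_count"])
    return df.drop(columns=["hap1_ancestry"]).reset_index(drop=True)


def assign_snps_to_features(snps: pd.DataFrame, features: pd.DataFrame,
                            feature_id_col: str) -> pd.DataFrame:
    """Map SNPs to every overlapping feature interval (multi-overlap SNPs
    count toward each feature). Returns the SNP table with a feature_id
    column added, one row per (SNP, feature) pair."""
    if not len(snps) or not len(features):
        out = snps.iloc[:0].copy()
        out["feature_id"] = pd.Series(dtype=object)
        return out
    q = pr.PyRanges(pd.DataFrame({
        "Chromosome": snps["chrom"], "Start": snps["pos"],
        "End": snps["pos"] + 1, "snp_idx": np.arange(len(snps)),
    }))
    f = pr.PyRanges(pd.DataFrame({
        "Chromosome": features["chrom"], "Start": features["start"],
        "End": features["end"], "feature_id": features[feature_id_col],
    }))
    j = q.join(f).df
    if not len(j):
        out = snps.iloc[:0].copy()
        out["feature_id"] = pd.Series(dtype=object)
        return out
    out = snps.iloc[j["snp_idx"].to_numpy()].reset_index(drop=True)
    out["feature_id"] = j["feature_id"].to_numpy()
    return out


def aggregate_feature(counts: pd.DataFrame, features: pd.DataFrame,
                      feature_id_col: str, min_snps: int = 2,
                      pseudocount: float = 1.0
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate maternal/paternal SNP counts over feature intervals.

    Returns (per-feature table, per-(feature, SNP) table). Features with
    fewer than ``min_snps`` retained SNPs are flagged untestable (zero-SNP
    features appear with n_snps = 0). log2fc = log2((mat + 1)/(pat + 1)).
    """
    assigned = assign_snps_to_features(counts, features, feature_id_col)
    if len(assigned):
        grouped = assigned.groupby("feature_id").agg(
            n_snps=("snp_id", "size"),
            maternal_sum=("maternal_count", "sum"),
            paternal_sum=("paternal_count", "sum"),
        )
    else:
        grouped = pd.DataFrame(columns=["n_snps", "maternal_sum", "paternal_sum"])
    all_ids = features[feature_id_col]
    out = grouped.reindex(all_ids)
    for col in ("n_snps", "maternal_sum", "paternal_sum"):
        out[col] = pd.to_numeric(out[col], errors="coerce").fillna(0).astype(int)
    out = out.reset_index(names="feature_id")
    out["log2fc"] = np.log2((out["maternal_sum"] + pseudocount)
                            / (out["paternal_sum"] + pseudocount))
    out["testable"] = out["n_snps"] >= min_snps
    return out, assigned


def call_diff_methylation(sites: pd.DataFrame, min_coverage: int = 10,
                          min_probability: float = 0.7) -> pd.DataFrame:
    """Per-cytosine differential methylation between haplotypes.

    A one-directional Fisher exact test on the 2x2 table
    (methylated/unmethylated x maternal/paternal), sided toward the observed
    difference, gives p_differential; a site is differential iff its
    combined read coverage >= ``min_coverage`` and the probability of
    differential methylation (1 - p) >= ``min_probability``. Sites with zero
    coverage on either haplotype are skipped.
    """
    df = sites.copy()
    cov_m = df["maternal_meth"] + df["maternal_unmeth"]
    cov_p = df["paternal_meth"] + df["paternal_unmeth"]
    df = df[(cov_m > 0) & (cov_p > 0)].reset_index(drop=True)
    pvals = np.ones(len(df))
    for i, row in enumerate(df.itertuples(index=False)):
        table = [[row.maternal_meth, row.maternal_unmeth],
                 [row.paternal_meth, row.paternal_unmeth]]
        fm = row.maternal_meth / (row.maternal_meth + row.maternal_unmeth)
        fp = row.paternal_meth / (row.paternal_meth + row.paternal_unmeth)
        alt = "greater" if fm >= fp else "less"
        pvals[i] = sps.fisher_exact(table, alternative=alt)[1]
    df["p_differential"] = pvals
    df["coverage"] = (df["maternal_meth"] + df["maternal_unmeth"]
                      + df["paternal_meth"] + df["paternal_unmeth"])
    df["is_differential"] = ((df["coverage"] >= min_coverage)
                             & (1.0 - df["p_differential"] >= min_probability))
    return df
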