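"""Gene x chromatin-factor matrix construction.

Seven data types (ATAC, four histone marks, DNA methylation, WGS coverage)
are quantified over four gene-relative regions — genic (full annotated
span), promoter (the kilobase strictly upstream of the TSS), and upstream /
downstream putative regulatory regions (ACRs within 5 kb of the promoter or
gene end, present only when such an ACR exists) — each as an overall level
and an allelic log2(maternal/paternal) ratio, giving 56 factors, with
promoter-deletion indicators and dN/dS appended.

Missingness rules: an allelic cell is NA when its region holds no phased
SNP, or when the region's SNP-based read total falls below the 10th
percentile for that factor x region (computed over testable genes, after the
coverage filter). Genes whose WGS allelic log-ratio lies beyond 1.5x the
interquartile range are dropped entirely as mapping artifacts. Missing is
encoded as NA, never 0.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import EXTRA_FACTORS, FACTOR_DATATYPES, REGIONS, factor_registry
from .allelic import assign_snps_to_features


class SchemaError(ValueError):
    """Factor registry mismatch."""


def gene_tss(gene: pd.Series) -> int:
    return gene["start"] if gene["strand"] == "+" else gene["end"]


def assign_regions(genes: pd.DataFrame, acrs: pd.DataFrame,
                   chrom_sizes: dict[str, int],
                   promoter_bp: int = 1_000,
                   window_bp: int = 5_000) -> pd.DataFrame:
    """The four gene-relative region intervals per gene.

    Genic and promoter are always defined; upstream_reg / downstream_reg are
    the ACR intervals found within ``window_bp`` of the promoter's far edge
    or the gene end, and are absent when no ACR falls in the window. All
    geometry is mirrored for minus-strand genes and clipped to
    [0, chrom_length). Returns one row per (gene, region[, ACR]) interval.
    """
    acr_by_chrom = {c: s.reset_index(drop=True) for c, s in acrs.groupby("chrom")} \
        if len(acrs) else {}
    rows = []

    def acr_hits(chrom, lo, hi):
        sub = acr_by_chrom.get(chrom)
        if sub is None or lo >= hi:
            return []
        sel = (sub.end > lo) & (sub.start < hi)
        return list(sub[sel][["start", "end"]].itertuples(index=False))

    for g in genes.itertuples(index=False):
        L = chrom_sizes[g.chrom]
        rows.append((g.gene_id, "genic", g.chrom, g.start, g.end))
        if g.strand == "+":
            prom = (max(0, g.start - promoter_bp), g.start)
            up_win = (max(0, prom[0] - window_bp), prom[0])
            dn_win = (g.end, min(L, g.end + window_bp))
        else:
            prom = (g.end, min(L, g.end + promoter_bp))
            up_win = (prom[1], min(L, prom[1] + window_bp))
            dn_win = (max(0, g.start - window_bp), g.start)
        if prom[0] < prom[1]:
            rows.append((g.gene_id, "promoter", g.chrom, prom[0], prom[1]))
        for a in acr_hits(g.chrom, *up_win):
            rows.append((g.gene_id, "upstream_reg", g.chrom, a.start, a.end))
        for a in acr_hits(g.chrom, *dn_win):
            rows.append((g.gene_id, "downstream_reg", g.chrom, a.start, a.end))
    return pd.DataFrame(rows, columns=["gene_id", "region", "chrom", "start", "end"])


def classify_acr(acrs: pd.DataFrame, genes: pd.DataFrame,
                 proximal_bp: int = 2_000) -> pd.Series:
    """Classify ACRs as genic / proximal / distal by nearest-gene distance
    (overlapping; gap <= ``proximal_bp``; further). Distances are gap sizes,
    0 when touching. With no genes at all, everything is distal."""
    if not len(genes):
        return pd.Series("distal", index=acrs.index)
    out = np.full(len(acrs), "distal", dtype=object)
    for chrom, sub in acrs.groupby("chrom"):
        gs = genes[genes.chrom == chrom]
        if not len(gs):
            continue
        gstart = gs.start.to_numpy()
        gend = gs.end.to_numpy()
        for i, row in zip(sub.index, sub.itertuples(index=False)):
            gap = np.maximum.reduce([gstart - row.end, row.start - gend,
                                     np.zeros(len(gs), dtype=int)])
            overlap = (gstart < row.end) & (gend > row.start)
            if overlap.any():
                out[acrs.index.get_loc(i)] = "genic"
            elif gap.min() <= proximal_bp:
                out[acrs.index.get_loc(i)] = "proximal"
    return pd.Series(out, index=acrs.index)


def _region_allelic(regions: pd.DataFrame, parent_counts: pd.DataFrame
                    ) -> pd.DataFrame:
    """Maternal/paternal sums per (gene, region) from re-keyed SNP counts."""
    reg = regions.rename(columns={"gene_id": "gr_id"})
    reg = reg.assign(key=reg["gr_id"] + "||" + reg["region"])
    assigned = assign_snps_to_features(parent_counts, reg, "key")
    if not len(assigned):
        return pd.DataFrame(columns=["gene_id", "region", "n_snps",
                                     "maternal_sum", "paternal_sum"])
    # SNPs in several ACR intervals of the same (gene, region) count once
    assigned = assigned.drop_duplicates(subset=["snp_id", "feature_id"])
    agg = assigned.groupby("feature_id").agg(
        n_snps=("snp_id", "size"),
        maternal_sum=("maternal_count", "sum"),
        paternal_sum=("paternal_count", "sum"),
    ).reset_index()
    parts = agg["feature_id"].str.split(r"\|\|", expand=True)
    agg["gene_id"], agg["region"] = parts[0], parts[1]
    return agg.drop(columns="feature_id")


def build_matrix(
    genes: pd.DataFrame,
    regions: pd.DataFrame,
    parent_counts: dict[str, pd.DataFrame],
    methylation: pd.DataFrame | None,
    region_coverage: pd.DataFrame | None,
    promoter_svs: pd.DataFrame | None = None,
    dnds: pd.DataFrame | None = None,
    percentile: float = 10.0,
    wgs_outlier_iqr: float = 1.5,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the gene x factor matrix.

    ``parent_counts`` maps data type (ATAC, marks, WGS; RNA not included
    here) to maternal/paternal-keyed SNP count tables; ``region_coverage``
    supplies the overall levels for count data types; ``methylation``
    supplies per-cytosine haplotype counts used for both overall (weighted
    mean fraction) and allelic methylation; ``promoter_svs`` has columns
    gene_id, parent for deletions overlapping [TSS - 1 kb, TSS).

    Returns (matrix, registry sidecar dict). Column count is 56 + 3.
    """
    registry = factor_registry()
    index = genes["gene_id"]
    X = pd.DataFrame(np.nan, index=index, columns=registry)

    # overall cells for count-type factors come from the coverage table,
    # restricted to regions the gene actually has (upstream/downstream exist
    # only when an ACR was detected in the window)
    present = set(zip(regions["gene_id"], regions["region"]))
    if region_coverage is not None and len(region_coverage):
        for (dt, region), sub in region_coverage.groupby(["datatype", "region"]):
            col = f"{dt}:{region}:overall"
            if col not in X.columns:
                raise SchemaError(f"unknown factor {dt}:{region} in coverage table")
            s = sub.set_index("gene_id")["value"].reindex(X.index)
            has_region = pd.Series(
                [(g, region) in present for g in X.index], index=X.index)
            X[col] = s.where(has_region)

    # allelic cells from SNP counts per region
    totals = {}
    for dt, counts in parent_counts.items():
        if dt not in FACTOR_DATATYPES:
            raise SchemaError(f"unknown data type {dt!r}")
        agg = _region_allelic(regions, counts)
        for row in agg.itertuples(index=False):
            col = f"{dt}:{row.region}:allelic"
            X.at[row.gene_id, col] = np.log2(
                (row.maternal_sum + pseudocount) / (row.paternal_sum + pseudocount))
            totals[(dt, row.region, row.gene_id)] = row.maternal_sum + row.paternal_sum

    # methylation: overall = coverage-weighted mean fraction; allelic = log2
    # ratio of methylated-read counts
    if methylation is not None and len(methylation):
        msites = methylation.rename(columns={"site_id": "snp_id"})
        msites = msites.assign(
            maternal_count=msites["maternal_meth"],
            paternal_count=msites["paternal_meth"],
            total_cov=(msites["maternal_meth"] + msites["maternal_unmeth"]
                       + msites["paternal_meth"] + msites["paternal_unmeth"]),
            meth_frac=lambda d: (d["maternal_meth"] + d["paternal_meth"])
            / d["total_cov"].clip(lower=1),
        )
        reg = regions.rename(columns={"gene_id": "gr_id"})
        reg = reg.assign(key=reg["gr_id"] + "||" + reg["region"])
        assigned = assign_snps_to_features(msites, reg, "key")
        if len(assigned):
            assigned = assigned.drop_duplicates(subset=["snp_id", "feature_id"])
            for fid, grp in assigned.groupby("feature_id"):
                gene_id, region = fid.split("||")
                w = grp["total_cov"].to_numpy()
                X.at[gene_id, f"methylation:{region}:overall"] = float(
                    np.average(grp["meth_frac"], weights=np.maximum(w, 1)))
                X.at[gene_id, f"methylation:{region}:allelic"] = float(np.log2(
                    (grp["maternal_count"].sum() + pseudocount)
                    / (grp["paternal_count"].sum() + pseudocount)))
                totals[("methylation", region, gene_id)] = int(w.sum())

    # 10th-percentile coverage filter per factor x region (allelic cells),
    # computed over genes that have the cell at all, applied after the
    # upstream coverage filter
    tot_df = pd.Series(totals)
    if len(tot_df):
        for (dt, region), sub in tot_df.groupby(level=[0, 1]):
            cut = np.percentile(sub.to_numpy(), percentile)
            low = sub[sub < cut]
            col = f"{dt}:{region}:allelic"
            for (_, _, gene_id) in low.index:
                X.at[gene_id, col] = np.nan

    # covariates
    X[list(EXTRA_FACTORS[:2])] = 0.0
    if promoter_svs is not None and len(promoter_svs):
        for row in promoter_svs.itertuples(index=False):
            col = ("maternal_promoter_deletion" if row.parent == "maternal"
                   else "paternal_promoter_deletion")
            if row.gene_id in X.index:
                X.at[row.gene_id, col] = 1.0
    if dnds is not None and len(dnds):
        X["dnds"] = dnds.set_index("gene_id")["dnds"].reindex(X.index)

    # WGS mapping-artifact outliers: drop whole genes beyond 1.5x IQR of the
    # genic WGS allelic log-ratio
    wgs_col = "WGS:genic:allelic"
    vals = X[wgs_col].dropna()
    n_dropped = 0
    if len(vals) >= 4:
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - wgs_outlier_iqr * iqr, q3 + wgs_outlier_iqr * iqr
        outliers = vals[(vals < lo) | (vals > hi)].index
        n_dropped = len(outliers)
        X = X.drop(index=outliers)

    if list(X.columns) != registry:
        raise SchemaError("factor registry mismatch after assembly")
    sidecar = {
        "registry": registry,
        "n_chromatin_factors": len(registry) - len(EXTRA_FACTORS),
        "n_genes": int(len(X)),
        "n_wgs_outliers_dropped": int(n_dropped),
        "median_missing_fraction": float(X.isna().mean(axis=1).median()),
    }
    return X, sidecar
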