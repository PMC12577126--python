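"""End-to-end orchestration: simulate -> ancestry -> allelic -> ase ->
features -> model -> link -> enrich, from a single config with fixed seeds.

Each stage reads its inputs from and writes its outputs into one run
directory; every output file is hashed into manifest.json, so a rerun with
identical config and seed reproduces identical hashes. Per-stage random
streams derive from the master seed and a stable hash of the stage name, so
adding a stage never perturbs the others' randomness.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelic, ancestry, ase, cislink, enet, enrich, features, io, simulate
from .config import FACTOR_DATATYPES, RunConfig, SimConfig

STAGES = ("simulate", "ancestry", "allelic", "ase", "features", "model",
          "link", "enrich")

_DEPS = {
    "simulate": (),
    "ancestry": ("simulate",),
    "allelic": ("ancestry",),
    "ase": ("allelic",),
    "features": ("ase",),
    "model": ("features",),
    "link": ("ase",),
    "enrich": ("ase",),
}


class DependencyError(RuntimeError):
    pass


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2^31)."""
    return (master * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(outdir: Path, stage: str, *names: str) -> None:
    for n in names:
        if not (outdir / n).exists():
            raise DependencyError(
                f"stage '{stage}' needs '{n}' from an upstream stage; run the "
                f"dependencies first ({', '.join(_DEPS[stage])})")


def run(stages: list[str] | None, config: RunConfig, outdir) -> dict:
    """Execute pipeline stages in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else list(stages)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; stages: {STAGES}")
    stages = [s for s in STAGES if s in stages]

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    for s in stages:
        _STAGE_FN[s](config, outdir)

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "files": {
            p.name: _hash_file(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    sim = config.simulate or SimConfig()
    sim = dataclasses.replace(sim, seed=stage_seed(config.seed, "simulate"))
    simulate.simulate_study(sim, outdir)


def _stage_ancestry(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "ancestry", "variants.tsv")
    variants = pd.read_csv(outdir / "variants.tsv", sep="\t",
                           keep_default_na=False,
                           dtype={"hap1_parent_call": str})
    anc, blocks = ancestry.assign_ancestry(variants, config.majority_threshold)
    io.write_tsv(anc, outdir / "ancestry.tsv")
    io.write_tsv(blocks, outdir / "blocks.tsv")


def _load_parent_counts(config: RunConfig, outdir: Path, assay: str) -> pd.DataFrame:
    counts = io.validate_counts(outdir / f"counts_{assay}.tsv", assay)
    anc = io.read_tsv(outdir / "ancestry.tsv")
    counts = allelic.filter_snp_counts(counts, config.min_snp_coverage)
    return allelic.rekey_to_parent(counts, anc)


def _stage_allelic(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "allelic", "ancestry.tsv", "genes.gff3", "acrs.bed")
    genes = io.read_genes_gff3(outdir / "genes.gff3")
    acrs = io.read_intervals(outdir / "acrs.bed", "BED").rename(
        columns={"name": "acr_id"})
    frames = []
    snp_frames = []
    gene_feats = genes.rename(columns={"gene_id": "fid"})
    acr_feats = acrs.rename(columns={"acr_id": "fid"})
    feature_sets = {
        "RNA_rep1": [gene_feats], "RNA_rep2": [gene_feats],
        "H3K4me3": [gene_feats], "H3K36me3": [gene_feats],
        "H3K56ac": [gene_feats], "H3K27me3": [gene_feats],
        "ATAC": [acr_feats],
        "WGS": [gene_feats, acr_feats],  # null is fitted on both classes
    }
    for assay, featsets in feature_sets.items():
        pc = _load_parent_counts(config, outdir, assay)
        for feats in featsets:
            agg, assigned = allelic.aggregate_feature(
                pc, feats, "fid", config.min_snps_per_feature)
            agg["assay"] = assay
            frames.append(agg)
            keep = assigned[["feature_id", "snp_id", "maternal_count",
                             "paternal_count"]].copy()
            keep["assay"] = assay
            snp_frames.append(keep)
    io.write_tsv(pd.concat(frames, ignore_index=True),
                 outdir / "feature_allelic.tsv")
    io.write_tsv(pd.concat(snp_frames, ignore_index=True),
                 outdir / "snp_feature_counts.tsv")
    meth = io.read_tsv(outdir / "methylation.tsv")
    calls = allelic.call_diff_methylation(
        meth, config.methyl_min_coverage, config.methyl_min_probability)
    io.write_tsv(calls, outdir / "methyl_calls.tsv")


def _fit_null_for(outdir: Path, config: RunConfig, feature_class: str
                  ) -> ase.BetaBinNull:
    """WGS beta-binomial null restricted to SNPs inside the tested feature
    class (gene spans or ACR peaks)."""
    snp_counts = io.read_tsv(outdir / "snp_feature_counts.tsv")
    wgs = snp_counts[snp_counts["assay"] == "WGS"]
    if feature_class == "gene":
        wgs = wgs[~wgs["feature_id"].str.startswith("acr")]
    else:
        wgs = wgs[wgs["feature_id"].str.startswith("acr")]
    wgs = wgs.drop_duplicates(subset="snp_id")
    return ase.fit_betabin_null(
        wgs["maternal_count"].to_numpy(),
        (wgs["maternal_count"] + wgs["paternal_count"]).to_numpy())


def _stage_ase(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "ase", "snp_feature_counts.tsv")
    snp_counts = io.read_tsv(outdir / "snp_feature_counts.tsv")
    seed = stage_seed(config.seed, "ase")

    null_gene = _fit_null_for(outdir, config, "gene")
    reps = []
    for i, assay in enumerate(("RNA_rep1", "RNA_rep2")):
        sub = snp_counts[snp_counts["assay"] == assay]
        reps.append(ase.ase_scan(sub, null_gene, config.ase_n_sims,
                                 seed + i, config.min_snps_per_feature))
    calls = ase.call_ase(reps, config.ase_alpha)
    io.write_tsv(calls, outdir / "ase_genes.tsv")

    null_acr = _fit_null_for(outdir, config, "acr")
    atac = snp_counts[snp_counts["assay"] == "ATAC"]
    res = ase.ase_scan(atac, null_acr, config.ase_n_sims, seed + 7,
                       config.min_snps_per_feature)
    acr_calls = ase.call_ase([res], config.ase_alpha)
    io.write_tsv(acr_calls, outdir / "as_acrs.tsv")
    with open(outdir / "betabin_null.json", "w") as fh:
        json.dump({
            "gene": dataclasses.asdict(null_gene),
            "acr": dataclasses.asdict(null_acr),
        }, fh, indent=1)


def _stage_features(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "features", "ase_genes.tsv", "region_coverage.tsv")
    genes = io.read_genes_gff3(outdir / "genes.gff3")
    acrs = io.read_intervals(outdir / "acrs.bed", "BED").rename(
        columns={"name": "acr_id"})
    chrom_sizes = dict(
        pd.read_csv(outdir / "chrom.sizes", sep="\t", header=None).itertuples(
            index=False, name=None))
    regions = features.assign_regions(genes, acrs, chrom_sizes,
                                      config.promoter_bp,
                                      config.regulatory_window_bp)
    parent_counts = {}
    for dt in FACTOR_DATATYPES:
        if dt == "methylation":
            continue
        parent_counts[dt] = _load_parent_counts(config, outdir, dt)
    meth = io.read_tsv(outdir / "methylation.tsv")
    coverage = io.read_tsv(outdir / "region_coverage.tsv")
    svs = io.read_intervals(outdir / "svs.bed", "BED").rename(
        columns={"name": "sv_id", "score": "haplotype"})
    svs["haplotype"] = svs["haplotype"].astype(int)
    svs["block_id"] = _locate_blocks(svs, outdir)
    anc = io.read_tsv(outdir / "ancestry.tsv")
    blocks = io.read_tsv(outdir / "blocks.tsv").fillna({"hap1_ancestry": ""})
    svs["parent"] = [
        ancestry.impute_sv_ancestry(row, anc, blocks)
        for _, row in svs.iterrows()
    ]
    io.write_tsv(svs, outdir / "svs_ancestry.tsv")
    promoter_svs = _promoter_deletions(genes, svs, config.promoter_bp)
    dnds = io.read_tsv(outdir / "dnds.tsv")
    X, sidecar = features.build_matrix(
        genes, regions, parent_counts, meth, coverage, promoter_svs, dnds,
        config.factor_percentile_filter, config.wgs_outlier_iqr)
    X.to_csv(outdir / "factor_matrix.tsv", sep="\t", na_rep="NA")
    with open(outdir / "factor_registry.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def _locate_blocks(intervals: pd.DataFrame, outdir: Path) -> list[int]:
    blocks = pd.read_csv(outdir / "blocks_sim.tsv", sep="\t")
    out = []
    for row in intervals.itertuples(index=False):
        mid = (row.start + row.end) // 2
        hit = blocks[(blocks.chrom == row.chrom) & (blocks.start <= mid)
                     & (blocks.end > mid)]
        out.append(int(hit.block_id.iloc[0]) if len(hit) else -1)
    return out


def _promoter_deletions(genes: pd.DataFrame, svs: pd.DataFrame,
                        promoter_bp: int) -> pd.DataFrame:
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            lo, hi = max(0, g.start - promoter_bp), g.start
        else:
            lo, hi = g.end, g.end + promoter_bp
        hit = svs[(svs.chrom == g.chrom) & (svs.start < hi) & (svs.end > lo)
                  & svs.parent.isin(["maternal", "paternal"])]
        for p in hit["parent"]:
            rows.append((g.gene_id, p))
    return pd.DataFrame(rows, columns=["gene_id", "parent"])


def _stage_model(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "model", "factor_matrix.tsv", "expression.tsv")
    X = pd.read_csv(outdir / "factor_matrix.tsv", sep="\t", index_col=0,
                    na_values=["NA"])
    seed = stage_seed(config.seed, "model")
    expr = io.read_tsv(outdir / "expression.tsv").set_index("gene_id")["log2_tpm"]
    responses = {"overall": expr}
    ase_tab = io.read_tsv(outdir / "ase_genes.tsv").set_index("feature_id")
    responses["allelic"] = ase_tab["log2fc"].reindex(X.index)
    for name, y in responses.items():
        y = y.reindex(X.index).dropna()
        Xy = X.loc[y.index]
        try:
            fit = enet.fit_cv(Xy, y, config.enet_folds, seed)
        except ValueError as exc:
            with open(outdir / f"enet_{name}.skip", "w") as fh:
                fh.write(str(exc))
            continue
        reduced = enet.reduce_1se(fit, Xy, y)
        tab = enet.report(reduced)
        tab["r_insample"] = reduced.r_insample
        tab["r_cv"] = fit.r_cv
        io.write_tsv(tab, outdir / f"enet_{name}.tsv")
        io.write_tsv(fit.cv_curve, outdir / f"cvcurve_{name}.tsv")


def _stage_link(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "link", "ase_genes.tsv", "as_acrs.tsv", "svs_ancestry.tsv")
    seed = stage_seed(config.seed, "link")
    genes = io.read_genes_gff3(outdir / "genes.gff3")
    genes["block_id"] = _locate_blocks(genes, outdir)
    ase_tab = io.read_tsv(outdir / "ase_genes.tsv")
    rna = io.read_tsv(outdir / "feature_allelic.tsv")
    rna = rna[rna["assay"] == "RNA_rep1"].set_index("feature_id")
    sig = ase_tab[ase_tab["significant"]]
    ase_genes = genes[genes.gene_id.isin(sig["feature_id"])].copy()
    ase_genes["maternal_sum"] = rna["maternal_sum"].reindex(ase_genes.gene_id).to_numpy()
    ase_genes["paternal_sum"] = rna["paternal_sum"].reindex(ase_genes.gene_id).to_numpy()
    ase_genes["log2fc_rna"] = sig.set_index("feature_id")["log2fc"].reindex(
        ase_genes.gene_id).to_numpy()
    svs = io.read_tsv(outdir / "svs_ancestry.tsv")
    pairs = cislink.pair_deletion_gene(ase_genes.reset_index(drop=True), svs,
                                       config.promoter_bp)
    io.write_tsv(pairs, outdir / "deletion_pairs.tsv")
    stats = {}
    if len(pairs) and pairs["sv_in_promoter"].sum() >= 2 and \
            (~pairs["sv_in_promoter"]).sum() >= 2:
        link = cislink.promoter_deletion_effect(pairs, config.n_perm, seed)
        stats["promoter_deletion"] = {
            "hedges_g": link.g_promoter, "p": link.p_promoter,
            "n_promoter": int(pairs["sv_in_promoter"].sum()),
            "n_other": int((~pairs["sv_in_promoter"]).sum()),
        }
    acr_tab = io.read_tsv(outdir / "as_acrs.tsv")
    acr_sig = acr_tab[acr_tab["significant"]]
    acr_int = io.read_intervals(outdir / "acrs.bed", "BED").rename(
        columns={"name": "acr_id"})
    as_acrs = acr_int[acr_int.acr_id.isin(acr_sig["feature_id"])].copy()
    as_acrs["block_id"] = _locate_blocks(as_acrs, outdir)
    as_acrs["log2fc_atac"] = acr_sig.set_index("feature_id")["log2fc"].reindex(
        as_acrs.acr_id).to_numpy()
    acr_pairs, corr = cislink.pair_acr_gene(
        as_acrs.reset_index(drop=True), ase_genes.reset_index(drop=True),
        genes, config.link_max_separation_bp)
    io.write_tsv(acr_pairs, outdir / "acr_gene_pairs.tsv")
    stats["acr_gene_correlation"] = corr
    with open(outdir / "link_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1)


def _stage_enrich(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "enrich", "as_acrs.tsv", "ase_genes.tsv")
    seed = stage_seed(config.seed, "enrich")
    acrs = io.read_intervals(outdir / "acrs.bed", "BED").rename(
        columns={"name": "acr_id"})
    tes = io.read_intervals(outdir / "tes.bed", "BED").rename(
        columns={"name": "te_class"})
    genes = io.read_genes_gff3(outdir / "genes.gff3")
    svs = io.read_intervals(outdir / "svs.bed", "BED")

    acr_tab = io.read_tsv(outdir / "as_acrs.tsv")
    as_ids = set(acr_tab.loc[acr_tab["significant"], "feature_id"])
    query = acrs[acrs.acr_id.isin(as_ids)]
    res_te = enrich.te_enrichment(query, acrs, tes, config.n_perm, seed)

    ase_tab = io.read_tsv(outdir / "ase_genes.tsv")
    promoters = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            promoters.append((g.gene_id, g.chrom, max(0, g.start - config.promoter_bp),
                              g.start))
        else:
            promoters.append((g.gene_id, g.chrom, g.end, g.end + config.promoter_bp))
    prom = pd.DataFrame(promoters, columns=["gene_id", "chrom", "start", "end"])
    tested = prom[prom.gene_id.isin(ase_tab["feature_id"])]
    sig_ids = set(ase_tab.loc[ase_tab["significant"], "feature_id"])
    res_sv = enrich.sv_promoter_enrichment(
        tested[tested.gene_id.isin(sig_ids)], tested, svs,
        config.n_perm, seed + 1)

    gwas = io.read_tsv(outdir / "gwas.tsv")
    res_gwas = enrich.trait_snp_acr_enrichment(
        gwas, acrs, genes, config.n_perm, seed + 2)

    for name, res in (("te", res_te), ("sv_promoter", res_sv),
                      ("gwas_acr", res_gwas)):
        with open(outdir / f"enrichment_{name}.json", "w") as fh:
            json.dump(res.to_dict(), fh)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "ancestry": _stage_ancestry,
    "allelic": _stage_allelic,
    "ase": _stage_ase,
    "features": _stage_features,
    "model": _stage_model,
    "link": _stage_link,
    "enrich": _stage_enrich,
}
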