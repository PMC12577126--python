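import filecmp
import json

import numpy as np
import pandas as pd
import pytest
from scipy import special

from haplocis import simulate
from haplocis.config import ConfigError, SimConfig

from conftest import small_sim


def test_fixed_seed_reproduces_byte_identical_files(tmp_path):
    cfg = small_sim(seed=3)
    simulate.simulate_study(cfg, tmp_path / "a")
    simulate.simulate_study(cfg, tmp_path / "b")
    names = [p.name for p in (tmp_path / "a").iterdir()]
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "a", tmp_path / "b", names, shallow=False)
    assert not mismatch and not errors
    assert len(match) == len(names)


def test_zero_genes_is_a_valid_empty_bundle():
    cfg = small_sim(n_genes=0, n_acrs=10)
    genome = simulate.simulate_genome(cfg)
    assert len(genome.genes) == 0
    assert len(genome.acrs) == 10


def test_chromosome_too_short_raises_sizing_error():
    cfg = small_sim(chrom_length=30_000, n_genes=60)
    with pytest.raises(simulate.SizingError, match="too short"):
        simulate.simulate_genome(cfg)


def test_genes_do_not_overlap(sim_config):
    genome = simulate.simulate_genome(sim_config)
    for _, sub in genome.genes.groupby("chrom"):
        sub = sub.sort_values("start")
        assert (sub.start.to_numpy()[1:] >= sub.end.to_numpy()[:-1]).all()


def test_sv_lengths_match_target_mean():
    # deletion lengths: log-normal with mean 332 bp at the study's SV count
    cfg = small_sim(n_svs=2_481, chrom_length=2_000_000)
    genome = simulate.simulate_genome(cfg)
    lengths = genome.svs.end - genome.svs.start
    assert abs(lengths.mean() - 332) / 332 < 0.10
    assert lengths.min() >= 41 and lengths.max() <= 11_084


def test_switch_error_rate_zero_gives_no_flips():
    cfg = small_sim(switch_error_rate=0.0)
    genome = simulate.simulate_genome(cfg)
    _, _, truth = simulate.simulate_phased_variants(genome, cfg)
    assert truth.snp_hap1_intended == truth.snp_hap1_actual


def test_switch_error_rate_half_rejected():
    with pytest.raises(ConfigError, match="switch_error_rate"):
        small_sim(switch_error_rate=0.5).validate()


def test_recombinant_blocks_change_ancestry_once():
    cfg = small_sim(recombinant_fraction=0.5, switch_error_rate=0.0, seed=2)
    genome = simulate.simulate_genome(cfg)
    variants, _, truth = simulate.simulate_phased_variants(genome, cfg)
    rec = [b for b, c in truth.block_class.items() if c == "recombinant"]
    assert rec, "no recombinant blocks generated"
    for b in rec:
        sub = variants[variants.block_id == b].sort_values("pos")
        labels = np.array([truth.snp_hap1_intended[s] for s in sub.snp_id])
        changes = int(np.sum(labels[1:] != labels[:-1]))
        assert changes == 1


def test_maternal_fraction_follows_true_effect():
    # one strong ASE gene: log2FC 2 at pi_ref 0.5 means E[maternal frac] = 0.8
    cfg = small_sim(ase_fraction=1.0, ase_log2fc_range=(2.0, 2.0),
                    rho=0.05, depth_mean=100.0, n_genes=40,
                    promoter_deletion_effect=0.0, seed=4)
    genome = simulate.simulate_genome(cfg)
    variants, _, truth = simulate.simulate_phased_variants(genome, cfg)
    counts, _, _ = simulate.simulate_allelic_counts(variants, genome, truth, cfg)
    rna = counts["RNA_rep1"]
    hap1_mat = np.array([truth.snp_hap1_actual[s] == "maternal"
                         for s in rna.snp_id])
    mat = np.where(hap1_mat, rna.hap1_count, rna.hap2_count)
    tot = (rna.hap1_count + rna.hap2_count).to_numpy()
    genic = np.zeros(len(rna), dtype=bool)
    for g in genome.genes.itertuples(index=False):
        genic |= ((rna.chrom == g.chrom) & (rna.pos >= g.start)
                  & (rna.pos < g.end)).to_numpy()
    up = np.array([truth.gene_log2fc[g] > 0 for g in genome.genes.gene_id])
    # pool SNPs of maternally-biased genes; expectation of the mixture is 0.8
    frac = mat[genic & (tot > 0)].sum() / tot[genic & (tot > 0)].sum()
    signed = []
    for g in genome.genes.itertuples(index=False):
        sel = ((rna.chrom == g.chrom) & (rna.pos >= g.start)
               & (rna.pos < g.end)).to_numpy() & (tot > 0)
        if sel.sum() == 0:
            continue
        f = mat[sel].sum() / tot[sel].sum()
        signed.append(f if truth.gene_log2fc[g.gene_id] > 0 else 1 - f)
    assert abs(np.mean(signed) - 0.8) < 0.03


def test_wgs_has_no_true_signal_and_matches_rho(sim_config):
    cfg = small_sim(chrom_length=1_500_000, snp_density=6.0, rho=0.15, seed=9)
    genome = simulate.simulate_genome(cfg)
    variants, _, truth = simulate.simulate_phased_variants(genome, cfg)
    counts, _, _ = simulate.simulate_allelic_counts(variants, genome, truth, cfg)
    wgs = counts["WGS"]
    hap1_mat = np.array([truth.snp_hap1_actual[s] == "maternal"
                         for s in wgs.snp_id])
    mat = np.where(hap1_mat, wgs.hap1_count, wgs.hap2_count)
    tot = (wgs.hap1_count + wgs.hap2_count).to_numpy()
    keep = tot >= 10
    assert keep.sum() > 10_000
    from haplocis.stats import betabin_mom
    pi, rho = betabin_mom(mat[keep], tot[keep])
    assert abs(pi - cfg.pi_ref) < 0.01
    assert abs(rho - cfg.rho) / cfg.rho < 0.10


def test_methylation_covers_both_sides_of_coverage_filter(study_dir):
    out, _, _ = study_dir
    meth = pd.read_csv(out / "methylation.tsv", sep="\t")
    cov = (meth.maternal_meth + meth.maternal_unmeth
           + meth.paternal_meth + meth.paternal_unmeth)
    assert (cov < 10).any() and (cov >= 10).any()


def test_gwas_bonferroni_split_and_maf_floor(study_dir):
    out, cfg, truth = study_dir
    gwas = pd.read_csv(out / "gwas.tsv", sep="\t")
    thr = 0.05 / len(gwas)
    assert (gwas.p < thr).sum() == cfg.n_gwas_significant
    assert set(gwas.loc[gwas.p < thr, "snp_id"]) == set(truth.trait_snps)
    assert gwas.maf.min() >= 0.03


def test_truth_never_leaks_into_analysis_files(study_dir):
    out, _, _ = study_dir
    truth_cols = {"gene_log2fc", "true_fc", "snp_hap1_actual", "sv_parent",
                  "significant_truth", "is_diff"}
    for name in ("counts_WGS.tsv", "gwas.tsv", "methylation.tsv",
                 "variants.tsv", "expression.tsv"):
        header = open(out / name).readline().strip().split("\t")
        assert not truth_cols & set(header), name


def test_factor_matrix_simulation_has_declared_support():
    from haplocis.config import factor_registry
    df, beta, sd = simulate.simulate_factor_matrix(
        200, factor_registry(), n_true=5, snr=2.0, seed=1)
    assert (beta != 0).sum() == 5
    assert df.shape == (200, 60)  # 59 factors + response
    signal_var = np.var(df[factor_registry()].to_numpy() @ beta)
    assert signal_var / sd**2 == pytest.approx(2.0, rel=0.3)
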