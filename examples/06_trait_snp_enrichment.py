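"""Enrichment of trait-associated SNPs in accessible chromatin.

Significant GWAS SNPs (Bonferroni) are compared to background SNPs matched
on minor allele frequency and distance to the nearest gene; the permutation
null resamples matched backgrounds, and fold is the ratio of in-ACR
fractions. The simulation injects a 3-fold enrichment.
"""
from haplocis import enrich, simulate
from haplocis.config import SimConfig

cfg = SimConfig(seed=2, trait_snp_acr_fold=3.0,
                n_gwas_snps=6000, n_gwas_significant=500)
genome = simulate.simulate_genome(cfg)
gwas, _ = simulate.simulate_gwas(genome, simulate.GroundTruth(), cfg)

res = enrich.trait_snp_acr_enrichment(gwas, genome.acrs, genome.genes,
                                      n_perm=1000, seed=2)
print(f"significant SNPs: {res.n_query} "
      f"(Bonferroni 0.05/{len(gwas)})")
print(f"fraction in ACRs: observed {res.observed:.3f}, "
      f"matched-background mean {res.null.mean():.3f}")
print(f"fold enrichment = {res.fold:.2f} (injected 3.0), "
      f"permutation p = {res.p:.4f}")
# fold near the injected value shows the matched-background resampling is
# calibrated; p uses the +1/+1 estimator and is one-sided for enrichment.
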