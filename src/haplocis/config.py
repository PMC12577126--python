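"""Configuration objects for simulation and pipeline runs.

All coordinates are 0-based half-open internally; files follow their own
standards (GFF3 1-based closed, BED 0-based half-open, VCF 1-based).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

ASSAYS = (
    "RNA_rep1",
    "RNA_rep2",
    "ATAC",
    "H3K4me3",
    "H3K36me3",
    "H3K56ac",
    "H3K27me3",
    "WGS",
)

#: chromatin data types entering the gene x factor matrix
FACTOR_DATATYPES = (
    "ATAC",
    "H3K4me3",
    "H3K36me3",
    "H3K56ac",
    "H3K27me3",
    "methylation",
    "WGS",
)

REGIONS = ("genic", "promoter", "upstream_reg", "downstream_reg")

#: appended covariates of the factor matrix (promoter SV indicators, dN/dS)
EXTRA_FACTORS = ("maternal_promoter_deletion", "paternal_promoter_deletion", "dnds")


def factor_registry(include_extra: bool = True) -> list[str]:
    """The 56-column chromatin factor registry (+3 covariates).

    7 data types x 4 gene-relative regions x {overall, allelic} = 56, with
    promoter-deletion indicators and dN/dS appended.
    """
    cols = [
        f"{dt}:{region}:{kind}"
        for dt in FACTOR_DATATYPES
        for region in REGIONS
        for kind in ("overall", "allelic")
    ]
    if include_extra:
        cols += list(EXTRA_FACTORS)
    return cols


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study generator.

    The defaults describe a desk-scale hybrid genome with the statistical
    structure the downstream analyses assume: phase blocks with parental
    ancestry and switch errors, beta-binomially overdispersed allelic counts
    with optional reference-mapping bias, chromatin factors linearly coupled
    to expression, TE-enriched deletions and trait SNPs enriched in open
    chromatin.
    """

    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 300
    n_acrs: int = 400
    n_phase_blocks: int = 45
    snp_density: float = 4.0          # SNPs per kb (heterozygous-hybrid scale)
    rho: float = 0.1                  # beta-binomial overdispersion, [0, 1)
    pi_ref: float = 0.5               # expected REF fraction with no ASE (mapping bias)
    ase_fraction: float = 0.3         # fraction of genes with true allelic imbalance
    ase_log2fc_range: tuple[float, float] = (0.5, 2.0)
    coupling_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "ATAC:genic": 0.5,
            "H3K4me3:genic": 0.4,
            "H3K36me3:genic": 0.4,
            "H3K56ac:genic": 0.3,
            "H3K27me3:genic": -0.5,
            "methylation:promoter": -0.3,
        }
    )
    te_enrichment_sv: float = 2.0     # relative odds an SV overlaps a TE
    trait_snp_acr_fold: float = 2.0   # true fold-enrichment of trait SNPs in ACRs
    switch_error_rate: float = 0.03   # per-SNP phase-toggle probability
    seed: int = 0

    # secondary knobs (free parameters of the emulation, see docs/methods.md)
    depth_mean: float = 60.0          # negative-binomial mean read depth per SNP
    depth_dispersion: float = 0.3     # NB dispersion: var = m + d*m^2
    informative_fraction: float = 0.10
    recombinant_fraction: float = 0.08
    unclassified_fraction: float = 0.10
    n_svs: int = 500
    sv_length_mean: float = 332.0     # bp, log-normal
    sv_length_sigma: float = 1.0
    te_fraction: float = 0.30         # genome fraction tiled by TEs
    acr_gene_coupling: float = 0.8    # allelic log2FC of an ACR near an ASE gene,
                                      # as a multiple of the gene's log2FC
    promoter_deletion_effect: float = 0.5  # log2 boost of the deletion-carrying allele
    n_methyl_sites: int = 20_000
    methyl_diff_rate: float = 0.05
    methyl_diff_gap: float = 0.5      # methylation-fraction gap at differential sites
    methyl_depth_mean: float = 15.0
    n_gwas_snps: int = 4000
    n_gwas_significant: int = 200
    n_accessions: int = 154
    expression_noise_sd: float = 0.5

    def validate(self) -> "SimConfig":
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_phase_blocks": self.n_phase_blocks,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be > 0, got {value}")
        for name in ("n_genes", "n_acrs", "n_svs", "n_gwas_snps"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError(f"rho must lie in [0, 1), got {self.rho}")
        if not 0.0 < self.pi_ref < 1.0:
            raise ConfigError(f"pi_ref must lie in (0, 1), got {self.pi_ref}")
        if self.trait_snp_acr_fold < 0:
            raise ConfigError("trait_snp_acr_fold must be >= 0")
        if not 0.0 <= self.switch_error_rate < 0.5:
            raise ConfigError(
                "switch_error_rate must lie in [0, 0.5): at 0.5 or above the "
                "haplotype labels carry no information"
            )
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "ase_log2fc_range" in d:
            d["ase_log2fc_range"] = tuple(d["ase_log2fc_range"])
        return cls(**d).validate()


@dataclass
class RunConfig:
    """Thresholds and knobs of the analysis pipeline.

    Every threshold default is the one used in the source study; all are
    overridable and the config is serialized into each run directory.
    """

    ase_alpha: float = 0.05
    min_snp_coverage: int = 10
    min_snps_per_feature: int = 2
    promoter_bp: int = 1_000
    proximal_bp: int = 2_000
    regulatory_window_bp: int = 5_000
    link_max_separation_bp: int = 5_000
    methyl_min_coverage: int = 10
    methyl_min_probability: float = 0.7
    wgs_outlier_iqr: float = 1.5
    factor_percentile_filter: float = 10.0
    ld_r2_threshold: float = 0.8
    ld_window_bp: int = 1_000_000
    sv_het_af: tuple[float, float] = (0.25, 0.75)
    sv_hom_af: float = 0.95
    n_perm: int = 1_000
    ase_n_sims: int = 10_000
    enet_folds: int = 5
    majority_threshold: float = 0.75
    seed: int = 0
    simulate: SimConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = SimConfig.from_dict(d["simulate"])
        if "sv_het_af" in d:
            d["sv_het_af"] = tuple(d["sv_het_af"])
        return cls(**d)
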