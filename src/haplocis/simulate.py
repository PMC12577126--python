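"""Synthetic study generator.

Produces a complete desk-scale study — interval annotations, phased variants
with parental-ancestry truth, beta-binomially overdispersed allelic count
tables for every assay, per-cytosine methylation counts, and GWAS summaries —
with the statistical structure the downstream analyses assume. Ground truth
is emitted alongside the data (truth bundle / truth.json), never mixed into
the analysis inputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from . import io
from .config import ASSAYS, FACTOR_DATATYPES, REGIONS, ConfigError, SimConfig
from .stats import rbetabin

TE_CLASSES = [
    "DNA/hAT", "DNA/MULE-MuDR", "DNA/CACTA",
    "LTR/Gypsy", "LTR/Copia", "LINE/L1",
]

LN2 = float(np.log(2.0))


class SizingError(ConfigError):
    """A chromosome is too short for the requested feature count."""


@dataclass
class GenomeBundle:
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame        # gene_id, chrom, start, end, strand
    acrs: pd.DataFrame         # acr_id, chrom, start, end
    tes: pd.DataFrame          # te_id, chrom, start, end, te_class
    svs: pd.DataFrame          # sv_id, chrom, start, end, haplotype (1|2)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must rediscover."""

    gene_log2fc: dict[str, float] = field(default_factory=dict)
    acr_log2fc: dict[str, float] = field(default_factory=dict)
    snp_hap1_intended: dict[str, str] = field(default_factory=dict)
    snp_hap1_actual: dict[str, str] = field(default_factory=dict)
    block_class: dict[int, str] = field(default_factory=dict)
    sv_parent: dict[str, str] = field(default_factory=dict)
    coupling_coefficients: dict[str, float] = field(default_factory=dict)
    trait_snps: list[str] = field(default_factory=list)
    methyl_diff_sites: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "gene_log2fc": self.gene_log2fc,
                "acr_log2fc": self.acr_log2fc,
                "snp_hap1_intended": self.snp_hap1_intended,
                "snp_hap1_actual": self.snp_hap1_actual,
                "block_class": {str(k): v for k, v in self.block_class.items()},
                "sv_parent": self.sv_parent,
                "coupling_coefficients": self.coupling_coefficients,
                "trait_snps": self.trait_snps,
                "methyl_diff_sites": self.methyl_diff_sites,
            }, fh)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    import zlib
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed,
                               spawn_key=(zlib.crc32(stream.encode()),))
    )


def _nbinom(rng, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative-binomial with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> GenomeBundle:
    """Lay out genes, ACRs, TEs and deletion SVs on the simulated chromosomes.

    Genes are non-nested on each strand; ACRs are placed so genic, proximal
    and distal classes all occur; SV lengths follow a log-normal with the
    configured mean; TEs tile roughly ``te_fraction`` of the genome; SVs
    overlap TEs with relative odds ``te_enrichment_sv``.
    """
    config.validate()
    rng = _rng(config, "genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sizes = {c: config.chrom_length for c in chroms}

    # genes: evenly allotted slots with jittered placement, never overlapping
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    slot_min = 6_000  # room for a gene plus regulatory windows
    gene_rows = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        slot = config.chrom_length // n
        if slot < slot_min:
            raise SizingError(
                f"{chrom} ({config.chrom_length} bp) too short for {n} genes: "
                f"needs >= {slot_min} bp per gene slot, has {slot}"
            )
        for j in range(n):
            length = int(rng.integers(1_000, 4_001))
            lo, hi = j * slot + 1_000, (j + 1) * slot - length - 1_000
            start = int(rng.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"gene{gid:05d}", chrom, start, start + length, strand))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    # ACRs: mixture of genic / proximal / distal placements
    acr_rows = []
    for k in range(config.n_acrs):
        length = int(rng.integers(500, 2_001))
        mode = rng.choice(["genic", "proximal", "distal"], p=[0.4, 0.3, 0.3])
        if len(genes) and mode in ("genic", "proximal"):
            g = genes.iloc[int(rng.integers(len(genes)))]
            if mode == "genic":
                start = int(rng.integers(g.start, max(g.start + 1, g.end - length)))
            else:
                off = int(rng.integers(1, 2_000))  # edge gap within proximal range
                start = (g.start - off - length) if rng.random() < 0.5 else (g.end + off)
            chrom = g.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - length))
        start = int(np.clip(start, 0, config.chrom_length - length))
        acr_rows.append((f"acr{k:05d}", chrom, start, start + length))
    acrs = pd.DataFrame(acr_rows, columns=["acr_id", "chrom", "start", "end"])

    # TEs: alternate TE / gap so that TEs tile ~te_fraction of each chromosome
    te_rows = []
    tid = 0
    f = config.te_fraction
    if f > 0:
        mean_te = 2_000.0
        mean_gap = mean_te * (1.0 - f) / f
        for chrom in chroms:
            pos = int(rng.exponential(mean_gap))
            while pos < config.chrom_length - 100:
                length = int(np.clip(rng.exponential(mean_te), 100, 10_000))
                end = min(pos + length, config.chrom_length)
                te_rows.append((f"te{tid:06d}", chrom, pos, end,
                                TE_CLASSES[int(rng.integers(len(TE_CLASSES)))]))
                tid += 1
                pos = end + int(rng.exponential(mean_gap)) + 1
    tes = pd.DataFrame(te_rows, columns=["te_id", "chrom", "start", "end", "te_class"])

    # SVs (deletions): log-normal lengths, TE-enriched placement by rejection
    mu = np.log(config.sv_length_mean) - 0.5 * config.sv_length_sigma ** 2
    lengths = np.clip(
        rng.lognormal(mu, config.sv_length_sigma, config.n_svs), 41, 11_084
    ).astype(int)
    te_lookup = {
        c: np.sort(tes.loc[tes.chrom == c, ["start", "end"]].to_numpy(), axis=0)
        for c in chroms
    }
    sv_rows = []
    w = max(config.te_enrichment_sv, 1e-9)
    for k, length in enumerate(lengths):
        while True:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - int(length)))
            arr = te_lookup[chrom]
            in_te = False
            if len(arr):
                j = np.searchsorted(arr[:, 0], start, side="right") - 1
                in_te = j >= 0 and start < arr[j, 1]
            accept = w if in_te else 1.0
            if rng.random() * max(w, 1.0) < accept:
                break
        sv_rows.append((f"sv{k:05d}", chrom, start, start + int(length)))
    svs = pd.DataFrame(sv_rows, columns=["sv_id", "chrom", "start", "end"])
    # the haplotype carrying each deletion is assigned with the phase blocks
    svs["haplotype"] = 0

    return GenomeBundle(sizes, genes, acrs, tes, svs)


# ---------------------------------------------------------------------------
# phased variants with ancestry truth
# ---------------------------------------------------------------------------

def simulate_phased_variants(
    genome: GenomeBundle, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Drop phased heterozygous SNPs into phase blocks with ancestry truth.

    Each block's haplotype 1 descends from one parent (recombinant blocks
    change parent once along the block). Phasing switch errors are isolated
    single-SNP flips — the dominant error mode of read-backed phasing — with
    each SNP's haplotype labels swapped independently with probability
    ``switch_error_rate``, so the per-SNP discordance count against truth is
    exactly binomial at that rate. A configurable subset of SNPs is
    ancestry-informative (parents homozygous for alternate alleles);
    unclassified blocks carry none. Deletion SVs are assigned the haplotype
    matching a randomly drawn parent of origin.
    """
    config.validate()
    rng = _rng(config, "variants")
    truth = GroundTruth()
    chroms = list(genome.chrom_sizes)

    # contiguous blocks: allot to chromosomes round-robin, random breakpoints
    per_chrom = np.full(len(chroms), config.n_phase_blocks // len(chroms))
    per_chrom[: config.n_phase_blocks % len(chroms)] += 1
    nt = "ACGT"
    var_rows = []
    block_rows = []
    block_id = 0
    for ci, chrom in enumerate(chroms):
        L = genome.chrom_sizes[chrom]
        nblocks = int(per_chrom[ci])
        if nblocks == 0:
            continue
        cuts = np.sort(rng.choice(np.arange(1, L), size=nblocks - 1, replace=False)) \
            if nblocks > 1 else np.array([], dtype=int)
        bounds = np.concatenate([[0], cuts, [L]])
        n_snps = rng.poisson(L / 1_000.0 * config.snp_density)
        pos = np.sort(rng.choice(L, size=min(n_snps, L), replace=False))
        for b in range(nblocks):
            lo, hi = int(bounds[b]), int(bounds[b + 1])
            bpos = pos[(pos >= lo) & (pos < hi)]
            m = len(bpos)
            u = rng.random()
            if u < config.unclassified_fraction or m == 0:
                bclass = "unclassified"
            elif u < config.unclassified_fraction + config.recombinant_fraction and m >= 4:
                bclass = "recombinant"
            else:
                bclass = "non_recombinant"
            parent0 = "maternal" if rng.random() < 0.5 else "paternal"
            other = "paternal" if parent0 == "maternal" else "maternal"
            intended = np.array([parent0] * m, dtype=object)
            if bclass == "recombinant" and m >= 4:
                cut = int(rng.integers(2, m - 1))
                intended[cut:] = other
            # isolated per-SNP phase flips at the configured rate
            state = rng.random(m) < config.switch_error_rate
            actual = intended.copy()
            flip = {"maternal": "paternal", "paternal": "maternal"}
            actual[state] = [flip[a] for a in intended[state]]
            informative = (
                np.zeros(m, dtype=bool)
                if bclass == "unclassified"
                else rng.random(m) < config.informative_fraction
            )
            truth.block_class[block_id] = bclass
            for j in range(m):
                ref, alt = rng.choice(4, size=2, replace=False)
                hap1_is_ref = rng.random() < 0.5
                snp_id = f"{chrom}_{int(bpos[j])}"
                var_rows.append((
                    snp_id, chrom, int(bpos[j]), nt[ref], nt[alt],
                    nt[ref] if hap1_is_ref else nt[alt],
                    nt[alt] if hap1_is_ref else nt[ref],
                    block_id, bool(informative[j]),
                    actual[j] if informative[j] else "",
                ))
                truth.snp_hap1_intended[snp_id] = str(intended[j])
                truth.snp_hap1_actual[snp_id] = str(actual[j])
            block_rows.append((block_id, chrom, lo, hi, m))
            block_id += 1

    variants = pd.DataFrame(var_rows, columns=io.VARIANT_COLUMNS)
    blocks = pd.DataFrame(block_rows,
                          columns=["block_id", "chrom", "start", "end", "n_snps"])

    # assign each deletion SV a parent of origin and the matching haplotype
    # label in its phase block (via the intended hap1 ancestry of the
    # nearest SNP)
    haps = np.zeros(len(genome.svs), dtype=int)
    for i, sv in enumerate(genome.svs.itertuples(index=False)):
        parent = "maternal" if rng.random() < 0.5 else "paternal"
        vc = variants[variants.chrom == sv.chrom]
        hap = 0
        if len(vc):
            mid = (sv.start + sv.end) // 2
            j = int(np.argmin(np.abs(vc.pos.to_numpy() - mid)))
            hap1_parent = truth.snp_hap1_intended[vc.snp_id.iloc[j]]
            hap = 1 if hap1_parent == parent else 2
        haps[i] = hap
        truth.sv_parent[sv.sv_id] = parent
    genome.svs["haplotype"] = haps
    return variants, blocks, truth


# ---------------------------------------------------------------------------
# allelic counts for all assays
# ---------------------------------------------------------------------------

def _snp_feature_map(variants: pd.DataFrame, feats: pd.DataFrame,
                     id_col: str) -> dict[str, np.ndarray]:
    """For each feature, the integer indices of variants inside its span."""
    out = {}
    for chrom, sub in feats.groupby("chrom"):
        vc = variants[variants.chrom == chrom]
        pos = vc.pos.to_numpy()
        idx = vc.index.to_numpy()
        for row in sub.itertuples(index=False):
            sel = (pos >= row.start) & (pos < row.end)
            out[getattr(row, id_col)] = idx[sel]
    return out


def simulate_allelic_counts(
    variants: pd.DataFrame,
    genome: GenomeBundle,
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Draw per-SNP allelic counts for every assay, plus latent region
    coverage and the coupled gene-expression table.

    Per SNP, total depth ~ NegBin(depth_mean, depth_dispersion) and the
    maternal count ~ BetaBin(depth, pi, rho) with
    logit(pi) = logit(pi_ref) + ln2 * log2FC for SNPs inside features with a
    true allelic effect. WGS always uses pi = pi_ref (no true signal; it is
    the mapping-bias calibration track). Counts are written as hap1/hap2
    using each SNP's *actual* (switch-error-bearing) haplotype ancestry, as
    an aligner would observe them.

    Gene-level log2 expression satisfies
    ``log2TPM = intercept + sum(coef * factor) + N(0, sd)`` over the latent
    standardized region factors, which are also emitted as the overall
    region-coverage table.
    """
    if not 0.0 <= config.rho < 1.0:
        raise ConfigError(f"rho must lie in [0, 1), got {config.rho}")
    rng = _rng(config, "counts")
    genes, acrs = genome.genes, genome.acrs

    # true ASE genes
    n_ase = int(round(config.ase_fraction * len(genes)))
    ase_idx = rng.choice(len(genes), size=n_ase, replace=False) if n_ase else []
    lo, hi = config.ase_log2fc_range
    for i, gi in enumerate(ase_idx):
        mag = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.gene_log2fc[genes.gene_id.iloc[int(gi)]] = float(sign * mag)
    for g in genes.gene_id:
        truth.gene_log2fc.setdefault(g, 0.0)

    # promoter deletions boost the deletion-carrying allele's expression
    eff = config.promoter_deletion_effect
    if eff != 0.0 and len(genome.svs):
        svs = genome.svs
        for g in genes.itertuples(index=False):
            if g.strand == "+":
                lo, hi = max(0, g.start - 1_000), g.start
            else:
                lo, hi = g.end, g.end + 1_000
            hits = svs[(svs.chrom == g.chrom) & (svs.start < hi) & (svs.end > lo)]
            for sv in hits.itertuples(index=False):
                parent = truth.sv_parent.get(sv.sv_id)
                if parent == "maternal":
                    truth.gene_log2fc[g.gene_id] += eff
                elif parent == "paternal":
                    truth.gene_log2fc[g.gene_id] -= eff

    # coupled ACRs: within the regulatory window of an ASE gene
    gene_by_chrom = {c: s for c, s in genes.groupby("chrom")}
    for row in acrs.itertuples(index=False):
        fc = 0.0
        gsub = gene_by_chrom.get(row.chrom)
        if gsub is not None and len(gsub):
            gap = np.maximum(gsub.start.to_numpy() - row.end,
                             row.start - gsub.end.to_numpy())
            near = gap <= 5_000
            if near.any():
                j = int(np.argmin(np.where(near, gap, np.inf)))
                fc = config.acr_gene_coupling * truth.gene_log2fc[gsub.gene_id.iloc[j]]
        truth.acr_log2fc[row.acr_id] = float(fc)

    # per-SNP allelic effect per assay
    gene_snps = _snp_feature_map(variants, genes, "gene_id")
    acr_snps = _snp_feature_map(variants, acrs, "acr_id")
    nv = len(variants)
    fc_gene = np.zeros(nv)
    for g, idx in gene_snps.items():
        fc_gene[idx] = truth.gene_log2fc[g]
    fc_acr = np.zeros(nv)
    for a, idx in acr_snps.items():
        fc_acr[idx] = truth.acr_log2fc[a]

    # allelic coupling of chromatin marks to the gene's allelic state:
    # active marks follow the expressed allele, H3K27me3 opposes it
    mark_fc = {
        "RNA_rep1": fc_gene,
        "RNA_rep2": fc_gene,
        "ATAC": fc_acr,
        "H3K4me3": config.acr_gene_coupling * fc_gene,
        "H3K36me3": config.acr_gene_coupling * fc_gene,
        "H3K56ac": config.acr_gene_coupling * fc_gene,
        "H3K27me3": -config.acr_gene_coupling * fc_gene,
        "WGS": np.zeros(nv),
    }
    truth.coupling_coefficients = dict(config.coupling_coefficients)

    hap1_is_mat = np.array(
        [truth.snp_hap1_actual[s] == "maternal" for s in variants.snp_id]
    )
    counts = {}
    logit_ref = special.logit(config.pi_ref)
    for assay in ASSAYS:
        depth = _nbinom(rng, config.depth_mean, config.depth_dispersion, nv)
        pi = special.expit(logit_ref + LN2 * mark_fc[assay])
        # vectorized beta-binomial with per-SNP pi
        if config.rho == 0.0:
            maternal = rng.binomial(depth, pi)
        else:
            a = pi * (1 - config.rho) / config.rho
            b = (1 - pi) * (1 - config.rho) / config.rho
            maternal = rng.binomial(depth, rng.beta(a, b))
        paternal = depth - maternal
        df = variants[["snp_id", "chrom", "pos", "block_id"]].copy()
        df["hap1_count"] = np.where(hap1_is_mat, maternal, paternal)
        df["hap2_count"] = np.where(hap1_is_mat, paternal, maternal)
        counts[assay] = df

    # latent region factors and the coupled expression response
    ng = len(genes)
    cov_rows = []
    z_by_factor = {}
    for dt in FACTOR_DATATYPES:
        for region in REGIONS:
            z = rng.standard_normal(ng)
            z_by_factor[f"{dt}:{region}"] = z
            if dt == "methylation":
                value = special.expit(z - 1.0)  # methylation fraction
            else:
                value = np.exp(np.log(config.depth_mean) + 0.4 * z)
            for g, v in zip(genes.gene_id, value):
                cov_rows.append((g, dt, region, float(v)))
    region_coverage = pd.DataFrame(
        cov_rows, columns=["gene_id", "datatype", "region", "value"]
    )
    log2tpm = np.full(ng, 4.0)
    for key, coef in config.coupling_coefficients.items():
        if key in z_by_factor:
            log2tpm = log2tpm + coef * z_by_factor[key]
    log2tpm = log2tpm + rng.normal(0.0, config.expression_noise_sd, ng)
    expression = pd.DataFrame({"gene_id": genes.gene_id, "log2_tpm": log2tpm})
    return counts, region_coverage, expression


# ---------------------------------------------------------------------------
# methylation, GWAS
# ---------------------------------------------------------------------------

def simulate_methylation(genome: GenomeBundle, truth: GroundTruth,
                         config: SimConfig) -> pd.DataFrame:
    """Per-cytosine, per-haplotype methylated/unmethylated counts.

    Differential sites are injected at ``methyl_diff_rate`` with a
    maternal-paternal methylation-fraction gap of ``methyl_diff_gap``;
    coverage is drawn so both sides of the downstream coverage >= 10 filter
    occur.
    """
    rng = _rng(config, "methylation")
    chroms = list(genome.chrom_sizes)
    n = config.n_methyl_sites
    chrom = rng.choice(chroms, size=n)
    pos = rng.integers(0, config.chrom_length, size=n)
    context = rng.choice(["CpG", "CHG", "CHH"], size=n, p=[0.5, 0.3, 0.2])
    base = rng.beta(0.7, 0.7, size=n)
    is_diff = rng.random(n) < config.methyl_diff_rate
    gap = config.methyl_diff_gap
    frac_m = np.where(is_diff, np.clip(base + gap / 2, 0, 1), base)
    frac_p = np.where(is_diff, np.clip(base - gap / 2, 0, 1), base)
    cov_m = _nbinom(rng, config.methyl_depth_mean / 2, 0.3, n)
    cov_p = _nbinom(rng, config.methyl_depth_mean / 2, 0.3, n)
    meth_m = rng.binomial(cov_m, frac_m)
    meth_p = rng.binomial(cov_p, frac_p)
    site_id = [f"{c}_{p}_{x}" for c, p, x in zip(chrom, pos, context)]
    truth.methyl_diff_sites = [s for s, d in zip(site_id, is_diff) if d]
    return pd.DataFrame({
        "site_id": site_id, "chrom": chrom, "pos": pos, "context": context,
        "maternal_meth": meth_m, "maternal_unmeth": cov_m - meth_m,
        "paternal_meth": meth_p, "paternal_unmeth": cov_p - meth_p,
    })


def simulate_gwas(genome: GenomeBundle, truth: GroundTruth,
                  config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GWAS summary statistics plus an accession genotype matrix for LD.

    Significant SNPs (below Bonferroni at the simulated SNP count) land in
    ACRs with probability ``trait_snp_acr_fold`` times the genomic ACR
    fraction; non-significant p-values are uniform; MAF >= 0.03. Dosages for
    ``n_accessions`` accessions follow a copying process so that r^2 decays
    with distance.
    """
    rng = _rng(config, "gwas")
    chroms = list(genome.chrom_sizes)
    n = config.n_gwas_snps
    n_sig = min(config.n_gwas_significant, n)
    thr = 0.05 / max(n, 1)

    acr_by_chrom = {
        c: np.sort(genome.acrs.loc[genome.acrs.chrom == c, ["start", "end"]]
                   .to_numpy(), axis=0)
        for c in chroms
    }
    total_acr = float((genome.acrs.end - genome.acrs.start).sum())
    genome_len = float(sum(genome.chrom_sizes.values()))
    f0 = total_acr / genome_len if genome_len else 0.0

    def in_acr(chrom, p):
        arr = acr_by_chrom[chrom]
        if not len(arr):
            return False
        j = np.searchsorted(arr[:, 0], p, side="right") - 1
        return j >= 0 and p < arr[j, 1]

    rows = []
    p_in = min(config.trait_snp_acr_fold * f0, 0.9)
    acr_arr = genome.acrs
    for k in range(n):
        sig = k < n_sig
        if sig and len(acr_arr) and rng.random() < p_in:
            a = acr_arr.iloc[int(rng.integers(len(acr_arr)))]
            chrom, p = a.chrom, int(rng.integers(a.start, a.end))
        else:
            while True:
                chrom = chroms[int(rng.integers(len(chroms)))]
                p = int(rng.integers(0, config.chrom_length))
                if not sig or not in_acr(chrom, p):
                    break
        pval = thr * 10 ** (-rng.uniform(0, 4)) if sig else rng.uniform(thr, 1.0)
        maf = 0.03 + 0.47 * rng.beta(0.8, 3.0)
        rows.append((f"gwas{k:05d}", chrom, p, pval, maf, sig))
    gwas = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p", "maf",
                                       "significant_truth"])
    gwas = gwas.sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth.trait_snps = gwas.loc[gwas.significant_truth, "snp_id"].tolist()

    # genotype dosages with distance-decaying LD (latent-uniform copying)
    na = config.n_accessions
    doses = np.zeros((len(gwas), na), dtype=np.int8)
    for chrom, sub in gwas.groupby("chrom"):
        idx = sub.index.to_numpy()
        pos = sub.pos.to_numpy()
        maf = sub.maf.to_numpy()
        for hap in range(2):
            u = rng.random((len(idx), na))
            for j in range(1, len(idx)):
                r = np.exp(-(pos[j] - pos[j - 1]) / 50_000.0)
                copy = rng.random(na) < r
                u[j, copy] = u[j - 1, copy]
            doses[idx] += (u < maf[:, None]).astype(np.int8)
    geno = pd.DataFrame(doses, index=gwas.snp_id,
                        columns=[f"acc{i:03d}" for i in range(na)])
    return gwas.drop(columns="significant_truth"), geno


def simulate_factor_matrix(
    n_genes: int,
    registry: list[str],
    n_true: int = 5,
    snr: float = 2.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Directly simulate a gene x factor matrix with a known linear response.

    Returns (matrix with response column 'y', true beta, noise sd). The
    response is y = X beta + eps with noise scaled so Var(X beta)/Var(eps)
    equals ``snr``. Missing cells (NaN) are injected completely at random.
    """
    rng = np.random.default_rng(seed)
    p = len(registry)
    X = rng.standard_normal((n_genes, p))
    beta = np.zeros(p)
    support = rng.choice(p, size=n_true, replace=False)
    beta[support] = rng.uniform(0.5, 1.5, n_true) * rng.choice([-1, 1], n_true)
    signal = X @ beta
    sd = float(np.std(signal) / np.sqrt(snr)) if snr > 0 else 1.0
    y = signal + rng.normal(0, sd, n_genes)
    if missing_rate > 0:
        mask = rng.random(X.shape) < missing_rate
        X = np.where(mask, np.nan, X)
    df = pd.DataFrame(X, columns=registry,
                      index=[f"gene{i:05d}" for i in range(n_genes)])
    df["y"] = y
    return df, beta, sd


# ---------------------------------------------------------------------------
# full-study driver
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig, outdir) -> GroundTruth:
    """Generate the complete synthetic study into ``outdir``.

    Writes genes.gff3, acrs.bed, tes.bed, svs.bed, chrom.sizes, variants.vcf,
    parents.vcf, blocks.tsv, counts_<assay>.tsv, region_coverage.tsv,
    expression.tsv, methylation.tsv, gwas.tsv, genotypes.tsv and truth.json.
    Identical config (including seed) reproduces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    variants, blocks, truth = simulate_phased_variants(genome, config)
    counts, region_coverage, expression = simulate_allelic_counts(
        variants, genome, truth, config)
    methylation = simulate_methylation(genome, truth, config)
    gwas, geno = simulate_gwas(genome, truth, config)

    with open(outdir / "chrom.sizes", "w") as fh:
        for c, s in genome.chrom_sizes.items():
            fh.write(f"{c}\t{s}\n")
    io.write_gff3(genome.genes, outdir / "genes.gff3")
    io.write_bed(genome.acrs.rename(columns={"acr_id": "name"}), outdir / "acrs.bed")
    # BED name column carries the RepeatMasker-style class string
    io.write_bed(genome.tes.rename(columns={"te_class": "name"}), outdir / "tes.bed",
                 score_col="te_id")
    io.write_bed(genome.svs.rename(columns={"sv_id": "name"}), outdir / "svs.bed",
                 score_col="haplotype")
    io.write_vcf_phased(variants, outdir / "variants.vcf", genome.chrom_sizes)
    io.write_parental_vcf(variants, outdir / "parents.vcf", genome.chrom_sizes)
    variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    blocks.to_csv(outdir / "blocks_sim.tsv", sep="\t", index=False)
    for assay, df in counts.items():
        io.write_counts(df, outdir / f"counts_{assay}.tsv")
    io.write_tsv(region_coverage, outdir / "region_coverage.tsv")
    io.write_tsv(expression, outdir / "expression.tsv")
    io.write_tsv(methylation, outdir / "methylation.tsv")
    io.write_tsv(gwas, outdir / "gwas.tsv")
    geno.to_csv(outdir / "genotypes.tsv", sep="\t")
    # dN/dS covariate: log-normal around 0.25 (purifying selection typical)
    rng = _rng(config, "dnds")
    dnds = pd.DataFrame({
        "gene_id": genome.genes.gene_id,
        "dnds": rng.lognormal(np.log(0.25), 0.5, len(genome.genes)),
    })
    io.write_tsv(dnds, outdir / "dnds.tsv")
    truth.to_json(outdir / "truth.json")
    return truth
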