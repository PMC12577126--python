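"""Linking structural variants and allele-specific ACRs to ASE genes.

Pairings are restricted to features sharing a phase block, because haplotype
labels are arbitrary between blocks. Deletion:gene pairs re-key the
expression ratio so the numerator is always the deletion-carrying haplotype;
the promoter-deletion effect is scored with Hedges' G and a label-permutation
null. AS-ACR:gene pairs within 5 kb and with no intervening gene correlate
allelic accessibility with allelic expression.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def hedges_g(a, b) -> float:
    """Hedges' G: pooled-variance standardized mean difference with the
    small-sample correction J = 1 - 3 / (4 (n_a + n_b) - 9).

    Undefined (NaN) when the pooled variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    s2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if s2 == 0:
        return float("nan")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float((a.mean() - b.mean()) / np.sqrt(s2) * j)


def permute_group_labels(values: np.ndarray, in_group: np.ndarray,
                         n_perm: int = 1_000, seed: int = 0) -> dict:
    """Permutation p-value for a two-group Hedges' G.

    Group labels are shuffled preserving group sizes; the statistic permuted
    is Hedges' G itself; p = (#{|g_perm| >= |g_obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("each group needs >= 2 members")
    g_obs = hedges_g(values[in_group], values[~in_group])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    k = int(in_group.sum())
    for i in range(n_perm):
        perm = np.zeros(len(values), dtype=bool)
        perm[rng.choice(len(values), size=k, replace=False)] = True
        null[i] = hedges_g(values[perm], values[~perm])
    p = float((np.sum(np.abs(null) >= abs(g_obs)) + 1.0) / (n_perm + 1.0))
    return {"g_observed": g_obs, "p": p, "null": null,
            "n_group": k, "n_other": int(len(values) - k)}


def _nearest(query: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Edge-to-edge nearest target per query row, same chromosome only.

    Distances are gap sizes (0 when touching or overlapping); ties break
    toward the smaller target name for determinism. Queries with no target
    on their chromosome are omitted.
    """
    rows = []
    for chrom, qsub in query.groupby("chrom"):
        t = targets[targets.chrom == chrom].sort_values("name", kind="stable")
        if not len(t):
            continue
        ts, te = t["start"].to_numpy(), t["end"].to_numpy()
        names = t["name"].to_numpy()
        for q in qsub.itertuples():
            gap = np.maximum.reduce([ts - q.end, q.start - te,
                                     np.zeros(len(t), dtype=np.int64)])
            j = int(np.argmin(gap))  # first minimum = smallest name on ties
            rows.append((q.Index, names[j], int(gap[j])))
    return pd.DataFrame(rows, columns=["query_index", "target", "gap"])


@dataclass
class DeletionLink:
    pairs: pd.DataFrame
    g_promoter: float
    p_promoter: float
    null: np.ndarray | None


def pair_deletion_gene(
    ase_genes: pd.DataFrame,
    deletions: pd.DataFrame,
    promoter_bp: int = 1_000,
) -> pd.DataFrame:
    """Pair each ASE gene with its nearest deletion, kept when both share a
    phase block.

    ``ase_genes`` needs gene_id, chrom, start, end, strand, block_id and the
    haplotype expression sums maternal_sum / paternal_sum; ``deletions``
    needs sv_id, chrom, start, end, block_id and parent (ancestry of the
    deletion-carrying haplotype). The log2 expression ratio is keyed so its
    numerator is the deletion-carrying haplotype, with a pseudocount of 1;
    sv_in_promoter marks deletions overlapping [TSS - promoter_bp, TSS).
    """
    if not len(ase_genes) or not len(deletions):
        return pd.DataFrame(columns=["gene_id", "sv_id", "same_block",
                                     "sv_in_promoter", "del_ratio"])
    near = _nearest(
        ase_genes.rename_axis("idx"),
        deletions.rename(columns={"sv_id": "name"}),
    )
    dele = deletions.set_index("sv_id")
    rows = []
    for rec in near.itertuples(index=False):
        g = ase_genes.loc[rec.query_index]
        d = dele.loc[rec.target]
        if g["block_id"] != d["block_id"]:
            continue
        if g["strand"] == "+":
            prom = (max(0, g["start"] - promoter_bp), g["start"])
        else:
            prom = (g["end"], g["end"] + promoter_bp)
        in_prom = (d["start"] < prom[1]) and (d["end"] > prom[0])
        if d["parent"] == "maternal":
            num, den = g["maternal_sum"], g["paternal_sum"]
        elif d["parent"] == "paternal":
            num, den = g["paternal_sum"], g["maternal_sum"]
        else:
            continue  # deletion ancestry unknown
        ratio = float(np.log2((num + 1.0) / (den + 1.0)))
        rows.append((g["gene_id"], rec.target, True, bool(in_prom), ratio))
    return pd.DataFrame(rows, columns=["gene_id", "sv_id", "same_block",
                                       "sv_in_promoter", "del_ratio"])


def promoter_deletion_effect(pairs: pd.DataFrame, n_perm: int = 1_000,
                             seed: int = 0) -> DeletionLink:
    """Hedges' G of the deletion-haplotype expression ratio, promoter
    deletions vs all other deletion:gene pairs, with a permutation p."""
    res = permute_group_labels(pairs["del_ratio"].to_numpy(),
                               pairs["sv_in_promoter"].to_numpy(),
                               n_perm=n_perm, seed=seed)
    return DeletionLink(pairs, res["g_observed"], res["p"], res["null"])


def pair_acr_gene(
    as_acrs: pd.DataFrame,
    ase_genes: pd.DataFrame,
    all_genes: pd.DataFrame,
    max_sep: int = 5_000,
) -> tuple[pd.DataFrame, dict]:
    """Pair each AS-ACR with its nearest ASE gene and correlate allelic
    accessibility with allelic expression.

    Kept pairs share a phase block, lie within ``max_sep`` bp (edge-to-edge
    gap) and have no intervening annotated gene. ``as_acrs`` needs acr_id,
    chrom, start, end, block_id, log2fc_atac; ``ase_genes`` needs gene_id,
    chrom, start, end, block_id, log2fc_rna. Pearson correlation is
    undefined (None) below 3 pairs.
    """
    cols = ["acr_id", "gene_id", "separation", "same_block",
            "log2fc_atac", "log2fc_rna"]
    if not len(as_acrs) or not len(ase_genes):
        return pd.DataFrame(columns=cols), {"r": None, "p": None, "n": 0}
    near = _nearest(
        as_acrs.rename_axis("idx"),
        ase_genes.rename(columns={"gene_id": "name"}),
    )
    genes_idx = ase_genes.set_index("gene_id")
    rows = []
    for rec in near.itertuples(index=False):
        a = as_acrs.loc[rec.query_index]
        g = genes_idx.loc[rec.target]
        if a["block_id"] != g["block_id"] or rec.gap > max_sep:
            continue
        lo = min(a["end"], g["end"])
        hi = max(a["start"], g["start"])
        between = all_genes[(all_genes.chrom == a["chrom"])
                            & (all_genes.start >= lo) & (all_genes.end <= hi)
                            & (all_genes.gene_id != rec.target)]
        if len(between):
            continue
        rows.append((a["acr_id"], rec.target, int(rec.gap), True,
                     float(a["log2fc_atac"]), float(g["log2fc_rna"])))
    pairs = pd.DataFrame(rows, columns=cols)
    if len(pairs) >= 3:
        r, p = sps.pearsonr(pairs["log2fc_atac"], pairs["log2fc_rna"])
        stats = {"r": float(r), "p": float(p), "n": len(pairs)}
    else:
        stats = {"r": None, "p": None, "n": len(pairs)}
    return pairs, stats
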