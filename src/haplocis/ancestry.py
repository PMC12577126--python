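"""Parental-ancestry assignment within phase blocks.

Haplotype labels (hap1/hap2) are arbitrary between phase blocks; SNPs that
are homozygous for alternate alleles in the two parents anchor each block's
haplotypes to the maternal or paternal genome. Blocks are classified as
unclassified (no informative SNPs), non-recombinant (unanimous ancestry per
haplotype after filtering discordant SNPs), recombinant (ancestry changes
once along a haplotype) or excluded_switching (repeated switching, dropped).
Uninformative SNPs in non-recombinant blocks inherit the block ancestry;
in recombinant blocks only parentally informative SNPs keep a label.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OPPOSITE = {"maternal": "paternal", "paternal": "maternal"}

BLOCK_CLASSES = ("unclassified", "non_recombinant", "recombinant", "excluded_switching")


class BlockStructureError(ValueError):
    """A phase block violates its structural invariants."""


@dataclass
class BlockCall:
    block_id: int
    block_class: str
    hap1_ancestry: str | None      # set for non-recombinant blocks
    n_informative: int
    n_discordant_removed: int
    retained_snp_ids: list         # informative SNPs surviving the filter


def _runs(labels: np.ndarray) -> int:
    if len(labels) == 0:
        return 0
    return int(1 + np.sum(labels[1:] != labels[:-1]))


def filter_discordant(labels: np.ndarray, threshold: float = 0.75
                      ) -> tuple[np.ndarray, int]:
    """Drop informative SNPs discordant with the haplotype majority.

    Returns a keep-mask and the removal count. Filtering happens only when
    the majority fraction reaches ``threshold``; below it (including exact
    ties) nothing is removed and the block falls through to recombinant
    handling — a majority is never fabricated.
    """
    m = len(labels)
    keep = np.ones(m, dtype=bool)
    if m == 0:
        return keep, 0
    n_mat = int(np.sum(labels == "maternal"))
    n_maj = max(n_mat, m - n_mat)
    if n_maj == m or n_maj / m < threshold or n_maj * 2 == m:
        return keep, 0
    majority = "maternal" if n_mat * 2 > m else "paternal"
    keep = labels == majority
    return keep, int(m - keep.sum())


def classify_block(block_id: int, snps: pd.DataFrame,
                   threshold: float = 0.75) -> BlockCall:
    """Classify one phase block from its informative SNPs.

    ``snps`` needs columns snp_id, chrom, pos, informative and
    hap1_parent_call (the parental-genotype ancestry of the hap1 allele,
    empty for uninformative SNPs). Classification:

    * no informative SNPs -> unclassified;
    * unanimous hap1 ancestry (possibly after removing discordant SNPs when
      the majority reaches ``threshold``) -> non_recombinant;
    * two ancestry runs -> recombinant;
    * three or more runs -> excluded_switching (repeated haplotype
      switching; the block is dropped from ancestry-dependent outputs).
    """
    if snps["chrom"].nunique() > 1:
        raise BlockStructureError(
            f"block {block_id} spans chromosomes {sorted(snps.chrom.unique())}"
        )
    inf = snps[snps["informative"]].sort_values("pos")
    labels = inf["hap1_parent_call"].to_numpy(dtype=object)
    if len(labels) == 0:
        return BlockCall(block_id, "unclassified", None, 0, 0, [])
    keep, removed = filter_discordant(labels, threshold)
    kept = labels[keep]
    if len(set(kept)) == 1:
        return BlockCall(block_id, "non_recombinant", str(kept[0]),
                         len(labels), removed, list(inf.snp_id[keep]))
    runs = _runs(labels)
    cls = "recombinant" if runs <= 2 else "excluded_switching"
    return BlockCall(block_id, cls, None, len(labels), 0, list(inf.snp_id))


def impute_snp_ancestry(snps: pd.DataFrame, call: BlockCall) -> pd.DataFrame:
    """Label every SNP in the block with hap1 ancestry where possible.

    Non-recombinant: all SNPs inherit the haplotype's unanimous ancestry
    (uninformative ones as source='imputed'). Recombinant: only retained
    informative SNPs keep their parental label. Unclassified and
    excluded_switching: everything unknown.
    """
    out = snps[["snp_id", "block_id", "pos"]].copy()
    out["hap1_ancestry"] = "unknown"
    out["source"] = ""
    if call.block_class == "non_recombinant":
        retained = set(call.retained_snp_ids)
        out["hap1_ancestry"] = call.hap1_ancestry
        out["source"] = np.where(out.snp_id.isin(retained), "informative", "imputed")
        # discordant informative SNPs were filtered: leave them unknown
        discord = snps["informative"].to_numpy() & ~out.snp_id.isin(retained).to_numpy()
        out.loc[discord, ["hap1_ancestry", "source"]] = ["unknown", ""]
    elif call.block_class == "recombinant":
        inf_ids = set(call.retained_snp_ids)
        mask = out.snp_id.isin(inf_ids)
        labels = snps.set_index("snp_id")["hap1_parent_call"]
        out.loc[mask, "hap1_ancestry"] = out.loc[mask, "snp_id"].map(labels)
        out.loc[mask, "source"] = "informative"
    out["hap2_ancestry"] = out["hap1_ancestry"].map(OPPOSITE).fillna("unknown")
    return out


def assign_ancestry(variants: pd.DataFrame, threshold: float = 0.75
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every phase block and impute SNP ancestry genome-wide.

    Returns (ancestry table, block table). The ancestry table has one row
    per SNP with hap1/hap2 ancestry in {maternal, paternal, unknown} and the
    label source in {informative, imputed}.
    """
    calls = []
    parts = []
    for block_id, sub in variants.groupby("block_id"):
        call = classify_block(int(block_id), sub, threshold)
        calls.append(call)
        parts.append(impute_snp_ancestry(sub, call))
    ancestry = (pd.concat(parts, ignore_index=True)
                if parts else pd.DataFrame(columns=[
                    "snp_id", "block_id", "pos", "hap1_ancestry", "source",
                    "hap2_ancestry"]))
    blocks = pd.DataFrame(
        [(c.block_id, c.block_class, c.hap1_ancestry or "", c.n_informative,
          c.n_discordant_removed) for c in calls],
        columns=["block_id", "class", "hap1_ancestry", "n_informative",
                 "n_discordant_removed"],
    )
    return ancestry, blocks


def impute_sv_ancestry(sv: pd.Series, snp_ancestry: pd.DataFrame,
                       blocks: pd.DataFrame, k: int = 5) -> str:
    """Ancestry of the haplotype carrying an SV.

    In a non-recombinant block the SV's haplotype inherits the block
    ancestry regardless of neighbors. In a recombinant block, a majority
    vote over the <= ``k`` nearest labeled SNPs on each side of the SV
    midpoint (<= 2k total) decides; ties and empty neighborhoods give
    'unknown'. The returned label refers to the SV's own haplotype
    (sv['haplotype'] in {1, 2}).
    """
    brow = blocks[blocks.block_id == sv["block_id"]]
    if not len(brow):
        return "unknown"
    bclass = brow["class"].iloc[0]
    col = "hap1_ancestry" if sv["haplotype"] == 1 else "hap2_ancestry"
    if bclass == "non_recombinant":
        anc = brow["hap1_ancestry"].iloc[0]
        if not anc:
            return "unknown"
        return anc if sv["haplotype"] == 1 else OPPOSITE[anc]
    if bclass != "recombinant":
        return "unknown"
    labeled = snp_ancestry[(snp_ancestry.block_id == sv["block_id"])
                           & (snp_ancestry[col] != "unknown")]
    if not len(labeled):
        return "unknown"
    mid = (sv["start"] + sv["end"]) // 2
    pos = labeled.pos.to_numpy()
    lab = labeled[col].to_numpy()
    order = np.argsort(pos)
    pos, lab = pos[order], lab[order]
    left = lab[pos < mid][-k:]
    right = lab[pos >= mid][:k]
    votes = np.concatenate([left, right])
    n_mat = int(np.sum(votes == "maternal"))
    if n_mat * 2 == len(votes):
        return "unknown"
    return "maternal" if n_mat * 2 > len(votes) else "paternal"


def estimate_switch_error(observed: pd.DataFrame, reference: pd.DataFrame
                          ) -> dict[str, float | None]:
    """Switch-error rate per haplotype against an independent label source.

    Both frames need snp_id, block_id, pos and hap{1,2}_ancestry columns.
    The rate is the fraction of evaluable SNPs whose observed haplotype
    label disagrees with the reference (simulation truth, or parental
    homozygous SNPs) — the per-SNP phase-flip rate. Blocks contributing
    fewer than two jointly labeled SNPs are skipped (a lone SNP carries no
    phase information); with nothing evaluable the rate is None (missing).
    """
    merged = observed.merge(reference, on="snp_id", suffixes=("_obs", "_ref"))
    out: dict[str, float | None] = {}
    for hap in ("hap1", "hap2"):
        col_o, col_r = f"{hap}_ancestry_obs", f"{hap}_ancestry_ref"
        sub = merged[(merged[col_o] != "unknown") & (merged[col_r] != "unknown")]
        n_flip = n_eval = 0
        for _, grp in sub.groupby("block_id_obs"):
            if len(grp) < 2:
                continue
            agree = (grp[col_o] == grp[col_r]).to_numpy()
            n_flip += int(np.sum(~agree))
            n_eval += len(agree)
        out[hap] = (n_flip / n_eval) if n_eval else None
    return out
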