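"""Allele-specific expression / accessibility calling.

Per-SNP allelic imbalance is scored against a beta-binomial null fitted to
whole-genome sequencing counts over the same feature class — WGS carries no
true allelic signal, so its marginal success probability pi_hat absorbs
reference-mapping bias and rho_hat absorbs extra-binomial noise. Per-SNP
two-sided tail probabilities become signed z-scores, pooled per feature with
Stouffer's method (sum z / sqrt(n)); feature significance comes from a
parametric bootstrap of the fitted null at the observed depths, and calls
are made at Benjamini-Hochberg FDR < alpha, requiring consistency (q < alpha
and matching log2FC sign) across replicates where more than one exists.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import BetaBinNull, betabin_cdf, fit_betabin

__all__ = [
    "BetaBinNull", "fit_betabin_null", "snp_effect", "pool_stouffer",
    "empirical_null_p", "ase_scan", "call_ase",
]


def fit_betabin_null(maternal, total, min_obs: int = 50) -> BetaBinNull:
    """Fit the beta-binomial null to WGS allelic counts (see stats.fit_betabin)."""
    return fit_betabin(maternal, total, min_obs=min_obs)


def _check_null(null: BetaBinNull) -> None:
    if not 0.0 < null.pi_hat < 1.0:
        raise ValueError(f"degenerate null: pi_hat={null.pi_hat}")
    if not 0.0 <= null.rho_hat < 1.0:
        raise ValueError(f"degenerate null: rho_hat={null.rho_hat}")


class _ZLookup:
    """Signed z for every (depth, count) pair under a fitted null.

    Builds, per distinct depth, the full two-sided tail-probability table
    (2 * min(lower, upper) capped at 1, ties at the observed count included
    in both tails) mapped through the inverse normal, signed by the
    direction of the maternal deviation from pi_hat.
    """

    def __init__(self, null: BetaBinNull):
        _check_null(null)
        self.null = null
        self._tables: dict[int, np.ndarray] = {}

    def table(self, n: int) -> np.ndarray:
        tab = self._tables.get(n)
        if tab is None:
            k = np.arange(n + 1)
            cdf = betabin_cdf(k, n, self.null.pi_hat, self.null.rho_hat)
            lower = cdf
            upper = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(X >= k)
            p2 = np.clip(2.0 * np.minimum(lower, upper), 1e-300, 1.0)
            z = sps.norm.isf(p2 / 2.0)
            z = np.where(np.isclose(p2, 1.0), 0.0, z)
            sign = np.sign(k / n - self.null.pi_hat) if n > 0 else np.zeros(1)
            tab = np.abs(z) * sign
            self._tables[n] = tab
        return tab

    def z(self, maternal: np.ndarray, total: np.ndarray) -> np.ndarray:
        out = np.empty(len(maternal), dtype=float)
        for n in np.unique(total):
            tab = self.table(int(n))
            sel = total == n
            out[sel] = tab[maternal[sel]]
        return out


def snp_effect(maternal: int, total: int, null: BetaBinNull
               ) -> tuple[float, float]:
    """Two-sided beta-binomial tail probability of one SNP's maternal count,
    and the corresponding signed z (positive = maternal excess)."""
    lut = _ZLookup(null)
    z = float(lut.z(np.array([maternal]), np.array([total]))[0])
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return p, z


def pool_stouffer(z: np.ndarray) -> float:
    """Stouffer combination: sum(z_i) / sqrt(n). Requires >= 2 finite z."""
    z = np.asarray(z, dtype=float)
    if len(z) < 2:
        raise ValueError(f"Stouffer pooling needs >= 2 SNPs, got {len(z)}")
    bad = np.nonzero(~np.isfinite(z))[0]
    if len(bad):
        raise ValueError(f"non-finite z at SNP index {bad[0]}")
    return float(np.sum(z) / np.sqrt(len(z)))


def _draw_betabin(rng: np.random.Generator, totals: np.ndarray,
                  null: BetaBinNull, size: int) -> np.ndarray:
    """(size, len(totals)) matrix of null maternal counts at fixed depths."""
    shape = (size, len(totals))
    if null.rho_hat < 1e-12:
        return rng.binomial(totals[None, :], null.pi_hat, size=shape)
    a = null.pi_hat * (1 - null.rho_hat) / null.rho_hat
    b = (1 - null.pi_hat) * (1 - null.rho_hat) / null.rho_hat
    p = rng.beta(a, b, size=shape)
    return rng.binomial(totals[None, :], p)


def empirical_null_p(z_obs: float, totals: np.ndarray, null: BetaBinNull,
                     n_sims: int, rng: np.random.Generator,
                     lut: _ZLookup | None = None) -> float:
    """Parametric-bootstrap p-value for one feature's pooled z.

    Replicates draw maternal counts from the fitted null at the feature's
    observed depths, recompute the pooled z, and compare |z|; the +1/+1
    estimator keeps p in (0, 1].
    """
    if n_sims < 100:
        raise ValueError(f"n_sims must be >= 100, got {n_sims}")
    totals = np.asarray(totals)
    if lut is None:
        lut = _ZLookup(null)
    draws = _draw_betabin(rng, totals, null, n_sims)
    znull = np.empty(draws.shape, dtype=float)
    for j, n in enumerate(totals):
        znull[:, j] = lut.table(int(n))[draws[:, j]]
    pooled = znull.sum(axis=1) / np.sqrt(len(totals))
    return float((np.sum(np.abs(pooled) >= abs(z_obs)) + 1.0) / (n_sims + 1.0))


def ase_scan(snp_counts: pd.DataFrame, null: BetaBinNull, n_sims: int = 10_000,
             seed: int = 0, min_snps: int = 2,
             pseudocount: float = 1.0) -> pd.DataFrame:
    """Score every feature for allelic imbalance.

    ``snp_counts`` has one row per (feature, SNP): feature_id, snp_id,
    maternal_count, paternal_count (coverage-filtered upstream). Features
    with fewer than ``min_snps`` SNPs are reported untestable. Per-feature
    bootstrap streams derive from the master seed and the feature's index in
    sorted order, so results are reproducible under any execution order.
    """
    _check_null(null)
    lut = _ZLookup(null)
    mat = snp_counts["maternal_count"].to_numpy(dtype=np.int64)
    tot = mat + snp_counts["paternal_count"].to_numpy(dtype=np.int64)
    z_all = lut.z(mat, tot)
    snp_counts = snp_counts.assign(_z=z_all, _m=mat, _t=tot)
    rows = []
    for fi, (fid, grp) in enumerate(sorted(snp_counts.groupby("feature_id"),
                                           key=lambda kv: str(kv[0]))):
        msum = int(grp["_m"].sum())
        psum = int(grp["_t"].sum() - grp["_m"].sum())
        log2fc = float(np.log2((msum + pseudocount) / (psum + pseudocount)))
        if len(grp) < min_snps:
            rows.append((fid, len(grp), np.nan, np.nan, log2fc, False))
            continue
        zpool = pool_stouffer(grp["_z"].to_numpy())
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(fi,)))
        p = empirical_null_p(zpool, grp["_t"].to_numpy(), null, n_sims, rng, lut)
        rows.append((fid, len(grp), zpool, p, log2fc, True))
    return pd.DataFrame(rows, columns=["feature_id", "n_snps", "pooled_z",
                                       "p_empirical", "log2fc", "testable"])


def call_ase(replicates: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg calls, consistent across replicates.

    BH adjustment runs within each replicate over its testable features. A
    feature is called significant iff q < alpha in *every* replicate and the
    replicate log2FC signs agree; with one replicate (e.g. the single ATAC
    library) the one-replicate rule applies. Replicates with different
    feature sets are intersected; the intersection size is reported in the
    ``n_common`` attribute.
    """
    if not replicates:
        raise ValueError("need at least one replicate of results")
    adjusted = []
    for rep in replicates:
        rep = rep[rep["testable"]].copy()
        if len(rep):
            rep["q_bh"] = multipletests(rep["p_empirical"], method="fdr_bh")[1]
        else:
            rep["q_bh"] = pd.Series(dtype=float)
        adjusted.append(rep.set_index("feature_id"))
    common = adjusted[0].index
    for rep in adjusted[1:]:
        common = common.intersection(rep.index)
    out = pd.DataFrame(index=common)
    for i, rep in enumerate(adjusted, 1):
        sub = rep.loc[common]
        out[f"q_rep{i}"] = sub["q_bh"]
        out[f"log2fc_rep{i}"] = sub["log2fc"]
        out[f"p_rep{i}"] = sub["p_empirical"]
    out["n_snps"] = adjusted[0].loc[common, "n_snps"]
    out["pooled_z"] = adjusted[0].loc[common, "pooled_z"]
    qcols = [c for c in out.columns if c.startswith("q_rep")]
    fcols = [c for c in out.columns if c.startswith("log2fc_rep")]
    sig = np.all([out[c] < alpha for c in qcols], axis=0)
    if len(fcols) > 1:
        signs = np.sign(out[fcols].to_numpy())
        sig &= np.all(signs == signs[:, [0]], axis=1) & np.all(signs != 0, axis=1)
    out["log2fc"] = out[fcols].mean(axis=1)
    out["significant"] = sig
    out = out.reset_index(names="feature_id")
    out.attrs["n_common"] = len(common)
    return out
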