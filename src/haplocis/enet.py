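"""Elastic-net models of expression from chromatin factors.

Two responses are modeled from the gene x factor matrix: overall expression
(log2 TPM) and allelic expression (log2 maternal/paternal). Predictors are
standardized and mean-imputed within training folds (no leakage); the
penalty mix and strength are chosen by 5-fold cross-validation, and a
reduced model takes the largest penalty whose CV mean-squared error stays
within one standard error of the minimum (the lambda-1SE rule), trading fit
for sparsity. R is the Pearson correlation of predicted vs observed; both
the in-sample and the cross-validated variant are reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold


@dataclass
class EnetFit:
    response: str
    alpha: float                      # L1/L2 mix (elastic-net mixing parameter)
    lambda_min: float
    lambda_1se: float
    coefficients: pd.Series           # standardized scale, at chosen lambda
    cv_curve: pd.DataFrame            # alpha, lambda, cv_mse, cv_se
    r_insample: float
    r_cv: float
    n_genes: int
    lambda_used: float
    dropped_columns: list[str] = field(default_factory=list)
    intercept: float = 0.0

    @property
    def support(self) -> list[str]:
        return list(self.coefficients[self.coefficients != 0].index)


def _prepare(X: np.ndarray):
    """Column means/stds for impute-then-standardize, NaN-aware."""
    mean = np.nanmean(X, axis=0)
    std = np.nanstd(X, axis=0)
    std[std == 0] = 1.0
    return mean, std


def _transform(X: np.ndarray, mean, std) -> np.ndarray:
    Z = (X - mean) / std
    return np.where(np.isnan(Z), 0.0, Z)  # mean imputation on the z scale


def fit_cv(
    matrix: pd.DataFrame,
    response: pd.Series,
    folds: int = 5,
    seed: int = 0,
    alpha_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_lambda: int = 100,
) -> EnetFit:
    """Cross-validated elastic net of ``response`` on the factor matrix.

    Rows are sorted by gene id before fold assignment, so permuting the
    input row order cannot change the fit. All-NA columns are dropped with
    a warning; a constant response is an error.
    """
    y_full = response.reindex(matrix.index)
    ok = y_full.notna()
    matrix, y_full = matrix[ok], y_full[ok]
    order = np.argsort(matrix.index.to_numpy(), kind="stable")
    matrix = matrix.iloc[order]
    y = y_full.iloc[order].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response: nothing to model")
    if len(matrix) < 10 * folds:
        raise ValueError(f"need >= {10 * folds} genes for {folds}-fold CV, "
                         f"got {len(matrix)}")
    all_na = [c for c in matrix.columns if matrix[c].isna().all()]
    if all_na:
        warnings.warn(f"dropping all-NA factor columns: {all_na}")
        matrix = matrix.drop(columns=all_na)
    cols = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    n = len(y)

    # shared geometric lambda path spanning the largest lambda_max over the mix grid
    mean0, std0 = _prepare(X)
    Z0 = _transform(X, mean0, std0)
    yc = y - y.mean()
    lam_max = np.max(np.abs(Z0.T @ yc)) / (n * min(alpha_grid))
    lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    mse = np.zeros((len(alpha_grid), n_lambda, folds))
    for f, (tr, te) in enumerate(kf.split(X)):
        mean, std = _prepare(X[tr])
        Ztr, Zte = _transform(X[tr], mean, std), _transform(X[te], mean, std)
        ytr_mean = y[tr].mean()
        ytr = y[tr] - ytr_mean
        for ai, a in enumerate(alpha_grid):
            _, coefs, _ = enet_path(Ztr, ytr, l1_ratio=a, alphas=lambdas)
            pred = Zte @ coefs + ytr_mean
            mse[ai, :, f] = np.mean((pred - y[te][:, None]) ** 2, axis=0)

    cv_mse = mse.mean(axis=2)
    cv_se = mse.std(axis=2, ddof=1) / np.sqrt(folds)
    ai, li = np.unravel_index(np.argmin(cv_mse), cv_mse.shape)
    alpha_star, lam_min = float(alpha_grid[ai]), float(lambdas[li])

    curve = pd.DataFrame({
        "alpha": np.repeat(alpha_grid, n_lambda),
        "lambda": np.tile(lambdas, len(alpha_grid)),
        "cv_mse": cv_mse.ravel(),
        "cv_se": cv_se.ravel(),
    })

    # out-of-fold predictions at (alpha*, lambda_min) for R_cv
    oof = np.empty(n)
    for tr, te in kf.split(X):
        mean, std = _prepare(X[tr])
        Ztr, Zte = _transform(X[tr], mean, std), _transform(X[te], mean, std)
        _, coefs, _ = enet_path(Ztr, y[tr] - y[tr].mean(), l1_ratio=alpha_star,
                                alphas=[lam_min])
        oof[te] = Zte @ coefs[:, 0] + y[tr].mean()
    r_cv = float(sps.pearsonr(oof, y)[0])

    # final fit on all rows
    _, coefs, _ = enet_path(Z0, yc, l1_ratio=alpha_star, alphas=[lam_min])
    beta = pd.Series(coefs[:, 0], index=cols)
    pred = Z0 @ beta.to_numpy() + y.mean()
    r_in = float(sps.pearsonr(pred, y)[0]) if np.ptp(pred) > 0 else 0.0

    # lambda_1se on the chosen mix: largest lambda within one SE of the minimum
    sel = cv_mse[ai] <= cv_mse[ai, li] + cv_se[ai, li]
    lam_1se = float(lambdas[np.argmax(sel)])  # lambdas descend: first True is largest

    return EnetFit(
        response=getattr(response, "name", "y") or "y",
        alpha=alpha_star, lambda_min=lam_min, lambda_1se=lam_1se,
        coefficients=beta, cv_curve=curve, r_insample=r_in, r_cv=r_cv,
        n_genes=n, lambda_used=lam_min, dropped_columns=all_na,
        intercept=float(y.mean()),
    )


def reduce_1se(fit: EnetFit, matrix: pd.DataFrame, response: pd.Series) -> EnetFit:
    """Refit at lambda-1SE: the sparser model whose CV error is within one
    standard error of the best. The nonzero support can only shrink or stay."""
    y_full = response.reindex(matrix.index)
    ok = y_full.notna()
    matrix, y_full = matrix[ok], y_full[ok]
    order = np.argsort(matrix.index.to_numpy(), kind="stable")
    matrix = matrix.iloc[order]
    y = y_full.iloc[order].to_numpy(dtype=float)
    matrix = matrix[fit.coefficients.index]
    X = matrix.to_numpy(dtype=float)
    mean, std = _prepare(X)
    Z = _transform(X, mean, std)
    _, coefs, _ = enet_path(Z, y - y.mean(), l1_ratio=fit.alpha,
                            alphas=[fit.lambda_1se])
    beta = pd.Series(coefs[:, 0], index=fit.coefficients.index)
    pred = Z @ beta.to_numpy() + y.mean()
    r_in = float(sps.pearsonr(pred, y)[0]) if np.ptp(pred) > 0 else 0.0
    return EnetFit(
        response=fit.response, alpha=fit.alpha, lambda_min=fit.lambda_min,
        lambda_1se=fit.lambda_1se, coefficients=beta, cv_curve=fit.cv_curve,
        r_insample=r_in, r_cv=fit.r_cv, n_genes=len(y),
        lambda_used=fit.lambda_1se, dropped_columns=fit.dropped_columns,
        intercept=float(y.mean()),
    )


def report(fit: EnetFit, top: int | None = None) -> pd.DataFrame:
    """Ranked signed-coefficient table with region/data-type grouping columns
    for plotting, plus the R values as frame attributes."""
    nz = fit.coefficients[fit.coefficients != 0]
    nz = nz.reindex(nz.abs().sort_values(ascending=False).index)
    if top is not None:
        nz = nz.iloc[:top]
    parts = [c.split(":") if ":" in c else [c, "", ""] for c in nz.index]
    out = pd.DataFrame({
        "factor": nz.index,
        "coefficient": nz.to_numpy(),
        "datatype": [p[0] for p in parts],
        "region": [p[1] for p in parts],
        "kind": [p[2] for p in parts],
    })
    out.attrs["r_insample"] = fit.r_insample
    out.attrs["r_cv"] = fit.r_cv
    out.attrs["n_nonzero"] = int((fit.coefficients != 0).sum())
    return out
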