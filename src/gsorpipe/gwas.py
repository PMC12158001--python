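"""Single-trait mixed-model association with leave-one-chromosome-out.

Phenotype preparation follows the standard animal-model workflow: records
beyond k standard deviations of the trait mean are set missing (single
pass), phenotypes are pre-adjusted for fixed effects by OLS, heritability
comes from two-component REML on the genomic relationship matrix, and the
per-variant scan refits variance components with the test chromosome left
out of the GRM (LOCO) before estimating the allelic substitution effect by
generalized least squares.  Genomic inflation and Benjamini-Hochberg FDR
round out the stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .core import GRM, GenotypeMatrix, compute_grm
from .lmm import GEig, VarianceComponents, eigen_grm, gls_fixed_effects, reml_fit

__all__ = [
    "remove_outliers",
    "adjust_covariates",
    "build_design",
    "reml_heritability",
    "mlm_loco_scan",
    "genomic_inflation",
    "bh_adjust",
]

CHI2_NULL_MEDIAN = float(chi2.ppf(0.5, df=1))  # ~0.4549364


def remove_outliers(y: pd.Series | np.ndarray, k: float = 4.0) -> tuple[pd.Series, int]:
    """Set records beyond ``k`` SD of the mean to missing (single pass).

    Mean and SD (n-1 denominator) are computed once over the non-missing
    values; points with ``|y - mean| > k*SD`` are masked.  Returns the
    masked series and the exclusion count.
    """
    s = pd.Series(np.asarray(y, dtype=float)) if not isinstance(y, pd.Series) else y.astype(float)
    vals = s.dropna()
    if len(vals) < 3:
        raise ValueError("need >= 3 non-missing values")
    mu, sd = vals.mean(), vals.std(ddof=1)
    if sd == 0:
        return s.copy(), 0
    mask = (s - mu).abs() > k * sd
    out = s.where(~mask)
    return out, int(mask.sum())


def build_design(
    covariates: pd.DataFrame, categorical: list[str], add_intercept: bool = True
) -> np.ndarray:
    """Design matrix from covariates: factor columns dummy-coded (first
    level dropped), quantitative columns passed through."""
    cols = [np.ones((len(covariates), 1))] if add_intercept else []
    for c in covariates.columns:
        if c in categorical or not pd.api.types.is_numeric_dtype(covariates[c]):
            dummies = pd.get_dummies(covariates[c].astype(str), drop_first=True)
            if dummies.shape[1]:
                cols.append(dummies.to_numpy(dtype=float))
        else:
            cols.append(covariates[[c]].to_numpy(dtype=float))
    return np.hstack(cols) if cols else np.empty((len(covariates), 0))


def adjust_covariates(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of y on X plus an intercept.

    Raises on rank deficiency, naming the aliased columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    has_intercept = np.any(np.all(X == X[0:1, :], axis=0) & (X[0, :] != 0))
    design = X if has_intercept else np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        q, r = np.linalg.qr(design)
        aliased = list(np.flatnonzero(np.abs(np.diag(r)) < 1e-10))
        raise ValueError(f"rank-deficient design; aliased columns {aliased}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def reml_heritability(
    y: np.ndarray, grm: GRM, X: np.ndarray | None = None
) -> VarianceComponents:
    """Two-component REML heritability of one trait on a GRM."""
    return reml_fit(np.asarray(y, float), grm.matrix, X)


def mlm_loco_scan(
    g: GenotypeMatrix,
    y_adj: np.ndarray,
    grm_panel_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant mixed-model scan, GRM excluding the test chromosome.

    For each chromosome the GRM is rebuilt from the relationship panel
    minus that chromosome, variance components are re-estimated by REML,
    and each test variant's substitution effect is the GLS solution of
    ``y = mu + b x + g + e`` in the rotated basis.  Returns a frame with
    chrom, pos, id, beta, se, t, p, q.
    """
    y = np.asarray(y_adj, dtype=float)
    chroms = g.variants["chrom"].to_numpy()
    unique_chroms = list(pd.unique(chroms))
    if len(unique_chroms) < 2:
        raise ValueError("LOCO needs >= 2 chromosomes")
    panel_ids = set(grm_panel_ids) if grm_panel_ids is not None else set(g.variants["id"])

    rows = []
    for c in unique_chroms:
        off = (chroms != c) & g.variants["id"].isin(panel_ids).to_numpy()
        if not off.any():
            raise ValueError(f"no relationship-panel variants off chromosome {c}")
        grm_c = compute_grm(g.subset_variants(off))
        eig = eigen_grm(grm_c.matrix)
        vc = reml_fit(y, eig)
        d = vc.sigma_g2 * eig.values + vc.sigma_e2
        w = 1.0 / d
        yt = eig.rotate(y)
        ones_t = eig.rotate(np.ones_like(y))
        test = np.flatnonzero(chroms == c)
        Xt_all = eig.vectors.T @ g.dosages[:, test]
        s11 = float(np.sum(w * ones_t * ones_t))
        s1y = float(np.sum(w * ones_t * yt))
        s1x = (w * ones_t) @ Xt_all
        sxx = (w[:, None] * Xt_all * Xt_all).sum(axis=0)
        sxy = (w * yt) @ Xt_all
        det = s11 * sxx - s1x**2
        poly = g.dosages[:, test].std(axis=0) > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (s11 * sxy - s1x * s1y) / det
            var_b = s11 / det
        beta = np.where(poly, beta, np.nan)
        se = np.where(poly, np.sqrt(var_b), np.nan)
        t = beta / se
        p = chi2.sf(t**2, df=1)
        sub = g.variants.iloc[test]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "pos": sub["pos"].to_numpy(),
                    "id": sub["id"].to_numpy(),
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": p,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    # restore genomic order of the input panel
    order = {vid: i for i, vid in enumerate(g.variants["id"])}
    out = out.sort_values("id", key=lambda s: s.map(order)).reset_index(drop=True)
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return out


def genomic_inflation(p: np.ndarray) -> float:
    """lambda = median(chi2(p)) / null median of the 1-df chi-squared."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_NULL_MEDIAN)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
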