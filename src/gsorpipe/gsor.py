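"""Genetic score omics regression (GSOR).

For each gene and trait the response is the gene's local genomic value in
the expression cohort and the predictor is that gene's observed
expression, with a polygenic random effect on the cohort's relationship
matrix absorbing population structure:

    gebv_local = b1 * expression + b2 * covariates + g + e,
    g ~ N(0, G sigma_g2),  e ~ N(0, I sigma_e2).

Variance components are re-estimated per gene by REML on the rotated
model and b1 gets a Wald 1-df chi-squared p-value; per-trait
Benjamini-Hochberg adjustment flags hits at FDR <= 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import GRM, ExpressionMatrix
from .gwas import bh_adjust
from .lmm import ConvergenceError, GEig, eigen_grm, gls_fixed_effects, reml_fit

__all__ = ["gsor_gene_trait", "gsor_scan"]


def gsor_gene_trait(
    local: np.ndarray,
    omega: np.ndarray,
    X: np.ndarray | None,
    G: GRM | GEig,
) -> tuple[float, float, float]:
    """Mixed-model association of one gene's local score with its expression.

    Returns ``(b1, se, p)`` for the expression coefficient.  ``X`` holds
    additional fixed-effect columns (no intercept; one is added).
    """
    local = np.asarray(local, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if omega.std() == 0:
        raise ValueError("constant expression vector")
    n = local.size
    cols = [np.ones(n), omega]
    if X is not None and np.asarray(X).size:
        Xa = np.asarray(X, dtype=float)
        cols.extend(Xa.T if Xa.ndim == 2 else [Xa])
    design = np.column_stack(cols)
    eig = G if isinstance(G, GEig) else eigen_grm(G.matrix)
    vc = reml_fit(local, eig, design)
    beta, se = gls_fixed_effects(local, design, eig, vc.sigma_g2, vc.sigma_e2)
    b1, se1 = float(beta[1]), float(se[1])
    p = float(chi2.sf((b1 / se1) ** 2, df=1))
    return b1, se1, max(p, np.finfo(float).tiny)


def gsor_scan(
    local_table: pd.DataFrame,
    expr: ExpressionMatrix,
    X: np.ndarray | None,
    G: GRM,
    trait: str,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Run the per-gene regression for every gene with a local score.

    ``local_table`` is gene x sample (one trait's BayesR effects);
    samples are aligned to its column order.  Genes absent from the
    expression matrix, constant in expression, or failing REML are
    dropped from the tested set.  Returns gene, trait, b1, se, p, q, hit.
    """
    samples = list(local_table.columns)
    Gx = G.reorder(samples)
    eig = eigen_grm(Gx.matrix)
    expr_aligned = expr.values[samples]

    rows = []
    for gene_id, local in local_table.iterrows():
        if gene_id not in expr_aligned.index:
            continue
        omega = expr_aligned.loc[gene_id].to_numpy(dtype=float)
        if omega.std() == 0 or np.asarray(local).std() == 0:
            continue
        try:
            b1, se1, p = gsor_gene_trait(local.to_numpy(), omega, X, eig)
        except (ConvergenceError, np.linalg.LinAlgError):
            continue
        rows.append((gene_id, trait, b1, se1, p))
    out = pd.DataFrame(rows, columns=["gene", "trait", "b1", "se", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["hit"] = out["q"] <= fdr
    else:
        out["q"] = pd.Series(dtype=float)
        out["hit"] = pd.Series(dtype=bool)
    return out
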