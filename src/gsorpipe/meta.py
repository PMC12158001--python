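"""Multi-trait meta-analysis of single-trait association statistics.

Per-trait signed t-values are joined on variant id into a variant x trait
matrix T; the trait x trait correlation V is estimated over all variants;
and each variant's multi-trait statistic is the quadratic form
``chi2_i = t_i' V^{-1} t_i`` on n-trait degrees of freedom.  Correlated
traits are thereby combined without double-counting shared signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .gwas import bh_adjust

__all__ = ["build_t_matrix", "t_correlation", "meta_scan"]


def build_t_matrix(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Variant x trait matrix of signed t-values (inner join on variant id).

    ``results`` maps trait name to a per-trait scan frame with columns
    ``id, beta, se`` (``t`` recomputed as beta/se).  Variants missing in
    any trait are dropped.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 traits for a meta-analysis")
    cols = {}
    for trait, df in results.items():
        t = (df["beta"] / df["se"]).to_numpy()
        cols[trait] = pd.Series(t, index=df["id"].to_numpy())
    out = pd.DataFrame(cols).dropna()
    if out.empty:
        raise ValueError("no variants shared across all traits")
    first = next(iter(results.values()))
    order = {vid: i for i, vid in enumerate(first["id"])}
    out = out.loc[sorted(out.index, key=lambda v: order.get(v, len(order)))]
    out.index.name = "id"
    return out


def t_correlation(T: pd.DataFrame) -> np.ndarray:
    """Pearson trait x trait correlation of the signed t-values."""
    if len(T) < 3:
        raise ValueError("need >= 3 variants to estimate the trait correlation")
    sd = T.std(axis=0, ddof=1)
    zero = list(sd.index[sd == 0])
    if zero:
        raise ValueError(f"zero-variance t column(s): {zero}")
    return np.corrcoef(T.to_numpy(), rowvar=False)


def meta_scan(
    T: pd.DataFrame,
    V: np.ndarray | None = None,
    ridge: float = 0.0,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Quadratic-form meta statistic per variant with n-trait df.

    ``ridge`` adds ``ridge * I`` to V and renormalizes the diagonal to 1;
    with ridge 0 an ill-conditioned V (condition number > 1e10) is an
    error recommending regularization.  Returns chi2, df, p, q and a
    significance flag at ``q <= fdr``.
    """
    if V is None:
        V = t_correlation(T)
    V = np.asarray(V, dtype=float)
    n_traits = T.shape[1]
    if V.shape != (n_traits, n_traits):
        raise ValueError("V shape does not match trait count")
    if ridge > 0:
        V = V + ridge * np.eye(n_traits)
        d = np.sqrt(np.diag(V))
        V = V / np.outer(d, d)
    cond = np.linalg.cond(V)
    if cond > 1e10:
        raise ValueError(
            f"trait correlation matrix is ill-conditioned (cond={cond:.3g}); "
            "pass ridge > 0"
        )
    Vinv = np.linalg.inv(V)
    tm = T.to_numpy()
    stat = np.einsum("ij,jk,ik->i", tm, Vinv, tm)
    stat = np.maximum(stat, 0.0)
    p = chi2.sf(stat, df=n_traits)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "id": T.index.to_numpy(),
            "chi2": stat,
            "df": n_traits,
            "p": p,
            "q": q,
            "significant": q <= fdr,
        }
    )
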