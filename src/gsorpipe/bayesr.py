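"""BayesR mixture-model SNP effects and per-gene local genomic scores.

SNP effects are modelled as a four-component normal mixture with variances
(0, 1e-4, 1e-3, 1e-2) times the current genetic variance, sampled by
single-site Gibbs: per iteration each SNP's component indicator and effect
are drawn from their conditionals given the running residual, mixture
proportions from a Dirichlet, variance components from scaled
inverse-chi-squared conditionals, a polygenic remainder through the
eigendecomposition of the relationship matrix, and fixed effects by their
Gaussian conditional.  Posterior mean effects then score each gene's
local genomic value: the dosage-weighted sum of effects for SNPs within a
flank (default +-1 Mb) of the gene's TSS.

The per-SNP sweep is compiled with numba; the chain is deterministic
under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core import GRM, GeneAnnotation, GenotypeMatrix
from .lmm import eigen_grm

__all__ = ["MixtureSpec", "SNPEffectPosterior", "bayesr_fit", "local_gebv"]


@dataclass
class MixtureSpec:
    """Mixture grid, starting proportions and chain-length settings."""

    variance_scalars: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    start_props: tuple[float, ...] = (0.994, 0.0055, 0.00049, 0.00001)
    n_iter: int = 5000
    n_burnin: int = 2500
    seed: int = 0
    update_props: bool = True
    prior_df: float = 4.0

    def __post_init__(self) -> None:
        if len(self.variance_scalars) != len(self.start_props):
            raise ValueError("scalars and start proportions differ in length")
        if self.variance_scalars[0] != 0.0:
            raise ValueError("first mixture component must be the null (scalar 0)")
        if any(b < a for a, b in zip(self.variance_scalars, self.variance_scalars[1:])):
            raise ValueError("variance scalars must be non-decreasing")
        if abs(sum(self.start_props) - 1.0) > 1e-8:
            raise ValueError("start proportions must sum to 1")
        if not self.n_iter > self.n_burnin >= 0:
            raise ValueError("need n_iter > n_burnin >= 0")


@dataclass
class SNPEffectPosterior:
    """Posterior summaries of the SNP-effect chain."""

    variant_ids: list[str]
    effect_mean: np.ndarray  # posterior mean effect per SNP (trait units/allele)
    inclusion_prob: np.ndarray  # posterior mass in non-null components
    trace: pd.DataFrame  # per kept iteration: proportions, sigma_g2, sigma_e2, sigma_a2

    def effects_frame(self, variants: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {"id": self.variant_ids, "effect": self.effect_mean, "pip": self.inclusion_prob}
        )
        if variants is not None:
            out = variants[["chrom", "pos", "id"]].merge(out, on="id", how="right")
        return out


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _snp_sweep(genoT, xtx, r, g, comp, gammas, log_pi, sigma_e2, sigma_g2):
    """One Gibbs sweep over all SNPs; updates r, g, comp in place.

    Returns per-component counts and the sum of g^2/gamma over non-null
    components (the sufficient statistic for sigma_g2).
    """
    m = genoT.shape[0]
    k = gammas.shape[0]
    counts = np.zeros(k, dtype=np.int64)
    ss = 0.0
    logl = np.empty(k)
    for j in range(m):
        x = genoT[j]
        old = g[j]
        if old != 0.0:
            for i in range(r.shape[0]):
                r[i] += x[i] * old
        rhs = 0.0
        for i in range(r.shape[0]):
            rhs += x[i] * r[i]
        # marginal likelihood of each component
        best = -1e300
        for c in range(k):
            v = gammas[c] * sigma_g2
            if v <= 0.0:
                logl[c] = log_pi[c]
            else:
                denom = sigma_e2 + xtx[j] * v
                logl[c] = (
                    log_pi[c]
                    - 0.5 * np.log(denom / sigma_e2)
                    + 0.5 * rhs * rhs * v / (sigma_e2 * denom)
                )
            if logl[c] > best:
                best = logl[c]
        tot = 0.0
        for c in range(k):
            logl[c] = np.exp(logl[c] - best)
            tot += logl[c]
        u = np.random.random() * tot
        acc = 0.0
        pick = k - 1
        for c in range(k):
            acc += logl[c]
            if u <= acc:
                pick = c
                break
        comp[j] = pick
        counts[pick] += 1
        v = gammas[pick] * sigma_g2
        if v <= 0.0:
            g[j] = 0.0
        else:
            post_var = sigma_e2 * v / (xtx[j] * v + sigma_e2)
            post_mean = rhs * v / (xtx[j] * v + sigma_e2)
            new = post_mean + np.sqrt(post_var) * np.random.standard_normal()
            g[j] = new
            ss += new * new / gammas[pick]
            for i in range(r.shape[0]):
                r[i] -= x[i] * new
    return counts, ss


class DivergenceError(RuntimeError):
    pass


def bayesr_fit(
    y: np.ndarray,
    X: np.ndarray | None,
    g: GenotypeMatrix,
    A: GRM | None,
    spec: MixtureSpec,
) -> SNPEffectPosterior:
    """Gibbs sampler for the mixture SNP-effect model ``y = Xu + Vg + a + e``.

    Parameters
    ----------
    y
        Phenotype vector (complete cases, aligned with ``g.sample_ids``).
    X
        Fixed-effect design (defaults to an intercept).
    g
        Genotype panel (LD-pruned recommended).
    A
        Relationship matrix for the polygenic remainder ``a``; pass None to
        drop that term (sigma_a2 fixed at 0).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != g.n_samples:
        raise ValueError("phenotype and genotype sample counts differ")
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    rng = np.random.default_rng(spec.seed)
    _seed_numba(int(rng.integers(0, 2**31 - 1)))

    genoT = np.ascontiguousarray(g.dosages.T)
    m = genoT.shape[0]
    xtx = (genoT**2).sum(axis=1)
    gammas = np.asarray(spec.variance_scalars, dtype=float)
    k = gammas.size
    pi = np.asarray(spec.start_props, dtype=float)

    var_y = float(np.var(y, ddof=1))
    nu0 = spec.prior_df
    s0_e = 0.5 * var_y
    # genetic-variance prior anchored at h2 ~ 0.5: keeps the mixture variances
    # on a usable scale so the chain cannot freeze in an all-null state
    s0_g = 0.5 * var_y
    s0_a = 0.1 * var_y

    # state
    XtX = X.T @ X
    u = np.linalg.solve(XtX, X.T @ y)
    snp_eff = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    a = np.zeros(n)
    sigma_e2 = 0.5 * var_y
    sigma_g2 = 0.5 * var_y
    sigma_a2 = 0.1 * var_y if A is not None else 0.0
    r = y - X @ u

    if A is not None:
        eig = eigen_grm(A.matrix)
        pos = eig.values > 1e-8 * eig.values.max()
        lam_pos = eig.values[pos]
        U_pos = eig.vectors[:, pos]

    chol_fx = np.linalg.cholesky(np.linalg.inv(XtX))

    eff_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    kept = 0
    trace_rows = []
    log_pi_floor = -745.0  # exp underflows below this

    for it in range(spec.n_iter):
        with np.errstate(divide="ignore"):
            log_pi = np.log(pi)
        log_pi = np.maximum(log_pi, log_pi_floor)
        counts, ss = _snp_sweep(
            genoT, xtx, r, snp_eff, comp, gammas, log_pi, sigma_e2, sigma_g2
        )
        if not np.isfinite(r).all():
            raise DivergenceError(f"non-finite residuals at iteration {it}")

        if spec.update_props:
            pi = rng.dirichlet(counts + 1.0)

        m_nonzero = int(counts[1:].sum())
        df_g = nu0 + m_nonzero
        sigma_g2 = (ss + nu0 * s0_g) / rng.chisquare(df_g)

        if A is not None:
            ra = r + a
            rt = U_pos.T @ ra
            post_var = lam_pos * sigma_a2 * sigma_e2 / (lam_pos * sigma_a2 + sigma_e2)
            post_mean = post_var * rt / sigma_e2
            alpha = post_mean + np.sqrt(post_var) * rng.standard_normal(lam_pos.size)
            a = U_pos @ alpha
            r = ra - a
            ss_a = float(np.sum(alpha**2 / lam_pos))
            sigma_a2 = (ss_a + nu0 * s0_a) / rng.chisquare(nu0 + lam_pos.size)

        # fixed effects: flat prior Gaussian conditional
        r_fx = r + X @ u
        u_hat = np.linalg.solve(XtX, X.T @ r_fx)
        u = u_hat + np.sqrt(sigma_e2) * (chol_fx @ rng.standard_normal(u.size))
        r = r_fx - X @ u

        sigma_e2 = (float(r @ r) + nu0 * s0_e) / rng.chisquare(nu0 + n)
        if sigma_e2 < 1e-12 * var_y:
            raise DivergenceError(f"residual variance collapsed at iteration {it}")

        if it >= spec.n_burnin:
            kept += 1
            eff_sum += snp_eff
            incl_sum += comp > 0
            trace_rows.append(
                tuple(pi) + (sigma_g2, sigma_e2, sigma_a2)
            )

    trace = pd.DataFrame(
        trace_rows,
        columns=[f"prop_{i}" for i in range(k)] + ["sigma_g2", "sigma_e2", "sigma_a2"],
    )
    return SNPEffectPosterior(
        variant_ids=list(g.variants["id"]),
        effect_mean=eff_sum / kept,
        inclusion_prob=incl_sum / kept,
        trace=trace,
    )


def local_gebv(
    post: SNPEffectPosterior,
    g: GenotypeMatrix,
    ann: GeneAnnotation,
    flank: int = 1_000_000,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene local genomic value: sum of dosage x effect within the flank.

    For each gene, SNPs with position in ``[tss - flank, tss + flank]``
    (inclusive) on the gene's chromosome contribute; genes with no SNP in
    the window (or on an absent chromosome) are excluded and returned in
    the flagged list.

    Returns ``(table, flagged)`` where table is gene x sample.
    """
    eff = pd.Series(post.effect_mean, index=post.variant_ids)
    shared = g.variants["id"].isin(eff.index).to_numpy()
    panel = g.subset_variants(shared)
    effects = eff.loc[panel.variants["id"]].to_numpy()
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()

    rows, kept_genes, flagged = [], [], []
    for _, gene in ann.table.iterrows():
        in_win = (
            (chroms == gene["chrom"])
            & (pos >= gene["tss"] - flank)
            & (pos <= gene["tss"] + flank)
        )
        if not in_win.any():
            flagged.append(gene["gene_id"])
            continue
        rows.append(panel.dosages[:, in_win] @ effects[in_win])
        kept_genes.append(gene["gene_id"])
    table = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, panel.n_samples)),
        index=pd.Index(kept_genes, name="gene_id"),
        columns=panel.sample_ids,
    )
    return table, flagged
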