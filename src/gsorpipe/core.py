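"""Core data containers and genotype-panel operations.

The pipeline moves four kinds of data between stages: a dosage genotype
panel with variant metadata, per-sample phenotype tables with covariates,
gene-by-sample expression matrices, and gene annotation with a derived
transcription start site (TSS).  This module defines those containers plus
the panel-level operations every stage shares: variant QC (MAF,
Hardy-Weinberg, imputation accuracy), the VanRaden genomic relationship
matrix, and sliding-window LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "ExpressionMatrix",
    "GeneAnnotation",
    "GRM",
    "qc_filter_variants",
    "compute_grm",
    "ld_prune",
]

#: columns every variant-metadata frame carries, in order
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "imp_r2"]


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class GenotypeMatrix:
    """A sample x variant panel of allele dosages in [0, 2].

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per dosage row.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt, imp_r2``
        (``imp_r2`` may be all-NaN when the panel was not imputed).
        Positions are 1-based and strictly increasing within chromosome.
    dosages
        ``(n_samples, n_variants)`` float array of alternate-allele dosages.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.variants = self.variants.reset_index(drop=True)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise ValidationError("dosages outside [0, 2]")
        if (self.variants["pos"] < 1).any():
            raise ValidationError("positions must be 1-based (>= 1)")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant (dosage mean / 2)."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        """Return a new panel restricted to a boolean mask or list of variant ids."""
        if isinstance(mask_or_ids, (list, set, pd.Index)):
            keep = self.variants["id"].isin(set(mask_or_ids)).to_numpy()
        else:
            keep = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.loc[keep].reset_index(drop=True),
            dosages=self.dosages[:, keep],
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(
            sample_ids=list(ids),
            variants=self.variants.copy(),
            dosages=self.dosages[rows, :],
        )


@dataclass
class PhenotypeTable:
    """Per-sample trait values plus categorical/quantitative covariates.

    ``traits`` and ``covariates`` are indexed by sample id; missing trait
    values are NaN.  ``categorical`` names the covariate columns treated as
    factors when building design matrices.
    """

    traits: pd.DataFrame
    covariates: pd.DataFrame
    categorical: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.traits.index.equals(self.covariates.index):
            raise ValidationError("trait and covariate sample indexes differ")
        for t in self.traits.columns:
            if self.traits[t].notna().sum() < 1:
                raise ValidationError(f"trait {t} has no non-missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.traits.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression levels (TPM-like scale, arbitrary units)."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def drop_constant_genes(self) -> tuple["ExpressionMatrix", list[str]]:
        """Remove zero-variance genes; returns (filtered matrix, dropped ids)."""
        sd = self.values.std(axis=1, ddof=0)
        dropped = list(self.values.index[sd == 0])
        return ExpressionMatrix(self.values.loc[sd > 0]), dropped


@dataclass
class GeneAnnotation:
    """Gene coordinates with a strand-aware transcription start site.

    The table has columns ``gene_id, chrom, start, end, strand``; ``tss``
    is derived as ``start`` on the + strand (or when strand is unknown)
    and ``end`` on the - strand.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if (t["start"] > t["end"]).any():
            raise ValidationError("gene start > end")
        if (t["start"] < 1).any():
            raise ValidationError("coordinates must be 1-based")
        if t["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")
        tss = np.where(t["strand"] == "-", t["end"], t["start"])
        t = t.assign(tss=tss)
        object.__setattr__(self, "table", t)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


@dataclass
class GRM:
    """Genomic relationship matrix over a fixed sample ordering."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValidationError("GRM shape does not match sample count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValidationError("GRM is not symmetric")

    def reorder(self, ids: list[str]) -> "GRM":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([index[s] for s in ids])
        return GRM(list(ids), self.matrix[np.ix_(rows, rows)])


# ---------------------------------------------------------------------------
# panel operations


def _hwe_chi2_p(dosages: np.ndarray) -> np.ndarray:
    """1-df chi-squared HWE p per variant from hard-called genotype counts.

    Dosages are rounded to the nearest integer for this test only.
    Monomorphic variants get p = 1 (no departure testable).
    """
    from scipy.stats import chi2

    hard = np.rint(dosages).astype(np.int64)
    n = hard.shape[0]
    n_alt_hom = (hard == 2).sum(axis=0)
    n_het = (hard == 1).sum(axis=0)
    p_hat = (2 * n_alt_hom + n_het) / (2.0 * n)
    q_hat = 1.0 - p_hat
    exp = np.stack([n * q_hat**2, 2 * n * p_hat * q_hat, n * p_hat**2])
    obs = np.stack([(hard == 0).sum(axis=0), n_het, n_alt_hom]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pvals = chi2.sf(stat, df=1)
    poly = (p_hat > 0) & (p_hat < 1)
    return np.where(poly, pvals, 1.0)


def qc_filter_variants(
    g: GenotypeMatrix,
    min_maf: float = 0.01,
    max_hwe_chi2_p: float = 1e-6,
    min_imp_r2: float = 0.5,
) -> GenotypeMatrix:
    """Standard variant QC: MAF, Hardy-Weinberg, imputation accuracy.

    Keeps variants with MAF >= ``min_maf``, HWE 1-df chi-squared
    p >= ``max_hwe_chi2_p`` and imputation R^2 >= ``min_imp_r2``
    (the R^2 test is skipped for variants whose field is missing).
    Boundary values are kept; input order is preserved.
    """
    for name, v in [
        ("min_maf", min_maf),
        ("max_hwe_chi2_p", max_hwe_chi2_p),
        ("min_imp_r2", min_imp_r2),
    ]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    keep = g.maf() >= min_maf
    keep &= _hwe_chi2_p(g.dosages) >= max_hwe_chi2_p
    r2 = g.variants["imp_r2"].to_numpy(dtype=float)
    has_r2 = ~np.isnan(r2)
    keep &= ~has_r2 | (r2 >= min_imp_r2)
    if not keep.any():
        raise ValidationError(
            "QC removed every variant; relax min_maf / max_hwe_chi2_p / min_imp_r2"
        )
    return g.subset_variants(keep)


def compute_grm(g: GenotypeMatrix, variant_ids: list[str] | None = None) -> GRM:
    """VanRaden method-1 GRM with panel-estimated allele frequencies.

    Dosages are centered by twice the panel allele frequency and the
    cross-product is scaled by ``2 * sum(p(1-p))`` over the variants used.
    """
    panel = g if variant_ids is None else g.subset_variants(variant_ids)
    p = panel.allele_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 1:
        raise ValidationError("all variants are monomorphic; cannot build a GRM")
    z = panel.dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return GRM(list(panel.sample_ids), (z @ z.T) / denom)


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 5000,
    step_snps: int = 500,
    r2_max: float = 0.95,
) -> list[str]:
    """Greedy sliding-window pairwise LD pruning on dosage correlation.

    Within each window of ``window_snps`` variants (slid by ``step_snps``,
    per chromosome), while any retained pair has squared dosage correlation
    above ``r2_max``, the member with smaller MAF is dropped (tie: the later
    position).  Retained variant ids are returned in genomic order.
    """
    if not window_snps >= step_snps >= 1:
        raise ValueError("need window_snps >= step_snps >= 1")
    maf = g.maf()
    keep = np.ones(g.n_variants, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step_snps):
            win = idx[start : start + window_snps]
            _prune_window(g.dosages, maf, keep, win, r2_max)
            if start + window_snps >= len(idx):
                break
    return list(g.variants.loc[keep, "id"])


def _prune_window(
    dosages: np.ndarray,
    maf: np.ndarray,
    keep: np.ndarray,
    win: np.ndarray,
    r2_max: float,
) -> None:
    """Drop in-window pairs with r^2 > r2_max until none remain."""
    active = [j for j in win if keep[j]]
    if len(active) < 2:
        return
    sub = dosages[:, active]
    sd = sub.std(axis=0)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub, rowvar=False)
    r2 = np.where(np.outer(ok, ok), r**2, 0.0)
    np.fill_diagonal(r2, 0.0)
    alive = np.ones(len(active), dtype=bool)
    while True:
        r2a = np.where(np.outer(alive, alive), r2, 0.0)
        i, j = np.unravel_index(np.argmax(r2a), r2a.shape)
        if r2a[i, j] <= r2_max:
            break
        lo, hi = (i, j) if active[i] < active[j] else (j, i)
        # drop smaller-MAF member; on a tie, the later genomic position
        drop_local = hi if maf[active[hi]] <= maf[active[lo]] else lo
        alive[drop_local] = False
    for local, j in enumerate(active):
        keep[j] = alive[local]
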