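"""Genome windowing, GWAS-marked windows, and exact 2x2 overlap/enrichment.

The genome is cut into fixed-width non-overlapping windows (1-based,
inclusive, final partial window kept).  A window is "GWAS-marked" when it
contains at least one meta-significant variant.  Two Fisher-exact
procedures follow: (1) are expression-association hits over-represented
inside marked windows (genes assigned by their start coordinate), and
(2) are the hits inside marked windows enriched for an ontology term
relative to all tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats.contingency import odds_ratio as _scipy_cmle_or

from .core import GeneAnnotation

__all__ = [
    "WindowPartition",
    "Contingency2x2",
    "EnrichmentResult",
    "partition_genome",
    "mark_windows",
    "assign_genes",
    "fisher_exact_2x2",
    "overlap_test",
    "term_enrichment",
    "truncate2",
]


@dataclass
class WindowPartition:
    """Non-overlapping fixed-width windows with a marked flag per window."""

    windows: pd.DataFrame  # chrom, start, end, index
    width: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_marked(self) -> int:
        return int(self.windows["marked"].sum()) if "marked" in self.windows else 0

    def to_bed(self, path, marked_only: bool = True) -> None:
        """Write windows as BED (0-based half-open) for browser inspection."""
        w = self.windows
        if marked_only and "marked" in w:
            w = w[w["marked"]]
        out = pd.DataFrame(
            {"chrom": w["chrom"], "start": w["start"] - 1, "end": w["end"]}
        )
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class Contingency2x2:
    """Cell counts (a, b) / (c, d), all non-negative, total >= 1."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cell counts must be non-negative integers: {cells}")
        if sum(cells) < 1:
            raise ValueError("empty table")
        self.a, self.b, self.c, self.d = (int(x) for x in cells)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    table: Contingency2x2
    p_two_sided: float
    odds_ratio: float  # cross-product ad/bc
    odds_ratio_cmle: float  # conditional maximum likelihood

    @property
    def display_or(self) -> float:
        """Two-decimal display convention: conditional-MLE OR, truncated."""
        return truncate2(self.odds_ratio_cmle)


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, the headline display rule."""
    if not np.isfinite(x):
        return x
    return np.trunc(x * 100.0) / 100.0


def partition_genome(chrom_lengths: dict[str, int], width: int) -> WindowPartition:
    """Fixed-width windows [1, W], [W+1, 2W], ... per chromosome."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    rows = []
    idx = 0
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        start = 1
        while start <= length:
            rows.append((chrom, start, min(start + width - 1, length), idx))
            idx += 1
            start += width
    return WindowPartition(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "index"]), width
    )


def _window_index(part: WindowPartition, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Window index per (chrom, pos); -1 when the coordinate is out of range."""
    w = part.windows
    base = {}
    limit = {}
    for c, sub in w.groupby("chrom", sort=False):
        base[c] = int(sub["index"].iloc[0])
        limit[c] = int(sub["end"].max())
    out = np.full(len(pos), -1, dtype=np.int64)
    for i, (c, p) in enumerate(zip(chrom, pos)):
        if c in base and 1 <= p <= limit[c]:
            out[i] = base[c] + (int(p) - 1) // part.width
    return out


def mark_windows(
    part: WindowPartition, meta: pd.DataFrame, variants: pd.DataFrame, fdr: float = 0.10
) -> WindowPartition:
    """Flag windows containing >= 1 meta-significant variant (q <= fdr).

    ``meta`` carries id and q; ``variants`` maps id to chrom and pos.
    A significant variant outside every window is a coordinate mismatch.
    """
    coords = variants.set_index("id")[["chrom", "pos"]]
    sig = meta.loc[meta["q"] <= fdr, "id"]
    sub = coords.loc[coords.index.intersection(sig)]
    idx = _window_index(part, sub["chrom"].to_numpy(), sub["pos"].to_numpy())
    if (idx < 0).any():
        bad = sub.index[idx < 0][0]
        raise ValueError(f"variant {bad} falls outside every window (coordinate mismatch)")
    marked = np.zeros(part.n_windows, dtype=bool)
    marked[idx] = True
    w = part.windows.copy()
    w["marked"] = marked
    return WindowPartition(w, part.width)


def assign_genes(part: WindowPartition, ann: GeneAnnotation) -> pd.Series:
    """Map each gene to the window containing its start coordinate.

    Genes on chromosomes absent from the partition are excluded (returned
    map simply omits them).
    """
    t = ann.table
    idx = _window_index(part, t["chrom"].to_numpy(), t["start"].to_numpy())
    keep = idx >= 0
    return pd.Series(idx[keep], index=t.loc[keep, "gene_id"], name="window")


def fisher_exact_2x2(t: Contingency2x2, compute_cmle: bool = True) -> EnrichmentResult:
    """Two-sided Fisher exact test with both odds-ratio conventions.

    p sums hypergeometric point probabilities <= that of the observed
    table (the minimum-likelihood two-sided convention).  The
    cross-product OR is ad/bc (inf when bc = 0 and ad > 0, NaN for 0/0);
    the conditional-MLE OR maximizes the noncentral hypergeometric
    likelihood (skipped, reported NaN, when ``compute_cmle`` is False —
    it costs far more than the p-value).
    """
    arr = t.as_array()
    _, p = _scipy_fisher(arr, alternative="two-sided")
    ad, bc = t.a * t.d, t.b * t.c
    if bc > 0:
        cross = ad / bc
    elif ad > 0:
        cross = float("inf")
    else:
        cross = float("nan")
    if compute_cmle:
        cmle = float(_scipy_cmle_or(arr, kind="conditional").statistic)
    else:
        cmle = float("nan")
    return EnrichmentResult(t, float(min(p, 1.0)), float(cross), cmle)


def overlap_test(
    hits: set[str],
    tested: set[str],
    assignment: pd.Series,
    part: WindowPartition,
) -> tuple[EnrichmentResult, dict]:
    """Are hit genes over-represented inside marked windows?

    Builds the (hit vs non-hit tested gene) x (in marked window vs not)
    table over genes present in the assignment, and reports the headline
    counts alongside the exact test.
    """
    if not hits <= tested:
        raise ValueError("hits must be a subset of tested genes")
    marked_idx = set(part.windows.loc[part.windows.get("marked", False), "index"])
    genes = [g for g in tested if g in assignment.index]
    in_marked = {g for g in genes if assignment[g] in marked_idx}
    a = len([g for g in genes if g in hits and g in in_marked])
    b = len([g for g in genes if g in hits and g not in in_marked])
    c = len([g for g in genes if g not in hits and g in in_marked])
    d = len(genes) - a - b - c
    result = fisher_exact_2x2(Contingency2x2(a, b, c, d))
    summary = {
        "total_windows": part.n_windows,
        "marked_windows": part.n_marked,
        "hits_in_marked": a,
        "total_hits": a + b,
        "tested_genes": len(genes),
        "genes_in_marked": a + c,
    }
    return result, summary


def term_enrichment(
    hits_in_marked: set[str],
    background: set[str],
    membership: pd.DataFrame,
    term: str,
) -> EnrichmentResult:
    """Is an ontology term over-represented among hits in marked windows?

    The comparison group is ALL tested genes of the tissue (hits are not
    removed from the background), mirroring the headline procedure whose
    printed margins overlap.  ``membership`` is a gene_id/term frame.
    """
    if term not in set(membership["term"]):
        raise ValueError(f"term {term!r} absent from the membership table")
    in_term = set(membership.loc[membership["term"] == term, "gene_id"])
    a = len(hits_in_marked & in_term)
    b = len(hits_in_marked - in_term)
    c = len(background & in_term)
    d = len(background - in_term)
    return fisher_exact_2x2(Contingency2x2(a, b, c, d))
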