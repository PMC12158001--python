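"""End-to-end orchestration: QC -> GWAS -> meta -> BayesR -> GSOR -> overlap.

``run_all`` drives every stage on an in-memory study (typically from the
synthetic-cohort generator, or assembled from files by the CLI), writes
stage outputs as self-describing TSVs plus a JSON report of all counts,
odds ratios and p-values, and logs provenance (seed, thresholds).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas as gw
from .bayesr import MixtureSpec, bayesr_fit, local_gebv
from .core import compute_grm, ld_prune, qc_filter_variants
from .gsor import gsor_scan
from .meta import build_t_matrix, meta_scan, t_correlation
from .simulate import SimData
from .windows import (
    assign_genes,
    mark_windows,
    overlap_test,
    partition_genome,
    term_enrichment,
)

log = logging.getLogger("gsorpipe")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All thresholds and settings of the pipeline (YAML-serializable)."""

    gwas_fdr: float = 0.10
    gsor_fdr: float = 0.01
    maf: float = 0.01
    hwe_p: float = 1e-6
    imp_r2: float = 0.5
    outlier_sd: float = 4.0
    flank_bp: int = 1_000_000
    window_kb: tuple[int, ...] = (100, 500)
    ld_window: int = 5000
    ld_step: int = 500
    ld_r2: float = 0.95
    meta_ridge: float = 0.0
    term: str = "lipid_metabolism"
    mixture: MixtureSpec = field(default_factory=MixtureSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v, lo, hi in [
            ("gwas_fdr", self.gwas_fdr, 0, 1),
            ("gsor_fdr", self.gsor_fdr, 0, 1),
            ("maf", self.maf, 0, 0.5),
            ("hwe_p", self.hwe_p, 0, 1),
            ("imp_r2", self.imp_r2, 0, 1),
            ("ld_r2", self.ld_r2, 0, 1),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.outlier_sd <= 0 or self.flank_bp < 1:
            raise ValueError("outlier_sd must be > 0 and flank_bp >= 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mixture" in d and isinstance(d["mixture"], dict):
            mx = d["mixture"]
            for key in ("variance_scalars", "start_props"):
                if key in mx:
                    mx[key] = tuple(mx[key])
            d["mixture"] = MixtureSpec(**mx)
        if "window_kb" in d:
            d["window_kb"] = tuple(d["window_kb"])
        return cls(**d)


def _prepare_trait(pheno, trait, cfg):
    """Outlier removal + OLS covariate adjustment; complete cases only."""
    y, n_out = gw.remove_outliers(pheno.traits[trait], k=cfg.outlier_sd)
    keep = y.notna().to_numpy()
    X = gw.build_design(pheno.covariates.loc[keep], pheno.categorical)
    y_adj = gw.adjust_covariates(y.to_numpy()[keep], X)
    return y_adj, keep, n_out


def run_all(
    data: SimData,
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> dict:
    """Execute every stage in order and return the report dictionary.

    Stage order: variant QC -> per-trait heritability and LOCO GWAS ->
    multi-trait meta-analysis -> LD pruning and per-trait BayesR ->
    local genomic scores on the expression cohort -> per-trait GSOR ->
    window partition, marking, overlap and term enrichment.  When
    ``data.expression`` is empty the expression stages are skipped with a
    logged notice.  Failures abort with the stage name; previously
    written outputs remain on disk.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    report: dict = {
        "seed": cfg.seed,
        "version": __version__,
        "thresholds": _threshold_dict(cfg),
    }
    stage = "qc"
    try:
        g_gwas = qc_filter_variants(
            data.genotypes_gwas, cfg.maf, cfg.hwe_p, cfg.imp_r2
        )
        g_expr = data.genotypes_expr.subset_variants(list(g_gwas.variants["id"]))
        log.info("QC kept %d/%d variants", g_gwas.n_variants, data.genotypes_gwas.n_variants)
        report["qc"] = {
            "variants_in": data.genotypes_gwas.n_variants,
            "variants_kept": g_gwas.n_variants,
        }

        stage = "gwas"
        grm = compute_grm(g_gwas)
        scans, herit = {}, {}
        for trait in data.phenotypes.trait_names:
            y_adj, keep, n_out = _prepare_trait(data.phenotypes, trait, cfg)
            g_t = (
                g_gwas if keep.all()
                else g_gwas.subset_samples(list(np.array(g_gwas.sample_ids)[keep]))
            )
            vc = gw.reml_heritability(y_adj, grm if keep.all() else compute_grm(g_t))
            scan = gw.mlm_loco_scan(g_t, y_adj)
            lam = gw.genomic_inflation(scan["p"].dropna().to_numpy())
            herit[trait] = {
                "h2": vc.h2, "se_h2": vc.se_h2, "lambda": lam, "outliers_removed": n_out,
            }
            scans[trait] = scan
            if out is not None:
                scan.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
            log.info("GWAS %s: h2=%.3f lambda=%.3f", trait, vc.h2, lam)
        report["heritability"] = herit

        stage = "meta"
        T = build_t_matrix(scans)
        V = t_correlation(T)
        meta = meta_scan(T, V, ridge=cfg.meta_ridge, fdr=cfg.gwas_fdr)
        report["meta"] = {
            "variants": int(len(meta)),
            "significant": int(meta["significant"].sum()),
        }
        if out is not None:
            coords = g_gwas.variants[["chrom", "pos", "id"]]
            coords.merge(meta, on="id").to_csv(out / "meta.tsv", sep="\t", index=False)
        log.info("meta: %d significant of %d", report["meta"]["significant"], len(meta))

        stage = "bayesr"
        pruned_ids = ld_prune(g_gwas, cfg.ld_window, cfg.ld_step, cfg.ld_r2)
        g_pruned = g_gwas.subset_variants(pruned_ids)
        g_expr_pruned = g_expr.subset_variants(pruned_ids)
        report["ld_prune"] = {"kept": len(pruned_ids)}
        local_tables = {}
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
        for i, trait in enumerate(data.phenotypes.trait_names):
            y, _ = gw.remove_outliers(data.phenotypes.traits[trait], k=cfg.outlier_sd)
            keep = y.notna().to_numpy()
            g_t = g_pruned if keep.all() else g_pruned.subset_samples(
                list(np.array(g_pruned.sample_ids)[keep])
            )
            X = gw.build_design(data.phenotypes.covariates.loc[keep], data.phenotypes.categorical)
            spec = replace(cfg.mixture, seed=int(rng.integers(0, 2**31 - 1)))
            post = bayesr_fit(y.to_numpy()[keep], X, g_t, compute_grm(g_t), spec)
            if out is not None:
                post.effects_frame(g_pruned.variants).to_csv(
                    out / f"bayesr_{trait}.tsv", sep="\t", index=False
                )
            stage = "local_gebv"
            table, flagged = local_gebv(post, g_expr_pruned, data.annotation, cfg.flank_bp)
            local_tables[trait] = table
            if i == 0:
                report["local_gebv"] = {
                    "genes_scored": int(len(table)), "genes_flagged": len(flagged),
                }
            stage = "bayesr"

        stage = "gsor"
        if data.expression.values.empty:
            log.info("no expression data: skipping GSOR and overlap stages")
            report["gsor"] = None
            return _finalize(report, out)
        grm_expr = compute_grm(g_expr_pruned)
        X_expr = gw.build_design(
            data.expr_covariates, categorical=["experiment"], add_intercept=False
        ) if len(data.expr_covariates.columns) else None
        gsor_frames = []
        for trait, table in local_tables.items():
            res = gsor_scan(table, data.expression, X_expr, grm_expr, trait, cfg.gsor_fdr)
            gsor_frames.append(res)
        gsor_all = pd.concat(gsor_frames, ignore_index=True)
        hits = set(gsor_all.loc[gsor_all["hit"], "gene"])
        tested = set(gsor_all["gene"])
        report["gsor"] = {
            "genes_tested": len(tested),
            "hit_genes": len(hits),
            "hit_gene_list": sorted(hits),
            "hits_per_trait": {
                t: int(d["hit"].sum()) for t, d in gsor_all.groupby("trait")
            },
        }
        if out is not None:
            gsor_all.to_csv(out / "gsor.tsv", sep="\t", index=False)
        log.info("GSOR: %d hit genes of %d tested", len(hits), len(tested))

        stage = "overlap"
        if chrom_lengths is None:
            chrom_lengths = _infer_chrom_lengths(data)
        coords = g_gwas.variants[["chrom", "pos", "id"]]
        report["overlap"] = {}
        for wkb in cfg.window_kb:
            part = partition_genome(chrom_lengths, wkb * 1000)
            part = mark_windows(part, meta, coords, fdr=cfg.gwas_fdr)
            assignment = assign_genes(part, data.annotation)
            res, counts = overlap_test(hits, tested, assignment, part)
            hits_in_marked = {
                g for g in hits
                if g in assignment.index
                and assignment[g] in set(part.windows.loc[part.windows["marked"], "index"])
            }
            enr = term_enrichment(hits_in_marked, tested, data.membership, cfg.term)
            report["overlap"][f"{wkb}kb"] = {
                "counts": counts,
                "overlap_p": res.p_two_sided,
                "overlap_or": res.odds_ratio,
                "overlap_or_cmle": res.odds_ratio_cmle,
                "enrichment_table": vars(enr.table),
                "enrichment_p": enr.p_two_sided,
                "enrichment_or": enr.odds_ratio,
                "enrichment_or_cmle": enr.odds_ratio_cmle,
            }
            if out is not None:
                part.to_bed(out / f"marked_windows_{wkb}kb.bed")
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        raise
    return _finalize(report, out)


def _threshold_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["mixture"] = asdict(cfg.mixture)
    return d


def _infer_chrom_lengths(data: SimData) -> dict[str, int]:
    """Upper-bound chromosome lengths from variant and gene coordinates."""
    v = data.genotypes_gwas.variants.groupby("chrom", sort=False)["pos"].max()
    g = data.annotation.table.groupby("chrom", sort=False)["end"].max()
    lengths = v.to_dict()
    for c, e in g.items():
        lengths[c] = max(int(lengths.get(c, 0)), int(e))
    return {c: int(l) for c, l in lengths.items()}


def _finalize(report: dict, out: Path | None) -> dict:
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        log.info("report written to %s", out / "report.json")
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
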