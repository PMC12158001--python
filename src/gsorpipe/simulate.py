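"""Synthetic cohorts with the structure the pipeline assumes.

The generator emulates a dairy-cattle style design at desk scale: a
genotyped GWAS cohort with quantitative milk-lipid-like traits, a disjoint
expression reference cohort drawn from the same population, block-LD
genotypes from a founder-haplotype mosaic, cis-eQTLs within 1 Mb of gene
TSSs, traits mediated by the genetic component of expression plus direct
QTLs and a diffuse polygenic background, and ground-truth labels for
parameter-recovery tests.

LD arises because every sample haplotype is a mosaic of a small founder
pool: nearby variants ride on shared founder segments, and correlation
decays with distance as recombination breakpoints accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneAnnotation, GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimData",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_expression",
    "simulate_traits",
    "simulate_cohort",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults give a desk-scale analogue of the real design (hundreds of
    cows, a few chromosomes, tens of genes, six traits with heritabilities
    spanning the 0.07-0.7 range).
    """

    n_gwas: int = 400
    n_expr: int = 150
    chrom_spec: tuple[tuple[str, int], ...] = (
        ("1", 5_000_000),
        ("2", 5_000_000),
        ("3", 5_000_000),
    )
    n_variants_per_chrom: int = 2000
    n_genes: int = 60
    n_founder_haplotypes: int = 12
    recomb_per_bp: float = 5e-6  # expected breakpoints per bp; LD decays over ~200 kb
    h2: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.55, 0.7)
    mediating_gene_count: int = 5
    direct_qtl_count: int = 3
    n_confounded: int = 1
    confound_r: float = 0.5
    eqtl_effect_sd: float = 1.0
    mediation_effect_sd: float = 0.5
    direct_effect_sd: float = 0.4
    polygenic_effect_sd: float = 0.02
    n_polygenic: int = 300
    n_batches: int = 9  # combined batch-year factor in the GWAS cohort
    batch_effect_sd: float = 0.5
    n_experiments: int = 5  # sampling-time factor in the expression cohort
    expr_covariate_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for h in self.h2:
            if not 0 <= h <= 1:
                raise ValueError(f"h2 {h} outside [0, 1]")

    @property
    def n_traits(self) -> int:
        return len(self.h2)

    @property
    def trait_names(self) -> list[str]:
        return [f"PL{i + 1}" for i in range(self.n_traits)]


@dataclass
class MediatingGene:
    gene_id: str
    eqtl_variant: str
    eqtl_beta: float
    trait_effects: dict[str, float]


@dataclass
class TruthSet:
    """Ground-truth labels emitted alongside the synthetic cohort."""

    mediating: list[MediatingGene] = field(default_factory=list)
    direct_qtls: dict[str, dict[str, float]] = field(default_factory=dict)
    confounded: list[tuple[str, str, float]] = field(default_factory=list)  # (gene, partner, r)
    realized_h2: dict[str, float] = field(default_factory=dict)

    @property
    def mediating_gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.mediating]

    def to_dict(self) -> dict:
        return {
            "mediating": [
                {
                    "gene_id": m.gene_id,
                    "eqtl_variant": m.eqtl_variant,
                    "eqtl_beta": m.eqtl_beta,
                    "trait_effects": m.trait_effects,
                }
                for m in self.mediating
            ],
            "direct_qtls": self.direct_qtls,
            "confounded": [list(c) for c in self.confounded],
            "realized_h2": self.realized_h2,
        }


@dataclass
class SimData:
    """Everything one synthetic study produces."""

    genotypes_gwas: GenotypeMatrix
    genotypes_expr: GenotypeMatrix
    annotation: GeneAnnotation
    expression: ExpressionMatrix
    phenotypes: PhenotypeTable
    expr_covariates: pd.DataFrame
    membership: pd.DataFrame
    truth: TruthSet


# ---------------------------------------------------------------------------


def _mosaic_haplotypes(rng, founders, positions, rate, n_hap):
    """Sample n_hap mosaic haplotypes from the founder pool."""
    n_var = founders.shape[1]
    gaps = np.diff(positions, prepend=positions[0])
    p_switch = 1.0 - np.exp(-rate * gaps)
    out = np.empty((n_hap, n_var), dtype=np.int8)
    for h in range(n_hap):
        switches = rng.random(n_var) < p_switch
        switches[0] = True
        seg_id = np.cumsum(switches) - 1
        founder_per_seg = rng.integers(0, founders.shape[0], size=seg_id[-1] + 1)
        out[h] = founders[founder_per_seg[seg_id], np.arange(n_var)]
    return out


def simulate_genotypes(
    cfg: SimConfig, n_samples: int, rng: np.random.Generator, prefix: str = "S"
) -> GenotypeMatrix:
    """Founder-haplotype mosaic dosage panel; deterministic under the rng state."""
    all_blocks, var_rows = [], []
    for chrom, length in cfg.chrom_spec:
        n_var = cfg.n_variants_per_chrom
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_var, replace=False))
        freqs = rng.uniform(0.1, 0.9, size=n_var)
        founders = (rng.random((cfg.n_founder_haplotypes, n_var)) < freqs).astype(np.int8)
        haps = _mosaic_haplotypes(rng, founders, pos, cfg.recomb_per_bp, 2 * n_samples)
        dosage = haps[0::2].astype(np.float64) + haps[1::2]
        all_blocks.append(dosage)
        for p in pos:
            var_rows.append((chrom, int(p), f"{chrom}:{int(p)}", "A", "B", np.nan))
    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "id", "ref", "alt", "imp_r2"]
    )
    sample_ids = [f"{prefix}{i + 1:04d}" for i in range(n_samples)]
    return GenotypeMatrix(sample_ids, variants, np.hstack(all_blocks))


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator) -> GeneAnnotation:
    """Genes placed uniformly along the simulated chromosomes."""
    rows = []
    per_chrom = np.array_split(np.arange(cfg.n_genes), len(cfg.chrom_spec))
    for (chrom, length), idx in zip(cfg.chrom_spec, per_chrom):
        starts = np.sort(rng.integers(1, max(2, length - 60_000), size=len(idx)))
        for g, start in zip(idx, starts):
            span = int(rng.integers(5_000, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"GENE{g + 1:03d}", chrom, int(start),
                         min(int(start) + span, length), strand))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def _cis_variant(g: GenotypeMatrix, chrom: str, tss: int, flank: int, min_maf: float):
    """Index of the variant nearest the TSS within +-flank with MAF >= min_maf."""
    v = g.variants
    maf = g.maf()
    ok = (
        (v["chrom"] == chrom)
        & (v["pos"] >= tss - flank)
        & (v["pos"] <= tss + flank)
        & (maf >= min_maf)
    ).to_numpy()
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    return idx[np.argmin(np.abs(v["pos"].to_numpy()[idx] - tss))]


def simulate_expression(
    g_expr: GenotypeMatrix,
    ann: GeneAnnotation,
    cfg: SimConfig,
    rng: np.random.Generator,
    flank: int = 1_000_000,
) -> tuple[ExpressionMatrix, TruthSet]:
    """cis-eQTL-driven expression for the expression cohort.

    Mediating genes get ``expression = beta * dosage(cis variant) + N(0,1)``;
    the remaining genes are noise, except for ``n_confounded`` genes whose
    expression is forced to correlate (target r) with a mediating gene's,
    emulating the LD/coexpression false-hit mode of expression-based
    prioritization.
    """
    truth = TruthSet()
    genes = ann.table
    expr = rng.standard_normal((len(genes), g_expr.n_samples))

    # choose mediating genes spread across chromosomes, each with a usable cis variant
    candidates = []
    for i, row in genes.iterrows():
        j = _cis_variant(g_expr, row["chrom"], int(row["tss"]), flank, min_maf=0.15)
        if j is not None:
            candidates.append((i, j))
    if len(candidates) < cfg.mediating_gene_count:
        raise ValueError("not enough genes with a cis variant within the flank")
    order = rng.permutation(len(candidates))
    chosen, used_chrom_counts = [], {}
    for k in order:  # round-robin-ish across chromosomes for spread
        i, j = candidates[k]
        c = genes.iloc[i]["chrom"]
        if used_chrom_counts.get(c, 0) >= int(np.ceil(cfg.mediating_gene_count / len(cfg.chrom_spec))) + 1:
            continue
        chosen.append((i, j))
        used_chrom_counts[c] = used_chrom_counts.get(c, 0) + 1
        if len(chosen) == cfg.mediating_gene_count:
            break

    for i, j in chosen:
        beta = float(
            cfg.eqtl_effect_sd * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        )
        dose = g_expr.dosages[:, j]
        expr[i] = beta * dose + rng.standard_normal(g_expr.n_samples)
        effects = {
            t: float(cfg.mediation_effect_sd * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0]))
            for t in cfg.trait_names
        }
        truth.mediating.append(
            MediatingGene(genes.iloc[i]["gene_id"], g_expr.variants.iloc[j]["id"],
                          beta, effects)
        )

    # confounded genes sit next to a mediating gene (overlapping local windows),
    # the coexpression/LD false-hit mode of expression-based prioritization
    mediating_rows = [i for i, _ in chosen]
    free = [i for i in range(len(genes)) if i not in mediating_rows]
    used_free: set[int] = set()
    for k in range(min(cfg.n_confounded, len(free), len(mediating_rows))):
        partner_row = mediating_rows[k % len(mediating_rows)]
        p_chrom = genes.iloc[partner_row]["chrom"]
        p_tss = genes.iloc[partner_row]["tss"]
        candidates_near = [
            i for i in free
            if i not in used_free and genes.iloc[i]["chrom"] == p_chrom
        ]
        if not candidates_near:
            candidates_near = [i for i in free if i not in used_free]
        row = min(candidates_near, key=lambda i: abs(genes.iloc[i]["tss"] - p_tss))
        used_free.add(row)
        z = expr[partner_row]
        z = (z - z.mean()) / z.std()
        r = cfg.confound_r
        expr[row] = r * z + np.sqrt(1 - r**2) * rng.standard_normal(g_expr.n_samples)
        truth.confounded.append(
            (genes.iloc[row]["gene_id"], genes.iloc[partner_row]["gene_id"], r)
        )

    # expression-cohort nuisance factor (sampling experiment) with a mild effect
    values = pd.DataFrame(expr, index=genes["gene_id"], columns=g_expr.sample_ids)
    return ExpressionMatrix(values), truth


def expression_covariates(
    cfg: SimConfig, sample_ids: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Experiment factor (categorical) and days-in-milk (quantitative)."""
    n = len(sample_ids)
    experiment = rng.integers(0, cfg.n_experiments, size=n)
    dim = rng.normal(86.0, 36.0, size=n).clip(5, 305)
    return pd.DataFrame(
        {"experiment": [f"E{e + 1}" for e in experiment], "dim": dim},
        index=pd.Index(sample_ids, name="sample_id"),
    )


def simulate_traits(
    g_gwas: GenotypeMatrix,
    truth: TruthSet,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """Traits for the GWAS cohort with exact realized heritability.

    Genetic value = mediated part (trait effect x genetic component of
    expression, i.e. eqtl beta x dosage) + direct QTL effects + a diffuse
    polygenic term; environmental noise is scaled so the realized
    variance-ratio h2 equals the target, then batch effects are added.
    """
    n = g_gwas.n_samples
    var_index = {v: j for j, v in enumerate(g_gwas.variants["id"])}
    maf = g_gwas.maf()

    # direct QTLs: common variants not reused as eQTLs
    eqtl_ids = {m.eqtl_variant for m in truth.mediating}
    common = [
        j for j in range(g_gwas.n_variants)
        if maf[j] >= 0.15 and g_gwas.variants.iloc[j]["id"] not in eqtl_ids
    ]
    direct_idx = rng.choice(common, size=cfg.direct_qtl_count, replace=False)
    direct_effects = {}
    for j in direct_idx:
        vid = g_gwas.variants.iloc[int(j)]["id"]
        direct_effects[vid] = {
            t: float(cfg.direct_effect_sd * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0]))
            for t in cfg.trait_names
        }
    truth.direct_qtls = direct_effects

    poly_idx = rng.choice(g_gwas.n_variants, size=min(cfg.n_polygenic, g_gwas.n_variants),
                          replace=False)
    poly_beta = rng.normal(0.0, cfg.polygenic_effect_sd, size=(len(poly_idx), cfg.n_traits))

    batch = rng.integers(0, cfg.n_batches, size=n)
    batch_effects = rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_batches)

    traits = {}
    for ti, (tname, h2) in enumerate(zip(cfg.trait_names, cfg.h2)):
        genetic = np.zeros(n)
        for m in truth.mediating:
            dose = g_gwas.dosages[:, var_index[m.eqtl_variant]]
            genetic += m.trait_effects[tname] * m.eqtl_beta * dose
        for vid, eff in direct_effects.items():
            genetic += eff[tname] * g_gwas.dosages[:, var_index[vid]]
        genetic += g_gwas.dosages[:, poly_idx] @ poly_beta[:, ti]

        noise = rng.standard_normal(n)
        noise = (noise - noise.mean()) / noise.std(ddof=1)
        var_g = genetic.var(ddof=1)
        if h2 == 0 or var_g == 0:
            y = noise
            truth.realized_h2[tname] = 0.0
        elif h2 == 1:
            y = genetic
            truth.realized_h2[tname] = 1.0
        else:
            y = genetic + noise * np.sqrt(var_g * (1.0 - h2) / h2)
            truth.realized_h2[tname] = float(
                var_g / (var_g + var_g * (1.0 - h2) / h2)
            )
        traits[tname] = y + batch_effects[batch]

    idx = pd.Index(g_gwas.sample_ids, name="sample_id")
    return PhenotypeTable(
        traits=pd.DataFrame(traits, index=idx),
        covariates=pd.DataFrame({"batch": [f"B{b + 1}" for b in batch]}, index=idx),
        categorical=["batch"],
    )


def simulate_term_membership(
    ann: GeneAnnotation,
    truth: TruthSet,
    rng: np.random.Generator,
    term: str = "lipid_metabolism",
    background_rate: float = 0.15,
) -> pd.DataFrame:
    """Synthetic ontology term with planted enrichment.

    Every mediating gene carries the term; other genes carry it at
    ``background_rate``.  Non-members are listed under ``other`` so the
    membership table covers the whole gene universe.
    """
    mediating = set(truth.mediating_gene_ids)
    rows = []
    for gid in ann.gene_ids:
        if gid in mediating or rng.random() < background_rate:
            rows.append((gid, term))
        else:
            rows.append((gid, "other"))
    return pd.DataFrame(rows, columns=["gene_id", "term"])


def simulate_cohort(cfg: SimConfig) -> SimData:
    """Run the full generator: genotypes for both cohorts, annotation,
    expression with truth labels, traits, and covariates."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_geno, rng_ann, rng_expr, rng_trait, rng_cov, rng_term = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    g_all = simulate_genotypes(cfg, cfg.n_gwas + cfg.n_expr, rng_geno, prefix="S")
    gwas_ids = g_all.sample_ids[: cfg.n_gwas]
    expr_ids = g_all.sample_ids[cfg.n_gwas:]
    g_gwas = g_all.subset_samples(gwas_ids)
    g_expr = g_all.subset_samples(expr_ids)
    ann = simulate_annotation(cfg, rng_ann)
    expression, truth = simulate_expression(g_expr, ann, cfg, rng_expr)
    phenotypes = simulate_traits(g_gwas, truth, cfg, rng_trait)
    expr_cov = expression_covariates(cfg, expr_ids, rng_cov)
    membership = simulate_term_membership(ann, truth, rng_term)
    return SimData(g_gwas, g_expr, ann, expression, phenotypes, expr_cov, membership, truth)
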