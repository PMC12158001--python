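"""Generate the synthetic study the downstream analyses run on.

Emulates the real design at desk scale: a 400-cow GWAS cohort with three
traits whose heritabilities span the 0.07-0.7 envelope, a disjoint
150-cow expression cohort, 3 chromosomes x 1200 variants of block-LD
genotypes, 60 genes of which 5 mediate trait variation through cis-driven
expression, plus a synthetic lipid-metabolism-style ontology term.
Writes the fixture directory and the ground-truth labels.
"""

import json
import sys
from pathlib import Path

from gsorpipe import io as gio
from gsorpipe.simulate import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"


def main(seed: int = 1) -> None:
    cfg = SimConfig(seed=seed, n_variants_per_chrom=1200, h2=(0.07, 0.4, 0.7))
    data = simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    gio.write_genotypes_tsv(data.genotypes_gwas, OUT / "genotypes_gwas.tsv")
    gio.write_genotypes_tsv(data.genotypes_expr, OUT / "genotypes_expr.tsv")
    gio.write_annotation_tsv(data.annotation, OUT / "annotation.tsv")
    gio.write_expression(data.expression, OUT / "expression.tsv")
    gio.write_phenotypes(data.phenotypes, OUT / "phenotypes.tsv")
    data.expr_covariates.to_csv(OUT / "expr_covariates.tsv", sep="\t")
    data.membership.to_csv(OUT / "membership.tsv", sep="\t", index=False)
    with open(OUT / "truth.json", "w") as fh:
        json.dump(data.truth.to_dict(), fh, indent=2)
    print(
        f"wrote fixture to {OUT}: {data.genotypes_gwas.n_samples} GWAS cows x "
        f"{data.genotypes_gwas.n_variants} variants, "
        f"{data.genotypes_expr.n_samples} expression cows, "
        f"{len(data.annotation.gene_ids)} genes "
        f"({len(data.truth.mediating_gene_ids)} mediating: "
        f"{', '.join(data.truth.mediating_gene_ids)})"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
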