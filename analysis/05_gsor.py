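"""Genetic score omics regression per trait.

For every gene, regresses its local genomic value (response) on its
observed expression with the expression-cohort polygenic effect, adjusts
per trait by Benjamini-Hochberg, and flags hits at FDR <= 0.01.
"""

import pandas as pd
from pathlib import Path

from gsorpipe import gwas as gw
from gsorpipe import io as gio
from gsorpipe.core import compute_grm
from gsorpipe.gsor import gsor_scan

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    expr = gio.read_expression(ROOT / "fixture" / "expression.tsv")
    g_expr = gio.read_genotypes(ROOT / "fixture" / "genotypes_expr.tsv")
    cov = pd.read_csv(ROOT / "fixture" / "expr_covariates.tsv", sep="\t", index_col=0)
    frames = []
    for path in sorted((ROOT / "bayesr").glob("local_gebv_*.tsv")):
        trait = path.stem.replace("local_gebv_", "")
        table = pd.read_csv(path, sep="\t", index_col=0)
        grm = compute_grm(g_expr.subset_samples(list(table.columns)))
        X = gw.build_design(cov.loc[list(table.columns)], ["experiment"], add_intercept=False)
        res = gsor_scan(table, expr, X, grm, trait, fdr=0.01)
        frames.append(res)
        hits = res.loc[res["hit"], "gene"].tolist()
        print(f"{trait}: {len(hits)} hits of {len(res)} genes: {', '.join(hits) or '-'}")
    allres = pd.concat(frames, ignore_index=True)
    allres.to_csv(ROOT / "gsor.tsv", sep="\t", index=False)
    union = sorted(set(allres.loc[allres["hit"], "gene"]))
    print(f"union over traits: {len(union)} hit genes")


if __name__ == "__main__":
    main()
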