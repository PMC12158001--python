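"""Shared fixtures: small deterministic panels and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gsorpipe.core import GenotypeMatrix
from gsorpipe.simulate import SimConfig, simulate_cohort


def make_panel(dosages, chrom=None, pos=None, ids=None, imp_r2=None):
    """Build a GenotypeMatrix from a raw (n_samples, n_variants) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else list(range(1, m + 1))
    ids = ids if ids is not None else [f"v{i}" for i in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": ids,
            "ref": "A",
            "alt": "B",
            "imp_r2": imp_r2 if imp_r2 is not None else np.nan,
        }
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dosages)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale mediated cohort shared by the slower integration tests."""
    cfg = SimConfig(
        seed=11,
        n_variants_per_chrom=800,
        h2=(0.2, 0.5),
        n_genes=40,
    )
    return cfg, simulate_cohort(cfg)
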