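"""Window partitioning, marking, gene assignment and exact 2x2 tests."""

import math

import numpy as np
import pandas as pd
import pytest

from gsorpipe.core import GeneAnnotation
from gsorpipe.windows import (
    Contingency2x2,
    assign_genes,
    fisher_exact_2x2,
    mark_windows,
    overlap_test,
    partition_genome,
    term_enrichment,
    truncate2,
)


def ann_from(rows):
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


class TestPartition:
    def test_partial_final_window(self):
        part = partition_genome({"1": 250_000}, 100_000)
        assert part.n_windows == 3
        last = part.windows.iloc[-1]
        assert (last["start"], last["end"]) == (200_001, 250_000)

    def test_exact_multiple(self):
        part = partition_genome({"1": 200_000}, 100_000)
        assert part.n_windows == 2

    def test_count_formula_and_coverage(self):
        lengths = {"1": 530_000, "2": 75_000, "3": 1_000_000}
        part = partition_genome(lengths, 100_000)
        assert part.n_windows == sum(math.ceil(l / 100_000) for l in lengths.values())
        widths = part.windows["end"] - part.windows["start"] + 1
        assert widths.sum() == sum(lengths.values())
        for chrom, sub in part.windows.groupby("chrom"):
            assert sub["start"].iloc[0] == 1
            assert (sub["start"].iloc[1:].to_numpy() == sub["end"].iloc[:-1].to_numpy() + 1).all()


def meta_frame(ids, q):
    return pd.DataFrame({"id": ids, "q": q})


def variants_frame(ids, chrom, pos):
    return pd.DataFrame({"id": ids, "chrom": chrom, "pos": pos})


class TestMarkWindows:
    def test_no_significant_no_marks(self):
        part = partition_genome({"1": 300_000}, 100_000)
        marked = mark_windows(
            part,
            meta_frame(["v0"], [0.5]),
            variants_frame(["v0"], ["1"], [150_000]),
        )
        assert marked.n_marked == 0

    def test_boundary_position_marks_earlier_window(self):
        part = partition_genome({"1": 300_000}, 100_000)
        marked = mark_windows(
            part,
            meta_frame(["v0"], [0.01]),
            variants_frame(["v0"], ["1"], [100_000]),
        )
        flags = marked.windows["marked"].tolist()
        assert flags == [True, False, False]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        lengths = {"1": 1_000_000, "2": 700_000}
        part = partition_genome(lengths, 100_000)
        n = 200
        chrom = rng.choice(["1", "2"], size=n)
        pos = np.array(
            [rng.integers(1, lengths[c] + 1) for c in chrom]
        )
        q = rng.uniform(0, 1, size=n)
        ids = [f"v{i}" for i in range(n)]
        marked = mark_windows(part, meta_frame(ids, q), variants_frame(ids, chrom, pos))
        for _, w in marked.windows.iterrows():
            inside = (chrom == w["chrom"]) & (pos >= w["start"]) & (pos <= w["end"])
            assert w["marked"] == bool((q[inside] <= 0.10).any())

    def test_out_of_range_variant_errors(self):
        part = partition_genome({"1": 100_000}, 100_000)
        with pytest.raises(ValueError, match="coordinate"):
            mark_windows(
                part,
                meta_frame(["v0"], [0.01]),
                variants_frame(["v0"], ["1"], [200_000]),
            )


class TestAssignGenes:
    def test_start_boundary(self):
        part = partition_genome({"1": 300_000}, 100_000)
        ann = ann_from(
            [("gA", "1", 100_000, 150_000, "+"), ("gB", "1", 100_001, 150_000, "+")]
        )
        m = assign_genes(part, ann)
        assert m["gA"] == 0 and m["gB"] == 1

    def test_every_gene_exactly_one_window(self):
        rng = np.random.default_rng(1)
        part = partition_genome({"1": 2_000_000}, 100_000)
        rows = [
            (f"g{i}", "1", int(rng.integers(1, 1_900_000)), 1_950_000, "+")
            for i in range(50)
        ]
        m = assign_genes(part, ann_from(rows))
        assert len(m) == 50
        # brute-force containment scan
        for gid, widx in m.items():
            w = part.windows.iloc[widx]
            start = dict(rows)[gid] if False else [r[2] for r in rows if r[0] == gid][0]
            assert w["start"] <= start <= w["end"]

    def test_unknown_chromosome_excluded(self):
        part = partition_genome({"1": 100_000}, 100_000)
        m = assign_genes(part, ann_from([("gA", "9", 10, 20, "+")]))
        assert "gA" not in m.index


def enumerate_fisher_p(a, b, c, d):
    """Exhaustive two-sided Fisher p: sum of same-margin table probabilities
    with point mass <= the observed (computed from factorials)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return min(total, 1.0)


class TestFisher:
    # printed worked examples: the four enrichment tables
    @pytest.mark.parametrize(
        "cells,p_3dp,or_2dp",
        [
            ((7, 63, 332, 11905), 0.003, 3.98),
            ((11, 161, 332, 11905), 0.008, 2.44),
            ((5, 90, 302, 12231), 0.08, 2.24),
            ((9, 232, 302, 12231), 0.19, 1.57),
        ],
    )
    def test_published_tables(self, cells, p_3dp, or_2dp):
        res = fisher_exact_2x2(Contingency2x2(*cells))
        digits = len(str(p_3dp).split(".")[1])
        assert math.trunc(res.p_two_sided * 10**digits) / 10**digits == p_3dp
        assert res.display_or == or_2dp

    def test_no_association_table(self):
        res = fisher_exact_2x2(Contingency2x2(3, 9, 3, 9))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_small_table_against_enumeration(self):
        res = fisher_exact_2x2(Contingency2x2(2, 3, 4, 1))
        assert res.p_two_sided == pytest.approx(enumerate_fisher_p(2, 3, 4, 1), rel=1e-9)

    def test_stratified_sweep_totals_up_to_40(self):
        # random tables stratified by total (the exhaustive sweep is part of
        # the acceptance checks)
        rng = np.random.default_rng(2)
        checked = 0
        for total in range(1, 41, 3):
            for _ in range(40):
                cut = np.sort(rng.integers(0, total + 1, size=3))
                a, b, c = cut[0], cut[1] - cut[0], cut[2] - cut[1]
                d = total - a - b - c
                res = fisher_exact_2x2(Contingency2x2(a, b, c, d))
                assert res.p_two_sided == pytest.approx(
                    enumerate_fisher_p(a, b, c, d), rel=1e-9, abs=1e-12
                )
                checked += 1
        assert checked >= 500

    def test_degenerate_odds_ratios(self):
        assert math.isinf(fisher_exact_2x2(Contingency2x2(1, 0, 0, 1)).odds_ratio)
        assert math.isnan(fisher_exact_2x2(Contingency2x2(0, 1, 0, 1)).odds_ratio)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b + c + d == 0:
                continue
            p1 = fisher_exact_2x2(Contingency2x2(a, b, c, d)).p_two_sided
            p2 = fisher_exact_2x2(Contingency2x2(a, c, b, d)).p_two_sided
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Contingency2x2(-1, 2, 3, 4)

    def test_truncation_rule(self):
        assert truncate2(2.2499) == 2.24
        assert truncate2(3.9843) == 3.98


class TestOverlapAndEnrichment:
    def _setup(self):
        part = partition_genome({"1": 1_000_000}, 100_000)
        rows = [(f"g{i}", "1", 50_000 + 100_000 * (i % 10), 60_000 + 100_000 * (i % 10), "+")
                for i in range(40)]
        ann = ann_from(rows)
        ids = ["v0", "v1"]
        marked = mark_windows(
            part,
            meta_frame(ids, [0.01, 0.01]),
            variants_frame(ids, ["1", "1"], [150_000, 250_000]),
        )
        assignment = assign_genes(marked, ann)
        return marked, assignment, {r[0] for r in rows}

    def test_margins_are_bookkept(self):
        part, assignment, tested = self._setup()
        hits = {"g1", "g2", "g11", "g5"}
        res, counts = self._run(part, assignment, tested, hits)
        t = res.table
        assert t.a + t.b == len(hits) == counts["total_hits"]
        assert t.a + t.c == counts["genes_in_marked"]
        assert t.a + t.b + t.c + t.d == counts["tested_genes"]

    @staticmethod
    def _run(part, assignment, tested, hits):
        return overlap_test(hits, tested, assignment, part)

    def test_enriched_hits_give_or_above_one(self):
        part, assignment, tested = self._setup()
        hits = {"g1", "g2", "g11", "g12"}  # all inside the two marked windows
        res, counts = self._run(part, assignment, tested, hits)
        assert res.odds_ratio > 1
        assert res.p_two_sided <= 0.05
        assert counts["hits_in_marked"] == 4

    def test_hits_must_be_subset(self):
        part, assignment, tested = self._setup()
        with pytest.raises(ValueError, match="subset"):
            overlap_test({"nope"}, tested, assignment, part)

    def test_term_enrichment_reproduces_published_margins(self):
        hits = {f"h{i}" for i in range(70)}
        background = {f"b{i}" for i in range(12_237)}
        term_rows = [(f"h{i}", "lipid") for i in range(7)]
        term_rows += [(f"b{i}", "lipid") for i in range(332)]
        term_rows += [(g, "other") for g in (hits | background)
                      if g not in {r[0] for r in term_rows}]
        membership = pd.DataFrame(term_rows, columns=["gene_id", "term"])
        res = term_enrichment(hits, background, membership, "lipid")
        t = res.table
        assert (t.a, t.b, t.c, t.d) == (7, 63, 332, 11_905)
        assert math.trunc(res.p_two_sided * 1000) / 1000 == 0.003
        assert res.display_or == 3.98

    def test_matching_proportions_or_near_one(self):
        hits = {f"h{i}" for i in range(100)}
        background = {f"b{i}" for i in range(1000)}
        rows = [(f"h{i}", "t") for i in range(10)] + [(f"b{i}", "t") for i in range(100)]
        rows += [(g, "other") for g in (hits | background) if g not in {r[0] for r in rows}]
        res = term_enrichment(hits, background, pd.DataFrame(rows, columns=["gene_id", "term"]), "t")
        assert res.odds_ratio == pytest.approx(1.0, abs=0.05)

    def test_missing_term_errors(self):
        membership = pd.DataFrame([("g1", "a")], columns=["gene_id", "term"])
        with pytest.raises(ValueError, match="absent"):
            term_enrichment({"g1"}, {"g1"}, membership, "zzz")
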