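"""Interval and loop overlap logic against quadratic brute-force scans, and
enrichment construction against exact 2x2 arithmetic."""

import numpy as np
import pandas as pd
import pytest

from mimqtl.containers import GenomeAnnotation, IntervalSet, LoopSet
from mimqtl.context import (
    loop_enrichment,
    loop_hits,
    overlap_cpgs,
    peak_signal_group_test,
    region_set_enrichment,
)
from mimqtl.screen import MimQTLTable


def make_annotation(records):
    return GenomeAnnotation(pd.DataFrame(
        records, columns=["feature_id", "chrom", "start", "end"]
    ).set_index("feature_id"))


class TestOverlap:
    def test_point_examples(self):
        ann = make_annotation([("in", "chr1", 150, 150), ("out", "chr1", 201, 201)])
        iset = IntervalSet("s", pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200]}))
        out = overlap_cpgs(ann, iset, ["in", "out"]).set_index("feature_id")
        assert out.loc["in", "hit"] and not out.loc["out", "hit"]

    def test_extension(self):
        ann = make_annotation([("cg", "chr1", 301, 301)])
        iset = IntervalSet("s", pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200]}))
        assert not overlap_cpgs(ann, iset, ["cg"])["hit"].iloc[0]
        assert overlap_cpgs(ann, iset, ["cg"], extend_bp=101)["hit"].iloc[0]

    def test_missing_chromosome_is_no_hit(self):
        ann = make_annotation([("cg", "chr9", 100, 100)])
        iset = IntervalSet("s", pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000]}))
        assert not overlap_cpgs(ann, iset, ["cg"])["hit"].iloc[0]

    def test_matches_quadratic_scan(self, rng):
        n_cpg, n_iv = 300, 60
        positions = rng.integers(1, 10_000, n_cpg)
        chroms = rng.choice(["chr1", "chr2"], n_cpg)
        ann = make_annotation([
            (f"cg{i}", chroms[i], int(positions[i]), int(positions[i]))
            for i in range(n_cpg)])
        starts = rng.integers(0, 9_900, n_iv)
        lens = rng.integers(1, 200, n_iv)
        ic = rng.choice(["chr1", "chr2"], n_iv)
        iset = IntervalSet("r", pd.DataFrame(
            {"chrom": ic, "start": starts, "end": starts + lens}))
        got = overlap_cpgs(ann, iset, [f"cg{i}" for i in range(n_cpg)])
        hits = dict(zip(got["feature_id"], got["hit"]))
        for i in range(n_cpg):
            s, e = positions[i] - 1, positions[i]  # half-open CpG interval
            expected = any(
                ic[j] == chroms[i] and starts[j] < e and s < starts[j] + lens[j]
                for j in range(n_iv))
            assert hits[f"cg{i}"] == expected

    def test_point_vs_interval_representation_equivalent(self, rng):
        """Treating CpGs as length-1 half-open intervals through the generic
        machinery yields identical hits."""
        positions = rng.integers(1, 1000, 50)
        ann_points = make_annotation(
            [(f"cg{i}", "chr1", int(p), int(p)) for i, p in enumerate(positions)])
        starts = rng.integers(0, 990, 20)
        iset = IntervalSet("r", pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 10}))
        a = overlap_cpgs(ann_points, iset, [f"cg{i}" for i in range(50)])
        from intervaltree import IntervalTree

        tree = IntervalTree()
        for row in iset.table.itertuples():
            tree.addi(row.start, row.end)
        for i, p in enumerate(positions):
            assert bool(tree.overlap(p - 1, p)) == a["hit"].iloc[i]


class TestRegionEnrichment:
    def test_fold_one_when_rates_match(self):
        ann = make_annotation(
            [(f"cg{i}", "chr1", 10 * i + 5, 10 * i + 5) for i in range(40)])
        # first half of CpGs are inside intervals
        iset = IntervalSet("r", pd.DataFrame(
            {"chrom": "chr1", "start": [10 * i for i in range(20)],
             "end": [10 * i + 9 for i in range(20)]}))
        cluster = [f"cg{i}" for i in range(0, 40, 2)]  # exactly half in-region
        res = region_set_enrichment(cluster, iset, [f"cg{i}" for i in range(40)], ann)
        assert res.fold == pytest.approx(1.0)

    def test_fisher_matches_exact_formula(self):
        from math import comb

        ann = make_annotation(
            [(f"cg{i}", "chr1", 10 * i + 5, 10 * i + 5) for i in range(10)])
        iset = IntervalSet("r", pd.DataFrame(
            {"chrom": "chr1", "start": [10 * i for i in range(5)],
             "end": [10 * i + 9 for i in range(5)]}))
        cluster = [f"cg{i}" for i in range(5)]  # all in-region CpGs
        res = region_set_enrichment(cluster, iset, [f"cg{i}" for i in range(10)], ann)
        # 2x2: x=5, n=5, K=5, N=10 -> hypergeometric point mass
        p_point = comb(5, 5) * comb(5, 0) / comb(10, 5)
        assert res.p_over == pytest.approx(p_point, abs=1e-12)
        # Fisher two-sided sums all tables with probability <= observed
        assert res.p_fisher == pytest.approx(2 * p_point, abs=1e-12)

    def test_no_background_hits_flagged(self):
        ann = make_annotation([("cg0", "chr1", 5, 5)])
        iset = IntervalSet("r", pd.DataFrame(
            {"chrom": ["chr2"], "start": [0], "end": [10]}))
        with pytest.raises(ValueError, match="undefined"):
            region_set_enrichment(["cg0"], iset, ["cg0"], ann)

    def test_invariant_to_record_order(self, rng):
        n = 30
        ann = make_annotation(
            [(f"cg{i}", "chr1", 7 * i + 3, 7 * i + 3) for i in range(n)])
        starts = rng.integers(0, 200, 12)
        df = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 9})
        cluster = [f"cg{i}" for i in range(10)]
        bg = [f"cg{i}" for i in range(n)]
        try:
            r1 = region_set_enrichment(cluster, IntervalSet("r", df), bg, ann)
            r2 = region_set_enrichment(
                cluster, IntervalSet("r", df.iloc[::-1]), bg, ann)
        except ValueError:
            pytest.skip("random intervals hit no CpG")
        assert (r1.p_over, r1.fold) == (r2.p_over, r2.fold)


def toy_loop_setup():
    ann = make_annotation([
        ("mirX", "chr1", 5001, 5080),  # precursor
        ("cgA", "chr1", 1050, 1050),
        ("cgB", "chr1", 5010, 5010),  # same foot as mirX
    ])
    loops = LoopSet("loops", pd.DataFrame(
        [("chr1", 1000, 1100, "chr1", 5000, 5100, "loop1")],
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "loop_id"]))
    return ann, loops


def table_of(pairs):
    return MimQTLTable(pd.DataFrame(
        [(m, c, -1, "cis") for m, c in pairs],
        columns=["mirna_id", "cpg_id", "sign", "cis_trans"]), (1, 1), 0.05)


class TestLoops:
    def test_hit_and_same_foot_no_hit(self):
        ann, loops = toy_loop_setup()
        hits = loop_hits(table_of([("mirX", "cgA"), ("mirX", "cgB")]), loops, ann)
        assert len(hits) == 1
        assert tuple(hits.iloc[0][["mirna_id", "cpg_id", "loop_id"]]) == \
            ("mirX", "cgA", "loop1")

    def test_orientation_symmetric(self):
        ann, loops = toy_loop_setup()
        swapped = LoopSet("loops", pd.DataFrame(
            [("chr1", 5000, 5100, "chr1", 1000, 1100, "loop1")],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                     "loop_id"]))
        h1 = loop_hits(table_of([("mirX", "cgA")]), loops, ann)
        h2 = loop_hits(table_of([("mirX", "cgA")]), swapped, ann)
        assert len(h1) == len(h2) == 1
        assert h1.iloc[0]["orientation"] != h2.iloc[0]["orientation"]

    def test_enrichment_counts_and_small_example(self):
        ann, loops = toy_loop_setup()
        table = table_of([("mirX", "cgA")])
        hits = loop_hits(table, loops, ann)
        res = loop_enrichment(hits, table, ann, loops)
        # universe: 1 miRNA x 2 CpGs on chr1 -> N=2; linked background: cgA
        # only -> K=1; n=1 cis mimQTL, x=1
        assert (res.population, res.successes, res.draws, res.observed) == (2, 1, 1, 1)
        assert res.p_over == pytest.approx(0.5)

    def test_empty_cis_set_p_one(self):
        ann, loops = toy_loop_setup()
        table = table_of([])
        res = loop_enrichment(loop_hits(table, loops, ann), table, ann, loops)
        assert res.p_over == 1.0


class TestPeakSignal:
    def test_per_sample_mean_matches_direct_average(self, rng):
        signal = pd.DataFrame(rng.normal(size=(4, 12)),
                              index=[f"p{i}" for i in range(4)],
                              columns=[f"s{i}" for i in range(12)])
        mapping = {"cg0": "p0", "cg1": "p2"}
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=signal.columns)
        _, p, means = peak_signal_group_test(signal, mapping, ["cg0", "cg1"], groups)
        np.testing.assert_allclose(
            means.to_numpy(), signal.loc[["p0", "p2"]].mean(axis=0).to_numpy())

    def test_planted_shift_detected(self, rng):
        base = rng.normal(size=(3, 60))
        base[:, 30:] += 1.0  # one-sd shift in group b
        signal = pd.DataFrame(base, index=["p0", "p1", "p2"],
                              columns=[f"s{i}" for i in range(60)])
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=signal.columns)
        _, p, _ = peak_signal_group_test(signal, {"cg": "p1"}, ["cg"], groups)
        assert p < 0.01

    def test_unmapped_cluster_rejected(self, rng):
        signal = pd.DataFrame(rng.normal(size=(2, 4)), index=["p0", "p1"],
                              columns=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=signal.columns)
        with pytest.raises(ValueError):
            peak_signal_group_test(signal, {}, ["cg0"], groups)
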