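"""Genomic context of mimQTL CpGs: interval-set overlap (super-enhancers,
chromatin states, TFBS with symmetric bp extension, ATAC peaks), region-set
enrichment, and chromatin-loop co-membership of cis pairs.

All overlap arithmetic is 0-based half-open; CpGs (1-based points) become
the half-open interval [pos-1, pos) before intersection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotate import EnrichmentResult, wilcoxon_rank_sum
from .containers import GenomeAnnotation, IntervalSet, LoopSet
from .screen import MimQTLTable

log = logging.getLogger("mimqtl")

__all__ = [
    "normalize_chrom",
    "build_trees",
    "overlap_cpgs",
    "region_set_enrichment",
    "loop_hits",
    "loop_enrichment",
    "peak_signal_group_test",
]


def normalize_chrom(name: str) -> str:
    """Normalize chromosome naming ('1' -> 'chr1')."""
    name = str(name)
    return name if name.startswith("chr") else f"chr{name}"


def build_trees(intervals: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in intervals.table.itertuples(index=True):
        chrom = normalize_chrom(row.chrom)
        trees.setdefault(chrom, IntervalTree()).addi(row.start, row.end, row.Index)
    return trees


def _cpg_interval(annotation: GenomeAnnotation, cpg: str, extend_bp: int) -> tuple[str, int, int]:
    chrom, s, e = annotation.half_open(cpg)
    return normalize_chrom(chrom), s - extend_bp, e + extend_bp


def overlap_cpgs(annotation: GenomeAnnotation, intervals: IntervalSet,
                 cpg_ids=None, extend_bp: int = 0) -> pd.DataFrame:
    """Intersect CpG points (extended symmetrically by ``extend_bp``) with an
    interval set. Returns one row per CpG with ``hit`` and the overlapping
    interval record indices. A chromosome absent from the set simply yields
    no hit."""
    trees = build_trees(intervals)
    if cpg_ids is None:
        cpg_ids = [f for f in annotation.table.index
                   if annotation.table.at[f, "start"] == annotation.table.at[f, "end"]]
    rows = []
    for cpg in cpg_ids:
        chrom, s, e = _cpg_interval(annotation, cpg, extend_bp)
        tree = trees.get(chrom)
        hits = sorted(iv.data for iv in tree.overlap(s, e)) if tree else []
        rows.append((cpg, bool(hits), hits))
    out = pd.DataFrame(rows, columns=["feature_id", "hit", "hit_intervals"])
    log.info("overlap_cpgs vs %s (extend %d bp): %d/%d CpGs hit",
             intervals.name, extend_bp, int(out["hit"].sum()), len(out))
    return out


def region_set_enrichment(cluster_cpgs, intervals: IntervalSet,
                          background_cpgs, annotation: GenomeAnnotation,
                          test: str = "hypergeometric",
                          extend_bp: int = 0) -> EnrichmentResult:
    """Enrichment of a CpG cluster for residing in a region set, against a
    CpG background (2x2: in-cluster x in-region). ``test`` selects the
    p-value reported alongside (hypergeometric upper tail, or Fisher's exact
    two-sided in ``p_fisher``; both are always computed)."""
    if test not in ("hypergeometric", "fisher"):
        raise ValueError(f"unknown test {test!r}")
    background = list(dict.fromkeys(background_cpgs))
    cluster = set(cluster_cpgs)
    if not cluster <= set(background):
        raise ValueError("cluster CpGs must be a subset of the background")
    ov = overlap_cpgs(annotation, intervals, cpg_ids=background, extend_bp=extend_bp)
    in_region = set(ov.loc[ov["hit"], "feature_id"])
    if not in_region:
        raise ValueError(f"background has no overlap with region set "
                         f"{intervals.name!r}: enrichment undefined")
    N, K, n = len(background), len(in_region), len(cluster)
    x = len(cluster & in_region)
    dist = stats.hypergeom(N, K, n)
    p_over = float(min(dist.sf(x - 1), 1.0))
    p_under = float(min(dist.cdf(x), 1.0))
    table = [[x, n - x], [K - x, (N - K) - (n - x)]]
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    expected = n * K / N
    fold = x / expected if expected else float("nan")
    log.info("region_set_enrichment %s: x=%d n=%d K=%d N=%d fold=%.2f p_over=%.3g "
             "p_fisher=%.3g", intervals.name, x, n, K, N, fold, p_over, p_fisher)
    return EnrichmentResult(intervals.name, N, K, n, x, p_over, p_under, fold,
                            p_fisher=float(p_fisher))


def _foot_trees(loops: LoopSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in loops.table.itertuples():
        for foot, (c, s, e) in enumerate(
            ((row.chrom1, row.start1, row.end1), (row.chrom2, row.start2, row.end2))
        ):
            trees.setdefault(normalize_chrom(c), IntervalTree()).addi(
                s, e, (row.loop_id, foot)
            )
    return trees


def loop_hits(table: MimQTLTable, loops: LoopSet,
              annotation: GenomeAnnotation,
              strict_containment: bool = False) -> pd.DataFrame:
    """For every cis mimQTL pair, report loops whose two feet hold the CpG
    and the miRNA precursor respectively. The precursor counts as 'in a
    foot' on any >= 1 bp overlap by default (``strict_containment=True``
    requires the full precursor interval inside the foot). Pairs whose
    precursor lacks an annotation entry are skipped with a log entry."""
    trees = _foot_trees(loops)
    rec = table.records
    if "cis_trans" in rec.columns:
        rec = rec[rec["cis_trans"] == "cis"]
    rows = []
    skipped = 0
    for r in rec.itertuples():
        if not (annotation.has(r.mirna_id) and annotation.has(r.cpg_id)):
            skipped += 1
            continue
        c_chrom, cs, ce = _cpg_interval(annotation, r.cpg_id, 0)
        m_chrom, ms, me = annotation.half_open(r.mirna_id)
        m_chrom = normalize_chrom(m_chrom)
        cpg_feet = {iv.data for iv in trees.get(c_chrom, IntervalTree()).overlap(cs, ce)}
        mir_feet = set()
        for iv in trees.get(m_chrom, IntervalTree()).overlap(ms, me):
            if strict_containment and not (iv.begin <= ms and me <= iv.end):
                continue
            mir_feet.add(iv.data)
        for loop_id, c_foot in cpg_feet:
            for m_loop, m_foot in mir_feet:
                if m_loop == loop_id and m_foot != c_foot:
                    rows.append((r.mirna_id, r.cpg_id, loop_id,
                                 "cpg_in_foot1" if c_foot == 0 else "cpg_in_foot2"))
    if skipped:
        log.warning("loop_hits: skipped %d pairs lacking annotations", skipped)
    out = pd.DataFrame(rows, columns=["mirna_id", "cpg_id", "loop_id", "orientation"])
    log.info("loop_hits: %d hits over %d cis pairs", len(out), len(rec))
    return out


def _loop_background_pairs(annotation: GenomeAnnotation, loops: LoopSet,
                           mirna_ids, cpg_ids) -> tuple[int, int]:
    """Count background cis pairs (N) and how many are loop-linked (K) over
    the annotated universe of miRNAs x CpGs."""
    ann = annotation.table
    mirnas = [m for m in mirna_ids if m in ann.index]
    cpgs = [c for c in cpg_ids if c in ann.index]
    m_chrom = ann.loc[mirnas, "chrom"].map(normalize_chrom)
    c_chrom = ann.loc[cpgs, "chrom"].map(normalize_chrom)
    m_per_chrom = m_chrom.value_counts()
    c_per_chrom = c_chrom.value_counts()
    N = int(sum(m_per_chrom.get(ch, 0) * c_per_chrom.get(ch, 0)
                for ch in set(m_per_chrom.index) | set(c_per_chrom.index)))
    # loop-linked background pairs: per loop, miRNAs overlapping one foot x
    # CpGs in the other, deduplicated at pair level
    trees = _foot_trees(loops)
    mir_feet: dict[tuple, set] = {}
    cpg_feet: dict[tuple, set] = {}
    for m in mirnas:
        chrom, s, e = annotation.half_open(m)
        for iv in trees.get(normalize_chrom(chrom), IntervalTree()).overlap(s, e):
            mir_feet.setdefault(iv.data, set()).add(m)
    for c in cpgs:
        chrom, s, e = _cpg_interval(annotation, c, 0)
        for iv in trees.get(chrom, IntervalTree()).overlap(s, e):
            cpg_feet.setdefault(iv.data, set()).add(c)
    linked: set[tuple[str, str]] = set()
    for (loop_id, foot), ms in mir_feet.items():
        other = (loop_id, 1 - foot)
        for c in cpg_feet.get(other, ()):  # feet of the same loop, opposite side
            for m in ms:
                if normalize_chrom(annotation.chrom(m)) == normalize_chrom(annotation.chrom(c)):
                    linked.add((m, c))
    return N, len(linked)


def loop_enrichment(hits: pd.DataFrame, table: MimQTLTable,
                    annotation: GenomeAnnotation, loops: LoopSet,
                    mirna_universe=None, cpg_universe=None) -> EnrichmentResult:
    """Hypergeometric enrichment of cis mimQTLs for loop co-membership,
    against all possible same-chromosome miRNA-CpG pairs of the annotated
    universe. A pair hit by several loops counts once."""
    ann = annotation.table
    if mirna_universe is None:
        mirna_universe = [f for f in ann.index if ann.at[f, "start"] != ann.at[f, "end"]]
    if cpg_universe is None:
        cpg_universe = [f for f in ann.index if ann.at[f, "start"] == ann.at[f, "end"]]
    N, K = _loop_background_pairs(annotation, loops, mirna_universe, cpg_universe)
    rec = table.records
    if "cis_trans" in rec.columns:
        rec = rec[rec["cis_trans"] == "cis"]
    n = len(rec)
    x = len(set(map(tuple, hits[["mirna_id", "cpg_id"]].to_numpy()))) if len(hits) else 0
    if K == 0:
        log.warning("loop_enrichment: no loop-linked background pairs; undefined")
        return EnrichmentResult(loops.name, N, 0, n, 0, 1.0, 1.0, float("nan"))
    dist = stats.hypergeom(N, K, n)
    p_over = float(min(dist.sf(x - 1), 1.0)) if n > 0 else 1.0
    p_under = float(min(dist.cdf(x), 1.0))
    expected = n * K / N
    fold = x / expected if expected else float("nan")
    log.info("loop_enrichment: x=%d n=%d K=%d N=%d p_over=%.3g", x, n, K, N, p_over)
    return EnrichmentResult(loops.name, N, K, n, x, p_over, p_under, fold)


def peak_signal_group_test(peak_signal: pd.DataFrame, cpg_to_peak: dict,
                           cluster_cpgs, sample_groups: pd.Series
                           ) -> tuple[float, float, pd.Series]:
    """Average the signal of peaks containing each cluster CpG per sample,
    then Wilcoxon rank-sum between the two sample groups. Returns
    (statistic, p, per-sample means)."""
    peaks = sorted({cpg_to_peak[c] for c in cluster_cpgs if c in cpg_to_peak})
    if not peaks:
        raise ValueError("no cluster CpG maps to any peak")
    means = peak_signal.loc[peaks].mean(axis=0)
    groups = sample_groups.reindex(means.index).dropna()
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("peak_signal_group_test expects exactly 2 sample groups")
    a = means[groups.index[groups == levels[0]]]
    b = means[groups.index[groups == levels[1]]]
    stat, p = wilcoxon_rank_sum(a, b)
    return stat, p, means
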