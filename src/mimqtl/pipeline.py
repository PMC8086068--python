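"""End-to-end orchestration: simulate/ingest -> preprocess -> discover ->
cluster -> annotate -> genomic context -> GMA, with a run manifest that
reproduces the accounting style of the analysis (totals, per-cluster pair
shares, sign fractions, cis fraction), plus ground-truth recovery metrics
when inputs are synthetic."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import annotate, cluster, context, gma, io, preprocess, screen, simulate

log = logging.getLogger("mimqtl")

__all__ = [
    "PipelineConfig",
    "accounting",
    "run_full",
    "report",
    "match_clusters",
    "planted_pair_sensitivity",
]


@dataclass
class PipelineConfig:
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    preprocessing: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)
    alpha: float = 0.05
    k_mirna: int = 3
    k_cpg: int = 2
    extend_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        sim = simulate.SimulationConfig(**cfg.get("simulation", {}))
        pre = preprocess.PreprocessConfig(**cfg.get("preprocess", {}))
        analysis = cfg.get("analysis", {})
        return cls(simulation=sim, preprocessing=pre,
                   alpha=analysis.get("alpha", 0.05),
                   k_mirna=analysis.get("k_mirna", 3),
                   k_cpg=analysis.get("k_cpg", 2),
                   extend_bp=analysis.get("extend_bp", 100),
                   seed=cfg.get("seed", sim.seed))


def accounting(per_cluster_counts: dict[str, int],
               mirna_counts: dict[str, int] | None = None,
               cpg_counts: dict[str, int] | None = None,
               significant_counts: dict[str, tuple[int, int]] | None = None,
               n_cis: int | None = None) -> dict:
    """Pure arithmetic over association counts: totals, per-cluster shares
    and tested-pair percentages, with unrounded and rounded forms.

    ``significant_counts`` maps cohort name -> (n significant, n tested).
    """
    total = sum(per_cluster_counts.values())
    out: dict = {"total_pairs": total, "per_cluster": {}}
    for name, count in per_cluster_counts.items():
        share = 100.0 * count / total if total else float("nan")
        out["per_cluster"][name] = {
            "n_pairs": count,
            "share_pct": share,
            "share_pct_rounded": round(share),
        }
    if mirna_counts is not None:
        out["n_unique_mirnas"] = sum(mirna_counts.values())
        out["mirnas_per_cluster"] = dict(mirna_counts)
    if cpg_counts is not None:
        out["n_unique_cpgs"] = sum(cpg_counts.values())
        out["cpgs_per_cluster"] = dict(cpg_counts)
    if significant_counts is not None:
        out["significant"] = {}
        for cohort, (n_sig, n_tested) in significant_counts.items():
            pct = 100.0 * n_sig / n_tested if n_tested else float("nan")
            out["significant"][cohort] = {
                "n_significant": n_sig,
                "n_tested": n_tested,
                "pct": pct,
                "pct_rounded": round(pct, 2),
            }
    if n_cis is not None:
        pct = 100.0 * n_cis / total if total else float("nan")
        out["cis"] = {"n_cis": n_cis, "pct": pct, "pct_rounded": round(pct, 1)}
    return out


def match_clusters(labels: pd.Series, truth: pd.Series) -> tuple[dict, float]:
    """Match discovered cluster aliases to planted labels by majority
    overlap and return the mapping plus the adjusted Rand index, computed
    over features carrying a planted (non-null) label."""
    common = labels.index.intersection(truth.index[truth != "null"])
    if len(common) == 0:
        return {}, float("nan")
    found = labels.loc[common]
    planted = truth.loc[common]
    mapping = {}
    for alias in found.unique():
        mapping[alias] = planted[found == alias].mode().iloc[0]
    ari = adjusted_rand_score(planted.to_numpy(), found.to_numpy())
    return mapping, float(ari)


def planted_pair_sensitivity(table: screen.MimQTLTable,
                             truth: simulate.PlantedTruth) -> dict:
    """Fraction of planted pairs recovered as mimQTLs (with the planted
    sign), plus the count of discovered pairs that were not planted."""
    found = {(r.mirna_id, r.cpg_id): r.sign for r in table.records.itertuples()}
    planted = truth.pairs
    hits = sum(
        1 for p in planted.itertuples()
        if found.get((p.mirna_id, p.cpg_id)) == p.expected_sign
    )
    planted_set = set(map(tuple, planted[["mirna_id", "cpg_id"]].to_numpy()))
    false_pairs = [k for k in found if k not in planted_set]
    return {
        "n_planted": len(planted),
        "n_recovered": hits,
        "sensitivity": hits / len(planted) if len(planted) else float("nan"),
        "n_unplanted_calls": len(false_pairs),
    }


def _preprocess_cohorts(sim: simulate.SimulatedCohorts,
                        pre: preprocess.PreprocessConfig):
    expr, meth = [], []
    for e, m in zip(sim.expr, sim.meth):
        m = preprocess.remove_high_missing(m, pre)
        m = preprocess.knn_impute(m, pre)
        m = preprocess.filter_cpgs_by_iqr(m, pre)
        e = preprocess.filter_mirnas_by_detection(e, pre)
        expr.append(e)
        meth.append(m)
    e1, e2 = preprocess.intersect_features(expr[0], expr[1])
    m1, m2 = preprocess.intersect_features(meth[0], meth[1])
    return (e1, e2), (m1, m2)


def run_full(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole pipeline on a synthetic study and assemble the run
    manifest. With ``outdir`` set, every stage writes its artifact files
    (TSV/BED/BEDPE/JSON) so stages can be re-run independently."""
    cfg = config
    sim = simulate.simulate_cohorts(cfg.simulation)
    normals = simulate.simulate_normals(cfg.simulation, sim.truth)
    annotation, interval_sets, loops = simulate.simulate_annotations(cfg.simulation, sim.truth)

    (e1, e2), (m1, m2) = _preprocess_cohorts(sim, cfg.preprocessing)

    s1 = screen.spearman_screen(e1, m1, cfg.alpha)
    s2 = screen.spearman_screen(e2, m2, cfg.alpha)
    table = screen.call_mimqtls(s1, s2, cfg.alpha)
    manifest: dict = {
        "seed": cfg.seed,
        "config": {
            "alpha": cfg.alpha, "k_mirna": cfg.k_mirna, "k_cpg": cfg.k_cpg,
            "extend_bp": cfg.extend_bp,
            "simulation": dataclasses.asdict(cfg.simulation),
            "preprocess": dataclasses.asdict(cfg.preprocessing),
        },
        "stage_dimensions": {
            "cohort1": {"expr": list(e1.shape), "meth": list(m1.shape)},
            "cohort2": {"expr": list(e2.shape), "meth": list(m2.shape)},
        },
    }
    if len(table) == 0:
        manifest["mimqtl"] = table.summary()
        manifest["accounting"] = accounting({})
        log.warning("run_full: no mimQTLs discovered; downstream stages skipped")
        if outdir is not None:
            _write_artifacts(Path(outdir), sim, normals, annotation, interval_sets,
                             loops, table, manifest)
        return manifest

    table = screen.classify_cis_trans(table, annotation)
    sign = screen.build_sign_matrix(table)
    mir_assign, cpg_assign = cluster.cluster_sign_matrix(sign, cfg.k_mirna, cfg.k_cpg)
    summaries = cluster.cluster_summaries(table, mir_assign, cpg_assign)

    # --- covariate annotation, matched to planted identities where synthetic
    ann1 = sim.samples[0]
    mir_map, mir_ari = match_clusters(mir_assign.labels, sim.truth.mirna_clusters)
    cpg_map, cpg_ari = match_clusters(cpg_assign.labels, sim.truth.cpg_clusters)
    inv = {v: k for k, v in mir_map.items()}
    background = set(e1.feature_ids)
    enrichments = {}
    for planted_label, cov, direction in (("A", "lymphocyte_score", "positive"),
                                          ("B", "fibroblast_score", "positive"),
                                          ("C", "esr1_expression", "positive")):
        alias = inv.get(planted_label)
        if alias is None:
            continue
        members = set(mir_assign.members(alias))
        res = annotate.cluster_covariate_enrichment(
            e1, ann1.covariate(cov), members, background, direction,
            name=f"{cov}:{alias}")
        enrichments[f"{cov}_cluster_{alias}"] = {
            "p_over": res.p_over, "fold": res.fold, "x": res.observed,
            "n": res.draws, "K": res.successes, "N": res.population,
        }

    # --- genomic context
    context_results = {}
    for iset in interval_sets:
        extend = cfg.extend_bp if iset.name == "TFBS" else 0
        by_cluster = {}
        for alias in cpg_assign.cluster_names:
            members = cpg_assign.members(alias)
            res = context.region_set_enrichment(
                members, iset, list(m1.feature_ids), annotation,
                extend_bp=extend)
            by_cluster[alias] = {"p_over": res.p_over, "fold": res.fold,
                                 "p_fisher": res.p_fisher, "x": res.observed}
        context_results[iset.name] = by_cluster
    hits = context.loop_hits(table, loops, annotation)
    loop_res = context.loop_enrichment(hits, table, annotation, loops)
    context_results["loops"] = {
        "n_hits": int(hits[["mirna_id", "cpg_id"]].drop_duplicates().shape[0]),
        "p_over": loop_res.p_over, "fold": loop_res.fold,
        "K": loop_res.successes, "N": loop_res.population, "n": loop_res.draws,
    }

    # --- GMA (cohort 1 vs normal panel)
    reference = gma.normal_reference(normals.subset_features(m1.feature_ids))
    gma_res = gma.gma_scores(m1, reference)
    er = ann1.covariate("er_status").reindex(gma_res.scores.index)
    stat, p_er = annotate.group_tests(gma_res.gma, er)
    members_by_cluster = {a: set(mir_assign.members(a)) for a in mir_assign.cluster_names}
    mimqtl_mirnas = set(table.mirnas)
    gma_expr = e1.subset_features(sorted(mimqtl_mirnas))
    _, gma_enrich = gma.gma_mirna_enrichment(gma_expr, gma_res, members_by_cluster,
                                             background=mimqtl_mirnas)
    gma_summary = {
        "er_wilcoxon_p": p_er,
        "er_positive_median": float(gma_res.gma[er == "positive"].median()),
        "er_negative_median": float(gma_res.gma[er == "negative"].median()),
        "cluster_enrichment": {
            a: {"p_over_positive": d["positive"].p_over,
                "p_over_negative": d["negative"].p_over}
            for a, d in gma_enrich.items()
        },
    }

    # --- manifest
    mimqtl_summary = table.summary()
    per_cluster_counts = {a: d["n_pairs"] for a, d in summaries["per_mirna_cluster"].items()}
    mirna_counts = {a: d["n_mirnas"] for a, d in summaries["per_mirna_cluster"].items()}
    manifest.update({
        "mimqtl": mimqtl_summary,
        "accounting": accounting(
            per_cluster_counts, mirna_counts, summaries["cpg_cluster_sizes"],
            significant_counts={
                "cohort1": (mimqtl_summary["n_significant_cohort1"], table.m[0]),
                "cohort2": (mimqtl_summary["n_significant_cohort2"], table.m[1]),
            },
            n_cis=mimqtl_summary.get("n_cis"),
        ),
        "clusters": {
            "mirna": {a: len(mir_assign.members(a)) for a in mir_assign.cluster_names},
            "cpg": {a: len(cpg_assign.members(a)) for a in cpg_assign.cluster_names},
        },
        "covariate_enrichment": enrichments,
        "genomic_context": context_results,
        "gma": gma_summary,
        "truth_recovery": {
            **planted_pair_sensitivity(table, sim.truth),
            "mirna_cluster_ari": mir_ari,
            "cpg_cluster_ari": cpg_ari,
            "mirna_cluster_mapping": mir_map,
            "cpg_cluster_mapping": cpg_map,
        },
    })
    if outdir is not None:
        _write_artifacts(Path(outdir), sim, normals, annotation, interval_sets,
                         loops, table, manifest, sign=sign,
                         mir_assign=mir_assign, cpg_assign=cpg_assign,
                         gma_res=gma_res)
    return manifest


def _write_artifacts(outdir: Path, sim, normals, annotation, interval_sets,
                     loops, table, manifest, sign=None, mir_assign=None,
                     cpg_assign=None, gma_res=None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (e, m, a) in enumerate(zip(sim.expr, sim.meth, sim.samples), 1):
        io.write_matrix(e, outdir / f"expr_cohort{i}.tsv")
        io.write_matrix(m, outdir / f"meth_cohort{i}.tsv")
        a.table.drop(columns=["_L", "_F", "_E"], errors="ignore").to_csv(
            outdir / f"samples_cohort{i}.tsv", sep="\t")
    io.write_matrix(normals, outdir / "meth_normals.tsv")
    io.write_annotation(annotation, outdir / "annotation.tsv")
    for iset in interval_sets:
        io.write_bed(iset, outdir / f"{iset.name}.bed")
    io.write_bedpe(loops, outdir / "loops.bedpe")
    io.write_table(table.records, outdir / "mimqtl_table.tsv")
    io.write_table(sim.truth.pairs, outdir / "truth_pairs.tsv")
    truth_features = pd.concat([
        sim.truth.mirna_clusters.rename("cluster").to_frame().assign(axis="mirna"),
        sim.truth.cpg_clusters.rename("cluster").to_frame().assign(axis="cpg"),
    ])
    truth_features.to_csv(outdir / "truth_features.tsv", sep="\t",
                          index_label="feature_id")
    if sign is not None:
        sign.to_csv(outdir / "sign_matrix.tsv", sep="\t")
    if mir_assign is not None:
        assign = pd.concat([
            mir_assign.labels.to_frame().assign(axis="mirna"),
            cpg_assign.labels.to_frame().assign(axis="cpg"),
        ])
        assign.to_csv(outdir / "cluster_assignments.tsv", sep="\t",
                      index_label="feature_id")
    if gma_res is not None:
        gma_res.scores.to_csv(outdir / "gma_scores.tsv", sep="\t",
                              index_label="sample_id")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report(manifest: dict) -> str:
    """Human-readable accounting summary of a run manifest."""
    if "mimqtl" not in manifest or "accounting" not in manifest:
        raise ValueError("incomplete manifest: missing mimqtl/accounting sections")
    acc = manifest["accounting"]
    mq = manifest["mimqtl"]
    lines = [f"mimQTL run (seed {manifest.get('seed', '?')})", "=" * 40]
    if acc["total_pairs"] == 0:
        lines.append("no mimQTLs discovered")
        return "\n".join(lines)
    lines.append(f"total mimQTLs: {acc['total_pairs']}")
    lines.append(f"unique miRNAs: {mq['n_unique_mirnas']}; unique CpGs: {mq['n_unique_cpgs']}")
    neg = 100 * mq["negative_fraction"]
    lines.append(f"sign: {neg:.2f}% negative ({round(neg)}% rounded), "
                 f"{100 - neg:.2f}% positive")
    for cohort, d in acc.get("significant", {}).items():
        lines.append(f"{cohort}: {d['n_significant']} / {d['n_tested']} significant "
                     f"({d['pct']:.4f}%, rounded {d['pct_rounded']}%)")
    for name, d in sorted(acc["per_cluster"].items()):
        lines.append(f"cluster {name}: {d['n_pairs']} pairs "
                     f"({d['share_pct']:.2f}%, rounded {d['share_pct_rounded']}%)")
    if "cis" in acc:
        lines.append(f"in cis: {acc['cis']['n_cis']} ({acc['cis']['pct']:.2f}%, "
                     f"rounded {acc['cis']['pct_rounded']}%)")
    return "\n".join(lines)
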