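"""Synthetic two-cohort generator with planted latent-factor structure.

The generator emulates the statistical skeleton of a matched miRNA-expression
/ CpG-methylation breast-cancer study: two independent tumor cohorts share
three latent per-sample factors —

* ``L`` — lymphocyte infiltration,
* ``F`` — fibroblast infiltration,
* ``E`` — estrogen-receptor (ER) signaling, a binary-status shift plus a
  continuous activity term, so that ER-positive tumors carry high ER
  signaling and ER-negative tumors sit near zero.

miRNA expression is linear in the factors on the log2 scale::

    x = mu + beta_L * L + beta_F * F + beta_E * E + eps

Methylation is generated on the logit scale and mapped through the inverse
logit, which keeps betas inside (0, 1) with realistic boundary compression
and preserves every rank correlation::

    beta = invlogit(b + gamma_L * L + gamma_F * F + gamma_E * E + eps)

Planted structure (defaults echo the three miRNA clusters and two CpG
clusters of the motivating analysis):

* miRNA cluster A loads positively on L, cluster B on F, cluster C on E;
* CpG cluster 1 loads negatively on E and positively on L;
* CpG cluster 2 loads negatively on L and negatively on F;
* all remaining features are null (no loadings).

Each planted miRNA-CpG pair therefore shares at least one factor, and the
expected correlation sign is the product of the two loading signs. Normal
tissue samples are drawn around the CpG baselines with small noise and no
factor loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GenomeAnnotation, IntervalSet, LoopSet, OmicsMatrix, SampleAnnotation

log = logging.getLogger("mimqtl")

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedCohorts",
    "simulate_cohorts",
    "simulate_normals",
    "simulate_annotations",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; ``seed`` fixes every random draw."""

    n_samples: tuple[int, int] = (300, 440)
    n_normals: int = 20
    n_mirnas: int = 346
    n_cpgs: int = 2000
    mirna_cluster_sizes: tuple[int, int, int] = (23, 59, 37)  # A, B, C
    cpg_cluster_sizes: tuple[int, int] = (300, 260)  # clusters 1, 2
    loading_scale: float = 1.0
    loading_jitter: float = 0.15
    expr_noise_sd: float = 0.8
    meth_noise_sd: float = 0.6
    normal_noise_sd: float = 0.15
    er_positive_fraction: float = 0.75
    er_shift: float = 2.0
    er_activity_sd: float = 0.6
    covariate_noise_sd: float = 0.3
    detection_floor_quantile: float = 0.05
    cohort2_scale: float = 1.25
    cohort2_shift: float = 0.3
    n_chromosomes: int = 5
    chrom_length: int = 10_000_000
    loop_fraction: float = 0.3
    n_decoy_loops: int = 50
    se_cluster1_fraction: float = 0.4
    background_interval_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples) < 2:
            raise ValueError("each cohort needs at least 2 samples")
        if sum(self.mirna_cluster_sizes) > self.n_mirnas:
            raise ValueError("miRNA cluster sizes exceed n_mirnas")
        if sum(self.cpg_cluster_sizes) > self.n_cpgs:
            raise ValueError("CpG cluster sizes exceed n_cpgs")
        for name in ("expr_noise_sd", "meth_noise_sd", "normal_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not np.isfinite(self.loading_scale):
            raise ValueError("loading_scale must be finite")
        if self.loading_scale == 0 and self.expr_noise_sd == 0:
            raise ValueError("degenerate config: zero loadings and zero noise")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class PlantedTruth:
    """Ground-truth ledger for parameter-recovery tests.

    ``mirna_clusters`` / ``cpg_clusters``: feature_id -> cluster label
    ("A"/"B"/"C", "1"/"2") or "null". ``loadings``: per-feature loadings on
    (L, F, E). ``pairs``: every planted miRNA-CpG pair with its expected
    correlation sign and shared factor. ``se_cpgs`` / ``tfbs_cpgs``: CpGs
    planted inside the super-enhancer / TFBS interval sets. ``loop_pairs``:
    planted cis pairs covered by a chromatin loop.
    """

    mirna_clusters: pd.Series
    cpg_clusters: pd.Series
    loadings: pd.DataFrame
    pairs: pd.DataFrame
    baselines: pd.Series
    se_cpgs: list = field(default_factory=list)
    tfbs_cpgs: list = field(default_factory=list)
    loop_pairs: pd.DataFrame | None = None


@dataclass
class SimulatedCohorts:
    expr: tuple[OmicsMatrix, OmicsMatrix]
    meth: tuple[OmicsMatrix, OmicsMatrix]
    samples: tuple[SampleAnnotation, SampleAnnotation]
    truth: PlantedTruth


def _feature_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    mirnas = [f"mir-{i:04d}" for i in range(cfg.n_mirnas)]
    cpgs = [f"cg{i:07d}" for i in range(cfg.n_cpgs)]
    return mirnas, cpgs


def _planted_labels(cfg: SimulationConfig) -> tuple[pd.Series, pd.Series]:
    mirnas, cpgs = _feature_ids(cfg)
    a, b, c = cfg.mirna_cluster_sizes
    m_lab = ["A"] * a + ["B"] * b + ["C"] * c + ["null"] * (cfg.n_mirnas - a - b - c)
    c1, c2 = cfg.cpg_cluster_sizes
    c_lab = ["1"] * c1 + ["2"] * c2 + ["null"] * (cfg.n_cpgs - c1 - c2)
    return (
        pd.Series(m_lab, index=mirnas, name="cluster"),
        pd.Series(c_lab, index=cpgs, name="cluster"),
    )


def _loadings(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-feature loadings on (L, F, E); magnitudes jittered around
    ``loading_scale`` so planted features are not exact clones."""
    m_lab, c_lab = _planted_labels(cfg)
    ids = list(m_lab.index) + list(c_lab.index)
    load = pd.DataFrame(0.0, index=ids, columns=["L", "F", "E"])

    def mag(n: int) -> np.ndarray:
        lo = cfg.loading_scale * (1 - cfg.loading_jitter)
        hi = cfg.loading_scale * (1 + cfg.loading_jitter)
        return rng.uniform(lo, hi, size=n)

    for label, col, sign in (("A", "L", +1), ("B", "F", +1), ("C", "E", +1)):
        idx = m_lab.index[m_lab == label]
        load.loc[idx, col] = sign * mag(len(idx))
    # CpG cluster 1: hypomethylated with ER signaling; half the cluster is
    # additionally hypermethylated with lymphocyte infiltration, so those
    # CpGs correlate with both cluster-C (negative) and cluster-A (positive)
    # miRNAs — mirroring the shared-CpG, opposite-sign overlap between the
    # immune and ER axes.
    idx1 = c_lab.index[c_lab == "1"]
    load.loc[idx1, "E"] = -mag(len(idx1))
    half = len(idx1) // 2
    load.loc[idx1[half:], "L"] = +mag(len(idx1) - half)
    # CpG cluster 2: hypomethylated with the microenvironment axes, split
    # into lymphocyte-only, fibroblast-only and mixed subgroups. The mixed
    # subgroup ties the two axes together so the cluster coheres at a 2-cut
    # while cluster-A and cluster-B miRNAs keep distinct CpG repertoires.
    idx2 = c_lab.index[c_lab == "2"]
    a = int(round(0.35 * len(idx2)))
    b = int(round(0.70 * len(idx2)))
    load.loc[idx2[:a], "L"] = -mag(a)
    load.loc[idx2[a:b], "F"] = -mag(b - a)
    load.loc[idx2[b:], "L"] = -mag(len(idx2) - b)
    load.loc[idx2[b:], "F"] = -mag(len(idx2) - b)
    return load


def _planted_pairs(m_lab: pd.Series, c_lab: pd.Series, load: pd.DataFrame) -> pd.DataFrame:
    """Enumerate all planted pairs: every (miRNA, CpG) couple with nonzero
    loadings on a shared factor; expected sign = product of loading signs
    (each miRNA loads on exactly one factor, so signs never conflict)."""
    rows = []
    mirnas = m_lab.index[m_lab != "null"]
    cpgs = c_lab.index[c_lab != "null"]
    for factor in ("L", "F", "E"):
        ms = [m for m in mirnas if load.at[m, factor] != 0]
        cs = [c for c in cpgs if load.at[c, factor] != 0]
        for m in ms:
            bm = load.at[m, factor]
            for c in cs:
                gc = load.at[c, factor]
                rows.append((m, c, int(np.sign(bm * gc)), factor))
    return pd.DataFrame(rows, columns=["mirna_id", "cpg_id", "expected_sign", "factor"])


def _draw_factors(cfg: SimulationConfig, n: int, rng: np.random.Generator,
                  prefix: str) -> SampleAnnotation:
    """Draw per-sample latent factors and the observed covariates derived
    from them (infiltration scores, ESR1 expression, ER status)."""
    er_pos = rng.random(n) < cfg.er_positive_fraction
    L = rng.normal(0.0, 1.0, n)
    F = rng.normal(0.0, 1.0, n)
    E = cfg.er_shift * er_pos + rng.normal(0.0, cfg.er_activity_sd, n)
    sd = cfg.covariate_noise_sd
    table = pd.DataFrame(
        {
            "er_status": np.where(er_pos, "positive", "negative"),
            "subtype_label": np.where(er_pos, "luminal-like", "basal-like"),
            "lymphocyte_score": L + rng.normal(0, sd, n),
            "fibroblast_score": F + rng.normal(0, sd, n),
            "esr1_expression": E + rng.normal(0, sd, n),
            "_L": L,
            "_F": F,
            "_E": E,
        },
        index=pd.Index([f"{prefix}_{i:04d}" for i in range(n)], name="sample_id"),
    )
    ann = SampleAnnotation(table)
    ann.add_quartile_groups("lymphocyte_score")
    ann.add_quartile_groups("fibroblast_score")
    return ann


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _cohort_matrices(cfg: SimulationConfig, ann: SampleAnnotation,
                     load: pd.DataFrame, mu: pd.Series, baselines: pd.Series,
                     rng: np.random.Generator) -> tuple[OmicsMatrix, OmicsMatrix]:
    mirnas, cpgs = _feature_ids(cfg)
    Z = ann.table[["_L", "_F", "_E"]].to_numpy().T  # 3 x n
    n = Z.shape[1]

    Bm = load.loc[mirnas].to_numpy()  # miRNAs x 3
    expr = mu.to_numpy()[:, None] + Bm @ Z + rng.normal(0, cfg.expr_noise_sd, (len(mirnas), n))
    # Common detection floor: everything below the floor quantile is set to
    # the floor value (the "non-expressed miRNAs set to a common minimum"
    # convention of array data).
    if cfg.detection_floor_quantile > 0:
        floor = np.quantile(expr, cfg.detection_floor_quantile)
        expr = np.maximum(expr, floor)

    Bc = load.loc[cpgs].to_numpy()
    latent = baselines.to_numpy()[:, None] + Bc @ Z + rng.normal(
        0, cfg.meth_noise_sd, (len(cpgs), n)
    )
    meth = _invlogit(latent)

    samples = ann.sample_ids
    return (
        OmicsMatrix(pd.DataFrame(expr, index=mirnas, columns=samples), "expression"),
        OmicsMatrix(pd.DataFrame(meth, index=cpgs, columns=samples), "methylation"),
    )


def simulate_cohorts(cfg: SimulationConfig) -> SimulatedCohorts:
    """Generate two matched cohorts sharing feature loadings but with
    independent samples and noise; cohort 2's expression additionally gets a
    global affine perturbation (rank-preserving) to exercise the method's
    reliance on ranks."""
    rng = np.random.default_rng(cfg.seed)
    m_lab, c_lab = _planted_labels(cfg)
    load = _loadings(cfg, rng)
    mirnas, cpgs = _feature_ids(cfg)
    mu = pd.Series(rng.uniform(2.0, 10.0, cfg.n_mirnas), index=mirnas)
    # Planted CpGs get mid-range baselines (room to move in both directions);
    # null CpGs span the full dynamic range.
    baselines = pd.Series(rng.uniform(-2.0, 2.0, cfg.n_cpgs), index=cpgs)
    planted = c_lab != "null"
    baselines[planted] = rng.uniform(-1.0, 1.0, int(planted.sum()))

    ann1 = _draw_factors(cfg, cfg.n_samples[0], rng, "c1")
    ann2 = _draw_factors(cfg, cfg.n_samples[1], rng, "c2")
    expr1, meth1 = _cohort_matrices(cfg, ann1, load, mu, baselines, rng)
    expr2, meth2 = _cohort_matrices(cfg, ann2, load, mu, baselines, rng)
    expr2 = OmicsMatrix(
        expr2.values * cfg.cohort2_scale + cfg.cohort2_shift, "expression"
    )

    truth = PlantedTruth(
        mirna_clusters=m_lab,
        cpg_clusters=c_lab,
        loadings=load,
        pairs=_planted_pairs(m_lab, c_lab, load),
        baselines=baselines,
    )
    log.info(
        "simulated cohorts: %d + %d samples, %d miRNAs, %d CpGs, %d planted pairs",
        *cfg.n_samples, cfg.n_mirnas, cfg.n_cpgs, len(truth.pairs),
    )
    return SimulatedCohorts((expr1, expr2), (meth1, meth2), (ann1, ann2), truth)


def simulate_normals(cfg: SimulationConfig, truth: PlantedTruth | None = None) -> OmicsMatrix:
    """Normal-tissue methylation: baseline betas plus small noise, no factor
    loadings. Uses a seed stream offset so normals are reproducible whether
    or not the tumor cohorts were generated first."""
    if cfg.n_normals < 2:
        raise ValueError("need at least 2 normal samples for a median reference")
    rng = np.random.default_rng((cfg.seed, 1))
    if truth is None:
        truth = simulate_cohorts(cfg).truth
    baselines = truth.baselines
    latent = baselines.to_numpy()[:, None] + rng.normal(
        0, cfg.normal_noise_sd, (len(baselines), cfg.n_normals)
    )
    cols = [f"normal_{i:03d}" for i in range(cfg.n_normals)]
    return OmicsMatrix(
        pd.DataFrame(_invlogit(latent), index=baselines.index, columns=cols),
        "methylation",
    )


def simulate_annotations(
    cfg: SimulationConfig, truth: PlantedTruth
) -> tuple[GenomeAnnotation, list[IntervalSet], LoopSet]:
    """Place features on chromosomes and plant genomic-context enrichments.

    * features spread over ``n_chromosomes`` chromosomes (so cis and trans
      pairs both occur);
    * a ``se_cluster1_fraction`` of cluster-1 CpGs sit inside the "SE"
      (super-enhancer) and "TFBS" interval sets, versus a smaller
      ``background_interval_fraction`` of all other CpGs;
    * a ``loop_fraction`` of planted cis pairs get a chromatin loop with one
      foot on the CpG and the other on the miRNA precursor, plus decoy loops.
    """
    rng = np.random.default_rng((cfg.seed, 2))
    mirnas, cpgs = _feature_ids(cfg)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    rows = []
    for m in mirnas:
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(10_000, cfg.chrom_length - 10_000))
        rows.append((m, chrom, start, start + 79, "+"))
    for c in cpgs:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(10_000, cfg.chrom_length - 10_000))
        rows.append((c, chrom, pos, pos, "."))
    ann = GenomeAnnotation(
        pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "strand"])
        .set_index("feature_id")
    )

    # Interval sets with planted enrichment of cluster-1 CpGs.
    cluster1 = list(truth.cpg_clusters.index[truth.cpg_clusters == "1"])
    others = list(truth.cpg_clusters.index[truth.cpg_clusters != "1"])
    interval_sets = []
    for set_name, half_width in (("SE", 500), ("TFBS", 200)):
        n_in = int(round(cfg.se_cluster1_fraction * len(cluster1)))
        n_bg = int(round(cfg.background_interval_fraction * len(others)))
        chosen = list(rng.choice(cluster1, size=n_in, replace=False)) + list(
            rng.choice(others, size=n_bg, replace=False)
        )
        recs = []
        for c in chosen:
            chrom, s, e = ann.half_open(c)
            recs.append((chrom, max(0, s - half_width), e + half_width, c))
        # plus intervals covering no CpG at all
        for i in range(40):
            chrom = chroms[rng.integers(len(chroms))]
            s = int(rng.integers(0, cfg.chrom_length))
            recs.append((chrom, s, s + 2 * half_width, f"empty_{i}"))
        interval_sets.append(
            IntervalSet(set_name, pd.DataFrame(recs, columns=["chrom", "start", "end", "label"]))
        )
        if set_name == "SE":
            truth.se_cpgs = sorted(chosen)
        else:
            truth.tfbs_cpgs = sorted(chosen)

    # Loops over planted cis pairs.
    pair_chrom_m = truth.pairs["mirna_id"].map(ann.table["chrom"])
    pair_chrom_c = truth.pairs["cpg_id"].map(ann.table["chrom"])
    cis_pairs = truth.pairs[pair_chrom_m.values == pair_chrom_c.values]
    n_loops = int(round(cfg.loop_fraction * len(cis_pairs)))
    loop_rows, truth_rows = [], []
    if n_loops:
        take = cis_pairs.iloc[
            rng.choice(len(cis_pairs), size=n_loops, replace=False)
        ]
        for _, pair in take.iterrows():
            chrom, cs, ce = ann.half_open(pair["cpg_id"])
            _, ms, me = ann.half_open(pair["mirna_id"])
            foot_c = (max(0, cs - 1000), ce + 1000)
            foot_m = (max(0, ms - 1000), me + 1000)
            if not (foot_c[1] <= foot_m[0] or foot_m[1] <= foot_c[0]):
                continue  # feet would overlap; skip this pair
            loop_rows.append((chrom, *foot_c, chrom, *foot_m))
            truth_rows.append((pair["mirna_id"], pair["cpg_id"]))
    for _ in range(cfg.n_decoy_loops):
        chrom = chroms[rng.integers(len(chroms))]
        s1 = int(rng.integers(0, cfg.chrom_length - 100_000))
        s2 = s1 + 50_000
        loop_rows.append((chrom, s1, s1 + 2000, chrom, s2, s2 + 2000))
    loops = LoopSet(
        "loops",
        pd.DataFrame(
            loop_rows,
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        ),
    )
    truth.loop_pairs = pd.DataFrame(truth_rows, columns=["mirna_id", "cpg_id"])
    log.info(
        "simulated annotations: %d chromosomes, %d loops (%d planted)",
        cfg.n_chromosomes, len(loops), len(truth_rows),
    )
    return ann, interval_sets, loops
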