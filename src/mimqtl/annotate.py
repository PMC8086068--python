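"""Cluster annotation statistics: covariate correlations, hypergeometric
enrichment, multivariate linear models of miRNA expression, co-expressed
gene selection, and nonparametric group tests with BH correction."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OmicsMatrix, SampleAnnotation
from .screen import spearman_pvalue

log = logging.getLogger("mimqtl")

__all__ = [
    "EnrichmentResult",
    "GlmFit",
    "covariate_correlations",
    "flag_correlated",
    "hypergeom_enrichment",
    "cluster_covariate_enrichment",
    "glm_mirna",
    "select_coexpressed_genes",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "group_tests",
    "bh_adjust",
]


@dataclass
class EnrichmentResult:
    """Hypergeometric (or Fisher) enrichment of a flagged subset within a
    member set drawn from a finite background."""

    name: str
    population: int  # N
    successes: int  # K: flagged in background
    draws: int  # n: members
    observed: int  # x: flagged members
    p_over: float  # P[X >= x]
    p_under: float  # P[X <= x]
    fold: float  # (x/n) / (K/N)
    p_fisher: float | None = None
    padj: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= min(self.draws, self.successes):
            raise ValueError("inconsistent enrichment counts")


def covariate_correlations(expr: OmicsMatrix, covariate: pd.Series) -> pd.DataFrame:
    """Spearman rho and two-sided p of every miRNA against one per-sample
    covariate (midranks; t-approximation p, matching the screening engine)."""
    cov = covariate.reindex(expr.sample_ids)
    mask = cov.notna().to_numpy()
    if mask.sum() < 3:
        raise ValueError("covariate defined on fewer than 3 samples")
    y = cov.to_numpy(dtype=float)[mask]
    if np.all(y == y[0]):
        raise ValueError("constant covariate: correlation undefined")
    X = expr.values.to_numpy()[:, mask]
    ry = stats.rankdata(y)
    ry = ry - ry.mean()
    ny = np.sqrt((ry ** 2).sum())
    rX = stats.rankdata(X, axis=1, method="average")
    rX = rX - rX.mean(axis=1, keepdims=True)
    nX = np.sqrt((rX ** 2).sum(axis=1))
    zero = nX == 0
    nX[zero] = 1.0
    rho = np.clip((rX / nX[:, None]) @ (ry / ny), -1.0, 1.0)
    rho[zero] = np.nan
    p = spearman_pvalue(rho, mask.sum())
    return pd.DataFrame({"rho": rho, "p": p}, index=expr.feature_ids)


def flag_correlated(corr: pd.DataFrame, direction: str = "positive",
                    rho_threshold: float = 0.0, alpha: float = 0.05) -> set[str]:
    """Flag features whose correlation is significant (p < alpha) and beyond
    the rho threshold in the requested direction."""
    if direction == "positive":
        mask = (corr["rho"] > rho_threshold) & (corr["p"] < alpha)
    elif direction == "negative":
        mask = (corr["rho"] < -rho_threshold) & (corr["p"] < alpha)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return set(corr.index[mask.fillna(False)])


def hypergeom_enrichment(members: set, flagged: set, background: set,
                         name: str = "") -> EnrichmentResult:
    """Exact hypergeometric tail probabilities for over- and
    under-representation of ``flagged`` within ``members``, relative to
    ``background``."""
    background = set(background)
    if not background:
        raise ValueError("empty background")
    members = set(members) & background
    flagged = set(flagged) & background
    N, K, n = len(background), len(flagged), len(members)
    x = len(members & flagged)
    dist = stats.hypergeom(N, K, n)
    p_over = float(dist.sf(x - 1))
    p_under = float(dist.cdf(x))
    expected = n * K / N
    fold = (x / expected) if expected > 0 else float("nan")
    return EnrichmentResult(name, N, K, n, x, min(p_over, 1.0), min(p_under, 1.0), fold)


def cluster_covariate_enrichment(expr: OmicsMatrix, covariate: pd.Series,
                                 members: set, background: set | None = None,
                                 direction: str = "positive",
                                 name: str = "") -> EnrichmentResult:
    """Convenience: correlate all background miRNAs with a covariate, flag
    the significant ones in ``direction``, and test the cluster ``members``
    for enrichment of flags."""
    background = set(background) if background is not None else set(expr.feature_ids)
    sub = expr.subset_features(sorted(background))
    corr = covariate_correlations(sub, covariate)
    flagged = flag_correlated(corr, direction)
    res = hypergeom_enrichment(members, flagged, background, name=name)
    log.info("enrichment %s (%s): x=%d/%d flagged K=%d/%d, p_over=%.3g",
             name, direction, res.observed, res.draws, res.successes,
             res.population, res.p_over)
    return res


@dataclass
class GlmFit:
    """Gaussian identity-link GLM (ordinary least squares) of one miRNA's
    expression on the microenvironment covariates."""

    feature_id: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper (95%)
    df_resid: int
    nobs: int
    resid: np.ndarray


def glm_mirna(y: pd.Series, covariates: SampleAnnotation | pd.DataFrame,
              columns: tuple[str, ...] = ("lymphocyte_score", "fibroblast_score",
                                          "esr1_expression")) -> GlmFit:
    """Model one miRNA's expression as intercept + lymphocyte + fibroblast +
    ESR1 (OLS; Wald t p-values; 95% CIs = estimate +/- t_{0.975,df} * SE)."""
    import statsmodels.api as sm

    table = covariates.table if isinstance(covariates, SampleAnnotation) else covariates
    X = table.loc[y.index, list(columns)].astype(float)
    data = pd.concat([y.rename("y"), X], axis=1).dropna()
    if len(data) < 10:
        raise ValueError("need at least 10 complete cases for the GLM")
    design = sm.add_constant(data[list(columns)])
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = design.iloc[:, 1:].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design matrix (collinear columns, "
                         f"e.g. {worst[0]} ~ {worst[1]})")
    fit = sm.OLS(data["y"], design).fit()
    ci = fit.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return GlmFit(
        feature_id=str(y.name),
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        conf_int=ci,
        df_resid=int(fit.df_resid),
        nobs=int(fit.nobs),
        resid=np.asarray(fit.resid),
    )


def select_coexpressed_genes(mirna_expr: tuple[pd.Series, pd.Series],
                             gene_expr: tuple[OmicsMatrix, OmicsMatrix],
                             pos_threshold: float = 0.4,
                             neg_threshold: float = -0.3,
                             alpha: float = 0.05) -> dict[str, list[str]]:
    """Genes positively (rho > pos_threshold, p < alpha) or negatively
    (rho < neg_threshold, p < alpha) correlated with a miRNA in BOTH
    cohorts, same direction."""
    corrs = []
    for series, genes in zip(mirna_expr, gene_expr):
        corrs.append(covariate_correlations(genes, series))
    c1, c2 = corrs
    common = c1.index.intersection(c2.index)
    c1, c2 = c1.loc[common], c2.loc[common]
    pos = common[(c1["rho"] > pos_threshold) & (c1["p"] < alpha)
                 & (c2["rho"] > pos_threshold) & (c2["p"] < alpha)]
    neg = common[(c1["rho"] < neg_threshold) & (c1["p"] < alpha)
                 & (c2["rho"] < neg_threshold) & (c2["p"] < alpha)]
    return {"positive": sorted(pos), "negative": sorted(neg)}


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U). Exact enumeration when
    both groups have n <= 10 and there are no ties; otherwise the normal
    approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group in Wilcoxon test")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    log.debug("wilcoxon_rank_sum: %s branch, U=%g, p=%g", method, res.statistic, res.pvalue)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test (chi-square approximation) for >= 3 groups."""
    for g in groups:
        if len(g) == 0:
            raise ValueError("empty group in Kruskal-Wallis test")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def group_tests(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """Dispatch on the number of groups: 2 -> Wilcoxon rank-sum,
    >= 3 -> Kruskal-Wallis."""
    df = pd.DataFrame({"v": values, "g": labels}).dropna()
    groups = [grp["v"].to_numpy() for _, grp in df.groupby("g")]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if len(groups) == 2:
        return wilcoxon_rank_sum(groups[0], groups[1])
    return kruskal_wallis(*groups)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
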