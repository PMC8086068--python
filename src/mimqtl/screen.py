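"""Genome-wide miRNA-CpG association screening and mimQTL calling.

A *mimQTL* is a miRNA-CpG pair whose expression and methylation are
significantly Spearman-correlated, with the same sign, in both cohorts
(Bonferroni-adjusted p < alpha in each cohort).

Spearman rho is computed with average ranks (midranks for ties); the
two-sided p-value uses the t approximation ``t = rho * sqrt((n-2) /
(1-rho^2))`` on ``n - 2`` degrees of freedom — the same fallback R's
``cor.test`` uses in the presence of ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenomeAnnotation, OmicsMatrix

log = logging.getLogger("mimqtl")

__all__ = [
    "ScreenResult",
    "MimQTLTable",
    "spearman_screen",
    "spearman_pvalue",
    "bonferroni_adjust",
    "call_mimqtls",
    "build_sign_matrix",
    "classify_cis_trans",
]

MIN_PAIR_N = 8  # pairs evaluated on fewer samples are excluded


@dataclass
class ScreenResult:
    """Per-cohort screening output: miRNA x CpG matrices of rho, raw p and
    Bonferroni-adjusted p; ``m`` is the test-family size (pairs actually
    tested, i.e. with defined rho and n_used >= 8)."""

    rho: pd.DataFrame
    p: pd.DataFrame
    padj: pd.DataFrame
    n_used: pd.DataFrame
    m: int


@dataclass
class MimQTLTable:
    """Cross-cohort sign-concordant significant associations."""

    records: pd.DataFrame  # mirna_id,cpg_id,rho1,p1,padj1,rho2,p2,padj2,sign[,cis_trans]
    m: tuple[int, int]
    alpha: float
    n_significant: tuple[int, int] = (0, 0)
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.records["mirna_id"].unique())

    @property
    def cpgs(self) -> list[str]:
        return sorted(self.records["cpg_id"].unique())

    def summary(self) -> dict:
        n = len(self.records)
        neg = int((self.records["sign"] < 0).sum()) if n else 0
        out = {
            "n_mimqtls": n,
            "n_unique_mirnas": self.records["mirna_id"].nunique() if n else 0,
            "n_unique_cpgs": self.records["cpg_id"].nunique() if n else 0,
            "negative_fraction": neg / n if n else float("nan"),
            "positive_fraction": (n - neg) / n if n else float("nan"),
            "m_cohort1": self.m[0],
            "m_cohort2": self.m[1],
            "n_significant_cohort1": self.n_significant[0],
            "n_significant_cohort2": self.n_significant[1],
            "alpha": self.alpha,
        }
        if "cis_trans" in self.records.columns and n:
            known = self.records[self.records["cis_trans"] != "unknown"]
            n_cis = int((known["cis_trans"] == "cis").sum())
            out["n_cis"] = n_cis
            out["cis_fraction"] = n_cis / len(known) if len(known) else float("nan")
        return out


def spearman_pvalue(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation (n-2 df)."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2.0) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2.0, 1.0))
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho), np.nan, np.minimum(p, 1.0))


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=1, method="average")


def _screen_complete(expr: np.ndarray, meth: np.ndarray) -> np.ndarray:
    """Vectorized Spearman rho for complete matrices: Pearson on midranks."""
    ra = _rank_rows(expr)
    rb = _rank_rows(meth)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.sqrt((ra ** 2).sum(axis=1))
    nb = np.sqrt((rb ** 2).sum(axis=1))
    zero_a, zero_b = na == 0, nb == 0
    na[zero_a] = 1.0
    nb[zero_b] = 1.0
    rho = (ra / na[:, None]) @ (rb / nb[:, None]).T
    rho = np.clip(rho, -1.0, 1.0)
    rho[zero_a, :] = np.nan  # zero-variance feature: rho undefined
    rho[:, zero_b] = np.nan
    return rho


def spearman_screen(expr: OmicsMatrix, meth: OmicsMatrix,
                    alpha: float = 0.05) -> ScreenResult:
    """Screen every miRNA x CpG pair for Spearman correlation.

    Sample ids must match between the matrices (any order). Complete
    matrices take a fast vectorized path; matrices with missing values are
    evaluated pairwise-complete per pair (small inputs only). Pairs with
    n_used < 8 or undefined rho (zero variance) are excluded from the test
    family and carry NaN.
    """
    if set(expr.sample_ids) != set(meth.sample_ids):
        raise ValueError("expression and methylation matrices must share sample ids")
    meth = meth.subset_samples(expr.sample_ids)
    E = expr.values.to_numpy()
    M = meth.values.to_numpy()
    n = E.shape[1]

    if not (np.isnan(E).any() or np.isnan(M).any()):
        rho = _screen_complete(E, M)
        n_used = np.full(rho.shape, n)
        if n < MIN_PAIR_N:
            rho[:] = np.nan
    else:
        if E.shape[0] * M.shape[0] > 200_000:
            log.warning("pairwise-complete screen on %d pairs: this path is slow; "
                        "impute first for genome-scale inputs",
                        E.shape[0] * M.shape[0])
        rho = np.full((E.shape[0], M.shape[0]), np.nan)
        n_used = np.zeros(rho.shape, dtype=int)
        for i in range(E.shape[0]):
            ei = E[i]
            for j in range(M.shape[0]):
                mask = ~(np.isnan(ei) | np.isnan(M[j]))
                k = int(mask.sum())
                n_used[i, j] = k
                if k < MIN_PAIR_N:
                    continue
                x, y = ei[mask], M[j][mask]
                if np.all(x == x[0]) or np.all(y == y[0]):
                    continue  # zero variance: rho undefined, pair skipped
                rho[i, j] = stats.spearmanr(x, y).statistic

    nu = np.where(np.isnan(rho), 0, n_used)
    p = spearman_pvalue(rho, np.maximum(n_used, 3))
    p = np.where(np.isnan(rho), np.nan, p)
    m = int(np.sum(~np.isnan(rho)))
    if m == 0:
        raise ValueError("no testable pairs (all excluded)")
    padj = bonferroni_adjust(p, m)
    idx, cols = expr.feature_ids, meth.feature_ids
    log.info("spearman_screen: %d miRNAs x %d CpGs, m=%d tested pairs, n=%d samples",
             len(idx), len(cols), m, n)
    return ScreenResult(
        rho=pd.DataFrame(rho, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        padj=pd.DataFrame(padj, index=idx, columns=cols),
        n_used=pd.DataFrame(nu, index=idx, columns=cols),
        m=m,
    )


def bonferroni_adjust(p, m: int):
    """Bonferroni adjustment: padj = min(1, p * m)."""
    if m <= 0:
        raise ValueError("test-family size m must be positive")
    if isinstance(p, pd.DataFrame):
        return (p * m).clip(upper=1.0)
    return np.minimum(np.asarray(p, dtype=float) * m, 1.0)


def call_mimqtls(screen1: ScreenResult, screen2: ScreenResult,
                 alpha: float = 0.05) -> MimQTLTable:
    """Retain pairs significant (padj < alpha) in BOTH cohorts with the
    same correlation sign."""
    if not (screen1.rho.index.equals(screen2.rho.index)
            and screen1.rho.columns.equals(screen2.rho.columns)):
        raise ValueError("cohorts were screened on different feature universes")
    r1, r2 = screen1.rho.to_numpy(), screen2.rho.to_numpy()
    a1, a2 = screen1.padj.to_numpy(), screen2.padj.to_numpy()
    with np.errstate(invalid="ignore"):
        sig1 = a1 < alpha
        sig2 = a2 < alpha
        keep = sig1 & sig2 & (np.sign(r1) == np.sign(r2)) & (r1 != 0) & (r2 != 0)
    ii, jj = np.nonzero(keep)
    records = pd.DataFrame(
        {
            "mirna_id": screen1.rho.index[ii],
            "cpg_id": screen1.rho.columns[jj],
            "rho1": r1[ii, jj],
            "p1": screen1.p.to_numpy()[ii, jj],
            "padj1": a1[ii, jj],
            "rho2": r2[ii, jj],
            "p2": screen2.p.to_numpy()[ii, jj],
            "padj2": a2[ii, jj],
            "sign": np.sign(r1[ii, jj]).astype(int),
        }
    )
    n1, n2 = int(np.nansum(sig1)), int(np.nansum(sig2))
    log.info("call_mimqtls: %d significant in cohort 1 (m=%d), %d in cohort 2 (m=%d), "
             "%d sign-concordant mimQTLs", n1, screen1.m, n2, screen2.m, len(records))
    return MimQTLTable(records, (screen1.m, screen2.m), alpha, (n1, n2))


def build_sign_matrix(table: MimQTLTable) -> pd.DataFrame:
    """CpG x miRNA matrix over {-1, 0, +1}; only features with at least one
    significant association are included."""
    if len(table) == 0:
        raise ValueError("cannot build a sign matrix from an empty mimQTL table")
    sign = table.records.pivot_table(
        index="cpg_id", columns="mirna_id", values="sign",
        aggfunc="first", fill_value=0,
    ).astype(int)
    return sign


def classify_cis_trans(table: MimQTLTable, annotation: GenomeAnnotation) -> MimQTLTable:
    """Flag each record cis (same chromosome) or trans; features without an
    annotation entry are flagged 'unknown' and excluded from cis summaries."""
    chrom = annotation.table["chrom"]
    cm = table.records["mirna_id"].map(chrom)
    cc = table.records["cpg_id"].map(chrom)
    flags = np.where(
        cm.isna() | cc.isna(), "unknown", np.where(cm == cc, "cis", "trans")
    )
    records = table.records.copy()
    records["cis_trans"] = flags
    n_unknown = int((records["cis_trans"] == "unknown").sum())
    if n_unknown:
        log.warning("classify_cis_trans: %d pairs with unannotated features", n_unknown)
    out = MimQTLTable(records, table.m, table.alpha, table.n_significant,
                      dict(table.extras))
    s = out.summary()
    log.info("classify_cis_trans: %s cis pairs (%.2f%%)",
             s.get("n_cis", 0), 100 * s.get("cis_fraction", float("nan")))
    return out
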