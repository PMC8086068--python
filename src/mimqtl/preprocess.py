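"""Feature filtering, imputation and normalization.

Order of operations in the pipeline: remove high-missing CpGs -> kNN
imputation -> IQR filter -> detection filter (expression) -> cross-cohort
feature intersection. Thresholds are strict inequalities (IQR > 0.1,
detected fraction > 10%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

log = logging.getLogger("mimqtl")

__all__ = [
    "PreprocessConfig",
    "filter_cpgs_by_iqr",
    "filter_mirnas_by_detection",
    "detect_floor",
    "remove_high_missing",
    "intersect_features",
    "knn_impute",
    "normalize_expression",
]


@dataclass
class PreprocessConfig:
    iqr_threshold: float = 0.1
    detection_fraction: float = 0.10
    knn_k: int = 10
    max_missing_fraction: float = 0.5
    floor: float | None = None  # detection floor; None = auto-detect

    def __post_init__(self) -> None:
        if not 0 <= self.detection_fraction < 1:
            raise ValueError("detection_fraction must be in [0, 1)")
        if self.iqr_threshold < 0:
            raise ValueError("iqr_threshold must be >= 0")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")


def row_iqr(values: np.ndarray) -> np.ndarray:
    """Per-row interquartile range over non-missing values, using
    linear-interpolation quantiles (R type-7, the numpy default)."""
    q75 = np.nanpercentile(values, 75, axis=1)
    q25 = np.nanpercentile(values, 25, axis=1)
    return q75 - q25


def filter_cpgs_by_iqr(meth: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """Keep CpGs with IQR strictly greater than the threshold. Rows with
    fewer than 4 non-missing values are excluded (quartiles unstable)."""
    cfg = cfg or PreprocessConfig()
    values = meth.values.to_numpy()
    n_ok = np.sum(~np.isnan(values), axis=1)
    too_sparse = n_ok < 4
    if too_sparse.any():
        log.warning("IQR filter: excluding %d rows with < 4 non-missing values",
                    int(too_sparse.sum()))
    with np.errstate(all="ignore"):
        iqr = row_iqr(values)
    keep = (~too_sparse) & (iqr > cfg.iqr_threshold)
    out = meth.subset_features(meth.feature_ids[keep])
    log.info("IQR filter (> %g): %d -> %d CpGs", cfg.iqr_threshold,
             len(meth.feature_ids), out.shape[0])
    return out


def detect_floor(expr: OmicsMatrix, min_mass: float = 0.05) -> float:
    """Auto-detect the common 'undetected' floor value: the global minimum,
    provided it carries at least ``min_mass`` of the non-missing entries
    (the common-minimum convention of floored array data). If the minimum is
    not a mass point, every value is treated as detected (-inf floor)."""
    arr = expr.values.to_numpy()
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("cannot detect floor of an all-missing matrix")
    mn = finite.min()
    mass = np.mean(finite == mn)
    if mass >= min_mass:
        log.info("detection floor auto-detected at %g (mass %.1f%%)", mn, 100 * mass)
        return float(mn)
    log.info("no floor mass point (min carries %.2f%% mass); all values detected", 100 * mass)
    return float("-inf")


def filter_mirnas_by_detection(expr: OmicsMatrix, cfg: PreprocessConfig | None = None,
                               floor: float | None = None) -> OmicsMatrix:
    """Keep miRNAs detected (strictly above the floor) in more than
    ``detection_fraction`` of samples."""
    cfg = cfg or PreprocessConfig()
    if floor is None:
        floor = cfg.floor
    if floor is None:
        floor = detect_floor(expr)
    values = expr.values.to_numpy()
    with np.errstate(invalid="ignore"):
        detected = np.nansum(values > floor, axis=1)
    n = np.sum(~np.isnan(values), axis=1)
    frac = np.where(n > 0, detected / np.maximum(n, 1), 0.0)
    keep = frac > cfg.detection_fraction
    out = expr.subset_features(expr.feature_ids[keep])
    out.meta["detection_floor"] = floor
    log.info("detection filter (> %.0f%% of samples above %g): %d -> %d miRNAs",
             100 * cfg.detection_fraction, floor, expr.shape[0], out.shape[0])
    return out


def remove_high_missing(meth: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """Drop rows whose missing fraction exceeds ``max_missing_fraction``."""
    cfg = cfg or PreprocessConfig()
    frac = meth.values.isna().mean(axis=1)
    keep = frac <= cfg.max_missing_fraction
    out = meth.subset_features(meth.feature_ids[keep])
    log.info("missingness filter (<= %.0f%%): %d -> %d rows",
             100 * cfg.max_missing_fraction, meth.shape[0], out.shape[0])
    return out


def intersect_features(a: OmicsMatrix, b: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both matrices to the feature-id intersection, identical order."""
    if a.kind != b.kind:
        raise ValueError(f"cannot intersect kinds {a.kind!r} and {b.kind!r}")
    common = [fid for fid in a.feature_ids if fid in set(b.feature_ids)]
    if not common:
        raise ValueError("empty feature intersection between cohorts")
    log.info("feature intersection: %d & %d -> %d", a.shape[0], b.shape[0], len(common))
    return a.subset_features(common), b.subset_features(common)


def _row_distances(values: np.ndarray, i: int) -> np.ndarray:
    """RMS distance from row i to every row over shared non-missing columns."""
    xi = values[i]
    diff = values - xi
    sq = diff ** 2
    shared = ~np.isnan(sq)
    counts = shared.sum(axis=1)
    with np.errstate(invalid="ignore"):
        msd = np.nansum(np.where(shared, sq, 0.0), axis=1) / np.maximum(counts, 1)
    d = np.sqrt(msd)
    d[counts == 0] = np.inf
    return d


def knn_impute(meth: OmicsMatrix, cfg: PreprocessConfig | None = None) -> OmicsMatrix:
    """k-nearest-neighbour imputation over feature rows.

    Each missing cell (row i, sample s) is replaced by the mean of sample
    s's values over the k nearest rows (RMS distance on shared non-missing
    columns) that are observed at s. If fewer than k such neighbour rows
    exist, falls back to the row mean with a warning. Non-missing cells are
    never altered.
    """
    cfg = cfg or PreprocessConfig()
    values = meth.values.to_numpy().copy()
    missing_rows = np.where(np.isnan(values).any(axis=1))[0]
    if missing_rows.size == 0:
        return meth.copy()
    filled = values.copy()
    for i in missing_rows:
        d = _row_distances(values, i)
        d[i] = np.inf
        order = np.argsort(d, kind="stable")
        row_mean = np.nanmean(values[i])
        for j in np.where(np.isnan(values[i]))[0]:
            candidates = order[np.isfinite(d[order]) & ~np.isnan(values[order, j])]
            if len(candidates) < cfg.knn_k:
                log.warning(
                    "knn_impute: row %s sample %s has %d < k=%d usable neighbours; "
                    "using row mean", meth.feature_ids[i], meth.sample_ids[j],
                    len(candidates), cfg.knn_k)
                filled[i, j] = row_mean
            else:
                filled[i, j] = values[candidates[: cfg.knn_k], j].mean()
    out = pd.DataFrame(filled, index=meth.feature_ids, columns=meth.sample_ids)
    log.info("knn_impute (k=%d): filled %d rows containing missing values",
             cfg.knn_k, len(missing_rows))
    return OmicsMatrix(out, meth.kind, dict(meth.meta))


def normalize_expression(expr: OmicsMatrix, mode: str = "none",
                         floor: float | None = None) -> OmicsMatrix:
    """Expression normalization conventions.

    ``oslo2_like``
        log2 transform, then per-sample median centering over detected
        features (raw values strictly above the common floor, supplied via
        ``floor`` or ``expr.meta['detection_floor']``; with no floor every
        value counts as detected). Undetected values keep the transformed
        floor value.
    ``tcga_like``
        log2(x + 1); missing values become 0.
    ``none``
        identity.
    """
    if mode == "none":
        return expr.copy()
    values = expr.values.copy()
    if mode == "tcga_like":
        if (values < 0).any().any():
            raise ValueError("tcga_like expects non-negative raw counts")
        out = np.log2(values.fillna(0.0) + 1.0)
        mat = OmicsMatrix(out, "expression", dict(expr.meta))
        mat.meta["detection_floor"] = 0.0
        return mat
    if mode == "oslo2_like":
        if (values <= 0).any().any():
            raise ValueError("oslo2_like requires strictly positive values for log2")
        if floor is None:
            floor = expr.meta.get("detection_floor", float("-inf"))
        logged = np.log2(values)
        log_floor = np.log2(floor) if floor > 0 else float("-inf")
        centered = logged.copy()
        for s in logged.columns:
            col = logged[s]
            detected = col > log_floor
            if detected.any():
                centered[s] = col - col[detected].median()
        if np.isfinite(log_floor):
            centered[logged <= log_floor] = log_floor
        mat = OmicsMatrix(centered, "expression", dict(expr.meta))
        mat.meta["detection_floor"] = log_floor
        return mat
    raise ValueError(f"unknown normalization mode: {mode!r}")
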