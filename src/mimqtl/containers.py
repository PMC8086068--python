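"""Core in-memory containers shared across the pipeline.

All genomic intervals use the BED convention (0-based, half-open).
CpGs are stored as 1-based points (methylation-array manifest convention)
and converted to half-open intervals only at overlap time; a CpG at 1-based
position ``p`` occupies the half-open interval ``[p-1, p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SampleAnnotation",
    "GenomeAnnotation",
    "IntervalSet",
    "LoopSet",
]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


@dataclass
class OmicsMatrix:
    """A feature x sample numeric matrix (methylation betas or log2 expression).

    Parameters
    ----------
    values
        DataFrame with features as rows and samples as columns. Missing
        values are encoded as NaN.
    kind
        ``"methylation"`` (betas in [0, 1]) or ``"expression"``
        (unbounded reals, typically log2 scale).
    """

    values: pd.DataFrame
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("methylation", "expression"):
            raise ValueError(f"unknown matrix kind: {self.kind!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        self.values = self.values.astype(float)
        if self.kind == "methylation":
            arr = self.values.to_numpy()
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[list(ids)], self.kind, dict(self.meta))

    def subset_samples(self, ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(ids)], self.kind, dict(self.meta))

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), self.kind, dict(self.meta))


@dataclass
class SampleAnnotation:
    """Per-sample covariates: ER status, subtype, infiltration scores, ESR1.

    ``table`` is indexed by sample_id with columns ``er_status``
    ({positive, negative, unknown}), ``subtype_label``, ``lymphocyte_score``,
    ``fibroblast_score``, ``esr1_expression`` and optional quartile-bin
    columns (``lymphocyte_group``, ``fibroblast_group`` with values 1-4).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def covariate(self, name: str) -> pd.Series:
        return self.table[name]

    def add_quartile_groups(self, column: str, out: str | None = None) -> None:
        """Bin a numeric covariate into quartile groups 1 (low) .. 4 (high)."""
        out = out or column.replace("_score", "") + "_group"
        vals = self.table[column]
        self.table[out] = pd.qcut(vals, 4, labels=[1, 2, 3, 4]).astype("Int64")


@dataclass
class GenomeAnnotation:
    """Genomic coordinates for CpGs (1-based points) and miRNA precursors
    (1-based closed intervals).

    ``table`` is indexed by feature_id with columns ``chrom``, ``start``,
    ``end`` (for CpGs start == end == position) and optional ``strand``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "feature ids")
        if (self.table["start"] <= 0).any() or (self.table["end"] <= 0).any():
            raise ValueError("annotation positions must be positive (1-based)")
        if (self.table["end"] < self.table["start"]).any():
            raise ValueError("annotation end < start")

    def has(self, feature_id: str) -> bool:
        return feature_id in self.table.index

    def chrom(self, feature_id: str) -> str:
        return self.table.at[feature_id, "chrom"]

    def half_open(self, feature_id: str) -> tuple[str, int, int]:
        """Return (chrom, start, end) in 0-based half-open coordinates."""
        row = self.table.loc[feature_id]
        return row["chrom"], int(row["start"]) - 1, int(row["end"])


def _validate_intervals(df: pd.DataFrame, cols=("start", "end")) -> None:
    bad = df[df[cols[0]] >= df[cols[1]]]
    if len(bad):
        raise ValueError(
            f"invalid interval(s) with start >= end, first at index {bad.index[0]}"
        )


@dataclass
class IntervalSet:
    """A named set of genomic intervals (0-based half-open), BED semantics."""

    name: str
    table: pd.DataFrame  # columns: chrom, start, end, optional label

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        _validate_intervals(self.table)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LoopSet:
    """A named set of chromatin loops, each with two feet (half-open)."""

    name: str
    table: pd.DataFrame  # chrom1,start1,end1,chrom2,start2,end2[,loop_id]

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        _validate_intervals(self.table, ("start1", "end1"))
        _validate_intervals(self.table, ("start2", "end2"))
        if "loop_id" not in self.table.columns:
            self.table["loop_id"] = [
                f"{self.name}_{i}" for i in range(len(self.table))
            ]

    def __len__(self) -> int:
        return len(self.table)
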