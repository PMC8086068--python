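"""Readers and writers for the plain-text formats the pipeline touches:
TSV matrices and tables, BED3+ interval sets, BEDPE loops, YAML config."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenomeAnnotation, IntervalSet, LoopSet, OmicsMatrix, SampleAnnotation

log = logging.getLogger("mimqtl")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_annotation",
    "write_annotation",
    "read_sample_annotation",
    "write_table",
    "read_table",
    "load_config_file",
]


def read_matrix(path, kind: str) -> OmicsMatrix:
    """Read a feature x sample TSV (header = sample ids, first column =
    feature ids). Empty cells become NaN; non-numeric cells are an error."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature id(s): {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dup[:5]}")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna() & (raw.str.strip() != "")
        if bad.any():
            row = raw.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}: "
                f"{raw[bad].iloc[0]!r}"
            )
        values[col] = numeric
    mat = OmicsMatrix(values, kind)
    log.info("read_matrix %s: %d features x %d samples", path, *mat.shape)
    return mat


def write_matrix(matrix: OmicsMatrix, path, float_format: str = "%.10g") -> None:
    matrix.values.to_csv(path, sep="\t", float_format=float_format, na_rep="")


def read_bed(path, name: str | None = None) -> IntervalSet:
    """Read BED3+ (0-based half-open). Malformed lines raise with line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], start, end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return IntervalSet(name or Path(path).stem, df)


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.table.to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path, name: str | None = None) -> LoopSet:
    """Read BEDPE loops (two half-open feet per line)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            try:
                s1, e1 = int(parts[1]), int(parts[2])
                s2, e2 = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            for s, e in ((s1, e1), (s2, e2)):
                if s >= e:
                    raise ValueError(f"{path}:{lineno}: start >= end ({s} >= {e})")
            loop_id = parts[6] if len(parts) > 6 else f"loop_{lineno}"
            rows.append((parts[0], s1, e1, parts[3], s2, e2, loop_id))
    df = pd.DataFrame(
        rows,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "loop_id"],
    )
    return LoopSet(name or Path(path).stem, df)


def write_bedpe(loops: LoopSet, path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "loop_id"]
    loops.table[cols].to_csv(path, sep="\t", header=False, index=False)


def read_annotation(path) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenomeAnnotation(df)


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="feature_id")


def read_sample_annotation(path) -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep="\t", index_col=0))


def write_table(records: pd.DataFrame, path, index: bool = False,
                float_format: str = "%.10g") -> None:
    """Write any tabular result as TSV."""
    records.to_csv(path, sep="\t", index=index, float_format=float_format)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def load_config_file(path) -> dict:
    """Load the declarative YAML config holding all pipeline thresholds."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
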