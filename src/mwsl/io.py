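"""Delimited-file ingestion and output for feature tables, outcomes and covariates.

All readers are thin wrappers around :mod:`pandas`. Rows carrying missing
values are dropped (complete-case policy) and the drop count is logged, since
downstream regression engines require fully observed rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CovariateMatrix, FeatureMatrix, Outcome

logger = logging.getLogger("mwsl")


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV with a header row; delimiter sniffed from the suffix."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate ids in header: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    return df


def _to_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    # distinguish unparseable text from declared missing values
    bad = out.isna() & df.notna() & ~df.astype(str).isin(["NA", "NaN", "nan", ""])
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell in {what} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def read_feature_table(path: str | Path, orientation: str = "samples-in-rows") -> FeatureMatrix:
    """Read a delimited feature table into a :class:`FeatureMatrix`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row and a leading label column.
    orientation
        ``samples-in-rows`` (default) or ``features-in-rows``; the latter is
        transposed on read so both orientations yield the same matrix.
    """
    if orientation not in {"samples-in-rows", "features-in-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _to_numeric(_read_table(path), "feature table")
    if orientation == "features-in-rows":
        df = df.T
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    n_before = len(df)
    df = df.dropna(axis=0, how="any")
    dropped = n_before - len(df)
    if dropped:
        logger.info("read_feature_table: dropped %d row(s) with missing values", dropped)
    return FeatureMatrix(df.values, list(df.columns), list(df.index))


def read_outcome(
    path: str | Path,
    family: str,
    columns: str | tuple[str, str] | None = None,
) -> Outcome:
    """Read an outcome vector of the declared family.

    ``survival`` requires ``columns=(time_col, event_col)``; other families
    take a single column name (default: the first data column).
    """
    df = _to_numeric(_read_table(path), "outcome table")
    if family == "survival":
        if not isinstance(columns, (tuple, list)) or len(columns) != 2:
            raise ValueError("survival outcome requires columns=(time, event)")
        tcol, ecol = columns
        sub = df[[tcol, ecol]].dropna(axis=0, how="any")
        return Outcome("survival", None, time=sub[tcol].values, event=sub[ecol].values)
    col = columns if columns is not None else df.columns[0]
    vals = df[col].dropna().values
    if family == "binary":
        levels = np.unique(vals)
        if levels.size > 2 or not np.all(np.isin(levels, (0.0, 1.0))):
            raise ValueError(f"binary outcome has levels {levels.tolist()}, expected subset of {{0, 1}}")
    return Outcome(family, vals)


def read_covariates(path: str | Path, columns: list[str] | None = None) -> CovariateMatrix:
    df = _to_numeric(_read_table(path), "covariate table")
    if columns is not None:
        df = df[columns]
    return CovariateMatrix(df.values, list(df.columns))


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a FeatureMatrix to delimited text at full float precision."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.DataFrame(fm.values, index=fm.sample_ids, columns=fm.feature_ids)
    df.to_csv(path, sep=sep)  # default repr formatting round-trips exactly


def write_outcome(outcome: Outcome, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    if outcome.family == "survival":
        df = pd.DataFrame({"time": outcome.time, "event": outcome.event})
    else:
        df = pd.DataFrame({outcome.family: outcome.values})
    df.index.name = "sample"
    df.to_csv(path, sep=sep, float_format="%.17g")
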