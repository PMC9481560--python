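"""Delimited-matrix readers and writers.

Coordinates travel as plain CSV/TSV: one point per row, numeric cells,
an optional single header row (off by default — pass ``header=True``).
Labels are one integer per row, aligned with the coordinate file.
Coordinates are written with 17 significant digits so a write/read
round trip is lossless for doubles.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .neighbors import PointSet

__all__ = ["read_matrix", "read_labels", "write_matrix", "write_labels",
           "write_report"]


def read_matrix(
    path: str | Path, delimiter: str = ",", header: bool = False
) -> PointSet:
    """Read an n x d coordinate matrix from a delimited text file."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=delimiter, header=0 if header else None, comment="#",
            skip_blank_lines=True, dtype=str,
        )
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: {exc}") from None
    if df.shape[0] == 0:
        raise InputError(f"{path}: no data rows")
    offset = 2 if header else 1  # 1-based line number of the first data row
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's parser is correctly rounded, so 17-digit round
            # trips are bitwise exact
            values[:, j] = df[col].to_numpy().astype(float)
        except (ValueError, TypeError):
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = int(np.flatnonzero(numeric.isna() & df[col].notna())[0])
            raise InputError(
                f"{path}: non-numeric cell {df[col].iloc[bad]!r} at line "
                f"{bad + offset}, column {j + 1}"
            ) from None
    if np.isnan(values).any():
        row = int(np.flatnonzero(np.isnan(values).any(axis=1))[0])
        raise InputError(f"{path}: ragged or missing cell at line {row + offset}")
    return PointSet(values)


def read_labels(path: str | Path, n_expected: int | None = None) -> np.ndarray:
    """Read one integer label per row; validate alignment if n_expected given."""
    path = Path(path)
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                labels.append(int(float(text)))
            except ValueError:
                raise InputError(
                    f"{path}: non-integer label {text!r} at line {lineno}"
                ) from None
    if not labels:
        raise InputError(f"{path}: empty label file")
    out = np.asarray(labels, dtype=int)
    if n_expected is not None and out.size != n_expected:
        raise InputError(
            f"{path}: {out.size} labels but {n_expected} data rows"
        )
    return out


def write_matrix(path: str | Path, coords: np.ndarray, delimiter: str = ",") -> None:
    """Write coordinates at 17 significant digits (lossless for doubles)."""
    np.savetxt(path, np.asarray(coords, dtype=float), fmt="%.17g",
               delimiter=delimiter)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def write_report(path: str | Path, entries: Mapping[str, Any]) -> None:
    """Write a key=value report, one entry per line."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")
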