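"""Binary incident matrices: validated containers, CSV I/O, and rater agreement.

An incident matrix has one row per reported bed-fall event and one 0/1 column
per contributing-factor code. A cell is 1 when the factor was documented as
contributing to that event; 0 means *not documented as contributing*, not
"known absent" — no missing-data mechanism is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from bedfallnet.codebook import Codebook

logger = logging.getLogger(__name__)


class MatrixFormatError(ValueError):
    """Header-level problem: missing, duplicate, or unknown factor codes."""


class MatrixValueError(ValueError):
    """Cell-level problem: a value outside {0, 1}, with its location."""


@dataclass(frozen=True)
class IncidentMatrix:
    """n x p table of binary factor indicators with an ordered code list.

    Attributes
    ----------
    records
        int8 array of shape (n, p) with values in {0, 1}.
    column_codes
        Factor code per column, in file/construction order.
    """

    records: np.ndarray
    column_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.records)
        if arr.ndim != 2:
            raise MatrixFormatError("records must be a 2-D array")
        if arr.shape[0] < 1:
            raise MatrixFormatError("incident matrix must contain at least one record")
        if arr.shape[1] != len(self.column_codes):
            raise MatrixFormatError("column count does not match code list")
        if len(set(self.column_codes)) != len(self.column_codes):
            raise MatrixFormatError("duplicate column codes")
        bad = (arr != 0) & (arr != 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixValueError(
                f"non-binary cell at row {i}, column {self.column_codes[j]!r}: "
                f"{arr[i, j]!r}"
            )
        object.__setattr__(self, "records", np.ascontiguousarray(arr, dtype=np.int8))
        object.__setattr__(self, "column_codes", tuple(self.column_codes))

    @property
    def n(self) -> int:
        return self.records.shape[0]

    @property
    def p(self) -> int:
        return self.records.shape[1]

    def column(self, code: str) -> np.ndarray:
        return self.records[:, self.column_codes.index(code)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=list(self.column_codes))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IncidentMatrix":
        return cls(frame.to_numpy(), tuple(map(str, frame.columns)))

    def subset(self, codes: Sequence[str]) -> "IncidentMatrix":
        idx = [self.column_codes.index(c) for c in codes]
        return IncidentMatrix(self.records[:, idx], tuple(codes))


@dataclass(frozen=True)
class RaterPair:
    """Two independent binary codings of the same reports and factors."""

    coder_a: IncidentMatrix
    coder_b: IncidentMatrix

    def __post_init__(self) -> None:
        if self.coder_a.records.shape != self.coder_b.records.shape:
            raise ValueError("rater matrices differ in shape")
        if self.coder_a.column_codes != self.coder_b.column_codes:
            raise ValueError("rater matrices differ in column codes or ordering")


def read_incident_matrix(path, codebook: Optional[Codebook] = None) -> IncidentMatrix:
    """Read a validated incident matrix from a comma-separated UTF-8 file.

    The first row holds factor codes; body cells must parse as 0 or 1. An
    optional leading ``report_id`` column is accepted and dropped. When a
    codebook is given, every code must appear in it.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    raw_codes = [c.strip() for c in header.split(",")]
    if len(set(raw_codes)) != len(raw_codes):
        raise MatrixFormatError(f"{path}: duplicate factor codes in header")
    frame = pd.read_csv(path, dtype=str, encoding="utf-8", names=raw_codes, skiprows=1)
    if frame.shape[0] == 0:
        raise MatrixFormatError(f"{path}: matrix body is empty")
    if raw_codes and raw_codes[0] == "report_id":
        logger.info("%s: dropping leading report_id column", path)
        frame = frame.drop(columns="report_id")
    codes = [str(c) for c in frame.columns]
    if codebook is not None:
        unknown = [c for c in codes if c not in codebook]
        if unknown:
            raise MatrixFormatError(f"{path}: codes not in codebook: {unknown}")
    values = np.empty(frame.shape, dtype=np.int8)
    for j, code in enumerate(codes):
        col = frame.iloc[:, j].str.strip()
        ok = col.isin(["0", "1"])
        if not ok.all():
            i = int(np.flatnonzero(~ok.to_numpy())[0])
            raise MatrixValueError(
                f"{path}: non-binary cell at row {i}, column {code!r}: "
                f"{frame.iloc[i, j]!r}"
            )
        values[:, j] = col.astype(np.int8)
    return IncidentMatrix(values, tuple(codes))


def write_incident_matrix(matrix: IncidentMatrix, path) -> None:
    """Write the matrix as CSV with the code header; round-trips exactly."""
    matrix.to_frame().to_csv(path, index=False)


def marginal_counts(matrix: IncidentMatrix) -> Dict[str, int]:
    """Positive (value 1) count per factor column."""
    sums = matrix.records.sum(axis=0)
    return {code: int(s) for code, s in zip(matrix.column_codes, sums)}


def cohens_kappa(pair: RaterPair) -> float:
    """Cohen's kappa for two binary codings, pooled over all n x p cells.

    Each cell is treated as one rated item, giving a single aggregate
    agreement score: kappa = (p_o - p_e) / (1 - p_e). When chance agreement
    p_e = 1 (both raters constant), kappa is 1 for identical codings.
    """
    a = pair.coder_a.records.ravel()
    b = pair.coder_b.records.ravel()
    p_o = float(np.mean(a == b))
    p1a, p1b = float(np.mean(a)), float(np.mean(b))
    p_e = p1a * p1b + (1 - p1a) * (1 - p1b)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o == 1.0 else -1.0
    return float(cohen_kappa_score(a, b))
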