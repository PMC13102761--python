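"""Decomposable BIC scoring for discrete (binary) Bayesian networks.

The local score of a child with parent set Pa is the multinomial maximum
log-likelihood of the child given each parent configuration, penalised by
(ln n)/2 per free parameter:

    score(child | Pa) = sum_j sum_k N_jk ln(N_jk / N_j) - (ln n)/2 * q * (r - 1)

with r = 2 child states, q = 2^|Pa| parent configurations, 0 * ln 0 = 0, and
empty parent configurations (N_j = 0) contributing no likelihood but still
counted in q. The total score of a DAG is the sum of local scores, which makes
single-edge search moves cheap to evaluate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from bedfallnet.data import IncidentMatrix


@dataclass(frozen=True)
class ContingencyTable:
    """Sufficient statistics for one child given an ordered parent list.

    ``counts`` has shape (q, r): row j is the parent configuration with
    little-endian binary index j over the ordered parent list (first parent is
    the least-significant bit), columns are child states 0 and 1.
    """

    child: str
    parents: tuple[str, ...]
    counts: np.ndarray

    @property
    def q(self) -> int:
        return self.counts.shape[0]

    @property
    def r(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def _column_indices(matrix: IncidentMatrix, child: str, parents: Sequence[str]) -> tuple[int, list[int]]:
    codes = matrix.column_codes
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    try:
        ci = codes.index(child)
        pi = [codes.index(p) for p in parents]
    except ValueError as exc:
        raise ValueError(f"unknown factor code in ({child!r}, {list(parents)})") from exc
    if len(set(parents)) != len(parents):
        raise ValueError(f"duplicate parents {list(parents)}")
    return ci, pi


def contingency_counts(
    matrix: IncidentMatrix, child: str, parents: Sequence[str] = ()
) -> ContingencyTable:
    """Exact joint counts N_jk of child state k under parent configuration j."""
    ci, pi = _column_indices(matrix, child, parents)
    q = 1 << len(pi)
    child_col = matrix.records[:, ci].astype(np.int64)
    if pi:
        weights = (1 << np.arange(len(pi), dtype=np.int64))
        config = matrix.records[:, pi].astype(np.int64) @ weights
    else:
        config = np.zeros(matrix.n, dtype=np.int64)
    flat = np.bincount(config * 2 + child_col, minlength=2 * q)
    return ContingencyTable(child, tuple(parents), flat.reshape(q, 2))


def bic_local(matrix: IncidentMatrix, child: str, parents: Sequence[str] = ()) -> float:
    """Local BIC score of one child given its parent set (natural log)."""
    table = contingency_counts(matrix, child, parents)
    return bic_from_counts(table.counts, matrix.n)


def bic_from_counts(counts: np.ndarray, n: int) -> float:
    """BIC score from a (q, r) count table; penalty (ln n)/2 * q * (r - 1)."""
    counts = np.asarray(counts, dtype=np.float64)
    q, r = counts.shape
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_terms = counts * (np.log(counts) - np.log(totals))
    ll = float(np.nansum(np.where(counts > 0, ll_terms, 0.0)))
    penalty = 0.5 * np.log(n) * q * (r - 1)
    return ll - penalty


def total_score(dag, matrix: IncidentMatrix) -> float:
    """Sum of local BIC scores over every node with its parent set in the DAG."""
    unknown = [v for v in dag.nodes if v not in matrix.column_codes]
    if unknown:
        raise ValueError(f"dag nodes not in matrix: {unknown}")
    return sum(bic_local(matrix, v, dag.parents(v)) for v in dag.nodes)
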