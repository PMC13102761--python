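"""BDeu-smoothed conditional probability tables for a fixed structure.

The Bayesian Dirichlet equivalent uniform prior spreads an equivalent sample
size (ESS) uniformly over all CPT cells: with r child states and q parent
configurations, each cell receives pseudo-count alpha = ESS / (r * q), so

    theta_jk = (N_jk + ESS/(r*q)) / (N_j + ESS/q).

With ESS > 0 every probability is strictly inside (0, 1), which removes the
zero-frequency problem in sparse binary incident data; a parent configuration
never observed falls back to the uniform 1/r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from bedfallnet.data import IncidentMatrix
from bedfallnet.scoring import contingency_counts


@dataclass(frozen=True)
class BdeuConfig:
    """Equivalent sample size of the BDeu prior (default 1.0)."""

    ess: float = 1.0

    def __post_init__(self) -> None:
        if not self.ess > 0:
            raise ValueError("ess must be > 0")


@dataclass(frozen=True)
class Cpt:
    """Conditional distribution of one binary child given its ordered parents.

    ``table`` has shape (q, 2); row j is the parent configuration with
    little-endian binary index j over ``parents`` and holds (P(child=0),
    P(child=1)). Rows sum to 1.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=np.float64)
        if tab.ndim != 2 or tab.shape != (1 << len(self.parents), 2):
            raise ValueError(
                f"CPT for {self.child!r} must have shape ({1 << len(self.parents)}, 2)"
            )
        if not np.allclose(tab.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError(f"CPT rows for {self.child!r} do not sum to 1")
        object.__setattr__(self, "table", tab)
        object.__setattr__(self, "parents", tuple(self.parents))

    @property
    def q(self) -> int:
        return self.table.shape[0]

    def p1(self, parent_config: int = 0) -> float:
        """P(child = 1) under the little-endian parent configuration index."""
        return float(self.table[parent_config, 1])


def fit_cpt(
    matrix: IncidentMatrix,
    child: str,
    parents: Sequence[str],
    config: BdeuConfig = BdeuConfig(),
) -> Cpt:
    """Fit one BDeu-smoothed CPT from exact joint counts."""
    counts = contingency_counts(matrix, child, tuple(parents)).counts.astype(np.float64)
    q, r = counts.shape
    alpha_cell = config.ess / (r * q)
    alpha_row = config.ess / q
    totals = counts.sum(axis=1, keepdims=True)
    table = (counts + alpha_cell) / (totals + alpha_row)
    return Cpt(child, tuple(parents), table)


def fit_cpts(dag, matrix: IncidentMatrix, config: BdeuConfig = BdeuConfig()) -> Dict[str, Cpt]:
    """BDeu-smoothed CPT for every node of the DAG, keyed by factor code."""
    return {v: fit_cpt(matrix, v, dag.parents(v), config) for v in dag.nodes}
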