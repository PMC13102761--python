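"""Bootstrap assessment of structural stability.

Structure learning is repeated on nonparametric bootstrap resamples (rows
drawn with replacement, resample size = n by default) and the occurrence
frequency of every directed edge is tallied. Edges whose frequency clears a
threshold form the stable subnetwork used for inference. Replicate b's
resample is fully determined by (seed, b), so replicates are reproducible and
order-independent.

Edge identity is the directed pair. Because BIC is score-equivalent, the
direction inside a Markov-equivalence class is an artifact of the search's
tie-breaking, so frequencies are best read at the adjacency (skeleton) level
when directions matter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from bedfallnet.data import IncidentMatrix
from bedfallnet.structure import Dag, SearchConfig, hill_climb

Edge = Tuple[str, str]


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 200
    seed: int = 0
    search: SearchConfig = field(default_factory=SearchConfig)
    resample_size: int | None = None  # None = original n

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.resample_size is not None and self.resample_size < 1:
            raise ValueError("resample_size must be >= 1")


@dataclass(frozen=True)
class EdgeFrequencyTable:
    """Per-directed-edge bootstrap occurrence counts and exact frequencies."""

    counts: Dict[Edge, int]
    B: int

    def __post_init__(self) -> None:
        for edge, c in self.counts.items():
            if not 0 <= c <= self.B:
                raise ValueError(f"count for edge {edge} outside [0, B]")
        object.__setattr__(self, "counts", dict(self.counts))

    def frequency(self, edge: Edge) -> float:
        return self.counts.get(edge, 0) / self.B

    def adjacency_frequency(self, a: str, b: str) -> float:
        """Frequency of the undirected adjacency a - b (either direction)."""
        return (self.counts.get((a, b), 0) + self.counts.get((b, a), 0)) / self.B

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"From": u, "To": v, "Frequency": c / self.B, "Count": c}
            for (u, v), c in self.counts.items()
        ]
        frame = pd.DataFrame(rows, columns=["From", "To", "Frequency", "Count"])
        return frame.sort_values(
            ["Frequency", "From", "To"], ascending=[False, True, True]
        ).reset_index(drop=True)


def _resample(matrix: IncidentMatrix, seed: int, b: int, size: int) -> IncidentMatrix:
    rng = np.random.default_rng([seed, b])
    idx = rng.integers(0, matrix.n, size=size)
    return IncidentMatrix(matrix.records[idx], matrix.column_codes)


def bootstrap_edge_frequencies(
    matrix: IncidentMatrix, config: BootstrapConfig = BootstrapConfig()
) -> EdgeFrequencyTable:
    """Directed-edge occurrence frequencies over B seeded resamples."""
    size = config.resample_size or matrix.n
    counts: Counter[Edge] = Counter()
    for b in range(config.replicates):
        resampled = _resample(matrix, config.seed, b, size)
        dag = hill_climb(resampled, config.search)
        counts.update(dag.edges)
    return EdgeFrequencyTable(dict(counts), config.replicates)


def stable_network(
    table: EdgeFrequencyTable, threshold: float = 0.5, nodes: Sequence[str] = ()
) -> Dag:
    """Edges with bootstrap frequency >= threshold, as a DAG.

    Raises if the selected edges contain a directed cycle (remedy: raise the
    threshold).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    selected = [e for e, c in sorted(table.counts.items()) if c / table.B >= threshold]
    node_set = list(dict.fromkeys(list(nodes) + [v for e in selected for v in e]))
    try:
        return Dag(tuple(node_set), frozenset(selected))
    except ValueError as exc:
        raise ValueError(
            f"stable edge selection at threshold {threshold} is cyclic; "
            "increase the threshold"
        ) from exc


def convergence_check(
    matrix: IncidentMatrix,
    config: BootstrapConfig,
    checkpoints: Sequence[int],
) -> pd.DataFrame:
    """Per-edge frequency drift between successive replicate checkpoints.

    Runs max(checkpoints) replicates once (the (seed, b) contract makes
    prefixes consistent) and reports, for every edge ever observed, the
    absolute frequency change between consecutive checkpoints.
    """
    checkpoints = list(checkpoints)
    if any(b <= a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be strictly increasing")
    if len(checkpoints) < 2:
        return pd.DataFrame(columns=["From", "To", "interval", "drift"])

    size = config.resample_size or matrix.n
    total = checkpoints[-1]
    cumulative: Counter[Edge] = Counter()
    freq_at: Dict[int, Dict[Edge, float]] = {}
    marks = set(checkpoints)
    for b in range(total):
        resampled = _resample(matrix, config.seed, b, size)
        cumulative.update(hill_climb(resampled, config.search).edges)
        if b + 1 in marks:
            freq_at[b + 1] = {e: c / (b + 1) for e, c in cumulative.items()}

    edges = sorted({e for f in freq_at.values() for e in f})
    rows = []
    for a, b in zip(checkpoints, checkpoints[1:]):
        for e in edges:
            drift = abs(freq_at[b].get(e, 0.0) - freq_at[a].get(e, 0.0))
            rows.append(
                {"From": e[0], "To": e[1], "interval": f"{a}-{b}", "drift": drift}
            )
    return pd.DataFrame(rows, columns=["From", "To", "interval", "drift"])
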