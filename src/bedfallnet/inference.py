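"""Exact inference on a fitted network and scenario/posterior analyses.

Queries are answered by variable elimination over the CPT factors, which is
exact for any elimination order; a min-degree heuristic keeps intermediate
factors small. Scenario analysis contrasts a model-marginal baseline with the
conditional probability under fixed evidence — observational conditioning,
not a do-intervention — and attaches percentile-bootstrap confidence
intervals obtained by refitting CPTs on row resamples with the structure held
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from bedfallnet.data import IncidentMatrix
from bedfallnet.parameters import BdeuConfig, Cpt, fit_cpts
from bedfallnet.structure import Dag


@dataclass(frozen=True)
class Evidence:
    """Observed factor states: map code -> state in {0, 1}."""

    assignments: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, state in self.assignments.items():
            if state not in (0, 1):
                raise ValueError(f"evidence state for {code!r} must be 0 or 1")
        object.__setattr__(self, "assignments", dict(self.assignments))

    def __contains__(self, code: object) -> bool:
        return code in self.assignments

    def items(self):
        return self.assignments.items()

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class BayesNet:
    """A DAG plus one BDeu-smoothed CPT per node."""

    dag: Dag
    cpts: Dict[str, Cpt]

    def __post_init__(self) -> None:
        if set(self.cpts) != set(self.dag.nodes):
            raise ValueError("need exactly one CPT per DAG node")
        for v in self.dag.nodes:
            if self.cpts[v].parents != self.dag.parents(v):
                raise ValueError(
                    f"CPT parents for {v!r} ({self.cpts[v].parents}) differ from "
                    f"DAG parents ({self.dag.parents(v)})"
                )


class _Factor:
    """Dense factor over a tuple of binary variables."""

    __slots__ = ("vars", "values")

    def __init__(self, variables: Tuple[str, ...], values: np.ndarray):
        self.vars = variables
        self.values = values  # shape (2,) * len(vars)

    @classmethod
    def from_cpt(cls, cpt: Cpt) -> "_Factor":
        # axes ordered (parent_1, ..., parent_k, child); table rows are
        # little-endian over parents, so parent_1 is the fastest axis
        k = len(cpt.parents)
        vals = cpt.table.reshape((2,) * k + (2,), order="F") if k else cpt.table.reshape(2)
        if k:
            return cls(cpt.parents + (cpt.child,), vals)
        return cls((cpt.child,), vals)

    def reduce(self, code: str, state: int) -> "_Factor":
        axis = self.vars.index(code)
        values = np.take(self.values, state, axis=axis)
        variables = self.vars[:axis] + self.vars[axis + 1:]
        return _Factor(variables, values)

    def multiply(self, other: "_Factor") -> "_Factor":
        merged = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._broadcast(merged)
        b = other._broadcast(merged)
        return _Factor(merged, a * b)

    def _broadcast(self, merged: Tuple[str, ...]) -> np.ndarray:
        shape = [2 if v in self.vars else 1 for v in merged]
        order = [self.vars.index(v) for v in merged if v in self.vars]
        return self.values.transpose(order).reshape(shape)

    def marginalize(self, code: str) -> "_Factor":
        axis = self.vars.index(code)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1:], self.values.sum(axis=axis)
        )


def _reshape_cpt_factor(cpt: Cpt) -> _Factor:
    return _Factor.from_cpt(cpt)


def variable_elimination(
    net: BayesNet, target: str, evidence: Optional[Evidence] = None
) -> np.ndarray:
    """Exact P(target | evidence) as a normalized length-2 array.

    Factors are reduced by the evidence, variables are eliminated in
    min-degree order, and the product over the target is normalized. Raises on
    zero-probability evidence (cannot occur for CPTs fitted with ESS > 0).
    """
    evidence = evidence or Evidence()
    if target in evidence:
        raise ValueError(f"target {target!r} is part of the evidence")
    unknown = [c for c, _ in evidence.items() if c not in net.dag.nodes]
    if unknown:
        raise ValueError(f"evidence codes not in network: {unknown}")

    factors = []
    for v in net.dag.nodes:
        f = _reshape_cpt_factor(net.cpts[v])
        for code, state in evidence.items():
            if code in f.vars:
                f = f.reduce(code, state)
        factors.append(f)

    to_eliminate = set(net.dag.nodes) - {target} - {c for c, _ in evidence.items()}
    while to_eliminate:
        # min-degree: eliminate the variable in the fewest factors first
        var = min(
            to_eliminate,
            key=lambda v: (sum(v in f.vars for f in factors), v),
        )
        to_eliminate.remove(var)
        involved = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors.append(prod.marginalize(var))

    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    if result.vars != (target,):
        result_vals = result.values.reshape(2)
    else:
        result_vals = result.values
    total = result_vals.sum()
    if total <= 0:
        raise ValueError("evidence event has zero probability under the network")
    return result_vals / total


def query_p1(net: BayesNet, target: str, evidence: Optional[Evidence] = None) -> float:
    """Convenience: P(target = 1 | evidence)."""
    return float(variable_elimination(net, target, evidence)[1])


@dataclass(frozen=True)
class ScenarioResult:
    """One conditional-scenario row: baseline vs conditional probability.

    Changes are computed from unrounded probabilities; rounding is applied
    only when rendering reports.
    """

    condition: Evidence
    target: str
    baseline_p1: float
    conditional_p1: float
    absolute_change: float
    relative_change_pct: Optional[float]
    baseline_ci: Optional[Tuple[float, float]] = None
    conditional_ci: Optional[Tuple[float, float]] = None


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior co-occurrence probability of a factor given observed ones."""

    observed: Evidence
    target: str
    posterior_p1: float


def posterior_cooccurrence(net: BayesNet, observed: Evidence, target: str) -> PosteriorResult:
    """P(target = 1 | observed) by exact inference (Bayes through the CPTs)."""
    return PosteriorResult(observed, target, query_p1(net, target, observed))


def bootstrap_ci(
    matrix: IncidentMatrix,
    dag: Dag,
    statistic: Callable[[BayesNet], float],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    bdeu: BdeuConfig = BdeuConfig(),
) -> Tuple[float, float]:
    """Percentile bootstrap interval of a network statistic, structure fixed.

    Each replicate resamples rows with replacement (replicate b's stream is
    fully determined by (seed, b)), refits CPTs on the fixed DAG, and
    recomputes the statistic.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    stats = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, matrix.n, size=matrix.n)
        resampled = IncidentMatrix(matrix.records[idx], matrix.column_codes)
        net = BayesNet(dag, fit_cpts(dag, resampled, bdeu))
        stats[b] = statistic(net)
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def scenario_analysis(
    net: BayesNet,
    matrix: IncidentMatrix,
    condition: Evidence,
    target: str,
    ci_replicates: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    bdeu: BdeuConfig = BdeuConfig(),
    compute_ci: bool = True,
) -> ScenarioResult:
    """Baseline vs conditional probability of a target with change metrics.

    The baseline is the model marginal P(target=1) obtained by summing the
    fitted CPTs over all other variables (not the raw sample frequency); the
    conditional fixes the condition evidence. 95% CIs, when requested, come
    from the percentile bootstrap with the structure held fixed.
    """
    baseline = query_p1(net, target)
    conditional = query_p1(net, target, condition)
    absolute = conditional - baseline
    relative = 100.0 * absolute / baseline if baseline > 0 else None

    baseline_ci = conditional_ci = None
    if compute_ci:
        baseline_ci = bootstrap_ci(
            matrix, net.dag, lambda m: query_p1(m, target),
            B=ci_replicates, level=ci_level, seed=seed, bdeu=bdeu,
        )
        conditional_ci = bootstrap_ci(
            matrix, net.dag, lambda m: query_p1(m, target, condition),
            B=ci_replicates, level=ci_level, seed=seed, bdeu=bdeu,
        )
    return ScenarioResult(
        condition=condition,
        target=target,
        baseline_p1=baseline,
        conditional_p1=conditional,
        absolute_change=absolute,
        relative_change_pct=relative,
        baseline_ci=baseline_ci,
        conditional_ci=conditional_ci,
    )
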