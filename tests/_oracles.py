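"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: inference by
full-joint enumeration, structure search by exhaustive DAG enumeration, and
BDeu smoothing by direct closed-form arithmetic.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterator, Sequence, Tuple

import numpy as np

from bedfallnet.inference import BayesNet
from bedfallnet.structure import Dag


def joint_table(net: BayesNet) -> tuple[list[str], np.ndarray]:
    """Full joint P(x_1..x_p) by brute-force product of CPT entries."""
    nodes = list(net.dag.nodes)
    joint = np.zeros((2,) * len(nodes))
    for state in itertools.product((0, 1), repeat=len(nodes)):
        assign = dict(zip(nodes, state))
        p = 1.0
        for v in nodes:
            cpt = net.cpts[v]
            j = sum(assign[par] << k for k, par in enumerate(cpt.parents))
            p *= cpt.table[j, assign[v]]
        joint[state] = p
    return nodes, joint


def brute_force_query(net: BayesNet, target: str, evidence: Dict[str, int]) -> np.ndarray:
    """P(target | evidence) by summing the enumerated joint."""
    nodes, joint = joint_table(net)
    result = np.zeros(2)
    for state in itertools.product((0, 1), repeat=len(nodes)):
        assign = dict(zip(nodes, state))
        if any(assign[c] != s for c, s in evidence.items()):
            continue
        result[assign[target]] += joint[state]
    return result / result.sum()


def all_dags(nodes: Sequence[str]) -> Iterator[Dag]:
    """Every DAG on the given nodes, by filtering all edge subsets."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for r in range(len(pairs) + 1):
        for subset in itertools.combinations(pairs, r):
            try:
                yield Dag(tuple(nodes), frozenset(subset))
            except ValueError:
                continue


def bdeu_theta(n_jk: float, n_j: float, ess: float, q: int, r: int = 2) -> float:
    """Closed-form BDeu posterior mean for one CPT cell."""
    return (n_jk + ess / (r * q)) / (n_j + ess / q)


def skeleton_and_vstructures(dag: Dag) -> tuple[frozenset, frozenset]:
    """Markov-equivalence invariants: undirected skeleton and collider set."""
    skeleton = frozenset(frozenset(e) for e in dag.edges)
    adjacent = {frozenset((u, v)) for u, v in dag.edges}
    colliders = set()
    for w in dag.nodes:
        pa = dag.parents(w)
        for i, u in enumerate(pa):
            for v in pa[i + 1:]:
                if frozenset((u, v)) not in adjacent:
                    colliders.add((frozenset((u, v)), w))
    return skeleton, frozenset(colliders)
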