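import numpy as np
import pytest

from bedfallnet.data import IncidentMatrix
from bedfallnet.inference import BayesNet
from bedfallnet.parameters import Cpt
from bedfallnet.structure import Dag
from bedfallnet.synthetic import canonical_fixture, canonical_truth


@pytest.fixture(scope="session")
def truth_net():
    return canonical_truth().net


@pytest.fixture(scope="session")
def fixture_fg():
    return canonical_fixture("FG")


@pytest.fixture(scope="session")
def fixture_fab():
    return canonical_fixture("FAB")


@pytest.fixture(scope="session")
def fixture_full():
    return canonical_fixture("full")


def random_matrix(rng: np.random.Generator, n: int, codes) -> IncidentMatrix:
    """i.i.d. Bernoulli matrix with column rates drawn from (0.15, 0.85)."""
    rates = rng.uniform(0.15, 0.85, size=len(codes))
    data = (rng.random((n, len(codes))) < rates).astype(np.int8)
    return IncidentMatrix(data, tuple(codes))


def random_net(rng: np.random.Generator, n_nodes: int) -> BayesNet:
    """Random DAG (edges kept with prob 0.4 under a random order) + random CPTs."""
    codes = [chr(65 + i) for i in range(n_nodes)]
    order = list(rng.permutation(codes))
    edges = set()
    parents = {c: [] for c in codes}
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if rng.random() < 0.4 and len(parents[v]) < 3:
                edges.add((u, v))
                parents[v].append(u)
    dag = Dag(tuple(codes), frozenset(edges))
    cpts = {}
    for v in codes:
        pa = dag.parents(v)
        p1 = rng.uniform(0.05, 0.95, size=1 << len(pa))
        cpts[v] = Cpt(v, pa, np.column_stack([1 - p1, p1]))
    return BayesNet(dag, cpts)
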