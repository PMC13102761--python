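"""Synthetic test inputs: canonical fixtures and seeded forward sampling.

The study's raw 102-report matrix is not publicly deposited, but its printed
marginal counts together with the BDeu-smoothed conditionals pin down every
relevant joint cell uniquely, because theta = (N_11 + 1/4) / (N_+1 + 1/2) is
strictly monotone in the integer joint count. The canonical fixtures are
deterministic 102-row matrices built from those inverted counts:

  FG:  F has 19 positives, G has 5, all G-positives also F-positive
       (0.003 = (0 + 0.25)/(83 + 0.5) forces the joint cell (G=1, F=0) = 0)
  FAB: A has 39 positives, exactly 1 also F-positive
       (0.458 = (38 + 0.25)/(83 + 0.5) forces (A=1, F=0) = 38);
       B has 15 positives, exactly 1 also A-positive
       (0.224 = (14 + 0.25)/(63 + 0.5) forces (B=1, A=0) = 14)
  ST:  S has 31, T has 26, no overlap (0.367 = (26 + 0.25)/(71 + 0.5))
  NU:  N has 4, U has 11 including all 4 N-positives
       (0.074 = (7 + 0.25)/(98 + 0.5))

Which individual rows carry the overlaps is arbitrary — the sufficient
statistics are unaffected — so a fixed canonical row layout is used.

``canonical_truth`` packages the five-edge stable structure with the exact
BDeu-fitted CPTs of these fixtures as a ground-truth network for forward
sampling, recovery, and coverage experiments. ``study_emulator`` extends it
with independent sparse noise columns to the study's full 102 x 22 shape;
those noise rates are synthetic free parameters (no counts are printed for
the non-component codes).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Mapping

import numpy as np

from bedfallnet.data import IncidentMatrix
from bedfallnet.inference import BayesNet
from bedfallnet.parameters import Cpt
from bedfallnet.structure import Dag

N_STUDY = 102

# Synthetic marginal rates for the 14 codes outside the stable components;
# chosen once as plausible sparse-report rates (3-9 positives per 102).
NOISE_RATES: Dict[str, float] = {
    "C": 7 / 102, "D": 3 / 102, "E": 5 / 102, "H": 9 / 102, "I": 4 / 102,
    "J": 6 / 102, "K": 5 / 102, "L": 3 / 102, "M": 4 / 102, "O": 6 / 102,
    "P": 5 / 102, "Q": 4 / 102, "R": 3 / 102, "V": 5 / 102,
}

STUDY_CODES = tuple("ABCDEFGHIJKLMNOPQRSTUV")
COMPONENT_CODES = ("A", "B", "F", "G", "N", "S", "T", "U")


@dataclass(frozen=True)
class GroundTruthNet:
    """A named Bayesian network with exact CPTs used as simulation truth."""

    net: BayesNet
    name: str


def _zeros(n: int, codes: tuple[str, ...]) -> np.ndarray:
    return np.zeros((n, len(codes)), dtype=np.int8)


def _component_columns() -> Dict[str, np.ndarray]:
    """Canonical row layout of the four stable components over 102 rows."""
    cols = {c: np.zeros(N_STUDY, dtype=np.int8) for c in COMPONENT_CODES}
    cols["F"][0:19] = 1                      # 19 F-positives
    cols["G"][0:5] = 1                       # 5 G-positives, all with F=1
    cols["A"][0] = 1                         # the single A & F overlap row
    cols["A"][19:57] = 1                     # 38 more A-positives with F=0
    cols["B"][19] = 1                        # the single B & A overlap row
    cols["B"][57:71] = 1                     # 14 more B-positives with A=0
    cols["S"][0:31] = 1                      # 31 S-positives
    cols["T"][31:57] = 1                     # 26 T-positives, disjoint from S
    cols["N"][0:4] = 1                       # 4 N-positives
    cols["U"][0:11] = 1                      # 11 U-positives incl. all N=1 rows
    return cols


def canonical_fixture(component: str) -> IncidentMatrix:
    """Deterministic 102-row fixture for one stable component, or ``full``.

    Components: ``FG``, ``FAB``, ``ST``, ``NU``, or ``full`` (all 22 codes,
    component blocks plus fixed sparse columns for the remaining codes).
    """
    cols = _component_columns()
    layouts = {
        "FG": ("F", "G"),
        "FAB": ("F", "A", "B"),
        "ST": ("S", "T"),
        "NU": ("N", "U"),
    }
    if component in layouts:
        codes = layouts[component]
        return IncidentMatrix(np.column_stack([cols[c] for c in codes]), codes)
    if component != "full":
        raise ValueError(f"unknown component {component!r}")

    data = _zeros(N_STUDY, STUDY_CODES)
    for c in COMPONENT_CODES:
        data[:, STUDY_CODES.index(c)] = cols[c]
    # fixed sparse columns for the remaining codes: count positives placed
    # consecutively from a staggered, deterministic start row
    for i, (code, rate) in enumerate(sorted(NOISE_RATES.items())):
        count = round(rate * N_STUDY)
        start = (13 * (i + 1)) % N_STUDY
        rows = [(start + j) % N_STUDY for j in range(count)]
        data[rows, STUDY_CODES.index(code)] = 1
    return IncidentMatrix(data, STUDY_CODES)


def _cpt(child: str, parents: tuple[str, ...], p1_rows: list[Fraction]) -> Cpt:
    table = np.array([[1 - float(p), float(p)] for p in p1_rows])
    return Cpt(child, parents, table)


def canonical_truth() -> GroundTruthNet:
    """The five-edge stable structure with its exact BDeu(ESS=1) CPTs.

    CPT entries are the exact fractions (N_jk + 1/4) / (N_j + 1/2) (roots:
    (N_k + 1/2) / (n + 1)) implied by the canonical fixtures.
    """
    dag = Dag(
        COMPONENT_CODES,
        frozenset({("F", "G"), ("F", "A"), ("A", "B"), ("S", "T"), ("N", "U")}),
    )
    F = Fraction
    cpts = {
        "F": _cpt("F", (), [F(39, 206)]),                       # (19+1/2)/103
        "S": _cpt("S", (), [F(63, 206)]),                       # (31+1/2)/103
        "N": _cpt("N", (), [F(9, 206)]),                        # (4+1/2)/103
        "G": _cpt("G", ("F",), [F(1, 334), F(21, 78)]),         # 0.25/83.5, 5.25/19.5
        "A": _cpt("A", ("F",), [F(153, 334), F(5, 78)]),        # 38.25/83.5, 1.25/19.5
        "B": _cpt("B", ("A",), [F(57, 254), F(5, 158)]),        # 14.25/63.5, 1.25/39.5
        "T": _cpt("T", ("S",), [F(105, 286), F(1, 126)]),       # 26.25/71.5, 0.25/31.5
        "U": _cpt("U", ("N",), [F(29, 394), F(17, 18)]),        # 7.25/98.5, 4.25/4.5
    }
    return GroundTruthNet(BayesNet(dag, cpts), "canonical-5-edge")


def forward_sample(truth: GroundTruthNet, n: int, seed: int) -> IncidentMatrix:
    """Ancestral sampling in topological order; deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    net = truth.net
    rng = np.random.default_rng(seed)
    order = net.dag.topological_order()
    columns: Dict[str, np.ndarray] = {}
    for v in order:
        cpt = net.cpts[v]
        if cpt.parents:
            weights = 1 << np.arange(len(cpt.parents))
            config = np.zeros(n, dtype=np.int64)
            for k, p in enumerate(cpt.parents):
                config += columns[p].astype(np.int64) * int(weights[k])
            p1 = cpt.table[config, 1]
        else:
            p1 = np.full(n, cpt.table[0, 1])
        columns[v] = (rng.random(n) < p1).astype(np.int8)
    codes = tuple(net.dag.nodes)
    return IncidentMatrix(np.column_stack([columns[v] for v in codes]), codes)


def study_emulator(seed: int, noise_rates: Mapping[str, float] = NOISE_RATES) -> IncidentMatrix:
    """A 102 x 22 matrix emulating the study's shape and sparsity.

    The eight component columns are forward-sampled from the canonical truth;
    the remaining codes are independent Bernoulli noise columns at the
    (synthetic) rates in ``noise_rates``.
    """
    truth = canonical_truth()
    component = forward_sample(truth, N_STUDY, seed)
    rng = np.random.default_rng([seed, 2**20])
    data = _zeros(N_STUDY, STUDY_CODES)
    for c in COMPONENT_CODES:
        data[:, STUDY_CODES.index(c)] = component.column(c)
    for code in sorted(noise_rates):
        data[:, STUDY_CODES.index(code)] = (
            rng.random(N_STUDY) < noise_rates[code]
        ).astype(np.int8)
    return IncidentMatrix(data, STUDY_CODES)
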