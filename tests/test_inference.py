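"""Exact inference, scenario analysis, posterior queries, bootstrap CIs."""

import numpy as np
import pytest

from bedfallnet.inference import (
    BayesNet,
    Evidence,
    bootstrap_ci,
    posterior_cooccurrence,
    query_p1,
    scenario_analysis,
    variable_elimination,
)
from bedfallnet.parameters import Cpt, fit_cpts
from bedfallnet.structure import Dag
from bedfallnet.synthetic import canonical_fixture, canonical_truth, forward_sample

from _oracles import brute_force_query
from conftest import random_net


class TestVariableElimination:
    def test_root_marginal_is_its_cpt_row(self, truth_net):
        dist = variable_elimination(truth_net, "F")
        assert dist[1] == pytest.approx(19.5 / 103)

    def test_two_variable_marginal_matches_total_probability(self, truth_net):
        # P(G=1) = P(G=1|F=1)P(F=1) + P(G=1|F=0)P(F=0)
        expected = (5.25 / 19.5) * (19.5 / 103) + (0.25 / 83.5) * (83.5 / 103)
        assert query_p1(truth_net, "G") == pytest.approx(expected, abs=1e-12)
        assert round(query_p1(truth_net, "G"), 3) == 0.053

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_joint_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, int(rng.integers(3, 13)))
        nodes = list(net.dag.nodes)
        target = nodes[int(rng.integers(len(nodes)))]
        others = [v for v in nodes if v != target]
        k = int(rng.integers(0, min(3, len(others)) + 1))
        evidence = {v: int(rng.integers(2)) for v in rng.choice(others, k, replace=False)}
        mine = variable_elimination(net, target, Evidence(evidence))
        oracle = brute_force_query(net, target, evidence)
        assert np.allclose(mine, oracle, atol=1e-10)

    def test_law_of_total_probability(self, truth_net):
        for target, ev in [("B", "F"), ("G", "A"), ("U", "N")]:
            p_ev1 = query_p1(truth_net, ev)
            total = query_p1(truth_net, target, Evidence({ev: 1})) * p_ev1 + query_p1(
                truth_net, target, Evidence({ev: 0})
            ) * (1 - p_ev1)
            assert total == pytest.approx(query_p1(truth_net, target), abs=1e-10)

    def test_bayes_identity(self, truth_net):
        # P(parent=1|child=1) P(child=1) = P(child=1|parent=1) P(parent=1)
        lhs = query_p1(truth_net, "F", Evidence({"G": 1})) * query_p1(truth_net, "G")
        rhs = query_p1(truth_net, "G", Evidence({"F": 1})) * query_p1(truth_net, "F")
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_target_in_evidence_rejected(self, truth_net):
        with pytest.raises(ValueError):
            variable_elimination(truth_net, "G", Evidence({"G": 1}))


class TestScenarioAnalysis:
    def test_fg_scenario_reproduces_published_row(self, truth_net, fixture_fg):
        res = scenario_analysis(
            truth_net, None, Evidence({"F": 0}), "G", compute_ci=False
        )
        assert round(res.baseline_p1, 3) == 0.053
        assert round(res.conditional_p1, 3) == 0.003
        assert round(res.absolute_change, 3) == -0.050
        assert round(res.relative_change_pct, 1) == -94.4

    def test_fab_scenario_reproduces_published_row(self, truth_net):
        res = scenario_analysis(
            truth_net, None, Evidence({"A": 0}), "B", compute_ci=False
        )
        assert round(res.conditional_p1, 3) == 0.224
        assert round(res.baseline_p1, 3) == 0.150
        assert round(res.relative_change_pct, 1) == 49.1

    def test_relative_change_uses_unrounded_probabilities(self, truth_net):
        # rounding first would give 100*(0.458-0.383)/0.383 = +19.6; the
        # correct full-precision computation gives +19.4
        res = scenario_analysis(
            truth_net, None, Evidence({"F": 0}), "A", compute_ci=False
        )
        assert round(res.relative_change_pct, 1) == 19.4
        rounded_first = 100 * (0.458 - 0.383) / 0.383
        assert round(rounded_first, 1) == 19.6

    def test_disconnected_condition_leaves_target_unchanged(self, truth_net):
        res = scenario_analysis(
            truth_net, None, Evidence({"S": 0}), "G", compute_ci=False
        )
        assert res.conditional_p1 == pytest.approx(res.baseline_p1, abs=1e-12)
        assert res.absolute_change == pytest.approx(0.0, abs=1e-12)


class TestPosterior:
    @pytest.mark.parametrize(
        "observed,target,expected",
        [
            ({"G": 1}, "F", 0.955),
            ({"T": 1}, "S", 0.009),
            ({"U": 1}, "N", 0.370),
            ({"B": 1}, "F", 0.267),
            ({"B": 1}, "A", 0.081),
        ],
    )
    def test_published_posteriors(self, truth_net, observed, target, expected):
        res = posterior_cooccurrence(truth_net, Evidence(observed), target)
        assert round(res.posterior_p1, 3) == expected

    def test_deterministic_link_gives_posterior_one(self):
        dag = Dag(("X", "Y"), frozenset({("X", "Y")}))
        cpts = {
            "X": Cpt("X", (), np.array([[0.5, 0.5]])),
            "Y": Cpt("Y", ("X",), np.array([[1.0, 0.0], [0.0, 1.0]])),
        }
        net = BayesNet(dag, cpts)
        res = posterior_cooccurrence(net, Evidence({"X": 1}), "Y")
        assert res.posterior_p1 == pytest.approx(1.0)


class TestBootstrapCi:
    def test_constant_statistic_zero_width(self, fixture_fg, truth_net):
        dag = Dag(("F", "G"), frozenset({("F", "G")}))
        lo, hi = bootstrap_ci(fixture_fg, dag, lambda net: 0.42, B=50, seed=1)
        assert lo == hi == 0.42

    def test_degenerate_interval_for_structural_zero(self, fixture_fg):
        # the zero joint cell survives resampling, so the interval for
        # P(G=1|F=0) collapses around 0.003
        dag = Dag(("F", "G"), frozenset({("F", "G")}))
        lo, hi = bootstrap_ci(
            fixture_fg,
            dag,
            lambda net: query_p1(net, "G", Evidence({"F": 0})),
            B=500,
            seed=3,
        )
        assert hi - lo < 0.002
        assert round(lo, 3) == round(hi, 3) == 0.003

    def test_seeded_determinism(self, fixture_fg):
        dag = Dag(("F", "G"), frozenset({("F", "G")}))
        stat = lambda net: query_p1(net, "G")
        assert bootstrap_ci(fixture_fg, dag, stat, B=100, seed=9) == bootstrap_ci(
            fixture_fg, dag, stat, B=100, seed=9
        )

    def test_interval_covers_truth_in_simulation(self):
        # coverage spot-check: resampling CIs for theta(T=1|S=0) on data
        # simulated from the canonical truth at the study's sample size
        truth = canonical_truth()
        theta = truth.net.cpts["T"].table[0, 1]
        dag = truth.net.dag
        covered = 0
        reps = 30
        for seed in range(reps):
            sample = forward_sample(truth, 102, seed=500 + seed)
            lo, hi = bootstrap_ci(
                sample,
                dag,
                lambda net: net.cpts["T"].table[0, 1],
                B=200,
                seed=seed,
            )
            covered += lo <= theta <= hi
        assert covered >= int(0.88 * reps) - 1
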