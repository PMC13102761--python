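"""Bootstrap edge-frequency stability, stable-network selection, convergence."""

import numpy as np
import pytest

from bedfallnet.bootstrap import (
    BootstrapConfig,
    EdgeFrequencyTable,
    bootstrap_edge_frequencies,
    convergence_check,
    stable_network,
)
from bedfallnet.data import IncidentMatrix
from bedfallnet.synthetic import canonical_truth, forward_sample

from conftest import random_matrix

# the published stable-edge frequency profile (counts out of B=200)
PUBLISHED_COUNTS = {
    ("F", "G"): 163,
    ("S", "T"): 149,
    ("F", "A"): 122,
    ("A", "B"): 104,
    ("N", "U"): 102,
    ("H", "Q"): 18,
    ("K", "P"): 12,
}


class TestEdgeFrequencyTable:
    def test_frequencies_are_exact_rationals(self):
        table = EdgeFrequencyTable(PUBLISHED_COUNTS, B=200)
        assert table.frequency(("F", "G")) == 163 / 200 == 0.815
        assert table.frequency(("N", "U")) == 0.510
        assert table.frequency(("X", "Y")) == 0.0

    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            EdgeFrequencyTable({("A", "B"): 201}, B=200)


class TestStableNetwork:
    def test_majority_threshold_retains_the_five_stable_edges(self):
        table = EdgeFrequencyTable(PUBLISHED_COUNTS, B=200)
        dag = stable_network(table, threshold=0.5)
        assert set(dag.edges) == {
            ("F", "G"), ("F", "A"), ("A", "B"), ("S", "T"), ("N", "U")
        }

    def test_empty_table_and_strict_threshold(self):
        assert len(stable_network(EdgeFrequencyTable({}, B=10)).edges) == 0
        table = EdgeFrequencyTable({("A", "B"): 9}, B=10)
        assert len(stable_network(table, threshold=1.0).edges) == 0

    def test_monotone_in_threshold(self):
        table = EdgeFrequencyTable(PUBLISHED_COUNTS, B=200)
        for t1, t2 in [(0.3, 0.5), (0.5, 0.7), (0.05, 0.95)]:
            assert set(stable_network(table, t2).edges) <= set(
                stable_network(table, t1).edges
            )

    def test_cyclic_selection_raises_with_remedy(self):
        table = EdgeFrequencyTable({("A", "B"): 9, ("B", "A"): 8}, B=10)
        with pytest.raises(ValueError, match="increase the threshold"):
            stable_network(table, threshold=0.5)


class TestBootstrapFrequencies:
    def test_seeded_determinism(self, fixture_fg):
        cfg = BootstrapConfig(replicates=25, seed=7)
        a = bootstrap_edge_frequencies(fixture_fg, cfg)
        b = bootstrap_edge_frequencies(fixture_fg, cfg)
        assert a.counts == b.counts

    def test_duplicated_column_has_frequency_one(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 2, 500).astype(np.int8)
        m = IncidentMatrix(np.column_stack([col, col]), ("X", "Y"))
        table = bootstrap_edge_frequencies(m, BootstrapConfig(replicates=30, seed=1))
        assert table.adjacency_frequency("X", "Y") == 1.0
        # deterministic tie-break: one direction across all replicates
        assert max(table.counts.values()) == 30 and len(table.counts) == 1

    def test_independent_columns_have_low_frequencies(self):
        # qualitative analogue of non-stable edges staying below threshold;
        # frequencies pooled over 5 seeded datasets since a single draw can
        # carry a borderline chance correlation
        B, seeds = 40, 5
        pooled: dict = {}
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            m = random_matrix(rng, 102, tuple("ABCDEFGH"))
            table = bootstrap_edge_frequencies(
                m, BootstrapConfig(replicates=B, seed=seed)
            )
            for e, c in table.counts.items():
                pooled[e] = pooled.get(e, 0) + c / (B * seeds)
        assert all(f < 0.3 for f in pooled.values()), pooled

    def test_structure_recovery_from_forward_samples(self):
        # adjacency frequencies at the skeleton level, pooled over 10 seeded
        # runs: the five generating edges are stable, everything else rare
        truth = canonical_truth()
        true_adj = {frozenset(e) for e in truth.net.dag.edges}
        B, seeds = 20, 10
        adj_freq: dict = {}
        for seed in range(seeds):
            sample = forward_sample(truth, 5000, seed=seed)
            table = bootstrap_edge_frequencies(
                sample, BootstrapConfig(replicates=B, seed=seed)
            )
            for (u, v), c in table.counts.items():
                key = frozenset((u, v))
                adj_freq[key] = adj_freq.get(key, 0) + c / (B * seeds)
        for adj in true_adj:
            assert adj_freq.get(adj, 0) >= 0.9, adj
        for adj, f in adj_freq.items():
            if adj not in true_adj:
                assert f <= 0.2, adj


class TestConvergence:
    def test_single_checkpoint_gives_empty_report(self, fixture_fg):
        report = convergence_check(fixture_fg, BootstrapConfig(seed=1), [50])
        assert report.empty

    def test_deterministic_edge_has_zero_drift(self):
        rng = np.random.default_rng(9)
        col = rng.integers(0, 2, 400).astype(np.int8)
        m = IncidentMatrix(np.column_stack([col, col]), ("X", "Y"))
        report = convergence_check(m, BootstrapConfig(seed=2), [10, 20])
        assert (report["drift"] == 0).all()

    def test_stable_edges_drift_little_beyond_200_replicates(self):
        # forward-sampled study-sized data: top-edge frequencies settle
        truth = canonical_truth()
        for seed in range(3):
            sample = forward_sample(truth, 102, seed=100 + seed)
            report = convergence_check(
                sample, BootstrapConfig(seed=seed), [200, 400]
            )
            top = report[report["From"].isin(["F", "S", "N", "A"])]
            assert (report["drift"] <= 0.10).all(), report[report["drift"] > 0.10]

    def test_decreasing_checkpoints_rejected(self, fixture_fg):
        with pytest.raises(ValueError):
            convergence_check(fixture_fg, BootstrapConfig(seed=1), [100, 50])
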