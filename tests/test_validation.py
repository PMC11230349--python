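import numpy as np
import pytest

import connsnr as cs
from connsnr.validation import poisson_sbm_fit
from conftest import random_graph_and_partition


def brute_force_modularity(graph, partition, alpha=1.0):
    """Independent double-loop modularity oracle (ordered pairs, 1/2m norm)."""
    a = graph.adjacency.astype(float)
    n = graph.n
    two_m = a.sum()
    deg = a.sum(axis=1)
    q = 0.0
    for u in range(n):
        for v in range(n):
            if partition.sigma[u] == partition.sigma[v]:
                q += a[u, v] - alpha * deg[u] * deg[v] / two_m
    return q / two_m


def two_triangles():
    a = np.zeros((6, 6))
    for tri in ([0, 1, 2], [3, 4, 5]):
        for i in tri:
            for j in tri:
                if i != j:
                    a[i, j] = 1
    return cs.BinaryConnectome(adjacency=a)


class TestModularity:
    def test_two_triangles_half(self):
        g = two_triangles()
        part = cs.Partition.from_labels([0, 0, 0, 1, 1, 1])
        assert cs.modularity(g, part) == pytest.approx(0.5)

    def test_single_community_zero(self):
        g = two_triangles()
        part = cs.Partition.from_labels([0] * 6)
        assert cs.modularity(g, part) == pytest.approx(0.0, abs=1e-15)

    def test_crossing_partition_negative(self):
        g = two_triangles()
        part = cs.Partition.from_labels([0, 1, 0, 1, 0, 1])
        assert cs.modularity(g, part) < 0

    def test_edgeless_graph_errors(self):
        g = cs.BinaryConnectome(adjacency=np.zeros((4, 4)))
        part = cs.make_planted_partition(4, 2)
        with pytest.raises(ValueError, match="edgeless"):
            cs.modularity(g, part)

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence(self, seed):
        rng = np.random.default_rng(200 + seed)
        g, part = random_graph_and_partition(rng)
        if g.n_edges == 0:
            return
        alpha = float(rng.uniform(0.5, 1.5))
        assert cs.modularity(g, part, alpha=alpha) == pytest.approx(
            brute_force_modularity(g, part, alpha=alpha), abs=1e-12
        )


class TestMaximizeModularity:
    def test_recovers_two_triangles(self):
        g = two_triangles()
        part = cs.maximize_modularity(g, seed=0)
        assert part.k == 2
        assert cs.modularity(g, part) == pytest.approx(0.5)

    def test_two_cliques_single_bridge(self):
        a = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        a[i, j] = 1
        a[4, 5] = a[5, 4] = 1
        part = cs.maximize_modularity(cs.BinaryConnectome(adjacency=a), seed=0)
        assert part.k == 2
        assert len(set(part.sigma[:5])) == 1 and len(set(part.sigma[5:])) == 1

    def test_complete_graph_degenerate(self):
        g = cs.BinaryConnectome(adjacency=1 - np.eye(6))
        part = cs.maximize_modularity(g, seed=0)
        assert cs.modularity(g, part) <= 1e-12

    def test_beats_ground_truth_on_easy_instance(self):
        part_true = cs.make_planted_partition(60, 3)
        w = np.full((3, 3), 0.05)
        np.fill_diagonal(w, 0.6)
        g = cs.sample_binary_sbm(part_true, w, seed=1)
        found = cs.maximize_modularity(g, seed=0)
        assert cs.modularity(g, found) >= cs.modularity(g, part_true) - 1e-12


class TestPoissonSbmFit:
    def test_easy_binary_instance_exact(self):
        part_true = cs.make_planted_partition(60, 2)
        w = np.full((2, 2), 0.05)
        np.fill_diagonal(w, 0.5)
        g = cs.sample_binary_sbm(part_true, w, seed=0)
        found = cs.poisson_sbm_fit(g, k=2, seed=0)
        assert cs.ami(found, part_true) == pytest.approx(1.0)

    def test_easy_weighted_instance_exact(self):
        part_true = cs.make_planted_partition(40, 2)
        rng = np.random.default_rng(0)
        m = rng.normal(0.1, 0.03, size=(40, 40))
        within = part_true.sigma[:, None] == part_true.sigma[None, :]
        m[within] = rng.normal(0.6, 0.05, size=within.sum())
        m = np.clip((m + m.T) / 2, -1, 1)
        np.fill_diagonal(m, 0.0)
        found = cs.poisson_sbm_fit(cs.WeightedConnectome(weights=m), k=2, seed=0)
        assert cs.ami(found, part_true) == pytest.approx(1.0)

    def test_structureless_graph_near_zero_ami(self):
        rng = np.random.default_rng(2)
        a = np.triu((rng.random((80, 80)) < 0.2).astype(int), 1)
        g = cs.BinaryConnectome(adjacency=a + a.T)
        planted = cs.make_planted_partition(80, 4)
        found = cs.poisson_sbm_fit(g, k=4, seed=0)
        assert abs(cs.ami(found, planted)) < 0.1

    def test_log_likelihood_non_decreasing(self):
        part_true = cs.make_planted_partition(40, 2)
        w = np.full((2, 2), 0.1)
        np.fill_diagonal(w, 0.5)
        g = cs.sample_binary_sbm(part_true, w, seed=3)
        _, trace = poisson_sbm_fit(g, k=2, seed=0, return_trace=True)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_k_bounds(self):
        g = cs.BinaryConnectome(adjacency=1 - np.eye(4))
        with pytest.raises(ValueError):
            cs.poisson_sbm_fit(g, k=1)
        with pytest.raises(ValueError):
            cs.poisson_sbm_fit(g, k=5)

    def test_determinism(self):
        part_true = cs.make_planted_partition(30, 3)
        w = np.full((3, 3), 0.1)
        np.fill_diagonal(w, 0.5)
        g = cs.sample_binary_sbm(part_true, w, seed=5)
        a = cs.poisson_sbm_fit(g, k=3, seed=1)
        b = cs.poisson_sbm_fit(g, k=3, seed=1)
        assert np.array_equal(a.sigma, b.sigma)


class TestAmi:
    def test_identical_partitions(self):
        p = cs.Partition.from_labels([0, 0, 1, 1, 2])
        assert cs.ami(p, p) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        p1 = cs.Partition.from_labels([0, 0, 1, 1, 2, 2])
        p2 = cs.Partition.from_labels([2, 2, 0, 0, 1, 1])
        assert cs.ami(p1, p2) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        p1 = cs.Partition.from_labels(rng.integers(0, 3, size=50))
        p2 = cs.Partition.from_labels(rng.integers(0, 3, size=50))
        assert cs.ami(p1, p2) == pytest.approx(cs.ami(p2, p1))

    def test_chance_adjustment_near_zero(self):
        """Independent uniform partitions score ~0 on average (the point of
        the chance correction)."""
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(50):
            p1 = cs.Partition.from_labels(rng.integers(0, 4, size=1000))
            p2 = cs.Partition.from_labels(rng.integers(0, 4, size=1000))
            vals.append(cs.ami(p1, p2))
        assert abs(np.mean(vals)) < 0.02

    def test_size_mismatch_errors(self):
        p1 = cs.Partition.from_labels([0, 1])
        p2 = cs.Partition.from_labels([0, 1, 1])
        with pytest.raises(ValueError):
            cs.ami(p1, p2)

    def test_nmi_variant_upper_bounds_ami(self):
        rng = np.random.default_rng(2)
        p1 = cs.Partition.from_labels(rng.integers(0, 3, size=60))
        p2 = cs.Partition.from_labels(rng.integers(0, 3, size=60))
        assert cs.ami(p1, p2, variant="nmi") >= cs.ami(p1, p2) - 1e-12


@pytest.fixture(scope="module")
def curves(planted_ga):
    ga, part = planted_ga
    return cs.agreement_curves(ga, part, seed=0)


class TestAgreementCurves:

    def test_ami_peak_tracks_snr_peak(self, curves):
        tau_snr = curves.taus[np.argmax(curves.snr_curve)]
        tau_ami = curves.taus[np.argmax(curves.ami_q)]
        assert abs(tau_snr - tau_ami) <= 0.05 + 1e-9

    def test_q_plateaus_high_decoupled_from_ami(self, curves):
        """Raw Q keeps climbing into the sparse regime and stays high where
        the AMI agreement has already collapsed."""
        tau_q = curves.taus[np.argmax(curves.q_scores)]
        tau_ami = curves.taus[np.argmax(curves.ami_q)]
        assert tau_q >= tau_ami + 0.05 - 1e-9
        late = (curves.taus >= tau_q) & ~curves.degenerate
        assert np.all(curves.q_scores[late] > 0.5)
        assert curves.ami_q[late][-1] < 0.5

    def test_edgeless_rows_flagged(self, curves):
        assert curves.degenerate[-1]
        assert curves.ami_q[curves.degenerate].max(initial=0.0) == 0.0

    def test_frame_columns(self, curves):
        df = curves.to_frame()
        assert list(df.columns) == ["tau", "q", "ami_q", "ami_sbm", "snr", "degenerate"]
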