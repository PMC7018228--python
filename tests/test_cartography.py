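import math

import numpy as np
import pytest

from navmaps import (
    Connectome,
    HyperbolicMap,
    Partition,
    PolarPoint,
    angular_localization,
    critical_gap_communities,
    empirical_connection_probability,
    nmi,
    region_angular_span,
)
from navmaps.geometry import EuclideanMetric

TWO_PI = 2 * math.pi


def _map_from_angles(angles: dict[str, float], R: float = 10.0) -> HyperbolicMap:
    return HyperbolicMap(
        coordinates={n: PolarPoint(R / 2, t) for n, t in angles.items()}, R=R, beta=2.0
    )


def _two_arc_map(n_per_arc=10, width=0.3, centers=(0.0, math.pi), seed=0):
    rng = np.random.default_rng(seed)
    angles = {}
    for k, c in enumerate(centers):
        for i in range(n_per_arc):
            angles[f"a{k}_{i:02d}"] = (c + rng.uniform(-width / 2, width / 2)) % TWO_PI
    return _map_from_angles(angles)


class TestCriticalGap:
    def test_two_planted_arcs_recovered_exactly(self):
        hmap = _two_arc_map()
        part = critical_gap_communities(hmap)
        assert len(part.labels) == 2
        comms = {frozenset(m) for m in part.communities().values()}
        assert comms == {
            frozenset(n for n in hmap.coordinates if n.startswith("a0")),
            frozenset(n for n in hmap.coordinates if n.startswith("a1")),
        }

    def test_single_node_single_community(self):
        part = critical_gap_communities(_map_from_angles({"only": 1.0}))
        assert part.assignment == {"only": "c0"}

    def test_rotation_invariance_up_to_labels(self):
        hmap = _two_arc_map(seed=3)
        part1 = critical_gap_communities(hmap)
        rotated = _map_from_angles(
            {n: (p.theta + 1.234) % TWO_PI for n, p in hmap.coordinates.items()}
        )
        part2 = critical_gap_communities(rotated)
        assert {frozenset(m) for m in part1.communities().values()} == \
            {frozenset(m) for m in part2.communities().values()}

    def test_uniform_nodes_form_one_community(self):
        # equally spaced angles: every gap is 2*pi/N < (2*pi/N) ln N
        angles = {f"u{i:02d}": TWO_PI * i / 50 for i in range(50)}
        part = critical_gap_communities(_map_from_angles(angles))
        assert len(part.labels) == 1

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            critical_gap_communities(_map_from_angles({}))


class TestNMI:
    def test_identical_partitions(self):
        p = Partition({"1": "x", "2": "x", "3": "y", "4": "y"})
        assert nmi(p, p) == pytest.approx(1.0)

    def test_crossed_partition_is_independent(self):
        p1 = Partition({"1": "a", "2": "a", "3": "b", "4": "b"})
        p2 = Partition({"1": "a", "2": "b", "3": "a", "4": "b"})
        assert nmi(p1, p2) == pytest.approx(0.0, abs=1e-12)

    def test_single_cluster_against_split(self):
        p1 = Partition({"1": "a", "2": "a", "3": "b", "4": "b"})
        p2 = Partition({n: "all" for n in "1234"})
        assert nmi(p1, p2) == 0.0
        assert nmi(p2, p2) == 1.0  # identical single-cluster partitions

    def test_symmetric_and_label_invariant(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(60)]
        p1 = Partition({n: f"g{rng.integers(0, 4)}" for n in nodes})
        p2 = Partition({n: f"h{rng.integers(0, 3)}" for n in nodes})
        assert nmi(p1, p2) == pytest.approx(nmi(p2, p1))
        relabeled = Partition({n: "Z" + v for n, v in p1.assignment.items()})
        assert nmi(relabeled, p2) == pytest.approx(nmi(p1, p2))

    def test_matches_reference_implementation(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(200)]
        a = rng.integers(0, 5, 200)
        b = (a + (rng.random(200) < 0.3) * rng.integers(1, 5, 200)) % 5
        p1 = Partition({n: str(a[i]) for i, n in enumerate(nodes)})
        p2 = Partition({n: str(b[i]) for i, n in enumerate(nodes)})
        for norm, method in [("arithmetic", "arithmetic"), ("max", "max"), ("sqrt", "geometric")]:
            expected = sklearn_metrics.normalized_mutual_info_score(a, b, average_method=method)
            assert nmi(p1, p2, normalization=norm) == pytest.approx(expected, abs=1e-10)

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nmi(Partition({"1": "a"}), Partition({"2": "a"}))


class TestAngularLocalization:
    def test_full_set_cluster_has_unit_ratio(self):
        rng = np.random.default_rng(2)
        angles = {f"n{i:03d}": rng.uniform(0, TWO_PI) for i in range(40)}
        hmap = _map_from_angles(angles)
        rep = angular_localization(hmap, list(angles), n_samples=200, seed=1)
        assert rep.ratio == pytest.approx(1.0)
        assert rep.p_value == 1.0

    def test_planted_arc_is_significant(self):
        rng = np.random.default_rng(4)
        angles = {f"bg{i:03d}": rng.uniform(0, TWO_PI) for i in range(180)}
        arc = {f"arc{i:02d}": rng.uniform(-0.15, 0.15) % TWO_PI for i in range(20)}
        hmap = _map_from_angles({**angles, **arc})
        rep = angular_localization(hmap, list(arc), n_samples=10_000, seed=7)
        assert rep.p_value < 0.01
        assert rep.ratio < 0.2
        assert rep.mean_sep_null == pytest.approx(math.pi / 2, rel=0.1)

    def test_single_node_cluster_rejected(self):
        hmap = _map_from_angles({"a": 0.0, "b": 1.0})
        with pytest.raises(ValueError):
            angular_localization(hmap, ["a"])

    def test_missing_cluster_node_rejected(self):
        hmap = _map_from_angles({"a": 0.0, "b": 1.0})
        with pytest.raises(ValueError):
            angular_localization(hmap, ["a", "zz"])

    def test_p_value_roughly_uniform_for_random_clusters(self):
        """Random 'clusters' should give a p-value with no systematic bias."""
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(10)
        angles = {f"n{i:03d}": rng.uniform(0, TWO_PI) for i in range(100)}
        hmap = _map_from_angles(angles)
        ids = sorted(angles)
        ps = []
        for rep_i in range(200):
            cluster = rng.choice(ids, size=6, replace=False)
            rep = angular_localization(hmap, cluster, n_samples=400, seed=1000 + rep_i)
            ps.append(rep.p_value)
        stat = scipy_stats.kstest(ps, "uniform").pvalue
        assert stat > 1e-3


class TestAngularSpan:
    def test_tight_arc_span(self):
        hmap = _map_from_angles({"a": 0.0, "b": 0.1, "c": 0.2})
        assert region_angular_span(hmap, ["a", "b", "c"]) == pytest.approx(0.2 / TWO_PI)

    def test_degenerate_cluster_has_zero_span(self):
        hmap = _map_from_angles({"a": 1.5, "b": 1.5, "c": 1.5})
        assert region_angular_span(hmap, ["a", "b", "c"]) == pytest.approx(0.0, abs=1e-12)

    def test_wraparound_arc(self):
        hmap = _map_from_angles({"a": TWO_PI - 0.1, "b": 0.0, "c": 0.1})
        assert region_angular_span(hmap, ["a", "b", "c"]) == pytest.approx(0.2 / TWO_PI)

    def test_uniform_angles_cover_most_of_circle(self):
        rng = np.random.default_rng(12)
        angles = {f"n{i:03d}": rng.uniform(0, TWO_PI) for i in range(100)}
        hmap = _map_from_angles(angles)
        assert region_angular_span(hmap, list(angles)) >= 0.9

    def test_empty_cluster_rejected(self):
        hmap = _map_from_angles({"a": 0.0})
        with pytest.raises(ValueError):
            region_angular_span(hmap, [])


class TestEmpiricalConnectionProbability:
    def _spatial(self, edges_fn, n=20, seed=3):
        rng = np.random.default_rng(seed)
        ids = [f"n{i:02d}" for i in range(n)]
        pos = {m: rng.uniform(0, 1, 3) for m in ids}
        edges = edges_fn(ids)
        return Connectome(node_ids=ids, edges=edges, positions=pos), EuclideanMetric(pos)

    def test_complete_graph_has_unit_fraction_everywhere(self):
        c, metric = self._spatial(
            lambda ids: {(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]}
        )
        curve = empirical_connection_probability(c, metric, 5)
        assert np.all(curve.fractions[curve.counts > 0] == 1.0)

    def test_empty_graph_has_zero_fraction_everywhere(self):
        c, metric = self._spatial(lambda ids: set())
        curve = empirical_connection_probability(c, metric, 5)
        assert np.all(curve.fractions[curve.counts > 0] == 0.0)
        assert np.all(np.isnan(curve.fractions[curve.counts == 0]))

    def test_counts_cover_all_pairs(self):
        c, metric = self._spatial(lambda ids: {(ids[0], ids[1])})
        curve = empirical_connection_probability(c, metric, 7)
        assert curve.counts.sum() == 20 * 19 // 2

    def test_too_few_nodes_rejected(self):
        c = Connectome(node_ids=["a"], edges=set(), positions={"a": np.zeros(3)})
        with pytest.raises(ValueError):
            empirical_connection_probability(c, EuclideanMetric(c.positions), 3)
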