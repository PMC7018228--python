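import math

import numpy as np
import pytest

from navmaps import (
    Connectome,
    HyperbolicMap,
    PolarPoint,
    S1Parameters,
    calibrate_mu,
    connection_prob_h2,
    connection_prob_s1,
    generate_s1_network,
    kappa_to_radius,
    log_likelihood,
    radius_to_kappa,
)
from navmaps.generators import S1GeneratorConfig
from navmaps.model import disk_radius_from_mu


class TestConnectionProbH2:
    def test_logistic_midpoint(self):
        assert connection_prob_h2(7.0, 7.0, 2.5) == pytest.approx(0.5)

    def test_closed_form_offset(self):
        beta = 3.0
        assert connection_prob_h2(5.0 + 2.0 / beta, 5.0, beta) == pytest.approx(1 / (1 + math.e))

    def test_step_limit_at_large_beta(self):
        assert connection_prob_h2(4.0, 5.0, 500.0) == pytest.approx(1.0, abs=1e-12)
        assert connection_prob_h2(6.0, 5.0, 500.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing(self):
        x = np.linspace(0, 20, 100)
        p = connection_prob_h2(x, 8.0, 2.0)
        assert np.all(np.diff(p) < 0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            connection_prob_h2(float("inf"), 5.0, 2.0)


class TestConnectionProbS1:
    def test_characteristic_scale(self):
        assert connection_prob_s1(0.06, 2.0, 3.0, 0.01, 2.5) == pytest.approx(0.5)

    def test_arithmetic_example(self):
        # dtheta = 2 mu ki kj, beta = 2 -> 1/(1+4) = 0.2
        assert connection_prob_s1(0.12, 2.0, 3.0, 0.01, 2.0) == pytest.approx(0.2)

    def test_certain_connection_at_zero_separation(self):
        assert connection_prob_s1(0.0, 1.0, 1.0, 0.01, 2.5) == 1.0

    def test_rejects_negative_separation(self):
        with pytest.raises(ValueError):
            connection_prob_s1(-0.1, 1.0, 1.0, 0.01, 2.5)


class TestKappaRadiusMapping:
    def test_minimum_degree_sits_on_boundary(self):
        assert kappa_to_radius(2.0, 2.0, 12.0) == pytest.approx(12.0)

    def test_disk_center(self):
        R = 10.0
        assert kappa_to_radius(2.0 * math.exp(R / 2), 2.0, R) == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(1)
        R, k0 = 14.0, 1.5
        kappas = k0 * (1 + rng.pareto(1.7, 100))
        r = kappa_to_radius(kappas, k0, R)
        back = radius_to_kappa(r, k0, R)
        assert np.allclose(back, kappas, rtol=1e-12)

    def test_rejects_kappa_below_minimum(self):
        with pytest.raises(ValueError):
            kappa_to_radius(0.5, 1.0, 10.0)


def test_s1_h2_isomorphism_identity():
    """Logistic law on the approximate geodesic equals the S1 law after the
    hidden-degree change of variables, to near machine precision."""
    rng = np.random.default_rng(99)
    mu, beta, k0 = 0.013, 2.5, 2.0
    R = disk_radius_from_mu(mu, k0)
    kmax = k0 * math.exp(R / 2)  # keep radii non-negative
    for _ in range(500):
        ki = min(k0 * (1 + rng.pareto(1.7)), kmax)
        kj = min(k0 * (1 + rng.pareto(1.7)), kmax)
        dth = rng.uniform(1e-8, math.pi)
        ri = kappa_to_radius(ki, k0, R)
        rj = kappa_to_radius(kj, k0, R)
        x = ri + rj + 2.0 * math.log(dth / 2.0)
        p_h2 = connection_prob_h2(x, R, beta)
        p_s1 = connection_prob_s1(dth, ki, kj, mu, beta)
        assert abs(p_h2 - p_s1) <= 1e-9 * p_s1


class TestCalibrateMu:
    def test_generate_and_measure(self):
        # homogeneous hidden degrees: realized mean degree within 5%
        kappas = np.full(2000, 10.0)
        mu = calibrate_mu(kappas, 2.5, 10.0)
        rng = np.random.default_rng(3)
        thetas = rng.uniform(0, 2 * math.pi, 2000)
        dth = np.pi - np.abs(np.pi - np.abs(thetas[:, None] - thetas[None, :]) % (2 * math.pi))
        p = connection_prob_s1(dth, 10.0, 10.0, mu, 2.5)
        iu = np.triu_indices(2000, 1)
        k_real = 2 * (rng.random(iu[0].size) < p[iu]).sum() / 2000
        assert k_real == pytest.approx(10.0, rel=0.05)

    def test_mu_scaling_with_target_degree(self):
        # with hidden degrees rescaled alongside the target (the standard
        # <kappa> = <k> convention), doubling the target halves mu; with
        # kappas held fixed the expected degree is linear in mu, so the
        # calibrated mu doubles instead
        rng = np.random.default_rng(7)
        kappas = 3.0 * (1 + rng.pareto(1.7, 1000))
        scale = 6.0 / kappas.mean()
        mu1 = calibrate_mu(kappas * scale, 2.5, 6.0)
        mu2 = calibrate_mu(kappas * 2 * scale, 2.5, 12.0)
        assert mu2 == pytest.approx(mu1 / 2, rel=0.10)
        mu_fixed = calibrate_mu(kappas * scale, 2.5, 12.0)
        assert mu_fixed == pytest.approx(2 * mu1, rel=0.10)

    def test_infeasible_target(self):
        with pytest.raises(ValueError):
            calibrate_mu(np.full(50, 5.0), 2.5, 50.0)


class TestLogLikelihood:
    def _two_node_map(self, R=6.0, beta=2.0):
        # both nodes at r = R/2, antipodal: distance exactly R, p = 1/2
        coords = {"a": PolarPoint(R / 2, 0.0), "b": PolarPoint(R / 2, math.pi)}
        return HyperbolicMap(coordinates=coords, R=R, beta=beta)

    def test_single_pair_at_midpoint(self):
        c = Connectome(node_ids=["a", "b"], edges={("a", "b")})
        assert log_likelihood(c, self._two_node_map()) == pytest.approx(math.log(0.5))

    def test_complete_triangle_sums_log_probs(self):
        coords = {
            "a": PolarPoint(2.0, 0.1),
            "b": PolarPoint(3.0, 1.7),
            "c": PolarPoint(1.0, 4.0),
        }
        hmap = HyperbolicMap(coordinates=coords, R=5.0, beta=2.2)
        c = Connectome(node_ids=["a", "b", "c"], edges={("a", "b"), ("b", "c"), ("a", "c")})
        from navmaps.geometry import hyperbolic_distance

        expected = sum(
            math.log(connection_prob_h2(hyperbolic_distance(coords[u], coords[v]), 5.0, 2.2))
            for u, v in [("a", "b"), ("b", "c"), ("a", "c")]
        )
        assert log_likelihood(c, hmap) == pytest.approx(expected)

    def test_against_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        ids = list("abcde")
        coords = {n: PolarPoint(rng.uniform(0, 6), rng.uniform(0, 2 * math.pi)) for n in ids}
        hmap = HyperbolicMap(coordinates=coords, R=6.5, beta=3.0)
        edges = {("a", "b"), ("b", "d"), ("c", "e"), ("a", "e")}
        c = Connectome(node_ids=ids, edges=edges)
        from navmaps.geometry import hyperbolic_distance

        expected = 0.0
        for i in range(5):
            for j in range(i + 1, 5):
                u, v = ids[i], ids[j]
                p = connection_prob_h2(hyperbolic_distance(coords[u], coords[v]), 6.5, 3.0)
                p = min(max(p, 1e-15), 1 - 1e-15)
                a = 1 if tuple(sorted((u, v))) in edges else 0
                expected += a * math.log(p) + (1 - a) * math.log(1 - p)
        assert log_likelihood(c, hmap) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_rotation_and_reflection(self):
        cfg = S1GeneratorConfig(N=60, seed=21, mean_degree=6.0)
        c, truth = generate_s1_network(cfg)
        hmap = truth.to_hyperbolic_map()
        base = log_likelihood(c, hmap)
        for transform in (lambda t: t + 1.234, lambda t: 2 * math.pi - t):
            coords = {
                n: PolarPoint(p.r, transform(p.theta) % (2 * math.pi))
                for n, p in hmap.coordinates.items()
            }
            other = HyperbolicMap(coordinates=coords, R=hmap.R, beta=hmap.beta)
            assert log_likelihood(c, other) == pytest.approx(base, rel=1e-9)

    def test_missing_coordinates_rejected(self):
        c = Connectome(node_ids=["a", "b"], edges={("a", "b")})
        hmap = HyperbolicMap(coordinates={"a": PolarPoint(1, 0)}, R=5.0, beta=2.0)
        with pytest.raises(ValueError, match="b"):
            log_likelihood(c, hmap)


def test_hyperbolic_map_round_trip(tmp_path):
    coords = {"a": PolarPoint(1.25, 0.5), "b": PolarPoint(3.5, 4.25)}
    hmap = HyperbolicMap(coordinates=coords, R=4.0, beta=2.5)
    hmap.write(tmp_path / "map.tsv")
    back = HyperbolicMap.read(tmp_path / "map.tsv")
    assert back.R == hmap.R and back.beta == hmap.beta
    for n in coords:
        assert back.coordinates[n].r == coords[n].r
        assert back.coordinates[n].theta == coords[n].theta


def test_s1_parameters_round_trip(tmp_path):
    params = S1Parameters(
        kappas={"a": 2.0, "b": 5.5}, thetas={"a": 0.25, "b": 3.5}, mu=0.02, beta=2.5, N=2
    )
    params.write(tmp_path / "truth.json")
    back = S1Parameters.read(tmp_path / "truth.json")
    assert back.kappas == params.kappas and back.thetas == params.thetas
    assert back.mu == params.mu and back.beta == params.beta
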