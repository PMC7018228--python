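"""The hidden-metric-space (S1/H2) network model.

A network is assumed to live in an effective geometry that couples to its
topology through a probabilistic connection law.  In the H2 (hyperbolic
disk) formulation every node has polar coordinates (r, theta) and a pair at
geodesic distance x is linked with probability

    p(x) = 1 / (1 + exp(beta/2 * (x - R))),

where the disk radius R sets the expected average degree and the inverse
temperature beta > 1 sets the clustering.  The isomorphic S1 formulation
replaces the radius with a hidden degree kappa ~ exp((R - r)/2), giving

    p_ij = 1 / (1 + (dtheta_ij / (mu * kappa_i * kappa_j))**beta),

with mu playing the role of R.  We fix the free constant of the kappa <-> r
proportionality by placing the minimum hidden degree kappa0 on the disk
boundary, r = R - 2 ln(kappa / kappa0), which forces

    R = 2 ln(2 / (mu * kappa0**2))

for the two forms to coincide under the approximate geodesic length.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .geometry import HyperbolicMetric, PolarPoint, hyperbolic_distance_matrix, wrap_angle
from .io import Connectome

logger = logging.getLogger(__name__)

PROB_CLAMP = 1e-15

__all__ = [
    "HyperbolicMap",
    "S1Parameters",
    "connection_prob_h2",
    "connection_prob_s1",
    "kappa_to_radius",
    "radius_to_kappa",
    "disk_radius_from_mu",
    "calibrate_mu",
    "expected_mean_degree",
    "log_likelihood",
]


@dataclasses.dataclass
class HyperbolicMap:
    """Per-node polar coordinates plus the global parameters (R, beta)."""

    coordinates: dict[str, PolarPoint]
    R: float
    beta: float

    # radial coordinates may exceed R by round-off only
    _R_SLACK = 1e-9

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError("disk radius R must be positive")
        if not self.beta > 1:
            raise ValueError("inverse temperature beta must exceed 1 (finite-clustering regime)")
        for n, p in self.coordinates.items():
            if p.r > self.R + self._R_SLACK:
                raise ValueError(f"node {n!r} has r={p.r} beyond disk radius R={self.R}")

    def metric(self) -> HyperbolicMetric:
        return HyperbolicMetric(self.coordinates)

    def arrays(self, node_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        r = np.array([self.coordinates[n].r for n in node_ids])
        theta = np.array([self.coordinates[n].theta for n in node_ids])
        return r, theta

    # -- serialization: TSV of (id, r, theta) plus a JSON sidecar -------
    def write(self, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        tsv_path = Path(tsv_path)
        with tsv_path.open("w") as fh:
            for n, p in self.coordinates.items():
                fh.write(f"{n}\t{p.r!r}\t{p.theta!r}\n")
        sidecar = Path(sidecar_path) if sidecar_path else tsv_path.with_suffix(".json")
        sidecar.write_text(json.dumps({"R": self.R, "beta": self.beta}, indent=1))

    @classmethod
    def read(cls, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> "HyperbolicMap":
        tsv_path = Path(tsv_path)
        sidecar = Path(sidecar_path) if sidecar_path else tsv_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        coords: dict[str, PolarPoint] = {}
        with tsv_path.open() as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                n, r, theta = line.split()
                coords[n] = PolarPoint(float(r), float(theta))
        return cls(coordinates=coords, R=float(meta["R"]), beta=float(meta["beta"]))


@dataclasses.dataclass
class S1Parameters:
    """Hidden degrees and angles of the S1 formulation (isomorphic to H2)."""

    kappas: dict[str, float]
    thetas: dict[str, float]
    mu: float
    beta: float
    N: int

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not self.beta > 1:
            raise ValueError("beta must exceed 1")
        for n, k in self.kappas.items():
            if not (math.isfinite(k) and k > 0):
                raise ValueError(f"hidden degree of node {n!r} must be finite and positive")
        self.thetas = {n: wrap_angle(t) for n, t in self.thetas.items()}

    @property
    def kappa0(self) -> float:
        return min(self.kappas.values())

    def to_hyperbolic_map(self) -> HyperbolicMap:
        """Change of variables to disk coordinates.

        Radii of very-high-degree nodes that would fall past the disk center
        are clamped at r = 0.
        """
        R = disk_radius_from_mu(self.mu, self.kappa0)
        k0 = self.kappa0
        coords = {
            n: PolarPoint(max(0.0, kappa_to_radius(k, k0, R)), self.thetas[n])
            for n, k in self.kappas.items()
        }
        return HyperbolicMap(coordinates=coords, R=R, beta=self.beta)

    def write(self, path: str | Path) -> None:
        payload = {
            "mu": self.mu,
            "beta": self.beta,
            "N": self.N,
            "nodes": {n: {"kappa": self.kappas[n], "theta": self.thetas[n]} for n in self.kappas},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "S1Parameters":
        payload = json.loads(Path(path).read_text())
        nodes = payload["nodes"]
        return cls(
            kappas={n: d["kappa"] for n, d in nodes.items()},
            thetas={n: d["theta"] for n, d in nodes.items()},
            mu=payload["mu"],
            beta=payload["beta"],
            N=payload["N"],
        )


# ---------------------------------------------------------------------------
# connection probabilities and the S1 <-> H2 mapping
# ---------------------------------------------------------------------------

def connection_prob_h2(x, R: float, beta: float):
    """Logistic connection probability in the disk; 1/2 at x = R."""
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and math.isfinite(R) and math.isfinite(beta)):
        raise ValueError("non-finite input")
    if R <= 0 or beta <= 0:
        raise ValueError("R and beta must be positive")
    # stable logistic: 1/(1+exp(u))
    u = 0.5 * beta * (x - R)
    out = np.exp(-np.logaddexp(0.0, u))
    return float(out) if out.ndim == 0 else out


def connection_prob_s1(dtheta, ki, kj, mu: float, beta: float):
    """S1 connection probability; equals 1 at zero angular separation."""
    dtheta = np.asarray(dtheta, dtype=float)
    ki = np.asarray(ki, dtype=float)
    kj = np.asarray(kj, dtype=float)
    if not (np.all(np.isfinite(dtheta)) and np.all(np.isfinite(ki)) and np.all(np.isfinite(kj))):
        raise ValueError("non-finite input")
    if np.any(dtheta < 0) or np.any(ki <= 0) or np.any(kj <= 0) or mu <= 0:
        raise ValueError("dtheta must be >= 0 and kappas/mu positive")
    with np.errstate(divide="ignore"):
        chi = dtheta / (mu * ki * kj)
        out = np.where(chi > 0, np.exp(-np.logaddexp(0.0, beta * np.log(np.where(chi > 0, chi, 1.0)))), 1.0)
    return float(out) if out.ndim == 0 else out


def kappa_to_radius(kappa, kappa0: float, R: float):
    """r = R - 2 ln(kappa/kappa0); the lowest degree sits on the boundary."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < kappa0) or kappa0 <= 0:
        raise ValueError("require kappa >= kappa0 > 0")
    out = R - 2.0 * np.log(kappa / kappa0)
    return float(out) if out.ndim == 0 else out


def radius_to_kappa(r, kappa0: float, R: float):
    """Inverse of :func:`kappa_to_radius`."""
    r = np.asarray(r, dtype=float)
    out = kappa0 * np.exp(0.5 * (R - r))
    return float(out) if out.ndim == 0 else out


def disk_radius_from_mu(mu: float, kappa0: float) -> float:
    """Disk radius making the H2 law match the S1 law: R = 2 ln(2/(mu kappa0^2))."""
    R = 2.0 * math.log(2.0 / (mu * kappa0**2))
    if R <= 0:
        raise ValueError(f"mu={mu}, kappa0={kappa0} give non-positive disk radius")
    return R


# ---------------------------------------------------------------------------
# mu calibration
# ---------------------------------------------------------------------------

def _mean_prob_given_log_scale(log_a: np.ndarray, beta: float) -> np.ndarray:
    """Angle-averaged S1 connection probability for characteristic scales
    a = mu*kappa_i*kappa_j given as log(a).

    The separation of two uniform angles is uniform on [0, pi], so
    E[p | a] = (1/pi) int_0^pi (1 + (t/a)^beta)^-1 dt
             = 2F1(1, 1/beta; 1 + 1/beta; -(pi/a)^beta).
    Evaluated on a log(a) grid (the hypergeometric call is the expensive
    part) and interpolated; far in the a << pi tail the integral reduces to
    a / (beta sin(pi/beta)).
    """
    from scipy.special import hyp2f1

    lo, hi = float(log_a.min()), float(log_a.max())
    if hi - lo < 1e-12:
        grid = np.array([lo, lo + 1.0])
    else:
        grid = np.linspace(lo, hi, 800)
    log_z = beta * (math.log(math.pi) - grid)
    f = np.empty_like(grid)
    small = log_z > 27.0  # z huge: asymptotic tail, avoids hyp2f1 overflow
    f[small] = np.exp(grid[small]) / (beta * math.sin(math.pi / beta))
    f[~small] = hyp2f1(1.0, 1.0 / beta, 1.0 + 1.0 / beta, -np.exp(log_z[~small]))
    f = np.clip(f, 1e-300, 1.0)
    return np.exp(np.interp(log_a, grid, np.log(f)))


def expected_mean_degree(
    kappas: np.ndarray,
    mu: float,
    beta: float,
    max_pairs: int = 8_000_000,
    seed: int = 987_654,
) -> float:
    """Expected mean degree of the S1 model for a given hidden-degree list.

    Angles are integrated out exactly (uniform angles make the pair
    separation uniform on [0, pi]); the pair expectation enumerates every
    i < j pair, falling back to ``max_pairs`` sampled pairs (fixed seed)
    for very large networks.
    """
    kappas = np.asarray(kappas, dtype=float)
    N = kappas.size
    logk = np.log(kappas)
    if N * (N - 1) // 2 <= max_pairs:
        iu, ju = np.triu_indices(N, k=1)
        log_kk = logk[iu] + logk[ju]
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, N, size=max_pairs)
        j = rng.integers(0, N - 1, size=max_pairs)
        j = np.where(j >= i, j + 1, j)
        log_kk = logk[i] + logk[j]
    mean_p = _mean_prob_given_log_scale(math.log(mu) + log_kk, beta).mean()
    return float((N - 1) * mean_p)


def calibrate_mu(
    kappas: Sequence[float],
    beta: float,
    target_mean_degree: float,
    tol: float = 0.005,
    max_steps: int = 60,
) -> float:
    """Find mu so the model's expected mean degree hits the target within
    ``tol`` (default 0.5%).

    Starts from the analytic homogeneous large-N seed
    mu0 = beta sin(pi/beta) / (2 pi <kappa>) and refines by bisection on
    the semi-analytic expected mean degree (deterministic).
    """
    kappas = np.asarray(kappas, dtype=float)
    N = kappas.size
    if not beta > 1:
        raise ValueError("beta must exceed 1")
    if not 0 < target_mean_degree < N - 1:
        raise ValueError(f"target mean degree {target_mean_degree} infeasible for N={N}")
    mu0 = beta * math.sin(math.pi / beta) / (2.0 * math.pi * kappas.mean())

    def realized(mu: float) -> float:
        return expected_mean_degree(kappas, mu, beta)

    # bracket the target (expected degree is increasing in mu)
    lo, hi = mu0, mu0
    k = realized(mu0)
    if abs(k - target_mean_degree) <= tol * target_mean_degree:
        return mu0
    for _ in range(max_steps):
        if k < target_mean_degree:
            hi *= 2.0
            k = realized(hi)
            if k >= target_mean_degree:
                lo = hi / 2.0
                break
        else:
            lo /= 2.0
            k = realized(lo)
            if k <= target_mean_degree:
                hi = lo * 2.0
                break
    else:
        raise RuntimeError("calibrate_mu: failed to bracket the target mean degree")

    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        k = realized(mid)
        if abs(k - target_mean_degree) <= tol * target_mean_degree:
            return mid
        if k < target_mean_degree:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"calibrate_mu: no convergence after {max_steps} bisection steps")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def log_likelihood(connectome: Connectome, hmap: HyperbolicMap) -> float:
    """Bernoulli log-likelihood of the topology under the H2 law.

    sum_{i<j} [a_ij ln p_ij + (1 - a_ij) ln(1 - p_ij)] with p_ij evaluated on
    exact hyperbolic distances and clamped away from {0, 1} before the logs.
    """
    missing = [n for n in connectome.node_ids if n not in hmap.coordinates]
    if missing:
        raise ValueError(f"map lacks coordinates for node(s): {missing[:5]}")
    ids = connectome.node_ids
    index = {n: i for i, n in enumerate(ids)}
    r, theta = hmap.arrays(ids)
    x = hyperbolic_distance_matrix(r, theta)
    p = connection_prob_h2(x, hmap.R, hmap.beta)
    p = np.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    A = np.zeros((len(ids), len(ids)), dtype=bool)
    for u, v in connectome.edges:
        A[index[u], index[v]] = True
        A[index[v], index[u]] = True
    iu = np.triu_indices(len(ids), k=1)
    a = A[iu]
    pv = p[iu]
    return float(np.sum(np.where(a, np.log(pv), np.log1p(-pv))))
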