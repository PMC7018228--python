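"""Distance and angle primitives for the Euclidean and hyperbolic metrics.

Two geometries are used throughout the package: the native 3D Euclidean
embedding of a spatial network (anatomical positions), and the 2D hyperbolic
disk in which effective network maps live.  Points in the disk are polar
pairs (r, theta); the geodesic length between two such points follows the
hyperbolic law of cosines,

    x = arccosh(cosh r1 cosh r2 - sinh r1 sinh r2 cos dtheta),

with dtheta the minimal angular separation.  For well separated angles and
large radii the geodesic is accurately approximated by
x ~ r1 + r2 + 2 ln(dtheta / 2).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "PolarPoint",
    "angular_separation",
    "euclidean_distance",
    "hyperbolic_distance",
    "hyperbolic_distance_approx",
    "hyperbolic_distance_matrix",
    "euclidean_distance_matrix",
    "circular_correlation",
    "EuclideanMetric",
    "HyperbolicMetric",
]


def wrap_angle(theta: float) -> float:
    """Wrap an angle into [0, 2*pi)."""
    return float(np.mod(theta, TWO_PI))


@dataclasses.dataclass(frozen=True)
class PolarPoint:
    """A point of the hyperbolic disk: radius ``r`` >= 0, angle in [0, 2*pi)."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r) and math.isfinite(self.theta)):
            raise ValueError("polar coordinates must be finite")
        if self.r < 0:
            raise ValueError(f"radial coordinate must be non-negative, got {self.r}")
        object.__setattr__(self, "r", float(self.r))
        object.__setattr__(self, "theta", wrap_angle(self.theta))


def angular_separation(theta1, theta2):
    """Minimal angular separation between two angles, in [0, pi].

    Accepts scalars or arrays; angles are wrapped internally, so the result
    is invariant under adding multiples of 2*pi to either argument.
    """
    t1 = np.asarray(theta1, dtype=float)
    t2 = np.asarray(theta2, dtype=float)
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise ValueError("angles must be finite")
    d = np.mod(np.abs(t1 - t2), TWO_PI)
    out = np.pi - np.abs(np.pi - d)
    return float(out) if out.ndim == 0 else out


def euclidean_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Straight-line distance between two points of equal dimension."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))


def hyperbolic_distance(a: PolarPoint, b: PolarPoint) -> float:
    """Exact geodesic length in the hyperbolic disk (law of cosines).

    The arccosh argument is clamped to [1, inf) to absorb floating-point
    round-off for nearly coincident points.
    """
    dtheta = angular_separation(a.theta, b.theta)
    if dtheta == 0.0:
        return abs(a.r - b.r)  # radial geodesic, exact (0 for identical points)
    arg = math.cosh(a.r) * math.cosh(b.r) - math.sinh(a.r) * math.sinh(b.r) * math.cos(dtheta)
    return float(np.arccosh(max(arg, 1.0)))


def hyperbolic_distance_approx(a: PolarPoint, b: PolarPoint) -> float:
    """Approximate geodesic length r1 + r2 + 2 ln(dtheta/2).

    Undefined at dtheta == 0; callers must fall back to the exact form there.
    Accurate to better than 1% once dtheta >~ 10 * exp(-min(r1, r2)).
    """
    dtheta = angular_separation(a.theta, b.theta)
    if dtheta <= 0.0:
        raise ValueError("approximation undefined at zero angular separation; use hyperbolic_distance")
    return a.r + b.r + 2.0 * math.log(dtheta / 2.0)


def hyperbolic_distance_matrix(r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Pairwise exact hyperbolic distances for radius/angle arrays."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    dtheta = np.pi - np.abs(np.pi - np.mod(np.abs(theta[:, None] - theta[None, :]), TWO_PI))
    ch, sh = np.cosh(r), np.sinh(r)
    arg = ch[:, None] * ch[None, :] - sh[:, None] * sh[None, :] * np.cos(dtheta)
    np.maximum(arg, 1.0, out=arg)
    x = np.arccosh(arg)
    np.fill_diagonal(x, 0.0)
    return x


def euclidean_distance_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances for an (n, d) coordinate array."""
    X = np.asarray(coords, dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def circular_correlation(alpha, beta) -> float:
    """Circular correlation coefficient between two angle samples.

    The Fisher–Lee/Jammalamadaka statistic
    sum sin(a - abar) sin(b - bbar) / sqrt(sum sin^2 * sum sin^2),
    with abar, bbar the circular means.  Invariant under global rotation of
    either sample; changes sign under reflection.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    abar = math.atan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = math.atan2(np.sin(b).sum(), np.cos(b).sum())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = math.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0.0:
        return 0.0
    return float((sa * sb).sum() / denom)


class EuclideanMetric:
    """Distance oracle over node ids backed by Euclidean positions."""

    def __init__(self, positions: Mapping[str, Sequence[float]]):
        self._pos = {k: np.asarray(v, dtype=float) for k, v in positions.items()}

    def __call__(self, u: str, v: str) -> float:
        return euclidean_distance(self._pos[u], self._pos[v])

    def matrix(self, node_ids: Sequence[str]) -> np.ndarray:
        X = np.stack([self._pos[n] for n in node_ids])
        return euclidean_distance_matrix(X)


class HyperbolicMetric:
    """Distance oracle over node ids backed by hyperbolic polar coordinates."""

    def __init__(self, coordinates: Mapping[str, PolarPoint]):
        self._coords = dict(coordinates)

    def __call__(self, u: str, v: str) -> float:
        return hyperbolic_distance(self._coords[u], self._coords[v])

    def matrix(self, node_ids: Sequence[str]) -> np.ndarray:
        r = np.array([self._coords[n].r for n in node_ids])
        theta = np.array([self._coords[n].theta for n in node_ids])
        return hyperbolic_distance_matrix(r, theta)
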