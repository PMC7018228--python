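"""Synthetic connectome generators with known ground truth.

Two families are produced:

* S1-model networks — nodes on a circle with heterogeneous (Pareto) hidden
  degrees, linked by the S1 connection law.  These play the role of
  connectomes whose effective geometry is known exactly, so embedding and
  cartography can be validated against planted coordinates.
* 3D spatial networks — nodes uniform in a box, linked with a probability
  that decays with Euclidean distance.  An optional hard cutoff removes
  links beyond a maximum length, emulating partial-volume reconstructions
  that miss long-range connections.

All randomness flows through one seeded generator per call; there is no
global random state.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .geometry import TWO_PI
from .io import Connectome, canonical_edge
from .model import S1Parameters, calibrate_mu, connection_prob_s1

__all__ = [
    "S1GeneratorConfig",
    "EuclideanGeneratorConfig",
    "sample_hidden_degrees",
    "generate_s1_network",
    "generate_euclidean_connectome",
]


@dataclasses.dataclass
class S1GeneratorConfig:
    """Study conditions for an S1-model network.

    ``planted_clusters`` is a list of (arc center, arc width, node count)
    triples; those nodes receive angles uniform within their arc and an
    annotation recording the arc they came from, the remainder are uniform
    on the circle.  When ``kappa0`` is omitted it is set so that the Pareto
    mean of the hidden degrees equals ``mean_degree``.
    """

    N: int
    gamma: float = 2.7
    kappa0: Optional[float] = None
    beta: float = 2.5
    mean_degree: float = 10.0
    planted_clusters: Optional[Sequence[tuple[float, float, int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.gamma <= 2:
            raise ValueError("gamma must exceed 2 (finite-mean hidden degrees)")
        if not self.beta > 1:
            raise ValueError("beta must exceed 1")
        if self.planted_clusters is not None:
            if any(w >= TWO_PI for _, w, _ in self.planted_clusters):
                raise ValueError("planted arc widths must be < 2*pi")
            if sum(m for _, _, m in self.planted_clusters) > self.N:
                raise ValueError("planted clusters exceed N nodes")

    @property
    def effective_kappa0(self) -> float:
        if self.kappa0 is not None:
            return self.kappa0
        # Pareto mean kappa0*(gamma-1)/(gamma-2) matched to the degree target
        return self.mean_degree * (self.gamma - 2.0) / (self.gamma - 1.0)


@dataclasses.dataclass
class EuclideanGeneratorConfig:
    """Study conditions for a 3D spatial network.

    Links form with probability 1/(1 + (d/lambda)^beta_e) (or exp(-d/lambda)
    when ``decay='exponential'``).  ``max_link_length`` removes longer links
    outright.
    """

    N: int
    box: tuple[float, float, float] = (100.0, 100.0, 100.0)
    decay_scale: float = 10.0
    beta_e: float = 3.0
    decay: str = "powerlaw"
    max_link_length: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if any(s <= 0 for s in self.box) or self.decay_scale <= 0:
            raise ValueError("box sides and decay scale must be positive")
        if self.beta_e < 0:
            raise ValueError("beta_e must be non-negative")
        if self.decay not in ("powerlaw", "exponential"):
            raise ValueError(f"unknown decay law {self.decay!r}")
        if self.max_link_length is not None and self.max_link_length <= 0:
            raise ValueError("max_link_length must be positive")


def _node_ids(N: int) -> list[str]:
    width = len(str(N - 1))
    return [f"n{i:0{width}d}" for i in range(N)]


def sample_hidden_degrees(config: S1GeneratorConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw N hidden degrees from a Pareto density ~ kappa^(-gamma), kappa >= kappa0."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u = rng.random(config.N)
    return config.effective_kappa0 * (1.0 - u) ** (-1.0 / (config.gamma - 1.0))


def _sample_angles(config: S1GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Angles plus the planted-arc label of every node ('bg' for background)."""
    thetas = np.empty(config.N)
    labels = ["bg"] * config.N
    pos = 0
    if config.planted_clusters:
        for k, (center, width, count) in enumerate(config.planted_clusters):
            thetas[pos:pos + count] = rng.uniform(center - width / 2.0, center + width / 2.0, size=count)
            for i in range(pos, pos + count):
                labels[i] = f"arc{k}"
            pos += count
    thetas[pos:] = rng.uniform(0.0, TWO_PI, size=config.N - pos)
    return np.mod(thetas, TWO_PI), labels


def generate_s1_network(config: S1GeneratorConfig) -> tuple[Connectome, S1Parameters]:
    """Sample an S1-model network together with its full ground truth.

    Hidden degrees are Pareto, angles uniform (or planted arcs), mu is
    calibrated so the expected mean degree matches the configured target,
    and every pair is linked independently with the S1 law.  Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    kappas = sample_hidden_degrees(config, rng)
    thetas, labels = _sample_angles(config, rng)
    mu = calibrate_mu(kappas, config.beta, config.mean_degree)

    ids = _node_ids(config.N)
    dtheta = np.pi - np.abs(np.pi - np.mod(np.abs(thetas[:, None] - thetas[None, :]), TWO_PI))
    p = connection_prob_s1(dtheta, kappas[:, None], kappas[None, :], mu, config.beta)
    iu, ju = np.triu_indices(config.N, k=1)
    link = rng.random(iu.size) < p[iu, ju]
    edges = {(ids[a], ids[b]) for a, b in zip(iu[link], ju[link])}

    annotations = None
    if config.planted_clusters:
        annotations = {ids[i]: {"planted": labels[i]} for i in range(config.N)}
    connectome = Connectome(node_ids=ids, edges=edges, annotations=annotations)
    truth = S1Parameters(
        kappas=dict(zip(ids, kappas.tolist())),
        thetas=dict(zip(ids, thetas.tolist())),
        mu=mu,
        beta=config.beta,
        N=config.N,
    )
    return connectome, truth


def generate_euclidean_connectome(config: EuclideanGeneratorConfig) -> Connectome:
    """Sample a spatial network with distance-decaying connectivity."""
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box, dtype=float)
    X = rng.random((config.N, 3)) * box
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if config.decay == "powerlaw":
        with np.errstate(divide="ignore"):
            ratio = d / config.decay_scale
            logratio = np.log(np.where(ratio > 0, ratio, 1.0))
            p = np.exp(-np.logaddexp(0.0, config.beta_e * logratio))
            p[ratio == 0] = 1.0 if config.beta_e > 0 else 0.5
    else:
        p = np.exp(-d / config.decay_scale)
    iu, ju = np.triu_indices(config.N, k=1)
    link = rng.random(iu.size) < p[iu, ju]
    if config.max_link_length is not None:
        link &= d[iu, ju] <= config.max_link_length
    ids = _node_ids(config.N)
    edges = {(ids[a], ids[b]) for a, b in zip(iu[link], ju[link])}
    positions = {ids[i]: X[i] for i in range(config.N)}
    return Connectome(node_ids=ids, edges=edges, positions=positions)
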