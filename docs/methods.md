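# Methods

This note records the models, conventions, numerical choices and known
limitations behind `navmaps`, at the level of detail a maintainer or a
careful user needs. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Greedy routing

The protocol: the current node forwards the signal to its neighbor
(out-neighbor, when routing a directed network) with the smallest metric
distance to the target. Three conventions pin the implementation down:

* **Failure = first revisit.** With a deterministic next-hop rule,
  entering any previously visited node guarantees an infinite loop, so
  the walk stops as a failure at the earliest possible moment. A hop cap
  of N is kept as a backstop only; it is unreachable in practice because
  a walk of N hops must revisit.
* **Ties** in neighbor distance are broken by the lexicographically
  smallest node id, making every run bit-reproducible.
* **The current node always forwards**, even when it is itself closer to
  the target than all of its neighbors; the revisit rule then catches the
  failure one step later. This matters for degenerate layouts where a
  node sits inside a "metric dead end".

Success-rate denominators count all ordered source≠target pairs within
undirected connected components; cross-component pairs are excluded from
numerator and denominator because they cannot succeed by definition.

Topological stretch divides greedy hops by the BFS shortest-path length.
Geometric stretch divides the greedy path's metric length by the metric
length of a *hop-minimal* path; when several hop-minimal paths exist, the
one of minimal metric length is used, computed by a layered relaxation
over the BFS level graph (each node's minimal geometric length is the
minimum over its predecessors one BFS level up). This makes the
denominator deterministic and conservative. Geometric stretch can drop
below 1 — a greedy walk of many short hops can be metrically shorter
than a two-hop path through a distant relay — and the test suite
constructs such an instance explicitly.

The per-pair greedy walks run on integer index arrays against a
precomputed N×N distance matrix, so a full navigability sweep of an
N = 300 network (≈ 90 000 ordered pairs) takes about a second.

## The S1/H2 model and its conventions

Connection laws:

* H2: `p(x) = 1 / (1 + exp(β/2 (x − R)))` on exact hyperbolic geodesics
  `x = arccosh(cosh r1 cosh r2 − sinh r1 sinh r2 cos Δθ)`.
* S1: `p = 1 / (1 + (Δθ/(μ κ_i κ_j))^β)`, with Δθ the minimal angular
  separation used directly (not an arc length; scale constants are
  absorbed into μ).

The hidden degree is related to the radius only up to a constant
(κ ∝ e^{(R−r)/2}); we fix it by placing the minimum hidden degree κ0 on
the disk boundary, r = R − 2 ln(κ/κ0). Under the approximate geodesic
x ≈ r1 + r2 + 2 ln(Δθ/2) the two laws then coincide exactly iff

    R = 2 ln(2 / (μ κ0²)),

which is the disk radius used throughout; the identity is verified to
10⁻⁹ relative error over 10⁴ random configurations in the acceptance
suite (and holds to ~10⁻¹⁵ in practice). Hidden degrees larger than
κ0·e^{R/2} would map to negative radii; they are clamped to the disk
center r = 0. Routing and likelihood ranking are insensitive to a global
additive shift of r, so a different normalization convention would change
none of the reported statistics.

**Validity of the approximate geodesic.** The approximation replaces
ln(sin(Δθ/2)) by ln(Δθ/2); its absolute error 2 ln((Δθ/2)/sin(Δθ/2))
grows with Δθ and does not vanish with radius. It is accurate to < 1% of
x for Δθ between ~10·e^{−min(r1,r2)} and ~1.2 rad at the radii typical of
sparse maps; near antipodal separations the error reaches a few percent.
For this reason the approximation is used *only* to state the S1↔H2
equivalence; routing and likelihoods always use the exact law of
cosines, with the arccosh argument clamped to [1, ∞) to absorb round-off
at nearly coincident points (and an exact early return |r1 − r2| at
Δθ = 0).

**μ calibration.** Given a hidden-degree list, a target mean degree and
β, μ is found by bisection on the model's expected mean degree. For
uniform angles the pair separation is uniform on [0, π], so the
angle-averaged connection probability has the closed form
₂F₁(1, 1/β; 1 + 1/β; −(π/a)^β) with a = μκ_iκ_j; it is evaluated on an
800-point log(a) grid (with the asymptotic tail a/(β sin(π/β)) where the
hypergeometric argument would overflow) and interpolated over all κκ'
pairs, enumerated exactly up to 8·10⁶ pairs and subsampled with a fixed
seed beyond. Bisection starts from the homogeneous large-N seed
μ0 = β sin(π/β)/(2π⟨κ⟩) and stops within 0.5% of the target. A
Monte-Carlo pair average was tried first and rejected: at feasible
sample counts the heavy-tailed κ products leave ~2% noise on the
expected degree, which is the same order as the calibration tolerance
itself. Note the scaling directions: with a *fixed* κ list the expected
degree is linear in μ (doubling the target doubles μ); μ is inversely
proportional to the target only when the κ's are rescaled alongside it
(the ⟨κ⟩ = ⟨k⟩ convention of the analytic seed).

The log-likelihood clamps probabilities to [10⁻¹⁵, 1 − 10⁻¹⁵] before
taking logs; it is invariant under global rotation and reflection of the
angles, which is why all quality metrics used in tests are
alignment-invariant.

## Synthetic generators (study conditions)

The S1 generator draws hidden degrees from a Pareto density ∝ κ^(−γ) for
κ ≥ κ0 (broad but integrable, matching the "heavy-tailed but not pure
power law" character of real degree sequences), angles uniform on the
circle or inside planted arcs, calibrates μ as above, and links every
pair independently. Defaults are N = 2000 at γ = 2.7, β = 2.5,
⟨k⟩ = 10 for calibration checks and N = 300 at β = 3 for the
embedding/routing demo — small enough to run in seconds-to-minutes on
one CPU, large enough that SRs and correlations are stable to a few
percent across seeds. When κ0 is not given it is set to
⟨k⟩(γ−2)/(γ−1), making the Pareto mean equal the degree target.

The Euclidean generator places N points uniformly in a 3D box and links
pairs with probability 1/(1 + (d/λ)^{β_e}) (an exponential-decay variant
is selectable). β_e = 0 is the exactly flat law p = 1/2 at all
distances; large λ at β_e > 0 flattens the curve toward p = 1. The
optional `max_link_length` removes all longer links outright, emulating
partial-volume reconstructions that cannot see long-range connections —
the acceptance script shows this cut lowers Euclidean SR substantially
(≈ 0.48 → ≈ 0.21 at the default demo conditions).

All generator randomness flows through one `numpy` Generator seeded per
call; there is no global random state anywhere in the package.

What the generators deliberately do not reproduce: spatial inhomogeneity
of real neuron placement, hemispheric symmetry, directedness, weighted
fiber densities, and degree–distance correlations beyond what the
connection laws imply. Tests passing on these synthetics therefore
certify the *methods* (protocol, inference, statistics), not any claim
about a particular species' connectome.

## Likelihood embedding

`embed_h2` fixes the radial coordinates from observed degrees
(κ_i = max(k_i, 1), μ calibrated to the observed mean degree, r from the
κ↔r map) and searches only the angles, the dominant unknowns. The search
is Metropolis–Hastings on the Bernoulli log-likelihood: per sweep, every
node in random order proposes either a local Gaussian move
(σ = 2π/√N by default, the angular scale of √N neighbors) or, with
probability 0.1, a global uniform move; acceptance is min(1, e^{ΔlogL}).
A proposal's ΔlogL touches only the proposing node's row, an O(N) vector
operation, so a sweep is O(N²). A run stops after 100 sweeps without a
gain above 10⁻⁴·N, capped at 3000 sweeps; the best angles across
restarts are returned, so the winning restart's final likelihood never
falls below its initial one.

**Initialization.** The first restart starts from a spectral guess —
θ = atan2(v₃, v₂) with v₂, v₃ the leading non-trivial eigenvectors of
the degree-normalized adjacency matrix — and the remaining restarts start
uniformly at random (`init="random"` makes all restarts random). This is
the one place the implementation departs from a pure random-restart
design: local angle moves are poor at untangling a random circular
ordering, and on the N = 300 demo the purely random init plateaus around
angular correlation ≈ 0.3 and SR ≈ 0.85, while the spectral start reaches
correlation 0.8–0.96 and SR 0.95–1.0 in the same budget.

`infer_beta` estimates the inverse temperature by bisection on
β ∈ (1.01, 10]: at each trial β it builds 5 S1 surrogates with κ set to
the observed degrees, uniform angles and calibrated μ, and compares their
mean local clustering coefficient with the observed one (tolerance
±0.01). Clustering is monotone in β, but the surrogate average is noisy,
so estimates carry an uncertainty of roughly ±0.5 around β = 3 at
N = 1000; an observed clustering outside the reachable range returns the
boundary with a warning (a tree, for instance, has nothing to match).

**Recovery metric.** Angular recovery is scored by the Pearson
correlation between planted and inferred pairwise angular separations.
Pairwise separations are exactly invariant under global rotations and
reflections, so no alignment step is needed. The Fisher–Lee circular
correlation coefficient (provided as `geometry.circular_correlation`) was
rejected as the headline metric: it weights deviations from circular
means and can *decrease* while the likelihood, the routing SR and the
pairwise congruence all improve.

## Null models

All three preserve N and L exactly. Position swap permutes the
node→coordinate assignment (works on 3D positions and on hyperbolic
maps). The rewiring models run double-edge swaps — two random distinct
edges, re-pairing orientation chosen uniformly, rejected if fewer than 4
distinct nodes or if a duplicate edge would arise — until 100·L
successful swaps, with an attempt budget of 100 attempts per requested
swap so swap-poor graphs (triangles, cliques) terminate with a logged
warning instead of hanging.

The cost-preserving variant bounds **each individual swap**:
|Δ| < ε·D with ε = 1/60 and D the total edge length of the *input*
network, computed once (each undirected edge counted once) and never
recomputed. Cumulative drift is therefore bounded only by
(accepted swaps)·ε·D; the binding contract, enforced in tests, is the
per-swap audit of the full swap log. On hyperbolic maps of sparse
networks the per-swap tolerance ε·D is rarely binding (edge lengths are
narrowly distributed around R), so the cost-preserving and
degree-preserving baselines can coincide there; the constraint bites on
Euclidean layouts with broad edge-length distributions.

## Cartography

* **Critical gap communities**: nodes sorted by angle; every consecutive
  gap (wraparound included) strictly greater than g_c splits communities.
  The default g_c = (2π/N)·ln N is the asymptotic expected largest gap of
  N uniform angles, so uniformly spread nodes typically form a single
  community; g_c is a parameter and can be replaced. Output is rotation
  invariant up to labels.
* **NMI**: 2I/(H1+H2) from the joint contingency table with natural
  logs; `max` and `sqrt` normalizations are selectable and all three are
  cross-checked against scikit-learn in the tests. Two identical
  single-cluster partitions score 1; if exactly one side has zero
  entropy the score is 0.
* **Angular localization**: observed statistic = mean pairwise angular
  separation within the cluster; null = the same statistic for 10 000
  uniformly random subsets of the same size drawn from *all* map nodes
  (cluster members included — excluding them would bias the null for
  large clusters). The p-value is the plain empirical fraction of null
  samples ≤ observed, with a 10⁻⁹ tie tolerance so the degenerate
  full-set cluster reports p = 1 exactly; no (k+1)/(n+1) smoothing, so
  p = 0 is reportable and means "smaller than anything seen in 10⁴
  samples".
* **Angular span**: 2π minus the largest gap among the cluster's sorted
  angles, as a fraction of 2π; a singleton spans 0.
* **Connection-probability curves**: all unordered pairs binned by
  metric distance into equal-width bins over the observed range; empty
  bins report count 0 and NaN fraction. Model-vs-empirical comparisons in
  the tests bin in log of the rescaled separation and compare per-bin
  connected counts with the summed model probabilities within 3 binomial
  standard deviations.

## Pipeline

`run_pipeline` sequences: load-or-generate → Euclidean routing → embed →
hyperbolic routing → null-model baselines (mean ± sd of SR over
replicates, randomizing whichever geometry drives routing) → cartography,
writing every artifact plus a consolidated `study_report.json` whose
content is byte-reproducible from (config, seed); timestamps are
deliberately omitted. Disconnected inputs are reduced to their giant
component (logged) before embedding, since `embed_h2` itself rejects
disconnected graphs rather than embedding a component silently.

## Problem sizes and limitations

Default analysis sizes (N = 300 demo, N = 1000 for β round trips,
N = 2000 for calibration; 10 000 localization samples) were chosen so the
full suite and the acceptance script each complete in a few minutes on a
single CPU while keeping the statistics stable across seeds.

Known limitations: β ≤ 1 (the clustering-free regime) is out of scope;
radii are never jointly sampled with angles, so embeddings of networks
whose hidden degrees deviate strongly from observed degrees will be
biased; the MH search is a reconstruction validated by parameter
recovery, not a reference implementation; and the localization null
assumes exchangeable nodes, so strongly non-uniform angular density
inflates its significance for clusters placed in dense sectors.
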