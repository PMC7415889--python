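"""Ground-truth synthetic tissue and solver test instances.

Emulates the structure of multiplexed-imaging datasets: anchors scattered
in a unit square, a spatially coherent topic-proportion field θ(x) with
smooth boundary transitions, topics over a phenotype vocabulary, and short
documents (tens of cells per neighborhood).  Also provides seeded random
fusion instances together with an independent long-run projected-
subgradient oracle solution for cross-checking the interior-point solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurization import (
    CellTable,
    NeighborhoodCorpus,
    SpatialGraph,
    build_spatial_graph,
)

__all__ = [
    "SyntheticTissueTruth",
    "generate_synthetic_tissue",
    "generate_fusion_instance",
    "fusion_oracle",
]


@dataclass
class SyntheticTissueTruth:
    """Ground truth behind a synthetic tissue draw."""

    true_topics: np.ndarray       # (K, V) simplex rows
    true_theta_field: np.ndarray  # (N, K) simplex rows, smooth in space
    positions: np.ndarray         # (N, 2)
    seed: int
    field_type: str
    bandwidth: float

    def __post_init__(self) -> None:
        for name, arr in (("true_topics", self.true_topics),
                          ("true_theta_field", self.true_theta_field)):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"{name} rows must sum to 1")

    @property
    def dominant_topic(self) -> np.ndarray:
        return self.true_theta_field.argmax(axis=1)


def _separated_centers(K, rng, min_separation=0.35, max_tries=500):
    """Region centers with a minimum pairwise distance.

    Identifiability guard: without a separation floor, two regions can sit
    so close that their boundary blend covers most of the tissue and the
    dominant-topic label is undefined for a large fraction of anchors —
    ground truth that no method (including one given the true parameters)
    could recover.
    """
    best, best_sep = None, -np.inf
    for _ in range(max_tries):
        cand = rng.uniform(0.15, 0.85, size=(K, 2))
        d = np.linalg.norm(cand[:, None] - cand[None, :], axis=2)
        sep = d[np.triu_indices(K, 1)].min() if K > 1 else np.inf
        if sep >= min_separation:
            return cand
        if sep > best_sep:
            best, best_sep = cand, sep
    return best


def _theta_field(positions, centers, field_type, bandwidth, island_radius=0.18):
    """Simplex field θ(x) from distance-to-region logistic blends."""
    d = np.linalg.norm(positions[:, None, :] - centers[None, :, :], axis=2)
    if field_type == "blocks":
        if bandwidth == 0:
            theta = np.zeros_like(d)
            theta[np.arange(len(d)), d.argmin(axis=1)] = 1.0
            return theta
        scores = -d / bandwidth
    elif field_type == "smooth-gradient":
        scores = -d / max(bandwidth, 1e-12)
    elif field_type == "islands":
        # topic 0 is background; others live on logistic discs around centers
        scores = np.empty_like(d)
        scores[:, 0] = 0.0
        h = max(bandwidth, 1e-12)
        scores[:, 1:] = (island_radius - d[:, 1:]) / h
    else:
        raise ValueError(f"unknown field_type {field_type!r}")
    scores -= scores.max(axis=1, keepdims=True)
    theta = np.exp(scores)
    theta /= theta.sum(axis=1, keepdims=True)
    return theta


def generate_synthetic_tissue(
    n_cells: int = 2000,
    n_topics: int = 3,
    n_phenotypes: int = 12,
    field_type: str = "smooth-gradient",
    counts_per_doc: float = 20.0,
    noise: float = 0.0,
    seed: int = 0,
    bandwidth: float = 0.05,
    topic_concentration: float = 0.3,
    neighborhood_radius: float = 0.02,
    center_separation: float = 0.35,
):
    """Draw a synthetic tissue with known microenvironment structure.

    ``n_cells`` anchors are placed uniformly in the unit square; the true
    topic-proportion field θ(x) is a logistic blend over ``n_topics``
    spatial regions (``bandwidth`` controls boundary smoothness); topics
    are Dirichlet(``topic_concentration``) rows over ``n_phenotypes``
    phenotypes; each document draws Poisson(``counts_per_doc``) cells from
    the mixture θ_i·β.  ``noise`` mixes each θ_i with an independent flat
    Dirichlet draw.  Returns (cells, corpus, graph, truth), all
    reproducible from ``seed``.
    """
    K, V = int(n_topics), int(n_phenotypes)
    if K < 2 or V < K:
        raise ValueError("need n_topics >= 2 and n_phenotypes >= n_topics")
    if not (0 <= noise <= 1):
        raise ValueError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=(int(n_cells), 2))
    centers = _separated_centers(K, rng, min_separation=center_separation)
    theta = _theta_field(positions, centers, field_type, bandwidth)
    if noise > 0:
        theta = (1 - noise) * theta + noise * rng.dirichlet(np.ones(K), size=len(theta))
    topics = rng.dirichlet(np.full(V, topic_concentration), size=K)

    lengths = rng.poisson(counts_per_doc, size=len(theta))
    mix = theta @ topics                         # (N, V) per-document phenotype law
    counts = np.zeros((len(theta), V), dtype=np.int64)
    for i, n_i in enumerate(lengths):
        if n_i > 0:
            counts[i] = rng.multinomial(n_i, mix[i])

    vocabulary = [f"phenotype_{v:02d}" for v in range(V)]
    anchor_ids = [f"anchor_{i:05d}" for i in range(len(theta))]
    index = pd.DataFrame({"sample_id": "synthetic", "cell_id": anchor_ids})
    corpus = NeighborhoodCorpus(counts, index, positions.copy(),
                                float(neighborhood_radius), vocabulary)
    graph = build_spatial_graph(positions, np.full(len(theta), "synthetic"),
                                weight_rule="constant")
    truth = SyntheticTissueTruth(topics, theta, positions.copy(), int(seed),
                                 field_type, float(bandwidth))

    # Cell table consistent with the draw: anchors plus their neighbor cells
    # placed uniformly inside each anchor's ball (for end-to-end CLI runs;
    # the returned corpus is the exact generative draw).
    rows = [pd.DataFrame({
        "sample_id": "synthetic", "cell_id": anchor_ids,
        "x": positions[:, 0], "y": positions[:, 1],
        "phenotype": "anchor", "is_anchor": True,
    })]
    for i in range(len(theta)):
        n_i = counts[i].sum()
        if n_i == 0:
            continue
        radii = neighborhood_radius * np.sqrt(rng.uniform(size=n_i))
        angle = rng.uniform(0, 2 * np.pi, size=n_i)
        ph = np.repeat(np.arange(V), counts[i])
        rows.append(pd.DataFrame({
            "sample_id": "synthetic",
            "cell_id": [f"cell_{i:05d}_{j:03d}" for j in range(n_i)],
            "x": positions[i, 0] + radii * np.cos(angle),
            "y": positions[i, 1] + radii * np.sin(angle),
            "phenotype": [vocabulary[p] for p in ph],
            "is_anchor": False,
        }))
    cells = CellTable(pd.concat(rows, ignore_index=True))
    return cells, corpus, graph, truth


# ---------------------------------------------------------------------------
# Fusion solver instances with oracle solutions
# ---------------------------------------------------------------------------

def fusion_oracle(e, edges, weights, rho, n_iter=50_000, polish=True):
    """Independent solution of the fused-ℓ1 problem for cross-checking.

    Minimizes F(ξ) = ρ/2‖ξ − e‖² + Σ_l w_l ‖ξ_i − ξ_j‖₁ (χ eliminated)
    by long-run subgradient descent with the strongly-convex step schedule
    2/(ρ(t+2)), tracking the best iterate, then (optionally) refines the
    result with scipy's trust-region constrained solver on the smooth
    epigraph reformulation (min ρ/2‖ξ−e‖² + wᵀχ s.t. ±(ξ_i−ξ_j) ≤ χ_l).
    Both routes are deliberately independent of the interior-point path;
    the best objective of the two is returned.

    Returns (xi_best, objective_best, certificate); the certificate is the
    relative objective improvement over the final 10% of subgradient
    iterations (≈0 when that phase has converged).
    """
    from scipy.optimize import LinearConstraint, minimize

    e = np.atleast_2d(np.asarray(e, dtype=float))
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    N, K = e.shape
    L = len(edges)

    def objective(x):
        pen = 0.0
        if L:
            pen = float(np.sum(weights[:, None]
                               * np.abs(x[edges[:, 0]] - x[edges[:, 1]])))
        return 0.5 * rho * float(((x - e) ** 2).sum()) + pen

    xi = e.copy()
    best = xi.copy()
    f_best = objective(xi)
    checkpoint = f_best
    for t in range(n_iter):
        g = rho * (xi - e)
        if L:
            sgn = np.sign(xi[edges[:, 0]] - xi[edges[:, 1]])
            np.add.at(g, edges[:, 0], weights[:, None] * sgn)
            np.add.at(g, edges[:, 1], -weights[:, None] * sgn)
        xi -= (2.0 / (rho * (t + 2.0))) * g
        f = objective(xi)
        if f < f_best:
            f_best, best = f, xi.copy()
        if t == int(0.9 * n_iter):
            checkpoint = f_best
    certificate = (checkpoint - f_best) / max(abs(f_best), 1.0)

    if polish and L:
        # epigraph variables z = (vec ξ, vec χ); smooth QP for trust-constr
        import scipy.sparse as sp

        A_inc = sp.csr_matrix(
            (np.tile([1.0, -1.0], L),
             (np.repeat(np.arange(L), 2), edges.reshape(-1))),
            shape=(L, N),
        )
        Ak = sp.kron(A_inc, sp.identity(K), format="csr")
        Ik = sp.identity(L * K, format="csr")
        C = sp.bmat([[Ak, -Ik], [-Ak, -Ik]], format="csr")
        wvec = np.repeat(weights, K)
        ev = e.reshape(-1)

        def f(z):
            x, chi = z[: N * K], z[N * K:]
            return 0.5 * rho * float(((x - ev) ** 2).sum()) + float(wvec @ chi)

        def jac(z):
            return np.concatenate([rho * (z[: N * K] - ev), wvec])

        hess_mat = sp.block_diag(
            [rho * sp.identity(N * K), sp.csr_matrix((L * K, L * K))], format="csr"
        )

        chi0 = np.abs(Ak @ best.reshape(-1)) + 1e-3
        z0 = np.concatenate([best.reshape(-1), chi0])
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Singular Jacobian")
            warnings.filterwarnings("ignore", message="delta_grad")
            res = minimize(
                f, z0, jac=jac, hess=lambda z: hess_mat, method="trust-constr",
                constraints=[LinearConstraint(C, -np.inf, 0.0)],
                options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 500, "verbose": 0},
            )
        x_pol = res.x[: N * K].reshape(N, K)
        f_pol = objective(x_pol)
        if f_pol < f_best:
            f_best, best = f_pol, x_pol
    return best, f_best, certificate


def _random_connected_edges(N, L, rng):
    """Random connected graph: spanning tree plus extra distinct edges."""
    if N < 2:
        return np.zeros((0, 2), dtype=int)
    perm = rng.permutation(N)
    edges = set()
    for a in range(1, N):
        i, j = int(perm[rng.integers(a)]), int(perm[a])
        edges.add((min(i, j), max(i, j)))
    all_pairs = [(i, j) for i in range(N) for j in range(i + 1, N)]
    rng.shuffle(all_pairs)
    for pair in all_pairs:
        if len(edges) >= L:
            break
        edges.add(pair)
    return np.array(sorted(edges), dtype=int)


def generate_fusion_instance(N, K, L, rho=1.0, seed=0, oracle_iters=200_000):
    """Random fusion subproblem with an independent oracle solution.

    Returns (e, graph, oracle) where ``oracle`` is a dict with keys
    ``xi``, ``objective`` and ``certificate`` from :func:`fusion_oracle`.
    ``L`` is capped at N(N−1)/2; the edge set is connected.
    """
    if L > N * (N - 1) // 2:
        raise ValueError("L exceeds the number of distinct pairs")
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, 1.0, size=(N, K))
    edges = _random_connected_edges(N, min(L, N * (N - 1) // 2), rng)
    edges = edges[: max(L, N - 1)] if len(edges) else edges
    d = rng.uniform(0.5, 2.0, size=len(edges))
    graph = SpatialGraph(edges, d, n_nodes=N)
    w = 1.0 / d if len(d) else np.zeros(0)
    xi, obj, cert = fusion_oracle(e, edges, w, rho, n_iter=oracle_iters)
    return e, graph, {"xi": xi, "objective": obj, "certificate": cert}
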