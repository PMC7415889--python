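"""Independent reference implementations used only for cross-checking.

Every function here is written deliberately without reusing the package's
computational paths: brute-force enumeration, textbook series, scipy
general-purpose optimizers, dense linear algebra.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, minimize
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# Featurization oracles
# ---------------------------------------------------------------------------

def brute_force_counts(df, anchor_mask, neighbor_mask, radius, vocabulary):
    """Exhaustive pairwise-distance neighborhood counts (closed ball)."""
    coords = ["x", "y"] + (["z"] if "z" in df.columns and df["z"].notna().all() else [])
    pos = df[coords].to_numpy(float)
    phen = df["phenotype"].astype(str).to_numpy()
    sample = df["sample_id"].to_numpy()
    vidx = {v: k for k, v in enumerate(vocabulary)}
    rows = []
    for a in np.flatnonzero(anchor_mask):
        row = np.zeros(len(vocabulary), dtype=int)
        for b in np.flatnonzero(neighbor_mask):
            if b == a or sample[b] != sample[a]:
                continue
            if math.dist(pos[a], pos[b]) <= radius:
                row[vidx[phen[b]]] += 1
        rows.append(row)
    return np.array(rows, dtype=int)


def voronoi_adjacency_halfplane(points, pad=50.0, min_facet=1e-5):
    """2D Voronoi facet adjacency by explicit half-plane intersection.

    Each cell is the intersection of a large bounding box with the
    half-planes closer to its site than to every other site; two sites are
    adjacent when their cells share a boundary segment of positive length.
    Uses shapely polygon clipping, entirely independent of Delaunay codes.
    """
    from shapely.geometry import Polygon

    points = np.asarray(points, float)
    lo, hi = points.min() - pad, points.max() + pad
    box = Polygon([(lo, lo), (hi, lo), (hi, hi), (lo, hi)])
    n = len(points)
    cells = []
    for i in range(n):
        cell = box
        for j in range(n):
            if j == i:
                continue
            mid = (points[i] + points[j]) / 2
            d = points[j] - points[i]
            # half-plane {x : (x - mid)·d <= 0}; clip by a big polygon
            nrm = d / np.linalg.norm(d)
            t = np.array([-nrm[1], nrm[0]])
            big = 10 * (hi - lo)
            half = Polygon([
                tuple(mid + t * big), tuple(mid - t * big),
                tuple(mid - t * big - nrm * big), tuple(mid + t * big - nrm * big),
            ])
            cell = cell.intersection(half)
        cells.append(cell)
    # robust shared-facet test: a thin buffer around cell i overlaps cell j
    # over an area ≈ 2·eps·facet_length iff the cells share a facet
    eps = 1e-7
    edges = set()
    for i in range(n):
        grown = cells[i].buffer(eps)
        for j in range(i + 1, n):
            facet_len = grown.intersection(cells[j]).area / (2 * eps)
            if facet_len > min_facet:
                edges.add((i, j))
    return edges


# ---------------------------------------------------------------------------
# Inference oracles
# ---------------------------------------------------------------------------

def digamma_series(x, terms=8):
    """Ψ(x) via the recurrence Ψ(x) = Ψ(x+1) − 1/x and asymptotic series."""
    x = float(x)
    acc = 0.0
    while x < 10.0:
        acc -= 1.0 / x
        x += 1.0
    # Bernoulli-number asymptotic expansion
    bern = [1.0 / 12, -1.0 / 120, 1.0 / 252, -1.0 / 240, 1.0 / 132,
            -691.0 / 32760, 1.0 / 12, -3617.0 / 8160]
    s = math.log(x) - 0.5 / x
    x2 = x * x
    p = x2
    for b in bern[:terms]:
        s -= b / p
        p *= x2
    return acc + s


def lda_estep_reference(counts_i, xi_i, lam, n_iter=2000):
    """Plain-loop LDA document update run far past convergence."""
    from scipy.special import psi

    V = len(counts_i)
    K = len(xi_i)
    elog_beta = psi(lam) - psi(lam.sum(axis=1))[:, None]
    gamma = xi_i + counts_i.sum() / K
    phi = np.full((V, K), 1.0 / K)
    for _ in range(n_iter):
        elog_theta = psi(gamma) - psi(gamma.sum())
        for v in range(V):
            row = np.exp(elog_theta + elog_beta[:, v] - (elog_theta + elog_beta[:, v]).max())
            phi[v] = row / row.sum()
        gamma = xi_i + counts_i @ phi
    return phi, gamma


# ---------------------------------------------------------------------------
# Prior-field (xi) oracles
# ---------------------------------------------------------------------------

def xi_objective_reference(xi, c, edges, d, n_docs):
    """Independent evaluation of the prior-field objective with math.lgamma."""
    xi = np.atleast_2d(xi)
    total = 0.0
    for i in range(xi.shape[0]):
        total += math.lgamma(float(xi[i].sum()))
        for k in range(xi.shape[1]):
            total -= math.lgamma(float(xi[i, k]))
            total += float(xi[i, k] * c[i, k])
    total /= n_docs
    for (i, j), dij in zip(edges, d):
        total -= float(np.abs(xi[i] - xi[j]).sum()) / dij
    return total


def full_xi_oracle(c, A, w, n_docs=None, n_sub=30_000, floor=1e-8):
    """Maximize the prior-field objective by projected subgradient ascent
    followed by a trust-region constrained polish on the epigraph form.

    Returns (xi_best, objective_best) where the objective is evaluated as
    (1/N)[Σ log Γ(Σξ) − Σ log Γ(ξ) + Σ ξc] − Σ w‖Aξ‖₁.
    """
    from scipy.special import psi

    c = np.atleast_2d(c)
    N, K = c.shape
    if n_docs is None:
        n_docs = N
    L = A.shape[0]
    w = np.asarray(w, float).reshape(-1)

    def B(x):
        return (gammaln(x.sum(1)).sum() - gammaln(x).sum() + (x * c).sum()) / n_docs \
            - float(np.sum(w[:, None] * np.abs(A @ x)))

    xi = np.ones((N, K))
    best, f_best = xi.copy(), B(xi)
    for t in range(n_sub):
        g = (psi(xi.sum(1, keepdims=True)) - psi(xi) + c) / n_docs
        if L:
            g -= A.T @ (w[:, None] * np.sign(A @ xi))
        xi = np.maximum(xi + (0.5 / math.sqrt(t + 1.0)) * g, floor)
        f = B(xi)
        if f > f_best:
            f_best, best = f, xi.copy()

    # polish (smooth objective + linear epigraph constraints, scipy solver)
    Ak = sp.kron(A, sp.identity(K), format="csr") if L else sp.csr_matrix((0, N * K))
    Ik = sp.identity(L * K, format="csr")
    C = sp.bmat([[Ak, -Ik], [-Ak, -Ik]], format="csr") if L else None
    wv = np.repeat(w, K)

    def f_obj(z):
        x = z[: N * K].reshape(N, K)
        smooth = -(gammaln(x.sum(1)).sum() - gammaln(x).sum() + (x * c).sum()) / n_docs
        return smooth + (wv @ z[N * K:] if L else 0.0)

    def f_jac(z):
        x = z[: N * K].reshape(N, K)
        gx = -(psi(x.sum(1, keepdims=True)) - psi(x) + c) / n_docs
        return np.concatenate([gx.reshape(-1), wv])

    chi0 = np.abs(Ak @ best.reshape(-1)) + 1e-3 if L else np.zeros(0)
    z0 = np.concatenate([best.reshape(-1), chi0])
    bounds = [(floor, None)] * (N * K) + [(None, None)] * (L * K)
    cons = [LinearConstraint(C, -np.inf, 0.0)] if L else []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(f_obj, z0, jac=f_jac, method="trust-constr",
                       constraints=cons, bounds=bounds,
                       options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 800})
    xp = np.maximum(res.x[: N * K].reshape(N, K), floor)
    if B(xp) > f_best:
        f_best, best = B(xp), xp
    return best, f_best


def per_document_dirichlet_newton(c_i, tol=1e-12, n_iter=200):
    """Damped Newton (dense Hessian inverse via numpy) for one document's
    unpenalized prior update: max log Γ(Σξ) − Σ log Γ(ξ) + ξᵀc."""
    from scipy.special import polygamma, psi

    K = len(c_i)
    xi = np.ones(K)

    def value(x):
        return -(math.lgamma(x.sum()) - sum(math.lgamma(v) for v in x) + x @ c_i)

    for _ in range(n_iter):
        g = psi(xi) - psi(xi.sum()) - c_i
        if np.abs(g).max() < tol:
            break
        H = np.diag(polygamma(1, xi)) - polygamma(1, xi.sum())
        step = np.linalg.solve(H, g)
        t = 1.0
        while np.any(xi - t * step <= 0) or value(xi - t * step) > value(xi) + 1e-15:
            t *= 0.5
            if t < 1e-12:
                break
        xi = xi - t * step
    return xi


def dense_kkt_newton(xi, chi, u1, u2, A_dense, rho, e, w, t):
    """Dense assembly and solve of the full PDIP block Newton system."""
    L, N = A_dense.shape
    K = xi.shape[1]
    d_xi = np.empty_like(xi)
    d_chi = np.empty_like(chi)
    d_u1 = np.empty_like(u1)
    d_u2 = np.empty_like(u2)
    for k in range(K):
        x = np.concatenate([xi[:, k], chi[:, k]])
        u = np.concatenate([u1[:, k], u2[:, k]])
        C = np.block([[A_dense, -np.eye(L)], [-A_dense, -np.eye(L)]])
        f1 = C @ x
        H = np.zeros((N + L, N + L))
        H[:N, :N] = rho * np.eye(N)
        grad0 = np.concatenate([rho * (xi[:, k] - e[:, k]), w])
        r_dual = grad0 + C.T @ u
        r_cent = -u * f1 - 1.0 / t
        top = np.hstack([H, C.T])
        bot = np.hstack([-(u[:, None] * C), -np.diag(f1)])
        M = np.vstack([top, bot])
        sol = np.linalg.solve(M, -np.concatenate([r_dual, r_cent]))
        d_xi[:, k] = sol[:N]
        d_chi[:, k] = sol[N:N + L]
        d_u1[:, k] = sol[N + L:N + 2 * L]
        d_u2[:, k] = sol[N + 2 * L:]
    return d_xi, d_chi, d_u1, d_u2


def bisect_1d(fn, lo, hi, tol=1e-13, n_iter=200):
    """Root of a monotone scalar function by bisection."""
    flo, fhi = fn(lo), fn(hi)
    if flo > 0 or fhi < 0:
        raise ValueError("root not bracketed")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if fn(mid) <= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
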