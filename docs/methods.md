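# Methods

`celltopics` fits a topic model to bag-of-cells documents built from
multiplexed-imaging cell tables, with one extension over standard latent
Dirichlet allocation (LDA): every document (the neighborhood anchored on one
cell) carries its own Dirichlet prior over topics, and the priors of
spatially adjacent anchors are tied by a graph-fused Laplace prior. This
document records the model, the inference machinery, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Model

Documents are phenotype count vectors: for anchor cell *i*, counts of the
neighbor cells (by phenotype) within a closed Euclidean ball of radius *r*
in the sample's native 2D/3D coordinates, excluding the anchor itself. The
generative model per document is LDA — topic proportions
θ_i ~ Dirichlet(α_i), topics β_k ~ Dirichlet(η), each neighbor cell drawing
a topic z ~ Mult(θ_i) and a phenotype w ~ Mult(β_z) — except that the prior
α_i varies per document and carries the spatial prior

    p(α) ∝ exp( − Σ_{(i,j) ∈ E} (1/d_ij) ‖α_i − α_j‖₁ ),

where E are Voronoi-facet (Delaunay) adjacencies between anchors of the
same sample and d_ij is either a constant or the inter-anchor distance.
Smaller d_ij ties neighbors harder; the ℓ1 norm makes the optimal prior
field piecewise constant (graph fused lasso).

## Inference

Mean-field variational Bayes with the factorization
q = Π_i q(θ_i) q(z_i) Π_k q(β_k) · δ(α − ξ):

* **E step** (per document, all documents vectorized):
  φ_ivk ∝ exp(E[log θ_ik] + E[log β_kv]), γ_ik = ξ_ik + Σ_v n_iv φ_ivk,
  iterated to a fixed point (∞-norm tolerance on γ, default 1e-4).
* **M step**: λ_kv = η + Σ_i n_iv φ_ivk.
* **Prior-field step**: ξ maximizes
  B(ξ) = (1/N) Σ_i [log Γ(Σ_k ξ_ik) − Σ_k log Γ(ξ_ik) + Σ_k ξ_ik c_ik]
  − Σ_l w_l ‖ξ_i − ξ_j‖₁, with c_ik = Ψ(γ_ik) − Ψ(Σ_k γ_ik) and per-edge
  weight w_l = penalty_scale / d_l. Both Dirichlet-derived terms carry the
  1/N factor; the reported evidence lower bound (ELBO) is normalized the
  same way — (1/N)·(standard LDA bound terms) minus the unscaled penalty —
  so the ξ step maximizes exactly the ξ-dependent part of the reported
  bound and the outer loop is a monotone ascent by construction. An ascent
  safeguard rejects any ξ update that lowers B(ξ) (possible only because
  the subproblem is solved inexactly), which keeps the ELBO trace
  non-decreasing under any solver budget.

The outer loop alternates (a) E/M sweeps at fixed ξ until the topic matrix
stabilizes and (b) one ξ update, and stops on a relative ELBO change below
`tol_outer` (default 1e-5) or `max_outer` (default 50). A final E sweep
leaves γ at the fixed point of the returned (ξ, λ). `transform` repeats the
same alternation for new anchors with λ frozen.

### The ξ update: ADMM with an interior-point fusion solver

B(ξ) is concave but non-smooth. We minimize −B by the alternating direction
method of multipliers after splitting ξ into a Dirichlet-side copy τ and an
edge-difference copy χ with the epigraph constraints χ ⪰ ±Aξ (A is the
signed edge incidence):

1. **Fusion step** — min_ξ,χ ρ/2‖ξ − e‖² + Σ_l w_l 1ᵀχ_l s.t. χ ⪰ ±Aξ with
   e = τ + v/ρ — is solved by a primal–dual interior-point method
   (barrier-perturbed KKT residuals, Newton steps, backtracking that
   preserves strict feasibility and shrinks ‖r_t‖; barrier multiplier
   μ = 10, backtracking α = 0.01, β = 0.5). The problem separates per
   topic; the block Newton system is reduced by eliminating (Δχ, Δu) to a
   sparse SPD system (ρI + Aᵀ diag(g) A) Δξ = rhs of size N per topic,
   solved densely for tiny problems and by one block-diagonal sparse LU
   across topics otherwise. Near-boundary rounding is handled by clamping
   slacks away from zero and, if the reduced system still degenerates, a
   1e-12-scaled diagonal perturbation. Inside ADMM the solver stops on a
   relative surrogate gap (1e-11 scaled by the objective) or when the gap
   stagnates at its numerical floor; called directly it runs to an
   absolute 1e-10 gap.
2. **Dirichlet prox** — min_τ (1/N) log B(τ_i) + ρ/2‖τ_i − r_i‖² with
   r = ξ − v/ρ + c/(ρN) — is separable per document and solved by a damped
   Newton method whose Hessian diag(Φ(τ)/N + ρ) − (Φ(Στ)/N)·11ᵀ is
   inverted with the Sherman–Morrison identity (no factorization), all
   rows simultaneously, with per-row backtracking that keeps τ > 0 and
   enforces sufficient decrease up to a roundoff allowance.
3. **Dual update** v ← v + ρ(τ − ξ), stopping when ‖τ − ξ‖∞ and ρ‖Δτ‖∞
   fall below tolerance.

**Penalty parameter ρ.** The Dirichlet terms are averaged over documents,
so their curvature scales as 1/N; ρ must match it or consensus crawls. The
default is ρ = 1/N (measured ~10× fewer iterations than ρ = 1). Bounded
residual balancing (×2/÷2 when the residuals disagree by >100×, every 5th
iteration) is on by default; it rescues the strongly-regularized regime
where the primal residual otherwise stalls.

With no edges (or penalty_scale = 0) the ξ update decouples into
per-document Dirichlet maximum-likelihood fits, solved by the same Newton
scheme — this is the "vanilla LDA with free per-document priors" baseline.

**Degenerate behavior worth knowing.** Point-estimating a per-document
Dirichlet prior from a single document is ill-posed: alternating the
E step with the decoupled prior update lets ξ_i chase its own posterior and
grow without bound (slowly — log-scale drift per outer iteration). The fit
therefore relies on the outer ELBO tolerance and iteration cap to stop;
with spatial regularization the drift is shared across neighbors and far
milder. This is a property of the model class (no hyperprior on α), not of
the solver.

**Penalty scale.** The per-edge coefficient is penalty_scale/d_ij, the
single regularization knob. Because the data terms are per-document
averaged, a scale of 1 makes the penalty O(N) against an O(1) data term
and fuses the whole field to a constant (global pooling); scale ≈ 1/N
reproduces the balance of the unnormalized bound. The default is 0.1/N,
chosen by a sensitivity scan on synthetic tissue with known ground truth:
between 0.03/N and 0.3/N recovery accuracy is flat and maximal, weaker
scales converge to the unregularized baseline, stronger ones collapse
smooth transitions into plateaus and lose boundary accuracy. Sharply
compartmentalized tissue justifies larger values; the knob is exposed
everywhere (`penalty_scale`).

### Initialization, identifiability, determinism

λ starts at η plus small positive seeded noise (Gamma(100, 0.01), mean 1);
ξ starts at the symmetric 1/K. All randomness flows from a single integer
seed through `numpy.random.default_rng`; fits are bit-reproducible.
Topics are exchangeable; for reporting, `canonical_order()` sorts by total
mass, and comparisons across runs should Hungarian-match topics on cosine
similarity (as the tests do).

## Featurization choices

Closed ball (distance ≤ r inclusive); anchors never count themselves;
dimensionality (2D/3D) inferred per sample from the coordinate columns and
the Voronoi adjacency computed in that native dimensionality; no
cross-sample edges ever. Collinear/coplanar degenerate point sets fall
back to a nearest-neighbor chain along the principal axis with a warning.
Convex-hull artifacts can be removed with `max_edge_length` (off by
default). Coordinates are unitless; the caller keeps positions and radius
in the same units.

## Synthetic data: what it emulates and what it does not

The generator places anchors uniformly in a unit square, builds a smooth
topic-proportion field θ(x) from logistic blends over K spatial regions
(`blocks`, `smooth-gradient`, `islands`; `bandwidth` sets boundary width),
draws topics as Dirichlet(0.3) rows over V phenotypes, and samples each
document's counts as Multinomial(Poisson(counts_per_doc), θ_iᵀβ). Default
counts_per_doc = 20 reflects the tens-of-cells neighborhoods of
multiplexed imaging; Poisson lengths deliberately produce occasional empty
documents, which the model must tolerate (they receive prior-driven
posteriors).

Region centers are redrawn until pairwise separation ≥ 0.35: without this
identifiability guard, two regions can overlap so broadly that even a
classifier given the true topics and true field cannot exceed ~0.85
dominant-topic accuracy, i.e. the ground-truth label itself is undefined
for much of the tissue. With the guard, the oracle ceiling is 0.95–0.98
across seeds, so recovery scores measure the method rather than the
ambiguity of the benchmark.

The generator does **not** simulate segmentation errors, phenotype
misassignment, marker spillover, holes/vessels in tissue, anisotropic cell
density, or batch effects between samples. Passing recovery tests shows
the inference machinery recovers the structure its own model class
assumes — it does not validate phenotype gating or robustness to upstream
errors on real CODEX/MIBI-TOF data.

The cell table emitted alongside a synthetic corpus places each document's
neighbor cells uniformly inside its anchor's ball, so the end-to-end CLI
path runs on it; re-featurizing that table reproduces the drawn counts
only approximately (overlapping balls double-count), and the exact drawn
corpus is returned separately for scoring.

## Numerical details and edge cases

* Digamma/trigamma from scipy; log-Beta via `gammaln`.
* ξ is floored at 1e-6 before use as a Dirichlet parameter (the fusion
  step has no positivity constraint; positivity is enforced by the
  Dirichlet prox and binds only at the floor in pathological cases).
* K = 1 collapses every stage to closed forms (φ ≡ 1,
  γ = ξ + total count, prox = identity) and skips the ξ update.
* Empty documents keep φ empty and γ = ξ.
* Dominant-topic ties break to the lowest index; the `> 1/K`
  summarization threshold is strict, on row-normalized weights (the only
  scale where 1/K is meaningful).
* Benchmark problem sizes used by the acceptance script (small random
  instances for the solver oracles, a 200-document decoupling corpus, a
  500-document ELBO run, 2,000-anchor recovery tissues) were chosen so
  each check exercises the full code path at desk scale.

## Known limitations

* The per-document prior drift described above means "run to full
  convergence" is not a well-posed target for the unregularized model;
  comparisons between fits should fix the outer iteration budget.
* ℓ1 fusing is piecewise-constant by design; fields that are genuinely
  smooth are tracked in a staircase fashion, and boundary anchors inherit
  whichever plateau they fall on.
* The ADMM subproblems are solved inexactly inside the fit (capped,
  warm-started); the ascent safeguard preserves monotonicity but the
  returned ξ is only an approximate maximizer of B(ξ) at intermediate
  outer iterations. `update_xi_admm` called directly solves to tolerance.
* Only Voronoi-facet edge sets are provided (no k-nearest-neighbor or
  fixed-radius graphs).
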