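"""Variational E/M steps, sufficient statistics, ELBO and model fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, psi

from celltopics.featurization import NeighborhoodCorpus, SpatialGraph
from celltopics.inference import (
    compute_elbo,
    compute_sufficient_stats,
    estep_document,
    fit_spatial_lda,
    mstep_topics,
    SpatialLDAModel,
    transform_cells,
)
from oracles import digamma_series, lda_estep_reference


def _corpus(counts, radius=1.0):
    counts = np.asarray(counts)
    N, V = counts.shape
    return NeighborhoodCorpus(
        counts,
        pd.DataFrame({"sample_id": "s", "cell_id": [f"c{i}" for i in range(N)]}),
        np.random.default_rng(0).uniform(0, 1, (N, 2)),
        radius,
        [f"p{v}" for v in range(V)],
    )


class TestEStep:
    def test_single_topic_degenerate(self):
        """K = 1 forces phi ≡ 1 and gamma = xi + total count."""
        counts = np.array([3.0, 0.0, 2.0])
        phi, gamma, conv = estep_document(counts, np.array([0.7]),
                                          np.array([[1.0, 2.0, 3.0]]))
        assert conv
        np.testing.assert_allclose(phi, 1.0)
        assert gamma[0] == pytest.approx(0.7 + 5.0)

    def test_symmetric_topics_uniform_phi(self):
        lam = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        counts = np.array([2.0, 1.0, 1.0])
        phi, gamma, _ = estep_document(counts, np.array([0.5, 0.5]), lam)
        np.testing.assert_allclose(phi, 0.5, atol=1e-12)

    def test_matches_plain_loop_reference(self):
        """Batch fixed point equals a simple per-word-loop implementation run
        to a much tighter tolerance."""
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 6, size=3).astype(float)
        xi_i = rng.uniform(0.3, 1.5, size=2)
        lam = rng.uniform(0.5, 3.0, size=(2, 3))
        phi, gamma, _ = estep_document(counts, xi_i, lam, tol=1e-10, max_iter=2000)
        phi_ref, gamma_ref = lda_estep_reference(counts, xi_i, lam)
        np.testing.assert_allclose(gamma, gamma_ref, atol=1e-7)
        np.testing.assert_allclose(phi, phi_ref, atol=1e-7)

    def test_responsibilities_normalize_and_gamma_identity(self):
        """Σ_k φ = 1 and γ − ξ = Σ_v n_v φ_v at the fixed point."""
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 8, size=5).astype(float)
        xi_i = rng.uniform(0.2, 2.0, size=3)
        lam = rng.uniform(0.3, 4.0, size=(3, 5))
        phi, gamma, _ = estep_document(counts, xi_i, lam, tol=1e-10)
        np.testing.assert_allclose(phi.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(gamma - xi_i, counts @ phi, atol=1e-9)
        assert np.all(gamma - xi_i >= -1e-12)


class TestMStep:
    def test_degenerate_responsibilities(self):
        corpus = _corpus([[2, 1], [0, 3]])
        phi = np.zeros((2, 2, 2))
        phi[:, :, 0] = 1.0  # all mass on topic 1
        lam = mstep_topics(phi, corpus, eta=0.5)
        np.testing.assert_allclose(lam[0], 0.5 + np.array([2.0, 4.0]))
        np.testing.assert_allclose(lam[1], 0.5)

    def test_uniform_responsibilities(self):
        corpus = _corpus([[2, 1], [0, 3]])
        phi = np.full((2, 2, 2), 0.5)
        lam = mstep_topics(phi, corpus, eta=1.0)
        np.testing.assert_allclose(lam, 1.0 + np.array([[1.0, 2.0]] * 2))

    def test_random_corpus_direct_summation(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(0, 5, size=(4, 3))
        corpus = _corpus(counts)
        phi = rng.dirichlet(np.ones(2), size=(4, 3))
        lam = mstep_topics(phi, corpus, eta=0.7)
        ref = np.full((2, 3), 0.7)
        for i in range(4):
            for v in range(3):
                for k in range(2):
                    ref[k, v] += counts[i, v] * phi[i, v, k]
        np.testing.assert_allclose(lam, ref, atol=1e-12)


class TestSufficientStats:
    def test_digamma_recurrence_unit_gamma(self):
        """γ = (1, 1): c = −1 exactly because Ψ(2) = Ψ(1) + 1."""
        c = compute_sufficient_stats(np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(c, -1.0, atol=1e-12)

    def test_strictly_negative(self):
        rng = np.random.default_rng(2)
        c = compute_sufficient_stats(rng.uniform(0.05, 20.0, size=(30, 4)))
        assert (c < 0).all()

    def test_matches_independent_digamma_series(self):
        gamma = np.array([[2.0, 3.0]])
        c = compute_sufficient_stats(gamma)
        expected = np.array([
            digamma_series(2.0) - digamma_series(5.0),
            digamma_series(3.0) - digamma_series(5.0),
        ])
        np.testing.assert_allclose(c[0], expected, atol=1e-12)


class TestELBO:
    def _model(self, corpus, K, seed=0):
        rng = np.random.default_rng(seed)
        N, V = corpus.counts.shape
        lam = rng.uniform(0.5, 2.0, (K, V))
        xi = rng.uniform(0.3, 1.5, (N, K))
        phi = np.zeros((N, V, K))
        gamma = np.empty((N, K))
        for i in range(N):
            phi[i], gamma[i], _ = estep_document(
                corpus.counts[i].astype(float), xi[i], lam, tol=1e-10)
        return SpatialLDAModel(lam=lam, eta=1.0, xi=xi, gamma=gamma,
                               vocabulary=corpus.vocabulary, phi=phi)

    def test_identical_xi_rows_zero_penalty(self):
        corpus = _corpus([[1, 2], [2, 0], [1, 1]])
        model = self._model(corpus, K=2)
        model.xi = np.tile([[0.8, 1.2]], (3, 1))
        graph = SpatialGraph(np.array([[0, 1], [1, 2]]), np.ones(2), 3)
        w = np.ones(2)
        without = compute_elbo(corpus, model, graph=None)
        with_pen = compute_elbo(corpus, model, graph=graph, penalty_weights=w)
        assert with_pen == pytest.approx(without, abs=1e-12)

    def test_single_document_single_topic_closed_form(self):
        """K = 1, one 2-phenotype document: the bound assembled by hand from
        the Dirichlet-multinomial terms."""
        counts = np.array([[3, 2]])
        corpus = _corpus(counts)
        lam = np.array([[2.0, 4.0]])
        xi = np.array([[0.9]])
        eta = 1.0
        phi, gamma, _ = estep_document(counts[0].astype(float), xi[0], lam)
        model = SpatialLDAModel(lam=lam, eta=eta, xi=xi,
                                gamma=gamma.reshape(1, 1),
                                vocabulary=corpus.vocabulary,
                                phi=phi.reshape(1, 2, 1))
        got = compute_elbo(corpus, model)
        # hand assembly from the Dirichlet-multinomial pieces (phi ≡ 1)
        elog_beta = psi(lam[0]) - psi(lam.sum())
        elog_theta = psi(gamma) - psi(gamma.sum())          # scalar, = 0 for K=1
        V = 2
        word = counts[0] @ elog_beta
        theta_prior = gammaln(xi.sum()) - gammaln(xi).sum() + (xi[0, 0] - 1) * elog_theta[0]
        theta_post = gammaln(gamma.sum()) - gammaln(gamma).sum() + (gamma[0] - 1) * elog_theta[0]
        beta_prior = gammaln(V * eta) - V * gammaln(eta) + (eta - 1) * elog_beta.sum()
        beta_post = gammaln(lam.sum()) - gammaln(lam).sum() + ((lam - 1) * elog_beta).sum()
        hand = word + theta_prior - theta_post + beta_prior - beta_post
        assert got == pytest.approx(float(hand), abs=1e-10)

    def test_monotone_over_outer_iterations(self, small_tissue):
        _, corpus, graph, _ = small_tissue
        model = fit_spatial_lda(corpus, graph, 3, seed=5, max_outer=12)
        deltas = np.diff(model.elbo_trace)
        assert (deltas >= -1e-6).all()


class TestFitAndTransform:
    def test_fit_shapes_and_determinism(self, small_tissue):
        _, corpus, graph, _ = small_tissue
        m1 = fit_spatial_lda(corpus, graph, 3, seed=2, max_outer=4)
        m2 = fit_spatial_lda(corpus, graph, 3, seed=2, max_outer=4)
        assert m1.lam.shape == (3, corpus.n_phenotypes)
        assert m1.gamma.shape == (corpus.n_documents, 3)
        np.testing.assert_array_equal(m1.lam, m2.lam)
        np.testing.assert_array_equal(m1.gamma, m2.gamma)

    def test_empty_edges_decouples_to_per_document_priors(self):
        """With no edges the fitted γ equals an independent per-document LDA
        pass at the decoupled prior optimum."""
        rng = np.random.default_rng(14)
        counts = rng.integers(0, 10, size=(40, 6))
        corpus = _corpus(counts)
        graph = SpatialGraph(np.zeros((0, 2)), np.zeros(0), n_nodes=40)
        model = fit_spatial_lda(corpus, graph, 2, seed=3)
        for i in range(0, 40, 7):
            _, gamma_ref, _ = estep_document(
                counts[i].astype(float), model.xi[i], model.lam,
                tol=1e-9, max_iter=2000)
            np.testing.assert_allclose(model.gamma[i], gamma_ref, atol=1e-4)

    def test_transform_idempotent_on_training_corpus(self, small_tissue):
        """Re-inferring the training anchors under the trained topics
        reproduces the topic weights (γ is compared on the normalized
        scale: its absolute magnitude tracks the slowly drifting prior
        field and is path-dependent by design)."""
        _, corpus, graph, _ = small_tissue
        model = fit_spatial_lda(corpus, graph, 3, seed=1, max_outer=15)
        gamma, xi = transform_cells(corpus, graph, model)
        w_new = gamma / gamma.sum(axis=1, keepdims=True)
        w_old = model.gamma / model.gamma.sum(axis=1, keepdims=True)
        assert np.abs(w_new - w_old).max() < 1e-3
        assert (w_new.argmax(1) == w_old.argmax(1)).all()

    def test_transform_rejects_vocabulary_mismatch(self, small_tissue):
        _, corpus, graph, _ = small_tissue
        model = fit_spatial_lda(corpus, graph, 2, seed=0, max_outer=2)
        other = _corpus(np.zeros((3, 4), dtype=int))
        bad_graph = SpatialGraph(np.zeros((0, 2)), np.zeros(0), n_nodes=3)
        with pytest.raises(ValueError, match="[Vv]ocabulary"):
            transform_cells(other, bad_graph, model)

    def test_transform_empty_documents_returns_prior(self):
        """With no observations the posterior equals the (decoupled) prior."""
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 9, size=(30, 5))
        corpus = _corpus(counts)
        graph = SpatialGraph(np.zeros((0, 2)), np.zeros(0), n_nodes=30)
        model = fit_spatial_lda(corpus, graph, 2, seed=4, max_outer=10)
        empty = _corpus(np.zeros((4, 5), dtype=int))
        egraph = SpatialGraph(np.zeros((0, 2)), np.zeros(0), n_nodes=4)
        gamma, xi = transform_cells(empty, egraph, model)
        np.testing.assert_allclose(gamma, xi, atol=1e-10)

    def test_single_topic_reduces_to_dirichlet_multinomial(self):
        counts = np.array([[2, 3], [1, 0]])
        corpus = _corpus(counts)
        graph = SpatialGraph(np.array([[0, 1]]), np.ones(1), n_nodes=2)
        model = fit_spatial_lda(corpus, graph, 1, seed=0, max_outer=3)
        np.testing.assert_allclose(
            model.gamma[:, 0], model.xi[:, 0] + counts.sum(axis=1), atol=1e-10)
        np.testing.assert_allclose(
            model.lam[0], model.eta + counts.sum(axis=0), atol=1e-10)
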