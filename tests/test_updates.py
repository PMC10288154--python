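"""Update-rule and objective correctness against scalar-loop oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from scjointnmf import FactorModel, frobenius_objective, kl_objective
from scjointnmf._updates import (
    ModalityWorkspace,
    update_h_l2norm,
    update_h_sparsity,
    update_w_frobenius,
    update_w_kl,
)
from scjointnmf.graph import build_knn_feature_graph, identity_graph
from scjointnmf.io import CountMatrix

from conftest import normalized_dataset_from_arrays
from oracles import (
    kl_objective_dense,
    mu_step_h_l2norm,
    mu_step_h_sparsity,
    mu_step_w_kl,
)

EPS = 1e-16


def seeded_instance(seed=0, shapes=((12, 8), (20, 8)), d=3, density=0.7):
    """V-modality instance with strictly positive factors and sparse counts."""
    rng = np.random.default_rng(seed)
    xs, ws = [], []
    n = shapes[0][1]
    for m, _ in shapes:
        x = np.where(rng.random((m, n)) < density, rng.integers(1, 30, (m, n)), 0)
        xs.append(x.astype(float))
        ws.append(rng.uniform(0.1, 2.0, (m, d)))
    h = rng.uniform(0.1, 2.0, (d, n))
    return xs, ws, h


class TestKlObjective:
    def test_zero_at_exact_factorization(self, rng):
        w = rng.uniform(0.5, 2, (6, 2))
        h = rng.uniform(0.5, 2, (2, 5))
        x = w @ h
        data = normalized_dataset_from_arrays([x])
        model = FactorModel([w], h, [0.0], 0.0)
        assert kl_objective(data, model) == pytest.approx(0.0, abs=1e-9)

    def test_hand_sum_against_unit_rates(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        w = np.ones((2, 1))
        h = np.ones((1, 2))  # WH is the all-ones matrix
        data = normalized_dataset_from_arrays([x])
        model = FactorModel([w], h, [0.0], 0.0)
        expected = sum(v * np.log(v) - v + 1.0 for v in x.ravel())
        assert kl_objective(data, model) == pytest.approx(expected, rel=1e-12)

    def test_identity_graph_penalty_is_half_lambda_frobenius(self, rng):
        xs, ws, h = seeded_instance(3, shapes=((9, 6),), d=2)
        data = normalized_dataset_from_arrays(xs)
        lam = 7.0
        base = FactorModel(ws, h, [0.0], 0.0)
        pen = FactorModel(ws, h, [lam], 0.0)
        g = [identity_graph(9)]
        diff = kl_objective(data, pen, g) - kl_objective(data, base, g)
        assert diff == pytest.approx(0.5 * lam * (ws[0] ** 2).sum(), rel=1e-12)

    def test_sparse_equals_dense_evaluation(self):
        for seed in range(5):
            xs, ws, h = seeded_instance(seed, shapes=((10, 7), (14, 7)), d=3)
            data = normalized_dataset_from_arrays(xs)
            graphs = [identity_graph(10), identity_graph(14)]
            lam_w, lam_h = [1.3, 0.4], 2.2
            model = FactorModel(ws, h, lam_w, lam_h, constraint="sparsity_H")
            mine = kl_objective(data, model, graphs)
            dense = kl_objective_dense(
                xs, ws, h, [g.laplacian for g in graphs], lam_w, lam_h
            )
            assert mine == pytest.approx(dense, rel=1e-10)

    def test_infinite_divergence_detected(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0]])
        w = np.array([[1.0], [0.0]])
        h = np.array([[1.0, 1.0]])
        data = normalized_dataset_from_arrays([x])
        model = FactorModel([w], h, [0.0], 0.0)
        with pytest.raises(FloatingPointError):
            kl_objective(data, model)


class TestFrobeniusObjective:
    def test_zero_at_exact_factorization(self, rng):
        w = rng.uniform(0.5, 2, (5, 2))
        h = rng.uniform(0.5, 2, (2, 4))
        data = normalized_dataset_from_arrays([w @ h])
        assert frobenius_objective(
            data, FactorModel([w], h, [0.0], 0.0)
        ) == pytest.approx(0.0, abs=1e-9)

    def test_scalar_example(self):
        data = normalized_dataset_from_arrays([np.array([[2.0]])])
        model = FactorModel([np.array([[1.0]])], np.array([[1.0]]), [0.0], 0.0)
        assert frobenius_objective(data, model) == pytest.approx(1.0)

    def test_brute_force_sum(self, rng):
        x = rng.uniform(0, 5, (6, 4))
        w = rng.uniform(0.1, 1, (6, 3))
        h = rng.uniform(0.1, 1, (3, 4))
        data = normalized_dataset_from_arrays([x])
        model = FactorModel([w], h, [0.0], 0.0)
        assert frobenius_objective(data, model) == pytest.approx(
            ((x - w @ h) ** 2).sum(), rel=1e-10
        )


class TestWUpdateKl:
    def test_stationary_at_exact_fit(self, rng):
        w = rng.uniform(0.5, 2, (7, 3))
        h = rng.uniform(0.5, 2, (3, 5))
        ws_ = ModalityWorkspace(sp.csr_matrix(w @ h))
        w_new = update_w_kl(ws_, w, h, 0.0, None, EPS)
        np.testing.assert_allclose(w_new, w, rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_loop(self, seed):
        xs, ws, h = seeded_instance(seed, shapes=((4, 3), (6, 3)), d=2)
        for x, w in zip(xs, ws):
            g = build_knn_feature_graph(
                CountMatrix(sp.csr_matrix(x), [f"f{i}" for i in range(x.shape[0])],
                            [f"c{j}" for j in range(x.shape[1])], "rna", "raw"),
                k=2,
            )
            lam = 1.7
            mine = update_w_kl(ModalityWorkspace(sp.csr_matrix(x)), w, h, lam, g, EPS)
            ref = mu_step_w_kl(x, w, h, lam, g.lap_pos, g.lap_neg, EPS)
            np.testing.assert_allclose(mine, ref, rtol=1e-12, atol=1e-14)

    def test_lambda_zero_reduces_to_lee_seung(self, rng):
        x = np.where(rng.random((8, 6)) < 0.8, rng.integers(1, 9, (8, 6)), 0).astype(float)
        w = rng.uniform(0.2, 1.5, (8, 3))
        h = rng.uniform(0.2, 1.5, (3, 6))
        mine = update_w_kl(ModalityWorkspace(sp.csr_matrix(x)), w, h, 0.0, None, EPS)
        wh = w @ h
        textbook = w * ((np.where(x > 0, x / wh, 0.0)) @ h.T) / (
            h.sum(axis=1)[None, :] + EPS
        )
        np.testing.assert_allclose(mine, textbook, rtol=1e-12)


class TestHUpdateSparsity:
    def test_stationary_at_exact_fit(self, rng):
        w = rng.uniform(0.5, 2, (6, 2))
        h = rng.uniform(0.5, 2, (2, 5))
        ws_ = [ModalityWorkspace(sp.csr_matrix(w @ h))]
        np.testing.assert_allclose(
            update_h_sparsity(ws_, [w], h, 0.0, EPS), h, rtol=1e-12
        )

    def test_positive_lambda_strictly_shrinks(self, rng):
        w = rng.uniform(0.5, 2, (6, 2))
        h = rng.uniform(0.5, 2, (2, 5))
        ws_ = [ModalityWorkspace(sp.csr_matrix(w @ h))]
        h_new = update_h_sparsity(ws_, [w], h, 5.0, EPS)
        assert np.all(h_new < h)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_scalar_loop(self, seed):
        xs, ws, h = seeded_instance(seed, shapes=((5, 4), (7, 4)), d=3)
        spaces = [ModalityWorkspace(sp.csr_matrix(x)) for x in xs]
        mine = update_h_sparsity(spaces, ws, h, 2.5, EPS)
        ref = mu_step_h_sparsity(xs, ws, h, 2.5, EPS)
        np.testing.assert_allclose(mine, ref, rtol=1e-12)


class TestHUpdateL2Norm:
    def test_unit_columns_after_safeguard(self):
        xs, ws, h = seeded_instance(1, shapes=((6, 5), (8, 5)), d=3)
        h = h / np.linalg.norm(h, axis=0)
        spaces = [ModalityWorkspace(sp.csr_matrix(x)) for x in xs]
        h_new = update_h_l2norm(spaces, ws, h, EPS)
        np.testing.assert_allclose(np.linalg.norm(h_new, axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_scalar_loop_pre_safeguard(self, seed):
        xs, ws, h = seeded_instance(seed, shapes=((5, 4), (6, 4)), d=2)
        h = h / np.linalg.norm(h, axis=0)
        spaces = [ModalityWorkspace(sp.csr_matrix(x)) for x in xs]
        mine = update_h_l2norm(spaces, ws, h, EPS, renormalize=False)
        ref = mu_step_h_l2norm(xs, ws, h, EPS)
        np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_correction_cancels_at_unit_norm_exact_fit(self, rng):
        # X = WH with unit-norm H columns: ratio is 1 so Wᵀ(X⊘WH) = Wᵀ1 and
        # numerator equals denominator columnwise -> multiplier 1
        w = rng.uniform(0.5, 2, (7, 3))
        h = rng.uniform(0.5, 2, (3, 6))
        h = h / np.linalg.norm(h, axis=0)
        spaces = [ModalityWorkspace(sp.csr_matrix(w @ h))]
        h_new = update_h_l2norm(spaces, [w], h, EPS, renormalize=False)
        np.testing.assert_allclose(h_new, h, rtol=1e-10)

    def test_zero_column_rejected(self, rng):
        xs, ws, h = seeded_instance(0, shapes=((5, 4),), d=2)
        h[:, 1] = 0.0
        spaces = [ModalityWorkspace(sp.csr_matrix(xs[0]))]
        with pytest.raises(ValueError, match="zero column"):
            update_h_l2norm(spaces, ws, h, EPS)


class TestFrobeniusUpdates:
    def test_fixed_point_and_textbook_reduction(self, rng):
        w = rng.uniform(0.5, 2, (6, 2))
        h = rng.uniform(0.5, 2, (2, 5))
        x = w @ h
        ws_ = ModalityWorkspace(sp.csr_matrix(x))
        np.testing.assert_allclose(
            update_w_frobenius(ws_, w, h, 0.0, None, EPS), w, rtol=1e-10
        )
        x2 = rng.uniform(0, 4, (6, 5))
        ws2 = ModalityWorkspace(sp.csr_matrix(x2))
        mine = update_w_frobenius(ws2, w, h, 0.0, None, EPS)
        textbook = w * (x2 @ h.T) / (w @ (h @ h.T) + EPS)
        np.testing.assert_allclose(mine, textbook, rtol=1e-12)
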