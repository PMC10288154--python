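import numpy as np
import pytest

from scjointnmf import (
    FactorModel,
    FitConfig,
    InitConfig,
    JointGraphNMF,
    fit_factorization,
    initialize_factors,
)
from scjointnmf.graph import build_knn_feature_graph

from conftest import normalized_dataset_from_arrays, small_sim
from oracles import kl_nmf_textbook


def normalized_pipeline(data, min_cells=3):
    from scjointnmf import filter_features, median_library_normalize

    filtered = data.map(lambda cm: filter_features(cm, min_cells))
    graphs = [build_knn_feature_graph(cm, k=5) for cm in filtered.modalities]
    return filtered.map(median_library_normalize), graphs


class TestFitBasics:
    def test_defaults_match_documented_solver_settings(self):
        cfg = FitConfig()
        assert cfg.max_iter == 10_000 and cfg.tol == 1e-6 and cfg.eps == 1e-16
        est = JointGraphNMF()
        assert est.max_iter == 10_000 and est.tol == 1e-6

    def test_single_modality_unpenalized_matches_textbook(self, rng):
        x = np.where(rng.random((20, 12)) < 0.8, rng.integers(1, 15, (20, 12)), 0)
        x = x.astype(float)
        data = normalized_dataset_from_arrays([x])
        w0, h0 = initialize_factors(data, InitConfig(method="nndsvd", d=4))
        n_iter = 150
        est = JointGraphNMF(
            n_components=4, max_iter=n_iter, tol=1e-300, loss_every=n_iter
        )
        est.fit(data, W_init=[w.copy() for w in w0], H_init=h0.copy())
        w_ref, h_ref = kl_nmf_textbook(x, w0[0], h0, n_iter)
        wh = est.W_[0] @ est.H_
        wh_ref = w_ref @ h_ref
        rel = np.linalg.norm(wh - wh_ref) / np.linalg.norm(wh_ref)
        assert rel < 1e-8

    def test_monotone_descent_sparsity_kl(self):
        for seed in range(3):
            data, _ = small_sim(seed=seed)
            normalized, graphs = normalized_pipeline(data)
            est = JointGraphNMF(
                n_components=5, lambda_w=[10.0, 50.0], lambda_h=500.0,
                max_iter=200, tol=1e-300, loss_every=1,
            )
            est.fit(normalized, graphs=graphs)
            losses = est.loss_trace_[:, 1]
            assert np.all(np.diff(losses) <= 1e-10 * np.abs(losses[:-1]))

    def test_monotone_descent_frobenius(self):
        data, _ = small_sim(seed=7)
        normalized, graphs = normalized_pipeline(data)
        est = JointGraphNMF(
            n_components=4, divergence="frobenius", lambda_w=[1.0, 2.0],
            lambda_h=5.0, max_iter=200, tol=1e-300, loss_every=1,
        )
        est.fit(normalized, graphs=graphs)
        losses = est.loss_trace_[:, 1]
        assert np.all(np.diff(losses) <= 1e-10 * np.abs(losses[:-1]))

    def test_l2norm_constraint_enforced_and_descending(self):
        data, _ = small_sim(seed=3)
        normalized, graphs = normalized_pipeline(data)
        for divergence in ("poisson_kl", "frobenius"):
            est = JointGraphNMF(
                n_components=4, constraint="l2norm_H", divergence=divergence,
                lambda_w=[3.0, 15.0], max_iter=150, tol=1e-300, loss_every=1,
            )
            est.fit(normalized, graphs=graphs)
            np.testing.assert_allclose(
                np.linalg.norm(est.H_, axis=0), 1.0, atol=1e-8
            )
            assert all(w.min() >= 0 for w in est.W_)
            losses = est.loss_trace_[:, 1]
            # the renormalization safeguard may cause local fluctuation; the
            # running minimum and the overall trend must still decrease
            assert losses[-1] < losses[0]
            running_min = np.minimum.accumulate(losses)
            assert np.all(np.diff(running_min) <= 1e-10 * np.abs(running_min[:-1]))

    def test_deterministic_loss_trace(self):
        data, _ = small_sim(seed=5)
        normalized, graphs = normalized_pipeline(data)
        runs = []
        for _ in range(2):
            est = JointGraphNMF(
                n_components=4, lambda_w=[10.0, 50.0], lambda_h=500.0,
                max_iter=50, loss_every=5, random_state=9,
            )
            est.fit(normalized, graphs=graphs)
            runs.append((est.loss_trace_.copy(), est.H_.copy(), [w.copy() for w in est.W_]))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])
        assert all(np.array_equal(a, b) for a, b in zip(runs[0][2], runs[1][2]))

    def test_nonnegativity_after_fit(self):
        data, _ = small_sim(seed=2)
        normalized, graphs = normalized_pipeline(data)
        est = JointGraphNMF(
            n_components=4, lambda_w=[10.0, 50.0], lambda_h=500.0, max_iter=60,
            loss_every=10,
        )
        est.fit(normalized, graphs=graphs)
        assert est.H_.min() >= 0
        assert all(w.min() >= 0 for w in est.W_)

    def test_convergence_flag_and_early_stop(self, rng):
        w = rng.uniform(0.5, 2, (10, 2))
        h = rng.uniform(0.5, 2, (2, 8))
        data = normalized_dataset_from_arrays([w @ h])
        est = JointGraphNMF(n_components=2, max_iter=5000, tol=1e-6)
        est.fit(data)
        assert est.converged_
        assert est.n_iter_ < 5000

    def test_validation_errors(self, rng):
        x = rng.uniform(0.1, 2, (8, 6))
        data = normalized_dataset_from_arrays([x])
        with pytest.raises(ValueError, match="constraint"):
            JointGraphNMF(constraint="bogus", n_components=2).fit(data)
        with pytest.raises(ValueError, match="lambda_w length"):
            JointGraphNMF(n_components=2, lambda_w=[1.0, 2.0]).fit(data)
        with pytest.raises(ValueError, match="strictly positive"):
            JointGraphNMF(n_components=2).fit(
                data, W_init=[np.zeros((8, 2))], H_init=np.ones((2, 6))
            )

    def test_sklearn_param_round_trip(self):
        est = JointGraphNMF(n_components=7, lambda_h=3.0)
        params = est.get_params()
        est2 = JointGraphNMF(**params)
        assert est2.n_components == 7 and est2.lambda_h == 3.0
        est2.set_params(tol=1e-4)
        assert est2.tol == 1e-4

    def test_transform_returns_cells_by_factors(self):
        data, _ = small_sim(seed=4)
        normalized, graphs = normalized_pipeline(data)
        est = JointGraphNMF(n_components=3, max_iter=20, loss_every=20)
        emb = est.fit_transform(normalized, graphs=graphs)
        assert emb.shape == (normalized.n_cells, 3)


class TestFactorModelSerialization:
    def test_save_load_round_trip(self, tmp_path):
        data, _ = small_sim(seed=6)
        normalized, graphs = normalized_pipeline(data)
        model = fit_factorization(
            normalized, graphs, init=InitConfig(d=3),
            config=FitConfig(max_iter=20, loss_every=10),
            lambda_w=[10.0, 50.0], lambda_h=500.0,
        )
        model.save(tmp_path / "model")
        back = FactorModel.load(tmp_path / "model")
        np.testing.assert_allclose(back.H, model.H, rtol=1e-12)
        for a, b in zip(back.W, model.W):
            np.testing.assert_allclose(a, b, rtol=1e-12)
        assert back.constraint == model.constraint
        assert back.lambda_W == model.lambda_W
        assert back.iterations_run == model.iterations_run
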