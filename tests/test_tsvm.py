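"""Transfer SVM core: dual QP, primal recovery, bias, transfer behavior.

The analytic anchor used throughout is the symmetric two-point problem
x = ±(1, 0), y = ±1 with w_s = (2, 0): at the optimum the margin
constraint w = 1 is active and primal stationarity (2μ+1)·w = 2μ·2 + 2β
gives the closed form β = (1 − 2μ)/2 for μ < 1/2, w_t = (1, 0), b_t = 0.
"""

import numpy as np
import pytest

from sleeptransfer.tsvm import (
    DEFAULT_MU_GRID,
    LabeledDataset,
    SourceModel,
    TsvmConfig,
    decide,
    fit_one_vs_rest,
    fit_svm,
    fit_tsvm,
    load_model,
    primal_from_dual,
    primal_objective,
    bias_from_margin_sv,
    save_model,
    select_mu,
    solve_dual,
)

from _oracles import dual_qp_oracle, well_conditioned_qp_instance


def two_point(mu: float, w_s=(2.0, 0.0), C=10.0):
    data = LabeledDataset(X=np.array([[1.0, 0.0], [-1.0, 0.0]]), y=np.array([1.0, -1.0]))
    return data, SourceModel(w_s=np.asarray(w_s)), TsvmConfig(C_t=C, mu=mu)


class TestSolveDual:
    def test_symmetric_pair_without_transfer(self):
        data, _, cfg = two_point(mu=0.0, w_s=(0.0, 0.0))
        sol = solve_dual(data, SourceModel(np.zeros(2)), cfg)
        np.testing.assert_allclose(sol.beta, [0.5, 0.5], atol=1e-10)

    @pytest.mark.parametrize("mu", [0.1, 0.25, 0.4])
    def test_two_point_closed_form(self, mu):
        """beta = (1 - 2*mu)/2 from primal KKT; cross-checked with the QP oracle."""
        data, src, cfg = two_point(mu)
        sol = solve_dual(data, src, cfg)
        expected = (1.0 - 2.0 * mu) / 2.0
        np.testing.assert_allclose(sol.beta, [expected, expected], atol=1e-9)
        beta_o, obj_o = dual_qp_oracle(data, src, cfg)
        np.testing.assert_allclose(sol.beta, beta_o, atol=1e-7)
        assert sol.objective == pytest.approx(obj_o, abs=1e-9)

    def test_frozen_random_instance_matches_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.where(rng.uniform(size=20) < 0.5, 1.0, -1.0)
        data = LabeledDataset(X=X, y=y)
        src = SourceModel(w_s=rng.normal(size=3))
        cfg = TsvmConfig(C_t=1.0, mu=0.3)
        sol = solve_dual(data, src, cfg)
        beta_o, obj_o = dual_qp_oracle(data, src, cfg)
        np.testing.assert_allclose(sol.beta, beta_o, atol=1e-6)
        assert sol.objective == pytest.approx(obj_o, abs=1e-6)

    def test_dual_feasibility_on_random_instances(self, rng):
        """Box and equality constraints hold at tolerance for every solve."""
        for _ in range(10):
            data, src, cfg = well_conditioned_qp_instance(rng)
            sol = solve_dual(data, src, cfg)
            assert np.all(sol.beta >= -1e-12)
            assert np.all(sol.beta <= cfg.C_t + 1e-12)
            assert abs(sol.beta @ data.y) <= 1e-9
            assert sol.kkt_gap <= cfg.qp_tolerance

    def test_single_class_rejected(self):
        data = LabeledDataset(X=np.eye(3), y=np.ones(3))
        with pytest.raises(ValueError, match="both classes"):
            solve_dual(data, SourceModel(np.zeros(3)), TsvmConfig())


class TestPrimalRecovery:
    def test_zero_beta_shrinks_source(self):
        data, src, cfg = two_point(mu=1.0)
        sol = solve_dual(data, src, cfg)
        np.testing.assert_allclose(sol.beta, [0.0, 0.0], atol=1e-10)
        w = primal_from_dual(sol, data, src, cfg)
        np.testing.assert_allclose(w, (2.0 / 3.0) * src.w_s, atol=1e-9)

    def test_mu_zero_is_support_vector_expansion(self, rng):
        data, src, cfg = well_conditioned_qp_instance(rng)
        cfg = TsvmConfig(C_t=cfg.C_t, mu=0.0)
        sol = solve_dual(data, src, cfg)
        w = primal_from_dual(sol, data, src, cfg)
        np.testing.assert_allclose(w, data.X.T @ (sol.beta * data.y), atol=1e-12)

    def test_two_point_recovers_unit_weight(self):
        data, src, cfg = two_point(mu=0.25)
        sol = solve_dual(data, src, cfg)
        w = primal_from_dual(sol, data, src, cfg)
        np.testing.assert_allclose(w, [1.0, 0.0], atol=1e-9)


class TestBias:
    def test_symmetric_pair_zero_bias(self):
        data, src, cfg = two_point(mu=0.25)
        model = fit_tsvm(data, src, cfg)
        assert model.b_t == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance(self):
        """Shifting all x by c shifts b_t by -w_t . c (QP-oracle cross-check)."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 2))
        y = np.where(np.arange(12) % 2 == 0, 1.0, -1.0)
        src = SourceModel(w_s=np.array([0.5, -0.2]))
        cfg = TsvmConfig(C_t=1.0, mu=0.2)
        m0 = fit_tsvm(LabeledDataset(X, y), src, cfg)
        c = np.array([3.0, 0.0])
        m1 = fit_tsvm(LabeledDataset(X + c, y), src, cfg)
        # identical geometry: same weights, bias shifted by -w.c
        np.testing.assert_allclose(m1.w_t, m0.w_t, atol=1e-6)
        assert m1.b_t == pytest.approx(m0.b_t - float(m0.w_t @ c), abs=1e-6)

    def test_fallback_when_no_interior_multiplier(self, caplog):
        """mu = 1 drives both beta to 0 on the two-point problem; midpoint bias."""
        data, src, cfg = two_point(mu=1.0)
        sol = solve_dual(data, src, cfg)
        assert np.all(sol.beta <= cfg.sv_margin_tolerance * cfg.C_t)
        w = primal_from_dual(sol, data, src, cfg)
        import logging

        logging.getLogger("sleeptransfer.tsvm").setLevel(logging.WARNING)
        with caplog.at_level("WARNING", logger="sleeptransfer.tsvm"):
            b = bias_from_margin_sv(sol, data, w, cfg)
        logging.getLogger("sleeptransfer.tsvm").setLevel(logging.ERROR)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert any("fallback" in r.message for r in caplog.records)


class TestDecide:
    def test_basic_scores(self):
        from sleeptransfer.tsvm import TargetModel

        m = TargetModel(w_t=np.array([1.0, 0.0]), b_t=0.0)
        labels, g = decide(m, np.array([[3.0, 5.0]]))
        assert labels[0] == 1.0 and g[0] == 3.0

    def test_hyperplane_tie_goes_positive(self):
        from sleeptransfer.tsvm import TargetModel

        m = TargetModel(w_t=np.array([1.0, 0.0]), b_t=-2.0)
        labels, g = decide(m, np.array([[2.0, 7.0]]))
        assert g[0] == 0.0 and labels[0] == 1.0

    def test_matches_direct_sign_oracle(self, rng):
        from sleeptransfer.tsvm import TargetModel

        w, b = rng.normal(size=4), 0.3
        m = TargetModel(w_t=w, b_t=b)
        X = rng.normal(size=(100, 4))
        labels, g = decide(m, X)
        expected = np.where(X @ w + b >= 0.0, 1.0, -1.0)
        np.testing.assert_array_equal(labels, expected)


class TestFitSvm:
    def test_two_point(self):
        data, _, _ = two_point(mu=0.0)
        m = fit_svm(data, TsvmConfig(C_t=10.0))
        np.testing.assert_allclose(m.w_t, [1.0, 0.0], atol=1e-9)
        assert m.b_t == pytest.approx(0.0, abs=1e-9)

    def test_mu_zero_ignores_source(self, rng):
        data, src, cfg = well_conditioned_qp_instance(rng)
        cfg0 = TsvmConfig(C_t=cfg.C_t, mu=0.0)
        a = fit_tsvm(data, src, cfg0)
        b = fit_tsvm(data, SourceModel(np.zeros(data.X.shape[1])), cfg0)
        assert np.max(np.abs(a.w_t - b.w_t)) < 1e-8

    def test_matches_reference_svm_on_separable_data(self):
        """Weights/margin/labels agree with scikit-learn's linear SVC oracle."""
        SVC = pytest.importorskip("sklearn.svm").SVC
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal((2, 2), 0.5, size=(25, 2)), rng.normal((-2, -2), 0.5, size=(25, 2))]
        )
        y = np.concatenate([np.ones(25), -np.ones(25)])
        m = fit_svm(LabeledDataset(X, y), TsvmConfig(C_t=1.0))
        svc = SVC(kernel="linear", C=1.0, tol=1e-10).fit(X, y)
        margin_ours = 2.0 / np.linalg.norm(m.w_t)
        margin_ref = 2.0 / np.linalg.norm(svc.coef_[0])
        assert margin_ours == pytest.approx(margin_ref, abs=1e-4)
        grid = rng.normal(size=(200, 2)) * 3.0
        ours, _ = decide(m, grid)
        np.testing.assert_array_equal(ours, svc.predict(grid))


class TestFitTsvm:
    def test_complementary_slackness(self, rng):
        """beta=0 points satisfy the margin; beta=C points are at or inside it."""
        for _ in range(5):
            data, src, cfg = well_conditioned_qp_instance(rng)
            sol = solve_dual(data, src, cfg)
            model = fit_tsvm(data, src, cfg)
            margins = data.y * (data.X @ model.w_t + model.b_t)
            tol = 1e-5
            assert np.all(margins[sol.beta < 1e-9] >= 1.0 - tol)
            assert np.all(margins[sol.beta > cfg.C_t - 1e-9] <= 1.0 + tol)

    def test_strong_duality_gap_vanishes(self, rng):
        """Primal objective + printed dual minimum == 0 (the dual is its negation)."""
        for _ in range(8):
            data, src, cfg = well_conditioned_qp_instance(rng)
            sol = solve_dual(data, src, cfg)
            model = fit_tsvm(data, src, cfg)
            assert primal_objective(model, data, src) + sol.objective == pytest.approx(
                0.0, abs=1e-5
            )

    def test_transfer_shrinkage_toward_source(self):
        """||w_t - w_s|| decreases with mu and obeys the dual-norm bound."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(16, 4))
        y = np.where(np.arange(16) % 2 == 0, 1.0, -1.0)
        data = LabeledDataset(X, y)
        src = SourceModel(w_s=rng.normal(size=4))
        C = 1.0
        dists = []
        for mu in (1.0, 10.0, 100.0, 1000.0):
            m = fit_tsvm(data, src, TsvmConfig(C_t=C, mu=mu))
            dist = float(np.linalg.norm(m.w_t - src.w_s))
            bound = (C * np.linalg.norm(X, axis=1).sum() + np.linalg.norm(src.w_s)) / (
                2.0 * mu + 1.0
            )
            assert dist <= bound + 1e-9
            dists.append(dist)
        assert dists == sorted(dists, reverse=True)
        assert dists[-1] < 1e-2


class TestSelectMu:
    def test_tie_breaks_toward_weak_transfer(self):
        """With a perfectly informative source every mu wins; smallest is returned."""
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(3, 0.3, size=(10, 2)), rng.normal(-3, 0.3, size=(10, 2))])
        y = np.concatenate([np.ones(10), -np.ones(10)])
        data = LabeledDataset(X, y)
        src = SourceModel(w_s=np.array([1.0, 1.0]))
        mu = select_mu(data, data, src, TsvmConfig(C_t=1.0))
        assert mu == min(DEFAULT_MU_GRID)

    def test_adversarial_source_gets_smallest_mu(self):
        """A negated source weight hurts at any mu > 0; grid picks the minimum."""
        rng = np.random.default_rng(4)
        w_true = np.array([1.0, -0.5, 2.0])
        X = rng.normal(size=(200, 3))
        # keep a clean margin so the task is noiseless-separable: small mu
        # ties at perfect accuracy, large mu is dragged toward -w_true
        keep = np.abs(X @ w_true) > 0.5
        X = X[keep]
        y = np.where(X @ w_true > 0, 1.0, -1.0)
        half = X.shape[0] // 2
        train = LabeledDataset(X[:half], y[:half])
        val = LabeledDataset(X[half:], y[half:])
        mu = select_mu(train, val, SourceModel(w_s=-100.0 * w_true), TsvmConfig(C_t=1.0))
        assert mu == min(DEFAULT_MU_GRID)

    def test_informative_source_prefers_transfer(self):
        """With 5 labeled points and a good source, mu > min grid in >=80% of runs."""
        w_true = np.array([1.5, -1.0, 0.5, 0.2])
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            Xl = rng.normal(size=(10, 4))
            yl = np.where(Xl @ w_true + rng.normal(0, 0.3, 10) > 0, 1.0, -1.0)
            Xv = rng.normal(size=(40, 4))
            yv = np.where(Xv @ w_true + rng.normal(0, 0.3, 40) > 0, 1.0, -1.0)
            if abs(yl[:5].sum()) == 5 or abs(yv.sum()) == 40:
                wins += 1  # single-class draw carries no information; skip
                continue
            mu = select_mu(
                LabeledDataset(Xl[:5].repeat(2, 0), yl[:5].repeat(2, 0)),
                LabeledDataset(Xv, yv),
                SourceModel(w_s=w_true),
                TsvmConfig(C_t=1.0),
            )
            if mu > min(DEFAULT_MU_GRID):
                wins += 1
        assert wins >= 0.8 * n_rep


class TestOneVsRest:
    def test_two_class_reduces_to_binary(self, rng):
        X = np.vstack([rng.normal(2, 1, size=(20, 3)), rng.normal(-2, 1, size=(20, 3))])
        labels = ["N2"] * 20 + ["W"] * 20
        cfg = TsvmConfig(C_t=1.0)
        ovr = fit_one_vs_rest(X, labels, None, cfg)
        binary = fit_svm(
            LabeledDataset(X, np.where(np.asarray(labels) == "N2", 1.0, -1.0)), cfg
        )
        pred_ovr = ovr.predict(X)
        pred_bin, _ = decide(binary, X)
        expected = ["N2" if p > 0 else "W" for p in pred_bin]
        assert pred_ovr == expected

    def test_separated_blobs_perfect_training_accuracy(self, rng):
        centers = {"W": (5, 0), "N2": (-5, 0), "N3": (0, 5)}
        X, labels = [], []
        for c, mu_c in centers.items():
            X.append(rng.normal(mu_c, 0.4, size=(15, 2)))
            labels += [c] * 15
        X = np.vstack(X)
        ovr = fit_one_vs_rest(X, labels, None, TsvmConfig(C_t=10.0))
        assert ovr.predict(X) == labels

    def test_argmax_matches_per_class_scores(self, rng):
        X = rng.normal(size=(30, 3))
        labels = (["W", "N2", "REM"] * 10)[:30]
        ovr = fit_one_vs_rest(X, labels, None, TsvmConfig(C_t=1.0))
        scores = ovr.decision_scores(X)
        for i, pred in enumerate(ovr.predict(X)):
            assert pred == ovr.classes[int(np.argmax(scores[i]))]

    def test_model_json_round_trip(self, tmp_path, rng):
        from sleeptransfer.features import feature_names
        from sleeptransfer.tsvm import Standardizer

        X = rng.normal(size=(30, 32))
        labels = (["W", "N2", "N3"] * 10)[:30]
        std = Standardizer().fit(X)
        ovr = fit_one_vs_rest(std.transform(X), labels, None, TsvmConfig(C_t=1.0))
        path = tmp_path / "model.json"
        save_model(path, ovr, std, feature_names())
        back, std2, names = load_model(path)
        assert back.classes == ovr.classes
        assert names == feature_names()
        np.testing.assert_array_equal(std2.mean, std.mean)
        assert back.predict(std2.transform(X)) == ovr.predict(std.transform(X))
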