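"""Linear-SVM classification, RFE, grouped validation, projection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, spearmanr

from slowwave.classify import (
    compare_projection_distributions,
    cross_validate,
    fit_linear_svm,
    label_pathway_from_light_response,
    leave_one_animal_out,
    project_to_hypervector,
    rfe_rank,
)


def two_gaussians(n, d=2.0, p_dims=1, seed=0):
    rng = np.random.default_rng(seed)
    X = np.r_[rng.normal(-d / 2, 1, (n, p_dims)), rng.normal(d / 2, 1, (n, p_dims))]
    y = np.r_[np.zeros(n), np.ones(n)]
    return X, y


class TestFit:
    def test_separable_clusters(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal([-2, 0], 0.1, (20, 2)), rng.normal([2, 0], 0.1, (20, 2))]
        y = np.r_[np.zeros(20), np.ones(20)]
        m = fit_linear_svm(X, y)
        assert np.mean(m.predict(X) == y) == 1.0

    def test_label_swap_negates_weights(self):
        X, y = two_gaussians(200, seed=1)
        m1 = fit_linear_svm(X, y)
        m2 = fit_linear_svm(X, 1 - y)
        assert np.allclose(m1.weights, -m2.weights, atol=1e-3)
        assert np.isclose(m1.intercept, -m2.intercept, atol=1e-3)

    def test_bayes_rate_on_gaussian_problem(self):
        X, y = two_gaussians(1000, seed=2)
        Xte, yte = two_gaussians(2000, seed=3)
        m = fit_linear_svm(X, y)
        acc = np.mean(m.predict(Xte) == yte)
        assert abs(acc - norm.cdf(1.0)) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_svm(np.random.default_rng(0).normal(0, 1, (10, 2)),
                           np.zeros(10))

    def test_json_round_trip(self, tmp_path):
        X, y = two_gaussians(50, seed=4)
        m = fit_linear_svm(pd.DataFrame(X, columns=["a"]), y)
        path = tmp_path / "model.json"
        m.to_json(path)
        from slowwave.classify import LinearClassifier
        m2 = LinearClassifier.from_json(path)
        assert np.allclose(m.weights, m2.weights)
        assert m.feature_names == m2.feature_names


class TestCrossValidate:
    def test_separable_data_perfect_every_fold(self):
        rng = np.random.default_rng(5)
        X = np.r_[rng.normal(-5, 0.2, (30, 1)), rng.normal(5, 0.2, (30, 1))]
        y = np.r_[np.zeros(30), np.ones(30)]
        mu, sd, accs = cross_validate(X, y, k=10, seed=0)
        assert mu == 1.0 and sd == 0.0

    def test_seed_reproducibility(self):
        X, y = two_gaussians(40, seed=6)
        r1 = cross_validate(X, y, k=5, seed=9)
        r2 = cross_validate(X, y, k=5, seed=9)
        assert np.allclose(r1[2], r2[2])

    def test_chance_level_on_identical_distributions(self):
        accs = []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (60, 3))
            y = np.r_[np.zeros(30), np.ones(30)]
            accs.append(cross_validate(X, y, k=5, seed=seed)[0])
        mean = np.mean(accs)
        half = 1.96 * np.std(accs) / np.sqrt(len(accs))
        assert mean - half - 0.02 < 0.5 < mean + half + 0.02

    def test_k_larger_than_class_rejected(self):
        X, y = two_gaussians(5, seed=7)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=10)


class TestRfe:
    def test_informative_feature_ranked_first(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.c_[np.r_[rng.normal(-1, 1, 100), rng.normal(1, 1, 100)],
                      rng.normal(0, 1, (200, 5))]
            y = np.r_[np.zeros(100), np.ones(100)]
            res = rfe_rank(pd.DataFrame(X, columns=[f"x{i}" for i in range(6)]),
                           y, compute_curve=False)
            wins += res.ranking[0] == "x0"
        assert wins >= 19

    def test_duplicated_informative_features_beat_noise(self):
        above = 0
        for seed in range(10):
            rng = np.random.default_rng(seed + 50)
            signal = np.r_[rng.normal(-1, 1, 100), rng.normal(1, 1, 100)]
            X = np.c_[signal, signal + rng.normal(0, 0.05, 200),
                      rng.normal(0, 1, (200, 4))]
            y = np.r_[np.zeros(100), np.ones(100)]
            res = rfe_rank(pd.DataFrame(X, columns=list("abcdef")), y,
                           compute_curve=False)
            above += set(res.ranking[:2]) == {"a", "b"}
        assert above >= 8

    def test_curve_length_and_ranking_permutation(self):
        X, y = two_gaussians(30, p_dims=4, seed=8)
        cols = [f"x{i}" for i in range(4)]
        res = rfe_rank(pd.DataFrame(X, columns=cols), y, k=5, seed=0)
        assert sorted(res.ranking) == sorted(cols)
        assert res.accuracy_curve.size == 4
        assert np.all((res.accuracy_curve >= 0) & (res.accuracy_curve <= 1))


class TestLeaveOneAnimalOut:
    def test_predictable_labels_all_correct(self):
        rng = np.random.default_rng(9)
        X = np.r_[rng.normal(-3, 0.3, (12, 2)), rng.normal(3, 0.3, (12, 2))]
        y = np.array(["a"] * 12 + ["b"] * 12)
        animals = np.tile(["m1", "m2", "m3"], 8)
        table, acc, flagged = leave_one_animal_out(X, y, animals)
        assert acc == 1.0
        assert not flagged
        assert len(table) == 24

    def test_held_out_cells_cannot_leak(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, (30, 3))
        y = np.r_[np.zeros(15), np.ones(15)]
        animals = np.repeat(["m1", "m2", "m3"], 10)
        X2 = X.copy()
        X2[animals == "m1"] += 100.0   # perturb held-out cells only
        names = ["x0", "x1", "x2"]
        m_ref = fit_linear_svm(pd.DataFrame(X[animals != "m1"], columns=names),
                               y[animals != "m1"])
        m_pert = fit_linear_svm(pd.DataFrame(X2[animals != "m1"], columns=names),
                                y[animals != "m1"])
        # the fold that holds out m1 trains on identical data either way,
        # so its standardizer and weights cannot depend on m1's cells
        assert np.allclose(m_ref.weights, m_pert.weights)
        assert np.allclose(m_ref.mean, m_pert.mean)
        assert np.allclose(m_ref.scale, m_pert.scale)

    def test_single_class_animal_flagged(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (12, 2))
        y = np.r_[np.zeros(6), np.ones(6)]
        animals = np.array(["m1"] * 6 + ["m2"] * 3 + ["m3"] * 3)
        _, _, flagged = leave_one_animal_out(X, y, animals)
        assert "m1" in flagged

    def test_batch_offsets_close_to_kfold(self):
        rng = np.random.default_rng(12)
        n_animals, cells = 8, 6
        X, y, animals = [], [], []
        for a in range(n_animals):
            offset = rng.normal(0, 0.5, 2)
            for c in range(cells):
                label = (a * cells + c) % 2
                X.append(rng.normal((label * 2 - 1) * 1.5, 1, 2) + offset)
                y.append(label)
                animals.append(f"m{a}")
        X = np.asarray(X)
        y = np.asarray(y)
        _, loao_acc, _ = leave_one_animal_out(X, y, np.asarray(animals))
        kfold_acc, _, _ = cross_validate(X, y, k=10, seed=0)
        assert abs(loao_acc - kfold_acc) <= 0.10


class TestProjection:
    def test_sign_reproduces_prediction(self):
        X, y = two_gaussians(40, p_dims=3, seed=13)
        m = fit_linear_svm(X, y)
        res = project_to_hypervector(m, X, labels=y)
        pred = m.predict(X)
        assert np.array_equal(res.projections > 0, pred == m.classes[1])

    def test_rank_correlation_with_decision_values(self):
        X, y = two_gaussians(40, p_dims=3, seed=14)
        m = fit_linear_svm(X, y)
        res = project_to_hypervector(m, X)
        rho, _ = spearmanr(res.projections, m.decision_function(X))
        assert rho == pytest.approx(1.0)

    def test_mixture_group_is_indistinguishable_from_pool(self):
        ok = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            A = rng.normal(-1, 1, (17, 3))
            B = rng.normal(1, 1, (17, 3))
            pick = rng.random(17) < 0.5
            M = np.where(pick[:, None], rng.normal(-1, 1, (17, 3)),
                         rng.normal(1, 1, (17, 3)))
            m = fit_linear_svm(np.r_[A, B], np.r_[np.zeros(17), np.ones(17)])
            pool = project_to_hypervector(m, np.r_[A, B]).projections
            mix = project_to_hypervector(m, M).projections
            ok += compare_projection_distributions(mix, pool) > 0.05
        assert ok / n_seeds >= 0.9

    def test_shifted_distributions_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            a = rng.normal(0, 1, 30)
            b = rng.normal(2, 1, 30)
            hits += compare_projection_distributions(a, b) < 0.01
        assert hits >= 19

    def test_identical_samples_give_p_one(self):
        x = np.arange(10.0)
        assert compare_projection_distributions(x, x) == pytest.approx(1.0)


class TestOptotagging:
    def test_step_response_labeled_indirect(self):
        rate = 20000.0
        t = np.arange(0, 0.05, 1 / rate)
        trials = np.tile(-70.0, (10, t.size))
        on = int(0.02 * rate)
        lat = int(0.002 * rate)
        trials[:, on + lat:] += 13.0
        assert label_pathway_from_light_response(trials, rate, 0.02) == "indirect"

    def test_flat_response_labeled_direct(self):
        rate = 20000.0
        rng = np.random.default_rng(15)
        trials = -70 + rng.normal(0, 0.3, (10, 1000))
        assert label_pathway_from_light_response(trials, rate, 0.02) == "putative_direct"
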