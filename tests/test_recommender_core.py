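import numpy as np
import pandas as pd
import pytest

from perspect.recommender_core import (
    FactorModelConfig,
    KnnConfig,
    NormalWishartPrior,
    PmfConfig,
    PosteriorSamples,
    baseline_predict,
    fit_bpmf,
    fit_pmf,
    infer_new_user,
    knn_predict,
    predict,
    predict_new_user,
)
from perspect.synthetic_data import GeneratorConfig, RatingDataset, generate_ratings

from conftest import constant_dataset


def manual_model(user_factors, item_factors, offset=3.0, hyper_precision_scale=1.0, alpha=2.0):
    """Hand-built posterior 'samples' for closed-form checks."""
    U = np.asarray(user_factors, dtype=float)  # (S, N, D)
    V = np.asarray(item_factors, dtype=float)
    S, _, D = U.shape
    return PosteriorSamples(
        user_factors=U,
        item_factors=V,
        user_hyper_mean=np.zeros((S, D)),
        user_hyper_precision=np.tile(hyper_precision_scale * np.eye(D), (S, 1, 1)),
        global_offset=offset,
        user_index={f"u{i}": i for i in range(U.shape[1])},
        message_index={f"m{j}": j for j in range(V.shape[1])},
        config=FactorModelConfig(latent_dim=D, noise_precision=alpha, n_samples=S, burn_in=0),
    )


class TestPredict:
    def test_single_sample_inner_product(self):
        model = manual_model([[[1.0, 0.0]]], [[[1.0, 0.0]]], offset=3.0)
        assert predict(model, "u0", "m0") == pytest.approx(4.0)

    def test_clipping_at_scale_top(self):
        model = manual_model([[[3.0, 0.0]]], [[[3.0, 0.0]]], offset=3.0)
        assert predict(model, "u0", "m0") == 5.0

    def test_multi_sample_equals_per_sample_loop(self, rng):
        U = rng.normal(size=(7, 3, 2))
        V = rng.normal(size=(7, 4, 2))
        model = manual_model(U, V, offset=3.0)
        got = predict(model, "u1", "m2")
        per_sample = [U[s, 1] @ V[s, 2] + 3.0 for s in range(7)]
        assert got == pytest.approx(np.clip(np.mean(per_sample), 1, 5))

    def test_unknown_ids_rejected(self):
        model = manual_model([[[1.0, 0.0]]], [[[1.0, 0.0]]])
        with pytest.raises(KeyError):
            predict(model, "ghost", "m0")
        with pytest.raises(KeyError):
            predict(model, "u0", "ghost")


class TestFitBpmf:
    def test_constant_data_predicts_the_constant(self):
        data = constant_dataset(3)
        model = fit_bpmf(data, FactorModelConfig(latent_dim=2, n_samples=60, burn_in=20, seed=0))
        preds = [predict(model, u, m) for u in data.users for m in data.messages]
        assert all(2.9 <= p <= 3.1 for p in preds)

    def test_same_seed_identical_samples(self, small_dataset):
        data, _ = small_dataset
        cfg = FactorModelConfig(latent_dim=2, n_samples=10, burn_in=5, seed=11)
        a = fit_bpmf(data, cfg)
        b = fit_bpmf(data, cfg)
        np.testing.assert_array_equal(a.user_factors, b.user_factors)
        np.testing.assert_array_equal(a.item_factors, b.item_factors)

    def test_unrated_entity_rejected(self):
        df = pd.DataFrame({"user": ["a", "b"], "message": ["m1", "m2"], "rating": [3, 4]})
        data = RatingDataset(df)
        # every user/message has one rating here; drop one user's rows via subset
        sub = data.subset_users(["a"])
        assert fit_bpmf(sub, FactorModelConfig(latent_dim=1, n_samples=2, burn_in=0)) is not None
        empty = pd.DataFrame({"user": [], "message": [], "rating": []})
        with pytest.raises(ValueError):
            fit_bpmf(RatingDataset(empty, validate=False), FactorModelConfig())

    def test_predictions_within_rating_scale(self, small_bpmf, small_dataset):
        data, _ = small_dataset
        preds = [predict(small_bpmf, u, data.messages[0]) for u in data.users]
        assert all(1.0 <= p <= 5.0 for p in preds)

    def test_heldout_rmse_near_noise_floor_on_noise_free_continuous_data(self, rng):
        """Strong-generalization recovery: noise-free data, RMSE under 0.15."""
        N, M, D, s = 150, 60, 2, 0.5
        U = rng.normal(0, s, (N, D))
        V = rng.normal(0, s, (M, D))
        rows = []
        for i in range(N):
            for j in rng.choice(M, 20, replace=False):
                rows.append((f"u{i}", f"m{j}", float(np.clip(3.0 + U[i] @ V[j], 1, 5))))
        df = pd.DataFrame(rows, columns=["user", "message", "rating"])
        train = RatingDataset(df[df.user.str[1:].astype(int) < 120])
        model = fit_bpmf(
            train,
            FactorModelConfig(latent_dim=2, noise_precision=16.0, n_samples=60, burn_in=40, seed=1),
        )
        sq = []
        for i in range(120, 150):
            ur = df[df.user == f"u{i}"].reset_index(drop=True)
            obs = {
                m: r
                for m, r in zip(ur.message[:16], ur.rating[:16])
                if m in model.message_index
            }
            u = infer_new_user(model, obs)
            held = [m for m in ur.message[16:] if m in model.message_index]
            preds = predict_new_user(model, u, held)
            actual = dict(zip(ur.message, ur.rating))
            sq += [(p - actual[m]) ** 2 for m, p in zip(held, preds)]
        assert np.sqrt(np.mean(sq)) < 0.15


class TestInferNewUser:
    def test_no_observations_fall_back_to_offset(self, small_bpmf):
        u = infer_new_user(small_bpmf, {})
        np.testing.assert_array_equal(u, 0.0)
        preds = predict_new_user(small_bpmf, u, list(small_bpmf.message_index)[:5])
        np.testing.assert_allclose(preds, small_bpmf.global_offset)

    def test_shrinkage_keeps_prediction_between_offset_and_observation(self):
        model = manual_model([[[0.0]]], [[[1.0], [1.0]]], offset=3.0)
        u = infer_new_user(model, {"m0": 5.0})
        pred = predict_new_user(model, u, ["m0"])[0]
        assert 3.0 < pred < 5.0

    def test_matches_scalar_ridge_closed_form(self):
        """D=1, one sample, all item factors = 2: u* = a*sum(v*(r-mu)) / (lam + a*sum(v^2))."""
        alpha, lam, offset = 2.0, 3.0, 3.0
        model = manual_model(
            [[[0.0]]], [[[2.0], [2.0], [2.0]]], offset=offset,
            hyper_precision_scale=lam, alpha=alpha,
        )
        observed = {"m0": 5.0, "m1": 4.0}
        expected = alpha * sum(2.0 * (r - offset) for r in observed.values()) / (
            lam + alpha * 2.0**2 * len(observed)
        )
        u = infer_new_user(model, observed)
        assert u[0, 0] == pytest.approx(expected)

    def test_unknown_message_rejected(self, small_bpmf):
        with pytest.raises(KeyError):
            infer_new_user(small_bpmf, {"ghost": 4.0})


class TestFitPmf:
    def test_constant_data(self):
        model = fit_pmf(constant_dataset(3), PmfConfig(latent_dim=2, seed=0))
        preds = [model.predict(u, m) for u in model.user_index for m in model.message_index]
        assert np.allclose(preds, 3.0, atol=0.05)

    def test_objective_monotone_non_increasing(self, small_dataset):
        data, _ = small_dataset
        model = fit_pmf(data, PmfConfig(latent_dim=3, seed=1))
        hist = model.objective_history
        assert len(hist) >= 2
        assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_heldout_rmse_within_ten_percent_of_bpmf(self):
        """PMF and BPMF share the generator oracle; their accuracy is close."""
        data, _ = generate_ratings(
            GeneratorConfig(n_users=120, n_messages=50, ratings_per_user=20, seed=21)
        )
        train = data.subset_users(data.users[:100])
        test_users = data.users[100:]
        bp = fit_bpmf(train, FactorModelConfig(latent_dim=2, n_samples=50, burn_in=30, seed=2))
        pm = fit_pmf(train, PmfConfig(latent_dim=2, regularization=2.0, seed=2))
        errs = {"bpmf": [], "pmf": []}
        for u in test_users:
            ur = data.user_ratings(u).reset_index(drop=True)
            obs = {
                m: float(r)
                for m, r in zip(ur.message[:16], ur.rating[:16])
                if m in bp.message_index
            }
            held = [m for m in ur.message[16:] if m in bp.message_index]
            actual = {m: float(r) for m, r in zip(ur.message, ur.rating)}
            pb = predict_new_user(bp, infer_new_user(bp, obs), held)
            pp = pm.predict_new_user(pm.infer_new_user(obs), held)
            errs["bpmf"] += [(p - actual[m]) ** 2 for m, p in zip(held, pb)]
            errs["pmf"] += [(p - actual[m]) ** 2 for m, p in zip(held, pp)]
        rmse_b = np.sqrt(np.mean(errs["bpmf"]))
        rmse_p = np.sqrt(np.mean(errs["pmf"]))
        assert rmse_p <= 1.10 * rmse_b


class TestKnn:
    def test_perfect_twin_neighbor(self):
        rows = [
            ("a", "m1", 2), ("a", "m2", 4), ("a", "m3", 3), ("a", "m4", 5),
            ("b", "m1", 2), ("b", "m2", 4), ("b", "m3", 3), ("b", "m4", 5), ("b", "m5", 3.5),
        ]
        data = RatingDataset(pd.DataFrame(rows, columns=["user", "message", "rating"]))
        pred = knn_predict(data, KnnConfig(k=5, min_overlap=2), "a", "m5")
        assert pred == pytest.approx(3.5)

    def test_no_overlap_falls_back_to_message_mean(self):
        rows = [
            ("a", "m1", 2), ("a", "m2", 4),
            ("b", "m3", 5), ("c", "m3", 3), ("c", "m4", 1), ("b", "m4", 2),
        ]
        data = RatingDataset(pd.DataFrame(rows, columns=["user", "message", "rating"]))
        pred = knn_predict(data, KnnConfig(k=3, min_overlap=2), "a", "m3")
        assert pred == pytest.approx(4.0)  # mean of 5 and 3

    def test_matches_brute_force_oracle_on_toy_matrix(self, rng):
        # 5 users x 6 messages, ~70% observed
        rows = []
        mat = {}
        for i in range(5):
            for j in range(6):
                if rng.random() < 0.7:
                    r = int(rng.integers(1, 6))
                    rows.append((f"u{i}", f"m{j}", r))
                    mat[(i, j)] = r
        data = RatingDataset(pd.DataFrame(rows, columns=["user", "message", "rating"]))
        cfg = KnnConfig(k=2, min_overlap=2)

        def oracle(target, j):
            def vals(i):
                return {jj: r for (ii, jj), r in mat.items() if ii == i}

            tv = vals(target)
            sims = []
            for i in range(5):
                if i == target or (i, j) not in mat:
                    continue
                common = set(tv) & set(vals(i))
                if len(common) < cfg.min_overlap:
                    continue
                x = np.array([tv[c] for c in sorted(common)], dtype=float)
                y = np.array([vals(i)[c] for c in sorted(common)], dtype=float)
                if x.std() == 0 or y.std() == 0:
                    continue
                sims.append((float(np.corrcoef(x, y)[0, 1]), i))
            sims.sort(key=lambda t: (-t[0], t[1]))
            top = sims[: cfg.k]
            tmean = np.mean(list(tv.values()))
            if top and sum(abs(s) for s, _ in top) > 0:
                num = sum(s * (mat[(i, j)] - np.mean(list(vals(i).values()))) for s, i in top)
                return float(np.clip(tmean + num / sum(abs(s) for s, _ in top), 1, 5))
            col = [r for (ii, jj), r in mat.items() if jj == j]
            return float(np.clip(np.mean(col), 1, 5))

        for i in range(5):
            for j in range(6):
                if (i, j) in mat:
                    continue
                if f"m{j}" not in data.message_index or f"u{i}" not in data.user_index:
                    continue
                got = knn_predict(data, cfg, f"u{i}", f"m{j}")
                assert got == pytest.approx(oracle(i, j)), (i, j)


class TestBaselines:
    def test_global_mean(self):
        rows = [("a", "m1", 4), ("a", "m2", 4), ("b", "m1", 5)]
        data = RatingDataset(pd.DataFrame(rows, columns=["user", "message", "rating"]))
        assert baseline_predict(data, "GLOBAL_MEAN") == pytest.approx(13 / 3)

    def test_message_mean_fallback_to_global(self):
        rows = [("a", "m1", 4), ("b", "m1", 2)]
        data = RatingDataset(pd.DataFrame(rows, columns=["user", "message", "rating"]))
        assert baseline_predict(data, "MESSAGE_MEAN", message="m9") == pytest.approx(3.0)

    def test_user_mean_matches_recomputation(self, small_dataset):
        data, _ = small_dataset
        by_user = data.triplets.groupby("user")["rating"].mean()
        for u in data.users[:10]:
            assert baseline_predict(data, "USER_MEAN", user=u) == pytest.approx(by_user[u])

    def test_unknown_mode_rejected(self, small_dataset):
        data, _ = small_dataset
        with pytest.raises(ValueError):
            baseline_predict(data, "MEDIAN")


class TestPersistence:
    def test_save_load_roundtrip(self, small_bpmf, tmp_path):
        path = tmp_path / "model.npz"
        small_bpmf.save(path)
        again = PosteriorSamples.load(path)
        np.testing.assert_array_equal(again.user_factors, small_bpmf.user_factors)
        np.testing.assert_array_equal(again.item_factors, small_bpmf.item_factors)
        assert again.global_offset == small_bpmf.global_offset
        assert again.message_index == small_bpmf.message_index
        # loaded model still serves cold-start inference
        u = infer_new_user(again, dict(list({m: 4.0 for m in again.message_index}.items())[:3]))
        assert u.shape == (again.sample_count, again.latent_dim)
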