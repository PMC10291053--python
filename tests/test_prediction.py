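"""Feature-matrix assembly, outlier masking, chained imputation, importance
selection, and the leave-one-film-out protocol."""

import numpy as np
import pandas as pd
import pytest

from filmphysio import (
    assemble_matrix,
    impute_chained,
    lofo_evaluate,
    mask_outliers,
    permuted_label_auc,
    prepare_folds,
    select_features,
)
from filmphysio.prediction import binary_labels, feature_columns


def _toy_matrix(n_subjects=6, n_films=4, n_features=8, seed=0, signal=0.0):
    """Small subject x film matrix with Gaussian features; optionally one
    feature carries ``signal`` x rating."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for f in range(n_films):
            rating = int(rng.integers(1, 11))
            feats = {f"feat{j}": rng.standard_normal() for j in range(n_features)}
            if signal:
                feats["feat0"] = signal * rating + 0.1 * rng.standard_normal()
            rows.append({"subject_id": f"s{s}", "film_id": f"f{f}", "genre": "comedy",
                         "rating": rating, **feats})
    return pd.DataFrame(rows)


class TestAssemble:
    def test_row_count_products(self):
        rows = [
            {"subject_id": f"s{s}", "film_id": f"f{f}", "genre": "drama", "rating": 5, "x": 0.0}
            for s in range(2) for f in range(3)
        ]
        assert len(assemble_matrix(rows)) == 6

    def test_duplicate_rows_rejected(self):
        rows = [{"subject_id": "a", "film_id": "b", "genre": "drama", "rating": 5, "x": 1.0}] * 2
        with pytest.raises(ValueError, match="duplicated"):
            assemble_matrix(rows)

    def test_missing_stream_gives_nan_cells_row_retained(self):
        rows = [
            {"subject_id": "a", "film_id": "f1", "genre": "drama", "rating": 5, "x": 1.0, "y": 2.0},
            {"subject_id": "a", "film_id": "f2", "genre": "drama", "rating": 6, "x": 1.5},
        ]
        m = assemble_matrix(rows)
        assert len(m) == 2
        assert np.isnan(m.loc[m["film_id"] == "f2", "y"]).all()


class TestMaskOutliers:
    def test_single_extreme_value_masked(self):
        m = _toy_matrix()
        m.loc[0, "feat1"] = 1e3
        masked, _ = mask_outliers(m)
        assert np.isnan(masked.loc[0, "feat1"])
        assert masked["feat2"].notna().all()

    def test_gaussian_mask_rate_matches_tail_mass(self):
        from scipy.stats import norm
        rng = np.random.default_rng(1)
        n = 100_000
        m = pd.DataFrame({
            "subject_id": "s", "film_id": [f"f{i}" for i in range(n)],
            "genre": "comedy", "rating": 5, "x": rng.standard_normal(n),
        })
        masked, _ = mask_outliers(m)
        rate = masked["x"].isna().mean()
        assert rate == pytest.approx(2 * norm.sf(3), rel=0.2)

    def test_constant_column_untouched(self):
        m = _toy_matrix()
        m["feat3"] = 1.0
        masked, _ = mask_outliers(m)
        assert masked["feat3"].notna().all()

    def test_rating_and_ids_never_masked(self):
        m = _toy_matrix()
        m.loc[0, "rating"] = 10
        masked, _ = mask_outliers(m)
        assert masked["rating"].notna().all()


class TestImputeChained:
    def test_complete_matrix_unchanged(self):
        m = _toy_matrix()
        out = impute_chained(m)
        pd.testing.assert_frame_equal(out, m)

    def test_perfectly_correlated_partner_recovers_exactly(self):
        rng = np.random.default_rng(2)
        n = 60
        a = rng.standard_normal(n)
        m = pd.DataFrame({
            "subject_id": "s", "film_id": [f"f{i}" for i in range(n)],
            "genre": "c", "rating": 5, "a": a, "b": a.copy(), "c": rng.standard_normal(n),
        })
        truth = m["b"].copy()
        miss = rng.choice(n, size=6, replace=False)
        m.loc[miss, "b"] = np.nan
        out = impute_chained(m, seed=0)
        np.testing.assert_allclose(out.loc[miss, "b"], truth[miss], atol=1e-6)

    def test_mcar_rmse_below_column_sd(self):
        rng = np.random.default_rng(3)
        n, p = 120, 6
        latent = rng.standard_normal(n)
        X = latent[:, None] + 0.5 * rng.standard_normal((n, p))
        m = pd.DataFrame(X, columns=[f"v{j}" for j in range(p)])
        m.insert(0, "rating", 5)
        m.insert(0, "genre", "c")
        m.insert(0, "film_id", [f"f{i}" for i in range(n)])
        m.insert(0, "subject_id", "s")
        truth = m["v0"].copy()
        miss = rng.random(n) < 0.10
        m.loc[miss, "v0"] = np.nan
        out = impute_chained(m, seed=1)
        rmse = np.sqrt(np.mean((out.loc[miss, "v0"] - truth[miss]) ** 2))
        assert rmse < truth.std()

    def test_deterministic_given_seed(self):
        m = _toy_matrix(seed=4)
        m.loc[0, "feat0"] = np.nan
        a = impute_chained(m, seed=7)
        b = impute_chained(m, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_fully_missing_column_rejected(self):
        m = _toy_matrix()
        m["feat5"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_chained(m)


class TestSelectFeatures:
    def test_planted_signal_ranks_first(self):
        hits = 0
        for seed in range(20):
            m = _toy_matrix(n_subjects=8, n_films=6, seed=seed, signal=1.0)
            X = m[feature_columns(m)]
            imp = select_features(X, m["rating"].to_numpy(float), "regression", k=3, seed=seed)
            hits += imp.index[0] == "feat0"
        assert hits >= 19  # >= 95% of seeds

    def test_k_equal_feature_count_returns_all(self):
        m = _toy_matrix()
        X = m[feature_columns(m)]
        imp = select_features(X, m["rating"].to_numpy(float), "regression", k=X.shape[1])
        assert set(imp.index) == set(X.columns)

    def test_k_too_large_rejected(self):
        m = _toy_matrix()
        X = m[feature_columns(m)]
        with pytest.raises(ValueError, match="exceeds"):
            select_features(X, m["rating"].to_numpy(float), "regression", k=X.shape[1] + 1)

    def test_duplicated_informative_column_splits_importance(self):
        m = _toy_matrix(n_subjects=10, n_films=6, seed=1, signal=1.0)
        X1 = m[feature_columns(m)]
        imp1 = select_features(X1, m["rating"].to_numpy(float), "regression", k=X1.shape[1], seed=0)
        m2 = m.copy()
        m2["feat0_dup"] = m2["feat0"]
        X2 = m2[feature_columns(m2)]
        imp2 = select_features(X2, m2["rating"].to_numpy(float), "regression", k=X2.shape[1], seed=0)
        combined = imp2["feat0"] + imp2["feat0_dup"]
        assert combined == pytest.approx(imp1["feat0"], rel=0.5)


class TestLofo:
    def test_eight_films_give_eight_folds(self):
        m = _toy_matrix(n_subjects=4, n_films=8, seed=5)
        report = lofo_evaluate(m, task="regression", seed=0, k=4)
        assert len(report.per_film) == 8
        assert all(len(v) == 4 for v in report.selected_features.values())

    def test_mape_mae_hand_arithmetic(self):
        y = np.array([5.0, 10.0])
        pred = np.array([4.0, 12.0])
        mape = np.mean(np.abs(pred - y) / y)
        mae = np.mean(np.abs(pred - y))
        assert mape == pytest.approx(0.2)
        assert mae == pytest.approx(1.5)

    def test_no_leakage_fingerprints_ignore_heldout_rows(self):
        m = _toy_matrix(n_subjects=5, n_films=4, seed=6)
        folds_a = prepare_folds(m, seed=0)
        tampered = m.copy()
        sel = tampered["film_id"] == "f0"
        tampered.loc[sel, [c for c in feature_columns(m)]] = 99.0
        folds_b = prepare_folds(tampered, seed=0)
        fa = {f.film_id: f.fingerprint for f in folds_a}
        fb = {f.film_id: f.fingerprint for f in folds_b}
        assert fa["f0"] == fb["f0"]          # training stats exclude held-out film
        assert any(fa[k] != fb[k] for k in fa if k != "f0")

    def test_mean_prediction_matches_closed_form_mape(self):
        # predicting the training mean for every test trial: compare the
        # reported MAPE against the value computed directly from the ratings
        m = _toy_matrix(n_subjects=6, n_films=5, seed=7)

        class MeanModel:
            def fit(self, X, y):
                self.mean = float(np.mean(y))
                return self

            def predict(self, X):
                return np.full(len(X), self.mean)

        report = lofo_evaluate(m, task="regression", models={"mean": MeanModel()}, seed=0, k=4)
        y = m["rating"].to_numpy(float)
        expected = []
        for film in m["film_id"].unique():
            te = m["film_id"] == film
            mu = y[~te].mean()
            expected.append(np.mean(np.abs(mu - y[te]) / y[te]))
        assert report.means["mean_mape"] == pytest.approx(np.mean(expected), abs=0.02)

    def test_binary_labels_are_within_subject_half_splits(self):
        m = _toy_matrix(n_subjects=5, n_films=6, seed=8)
        labels = binary_labels(m, seed=0)
        df = m.assign(label=labels)
        for _, g in df.groupby("subject_id"):
            assert (g["label"] == "high").sum() == 3
            assert g.loc[g["label"] == "high", "rating"].mean() >= g.loc[g["label"] == "low", "rating"].mean()

    def test_classification_reports_all_models_and_metrics(self):
        m = _toy_matrix(n_subjects=6, n_films=4, seed=9, signal=0.5)
        report = lofo_evaluate(m, task="classification", seed=0, k=4)
        for model in ("logreg", "knn", "tree", "gbc", "svc"):
            for metric in ("accuracy", "f1", "auc"):
                assert f"{model}_{metric}" in report.per_film.columns
        assert 0.0 <= report.means["logreg_auc"] <= 1.0

    def test_determinism(self):
        m = _toy_matrix(n_subjects=5, n_films=4, seed=10, signal=0.3)
        r1 = lofo_evaluate(m, task="classification", seed=3, k=4)
        r2 = lofo_evaluate(m, task="classification", seed=3, k=4)
        pd.testing.assert_frame_equal(r1.per_film, r2.per_film)
        assert r1.means == r2.means

    def test_too_few_films_rejected(self):
        m = _toy_matrix(n_subjects=5, n_films=2)
        with pytest.raises(ValueError, match="3 films"):
            lofo_evaluate(m, task="regression", k=4)


class TestPermutedAUC:
    def test_null_matrix_auc_near_half(self):
        m = _toy_matrix(n_subjects=10, n_films=6, seed=11)
        mean_auc, runs = permuted_label_auc(m, n_permutations=30, seed=0, k=4)
        assert len(runs) == 30
        assert mean_auc == pytest.approx(0.5, abs=0.05)

    def test_signal_matrix_beats_permuted_labels(self):
        m = _toy_matrix(n_subjects=12, n_films=6, seed=12, signal=1.0)
        report = lofo_evaluate(m, task="classification", seed=0, k=4)
        perm_auc, _ = permuted_label_auc(m, n_permutations=15, seed=0, k=4)
        assert report.means["logreg_auc"] > perm_auc + 0.08
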