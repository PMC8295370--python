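"""Encoding models: designs, nested-CV ridge, decoding, AUC, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from recallnets.encoding_models import (
    DecodingResult,
    auc_score,
    bootstrap_electrode_auc,
    build_content_design,
    build_context_design,
    decode,
    decode_events,
    default_lambda_grid,
    fit_ridge_nested_cv,
    predict_class_patterns,
)
from recallnets.synthetic_data import SimulationConfig, simulate_subject


def _events(n_lists=3, n_sessions=1, list_length=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    item = 0
    for sess in range(n_sessions):
        for li in range(n_lists):
            cats = rng.permutation(25)[:3]
            for pos in range(1, list_length + 1):
                rows.append({"session": sess, "list": li + sess * n_lists,
                             "position": pos, "item": item,
                             "category": int(cats[(pos - 1) // 4])})
                item += 1
    return pd.DataFrame(rows)


class TestContentDesign:
    def test_rows_are_category_centroids(self, rng):
        ev = _events()
        emb = rng.standard_normal((ev["item"].max() + 1, 20))
        d = build_content_design(ev, emb, None)
        # same-category events share a row; the row is the mean embedding of
        # that category's presented words
        for cat in ev["category"].unique():
            rows = d.X[ev["category"].to_numpy() == cat]
            assert np.allclose(rows, rows[0])
            items = ev.loc[ev["category"] == cat, "item"].unique()
            assert np.allclose(rows[0], emb[items].mean(axis=0))

    def test_feature_dimension_follows_embedding(self, rng):
        ev = _events()
        emb = rng.standard_normal((ev["item"].max() + 1, 300))
        assert build_content_design(ev, emb, None).X.shape[1] == 300

    def test_missing_embedding_names_word(self, rng):
        ev = _events()
        emb = rng.standard_normal((3, 10))  # far too few rows
        with pytest.raises(KeyError, match="word id"):
            build_content_design(ev, emb, None)


class TestContextDesign:
    def test_single_session_column_count(self):
        ev = _events(n_lists=25)
        d = build_context_design(ev)
        assert d.X.shape[1] == 12 + 25  # session block omitted

    def test_multi_session_adds_session_block(self):
        ev = _events(n_lists=5, n_sessions=2)
        assert build_context_design(ev).X.shape[1] == 12 + 10 + 2

    def test_position_block_is_one_hot(self):
        ev = _events()
        d = build_context_design(ev)
        row = d.X[ev.index[ev["position"] == 3][0]]
        assert row[:12].sum() == 1.0 and row[2] == 1.0

    def test_same_position_different_list_blocks(self):
        ev = _events(n_lists=2)
        d = build_context_design(ev)
        a = d.X[(ev["position"] == 5) & (ev["list"] == 0)][0]
        b = d.X[(ev["position"] == 5) & (ev["list"] == 1)][0]
        assert np.allclose(a[:12], b[:12])
        assert not np.allclose(a[12:], b[12:])

    def test_out_of_range_position_rejected(self):
        ev = _events()
        ev.loc[0, "position"] = 13
        with pytest.raises(ValueError, match="lie in"):
            build_context_design(ev)


def _closed_form_ridge(X, Y, lam):
    """Independent oracle: (X'X + lam I)^-1 X'Y by direct solve."""
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ Y)


class TestRidgeNestedCV:
    def _design(self, X, seed=0):
        from recallnets.encoding_models import DesignMatrix
        n = X.shape[0]
        return DesignMatrix(X=X, kind="content",
                            class_features=X[:2].copy(),
                            class_labels=np.zeros(n, dtype=int),
                            class_ids=np.array([0, 1]),
                            word_ids=np.arange(n))

    def test_noiseless_recovery_matches_planted_weights(self, rng):
        n, p, q = 120, 8, 4
        X = rng.standard_normal((n, p))
        w = rng.standard_normal((p, q))
        Y = X @ w
        fit = fit_ridge_nested_cv(self._design(X), Y, seed=0)
        # the smallest grid penalty (1e-2) leaves a relative shrinkage bias
        # of about lambda/n ~ 1e-4, which bounds the attainable error
        for fold in range(fit.n_folds):
            assert np.all(fit.selected_lambda[fold] ==
                          default_lambda_grid()[0])
            test = fit.fold_of_event == fold
            pred = fit.predict(fold, X[test])
            assert np.max(np.abs(pred - Y[test])) < 1e-2
            # recovered weights on the standardized scale map back to w
            w_raw = fit.weights[fold] / fit.x_scale[fold][:, None]
            assert np.allclose(w_raw, w, atol=1e-3)

    def test_matches_closed_form_oracle_for_each_selected_lambda(self, rng):
        """The weights of every outer fold equal the normal-equations ridge
        solution at the selected penalty (relative tolerance 1e-8)."""
        n, p, q = 80, 6, 3
        X = rng.standard_normal((n, p))
        Y = X @ rng.standard_normal((p, q)) + 0.5 * rng.standard_normal((n, q))
        fit = fit_ridge_nested_cv(self._design(X), Y, seed=1)
        for fold in range(fit.n_folds):
            train = fit.fold_of_event != fold
            Z = (X[train] - fit.x_mean[fold]) / fit.x_scale[fold]
            Yc = Y[train] - fit.y_mean[fold]
            for col in range(q):
                lam = fit.selected_lambda[fold][col]
                oracle = _closed_form_ridge(Z, Yc[:, [col]], lam)
                got = fit.weights[fold][:, [col]]
                assert np.allclose(got, oracle, rtol=1e-8, atol=1e-10)

    def test_matches_sklearn_ridge(self, rng):
        """Cross-check against scikit-learn's Ridge at a fixed penalty."""
        from sklearn.linear_model import Ridge

        n, p = 60, 5
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 2))
        lam = 3.7
        fit = fit_ridge_nested_cv(self._design(X), Y, seed=0,
                                  lambda_grid=np.array([lam]))
        fold = 0
        train = fit.fold_of_event != fold
        Z = (X[train] - fit.x_mean[fold]) / fit.x_scale[fold]
        Yc = Y[train] - fit.y_mean[fold]
        sk = Ridge(alpha=lam, fit_intercept=False).fit(Z, Yc)
        assert np.allclose(fit.weights[fold], sk.coef_.T, atol=1e-8)

    def test_infinite_shrinkage_kills_weights(self, rng):
        n, p = 100, 6
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 2))
        fit = fit_ridge_nested_cv(self._design(X), Y, seed=0,
                                  lambda_grid=np.array([1e10]))
        for W in fit.weights:
            assert np.linalg.norm(W) < 1e-6 * np.linalg.norm(Y)

    def test_permuted_responses_decorrelate_predictions(self, rng):
        n, p = 600, 10
        X = rng.standard_normal((n, p))
        Y = X @ rng.standard_normal((p, 1))
        rs = []
        for rep in range(8):
            Yp = Y[rng.permutation(n)]
            fit = fit_ridge_nested_cv(self._design(X), Yp, seed=rep)
            # model-driven component only: the training-fold mean offset
            # carries the usual negative CV bias and is not the model's doing
            preds = np.empty(n)
            for fold in range(fit.n_folds):
                m = fit.fold_of_event == fold
                preds[m] = fit.predict(fold, X[m])[:, 0] - fit.y_mean[fold]
            if preds.std() == 0:
                continue
            rs.append(np.corrcoef(preds, Yp[:, 0])[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_selected_lambda_comes_from_grid(self, rng):
        X = rng.standard_normal((50, 4))
        Y = rng.standard_normal((50, 3))
        fit = fit_ridge_nested_cv(self._design(X), Y, seed=0)
        grid = set(default_lambda_grid())
        for lams in fit.selected_lambda:
            assert set(lams) <= grid

    def test_word_groups_never_straddle_folds(self, rng):
        X = rng.standard_normal((60, 4))
        from recallnets.encoding_models import DesignMatrix
        d = DesignMatrix(X=X, kind="content", class_features=X[:2],
                         class_labels=np.zeros(60, dtype=int),
                         class_ids=np.array([0, 1]),
                         word_ids=np.repeat(np.arange(30), 2))
        fit = fit_ridge_nested_cv(d, rng.standard_normal((60, 2)), seed=0)
        for w in np.unique(d.word_ids):
            folds = fit.fold_of_event[d.word_ids == w]
            assert len(set(folds)) == 1

    def test_too_few_events_rejected(self, rng):
        X = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="fewer events"):
            fit_ridge_nested_cv(self._design(X), rng.standard_normal((3, 1)),
                                outer_folds=5, seed=0)


class TestDecode:
    def test_exact_match_wins(self, rng):
        patterns = rng.standard_normal((4, 30))
        probs = decode(patterns[2], patterns)
        assert probs.argmax() == 2
        assert probs.sum() == pytest.approx(1.0)

    def test_identical_patterns_give_uniform(self, rng):
        patterns = np.tile(rng.standard_normal(10), (5, 1))
        probs = decode(rng.standard_normal(10), patterns)
        assert np.allclose(probs, 0.2)

    def test_softmax_of_fixed_evidence(self):
        """Correlations (1, 0, -1) map to softmax probabilities computed
        independently."""
        base = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        patterns = np.stack([base, np.array([1, 1, -1, -1, -1, -1.0]), -base])
        obs = base.copy()
        r = np.array([np.corrcoef(obs, p)[0, 1] for p in patterns])
        assert np.allclose(r, [1.0, 0.0, -1.0], atol=1e-12)
        expected = np.exp(r) / np.exp(r).sum()
        assert np.allclose(decode(obs, patterns), expected)

    def test_zero_variance_observation_warns_uniform(self):
        patterns = np.eye(3, 6)
        with pytest.warns(UserWarning, match="zero-variance"):
            probs = decode(np.zeros(6), patterns)
        assert np.allclose(probs, 1 / 3)

    def test_probabilities_live_on_simplex(self, rng):
        for _ in range(20):
            probs = decode(rng.standard_normal(24),
                           rng.standard_normal((12, 24)))
            assert np.all(probs >= 0) and probs.sum() == pytest.approx(1.0)


def _pair_counting_auc(scores, labels):
    """Brute-force one-vs-rest AUC: fraction of positive-negative pairs
    ranked correctly, ties counted half."""
    aucs = []
    for c in np.unique(labels):
        pos = scores[labels == c, c]
        neg = scores[labels != c, c]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        aucs.append(wins / (len(pos) * len(neg)))
    return float(np.mean(aucs))


class TestAUC:
    def test_one_hot_probabilities_score_one(self):
        labels = np.array([0, 1, 2, 1])
        probs = np.eye(3)[labels]
        assert auc_score((probs, labels)) == pytest.approx(1.0)

    def test_uniform_probabilities_score_half(self):
        labels = np.array([0, 1, 0, 1, 2])
        probs = np.full((5, 3), 1 / 3)
        assert auc_score((probs, labels)) == pytest.approx(0.5)

    def test_two_class_example_matches_pair_counting(self):
        labels = np.array([0, 1, 0, 1])
        p0 = np.array([0.9, 0.4, 0.6, 0.1])
        probs = np.stack([p0, 1 - p0], axis=1)
        assert auc_score((probs, labels)) == pytest.approx(
            _pair_counting_auc(probs, labels))
        # by hand: class 0 pairs all ranked correctly -> 1.0 each way
        assert auc_score((probs, labels)) == pytest.approx(1.0)

    def test_random_instances_match_pair_counting_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(6, 21)
            k = rng.integers(2, 5)
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            probs = rng.dirichlet(np.ones(k), size=n)
            # quantize to force ties sometimes
            probs = np.round(probs, 1)
            assert auc_score((probs, labels)) == pytest.approx(
                _pair_counting_auc(probs, labels))

    def test_invariant_to_monotone_transform_of_evidence(self, rng):
        labels = rng.integers(0, 3, size=30)
        evidence = rng.standard_normal((30, 3))
        warped = np.tanh(2.0 * evidence) + 1.5  # strictly monotone, elementwise
        assert auc_score((evidence, labels)) == pytest.approx(
            auc_score((warped, labels)))

    def test_single_class_undefined(self):
        with pytest.warns(UserWarning, match="single-class"):
            assert np.isnan(auc_score((np.ones((3, 2)) / 2, np.zeros(3))))


class TestEndToEndRecovery:
    def test_noiseless_generative_data_decodes_perfectly(self, clean_subject):
        """Zero-noise simulation: category decodable from AT power and
        serial position from PM power, both with AUC approaching 1."""
        sub = clean_subject
        labels = sub.config.network_labels
        enc = sub.encoding
        d_content = build_content_design(sub.events,
                                         sub.truth.true_embeddings, None)
        Y_at = enc[:, labels == "AT", :].reshape(enc.shape[0], -1)
        auc_cat = decode_events(
            fit_ridge_nested_cv(d_content, Y_at, seed=0), Y_at).auc
        assert auc_cat > 0.99

        d_context = build_context_design(sub.events)
        Y_pm = enc[:, labels == "PM", :].reshape(enc.shape[0], -1)
        auc_pos = decode_events(
            fit_ridge_nested_cv(d_context, Y_pm, seed=0), Y_pm).auc
        assert auc_pos > 0.99

    def test_class_patterns_recover_generative_loadings(self, clean_subject):
        """Zero noise: the context model's predicted per-position patterns
        match the planted per-position PM loadings."""
        sub = clean_subject
        labels = sub.config.network_labels
        pm = labels == "PM"
        Y_pm = sub.encoding[:, pm, :].reshape(sub.encoding.shape[0], -1)
        d = build_context_design(sub.events)
        fit = fit_ridge_nested_cv(d, Y_pm, seed=0)
        truth_patterns = sub.truth.position_loadings[:, pm, :].reshape(12, -1)
        pats = predict_class_patterns(fit, 0)
        # compare up to the fold's list/session offset: correlation per class
        for c in range(12):
            r = np.corrcoef(pats[c], truth_patterns[c])[0, 1]
            assert r > 0.999


class TestBootstrap:
    def test_degenerate_when_k_equals_all_electrodes(self, small_subject):
        sub = small_subject
        d = build_context_design(sub.events)
        out = bootstrap_electrode_auc(
            sub.encoding, d, sub.config.network_labels, networks=("PM",),
            k=5, n_boot=4, seed=0)
        assert np.allclose(out["PM"]["auc"], out["PM"]["auc"][0])

    def test_network_specific_position_effects_rank_pm_above_at(self):
        cfg = SimulationConfig(n_lists=8, effect_size_category=0.0,
                               effect_size_position=1.5, noise_sd=0.5,
                               network_shared_sd=0.0, seed=21)
        sub = simulate_subject(cfg)
        d = build_context_design(sub.events)
        out = bootstrap_electrode_auc(
            sub.encoding, d, sub.config.network_labels, k=4, n_boot=8, seed=0)
        assert out["PM"]["mean"] > out["AT"]["mean"] + 0.2

    def test_fixed_seed_reproducible(self, small_subject):
        sub = small_subject
        d = build_context_design(sub.events)
        a = bootstrap_electrode_auc(sub.encoding, d,
                                    sub.config.network_labels,
                                    networks=("AT",), k=3, n_boot=3, seed=9)
        b = bootstrap_electrode_auc(sub.encoding, d,
                                    sub.config.network_labels,
                                    networks=("AT",), k=3, n_boot=3, seed=9)
        assert np.array_equal(a["AT"]["auc"], b["AT"]["auc"])

    def test_undersized_network_skipped(self, small_subject):
        sub = small_subject
        d = build_context_design(sub.events)
        out = bootstrap_electrode_auc(sub.encoding, d,
                                      sub.config.network_labels,
                                      networks=("PM",), k=50, n_boot=2, seed=0)
        assert out == {}
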