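"""Directional SVM training, Platt scaling, feature extraction, model selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from molconf.confidence import (
    ConfidenceResults,
    ConfidenceSVM,
    DEFAULT_SCHEMA,
    Feature,
    FeatureSchema,
    HitFeatures,
    ModelRegistry,
    extract_features,
    platt_fit,
    platt_probability,
    select_model,
)


# ---------------------------------------------------------------------------
# feature extraction


def candidates_df(rows):
    return pd.DataFrame(rows, columns=["candidate_id", "score", "formula"])


class TestExtractFeatures:
    def test_single_candidate_marks_multi_features_missing(self):
        feats = extract_features(
            candidates_df([("c1", 5.0, "C6H6")]), query_id="q"
        )
        assert feats.n_candidates == 1
        assert "score_gap_runner_up" not in feats.values
        assert "log_num_candidates" not in feats.values
        assert feats.values["hit_score"] == 5.0

    def test_score_gap(self):
        feats = extract_features(
            candidates_df([("a", 10.0, "X"), ("b", 7.0, "X")])
        )
        assert feats.values["score_gap_runner_up"] == pytest.approx(3.0)
        assert feats.hit_id == "a"

    def test_formula_filter_before_counting(self):
        rows = [("a", 10.0, "C6H6"), ("b", 9.0, "C7H8"), ("c", 8.0, "C6H6"),
                ("d", 7.0, "C6H6")]
        feats = extract_features(candidates_df(rows))
        # only hit-formula candidates (a, c, d) counted; gap to c not b
        assert feats.n_candidates == 3
        assert feats.values["log_num_candidates"] == pytest.approx(np.log(3))
        assert feats.values["score_gap_runner_up"] == pytest.approx(2.0)

    def test_tie_break_is_lexicographic(self):
        feats = extract_features(candidates_df([("z", 5.0, "X"), ("a", 5.0, "X")]))
        assert feats.hit_id == "a"

    def test_empty_candidate_list_raises(self):
        with pytest.raises(ValueError):
            extract_features(candidates_df([]), query_id="q0")

    def test_random_selection_is_seeded(self):
        rows = [(f"c{i}", float(i), "X") for i in range(10)]
        a = extract_features(candidates_df(rows), select="random", rng=5)
        b = extract_features(candidates_df(rows), select="random", rng=5)
        assert a.hit_id == b.hit_id
        assert a.n_candidates == 1


# ---------------------------------------------------------------------------
# Platt scaling


class TestPlatt:
    def test_zero_parameters_give_half(self, rng):
        f = rng.normal(0, 3, 20)
        np.testing.assert_allclose(platt_probability(f, 0.0, 0.0), 0.5)

    def test_separated_classes_score_above_half(self):
        f = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        A, B = platt_fit(f, y)
        assert np.all(platt_probability(f[y == 1], A, B) > 0.5)
        assert np.all(platt_probability(f[y == 0], A, B) < 0.5)

    def test_matches_logistic_regression_oracle(self):
        """On two-Gaussian decision values the ML sigmoid agrees with a
        generic logistic regression on f (small prior-correction offset)."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        f = np.concatenate([rng.normal(1.2, 1, 400), rng.normal(-1.0, 1, 400)])
        y = np.array([1] * 400 + [0] * 400)
        A, B = platt_fit(f, y)
        lr = LogisticRegression(C=1e6).fit(f[:, None], y)
        assert A == pytest.approx(-lr.coef_[0][0], abs=0.15)
        assert B == pytest.approx(-lr.intercept_[0], abs=0.15)

    def test_degenerate_decision_values_fit_intercept_only(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(RuntimeWarning):
            A, B = platt_fit(np.ones(6), y)
        assert A == 0.0
        assert platt_probability(0.0, A, B) == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            platt_fit([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# directional SVM


def toy_problem(seed=5, n=80):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = pd.DataFrame(
        {
            "a": rng.normal(0, 1, n) + 1.2 * y,   # informative, direction +1
            "b": rng.normal(0, 1, n) - 0.8 * y,   # anti-correlated, direction +1
        }
    )
    return X, y


def bound_constrained_oracle(Z, yy, directions, C=1.0, S=100.0):
    """Sign-constrained squared-hinge SVM solved directly with L-BFGS-B
    bounds — the independent route against the augmentation trick."""
    n_feat = Z.shape[1]

    def unpack(params):
        return params[:-1], params[-1]

    def obj(params):
        w, wb = unpack(params)
        act = np.maximum(0, 1 - yy * (Z @ w + wb * S))
        return 0.5 * (w @ w + wb * wb) + C * np.sum(act**2)

    def grad(params):
        w, wb = unpack(params)
        act = np.maximum(0, 1 - yy * (Z @ w + wb * S))
        gw = w - 2 * C * ((act * yy) @ Z)
        gb = wb - 2 * C * np.sum(act * yy) * S
        return np.concatenate([gw, [gb]])

    bounds = [
        (0, None) if d > 0 else (None, 0) if d < 0 else (None, None)
        for d in directions
    ] + [(None, None)]
    res = minimize(
        obj, np.zeros(n_feat + 1), jac=grad, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=100_000, ftol=1e-18, gtol=1e-14),
    )
    return res.x[:-1], res.x[-1] * S


class TestDirectionalSVM:
    def test_separable_positive_directions(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 30)
        X = pd.DataFrame(
            {"a": np.where(y == 1, 2.0, -2.0) + rng.normal(0, 0.1, 60),
             "b": np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.1, 60)}
        )
        schema = FeatureSchema([Feature("a", +1), Feature("b", +1)])
        res = ConfidenceSVM(X, y, schema=schema).fit(C=1.0, seed=0)
        assert (res.weights >= 0).all()
        pred = res.decision_values(X) > 0
        assert np.array_equal(pred.astype(int), y)

    def test_anticorrelated_feature_driven_to_zero(self):
        X, y = toy_problem()
        constrained = ConfidenceSVM(
            X, y, schema=FeatureSchema([Feature("a", +1), Feature("b", +1)])
        ).fit(C=1.0, seed=0)
        unconstrained = ConfidenceSVM(
            X, y, schema=FeatureSchema([Feature("a", 0), Feature("b", 0)])
        ).fit(C=1.0, seed=0)
        assert unconstrained.weights["b"] < -0.05
        assert 0 <= constrained.weights["b"] < 1e-4

    def test_matches_bound_constrained_oracle(self):
        X, y = toy_problem()
        schema = FeatureSchema([Feature("a", +1), Feature("b", +1)])
        res = ConfidenceSVM(X, y, schema=schema).fit(C=1.0, seed=0)
        Z = res.standardize_and_cap(X)
        w_oracle, b_oracle = bound_constrained_oracle(
            Z, 2 * y - 1, schema.directions, C=1.0
        )
        np.testing.assert_allclose(res.weights.to_numpy(), w_oracle, atol=2e-4)
        assert res.bias == pytest.approx(b_oracle, abs=2e-3)

    @pytest.mark.parametrize("beta", [1e8, 1e9])
    def test_beta_magnitude_is_immaterial(self, beta):
        X, y = toy_problem(seed=8)
        schema = FeatureSchema([Feature("a", +1), Feature("b", +1)])
        w_ref = ConfidenceSVM(X, y, schema=schema).fit(C=1.0, beta=1e7, seed=0)
        w_alt = ConfidenceSVM(X, y, schema=schema).fit(C=1.0, beta=beta, seed=0)
        rel = np.linalg.norm(
            w_alt.weights.to_numpy() - w_ref.weights.to_numpy()
        ) / np.linalg.norm(w_ref.weights.to_numpy())
        assert rel < 1e-4

    def test_single_class_raises(self):
        X, _ = toy_problem()
        with pytest.raises(ValueError):
            ConfidenceSVM(X, np.ones(len(X), dtype=int))

    def test_sign_constraints_on_session_model(self, trained_model):
        prods = trained_model.weights.to_numpy() * trained_model.schema.directions
        assert np.all(prods >= -1e-9)


# ---------------------------------------------------------------------------
# capping / standardization / scoring


class TestApplication:
    def test_training_mean_maps_to_zero(self, trained_model):
        mu = trained_model.mean.to_frame().T
        z = trained_model.standardize_and_cap(mu)
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_values_beyond_cap_are_clipped(self, trained_model):
        hi = trained_model.cap_max.to_frame().T
        beyond = hi + 100.0
        np.testing.assert_allclose(
            trained_model.standardize_and_cap(beyond),
            trained_model.standardize_and_cap(hi),
        )

    def test_clip_then_scale_composition(self, trained_model, rng):
        names = trained_model.schema.names
        X = pd.DataFrame(rng.normal(0, 5, (20, len(names))), columns=names)
        z = trained_model.standardize_and_cap(X)
        manual = (
            np.clip(X.to_numpy(), trained_model.cap_min.to_numpy(),
                    trained_model.cap_max.to_numpy())
            - trained_model.mean.to_numpy()
        ) / trained_model.std.to_numpy()
        np.testing.assert_allclose(z, manual)

    def test_capping_is_idempotent(self, trained_model, rng):
        names = trained_model.schema.names
        X = pd.DataFrame(rng.normal(0, 5, (10, len(names))), columns=names)
        once = trained_model.standardize_and_cap(X)
        capped = np.clip(X.to_numpy(), trained_model.cap_min.to_numpy(),
                         trained_model.cap_max.to_numpy())
        twice = trained_model.standardize_and_cap(
            pd.DataFrame(capped, columns=names)
        )
        np.testing.assert_allclose(once, twice)

    def test_confidence_is_sigmoid_of_decision(self, trained_model, hit_dataset):
        multi = hit_dataset[hit_dataset.n_candidates > 1].dropna().head(50)
        f = trained_model.decision_values(multi)
        p = trained_model.confidence_score(multi)
        expected = 1.0 / (1.0 + np.exp(trained_model.platt_a * f + trained_model.platt_b))
        np.testing.assert_allclose(p, expected, rtol=1e-12)
        assert np.all((p > 0) & (p < 1))

    def test_batch_equals_per_item(self, trained_model, hit_dataset):
        multi = hit_dataset[hit_dataset.n_candidates > 1].dropna().head(10)
        batch = trained_model.confidence_score(multi)
        single = [
            trained_model.confidence_score(multi.iloc[[i]])[0]
            for i in range(len(multi))
        ]
        np.testing.assert_allclose(batch, single)

    def test_regime_mismatch_raises(self, trained_model):
        feats = HitFeatures("q", "h", {"hit_score": 1.0}, n_candidates=1)
        with pytest.raises(ValueError):
            trained_model.confidence_score(feats)


# ---------------------------------------------------------------------------
# persistence and model selection


class TestPersistence:
    def test_json_round_trip_preserves_scoring(self, trained_model, hit_dataset, tmp_path):
        path = tmp_path / "model.json"
        trained_model.save(path)
        loaded = ConfidenceResults.load(path)
        multi = hit_dataset[hit_dataset.n_candidates > 1].dropna().head(30)
        np.testing.assert_allclose(
            loaded.confidence_score(multi), trained_model.confidence_score(multi)
        )
        assert loaded.regime == trained_model.regime
        assert loaded.collision_energy == trained_model.collision_energy


def make_results(energy, regime="multi-candidate") -> ConfidenceResults:
    names = ["hit_score"]
    series = lambda v: pd.Series([v], index=names)
    return ConfidenceResults(
        schema=FeatureSchema([Feature("hit_score", +1)]),
        weights=series(1.0), bias=0.0, mean=series(0.0), std=series(1.0),
        cap_min=series(-5.0), cap_max=series(5.0), platt_a=-1.0, platt_b=0.0,
        C=1.0, beta=1e7, collision_energy=energy, regime=regime,
    )


class TestModelSelection:
    @pytest.fixture
    def registry(self):
        return ModelRegistry(
            [make_results(e) for e in (10.0, 20.0, 40.0, "merged")]
            + [make_results("merged", regime="single-candidate")]
        )

    def test_nearest_energy_35_ev_takes_40(self, registry):
        assert select_model(registry, 35.0, 5).collision_energy == 40.0

    def test_exact_energy(self, registry):
        assert select_model(registry, 20.0, 5).collision_energy == 20.0

    def test_merged_query_takes_merged_model(self, registry):
        assert select_model(registry, "merged", 5).collision_energy == "merged"

    def test_single_candidate_regime(self, registry):
        chosen = select_model(registry, "merged", 1)
        assert chosen.regime == "single-candidate"

    def test_empty_registry_raises(self):
        with pytest.raises(ValueError):
            select_model(ModelRegistry(), 20.0, 5)
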