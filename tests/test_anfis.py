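"""FCM clustering, Sugeno forward pass, and hybrid ANFIS training."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans

from respmark.anfis import (
    AnfisModel,
    TrainConfig,
    anfis_forward,
    anfis_predict,
    block_split,
    fcm_cluster,
    fit_anfis,
    init_from_fcm,
    model_from_dict,
    model_to_dict,
    predict_setup,
    train_hybrid,
)
from respmark.errors import InvalidParameterError, SchemaError


def naive_forward(model, x):
    """Literal term-by-term evaluation of the Sugeno formulas (oracle)."""
    num = den = 0.0
    for rule in model.rules:
        w = 1.0
        for mf, xk in zip(rule.premise, x):
            w *= np.exp(-((xk - mf.center) ** 2) / (2.0 * mf.sigma**2))
        f = float(np.dot(rule.consequent[:-1], x) + rule.consequent[-1])
        num += w * f
        den += w
    return num / den


def random_model(rng, c=3, d=2):
    return AnfisModel(
        rng.normal(size=(c, d)),
        0.5 + rng.random((c, d)),
        rng.normal(size=(c, d + 1)),
    )


class TestFcm:
    def test_single_cluster_closed_form(self, rng):
        x = rng.normal(size=(40, 3))
        res = fcm_cluster(x, c=1, seed=0)
        assert np.allclose(res.centers[0], x.mean(axis=0), atol=1e-9)
        assert np.allclose(res.memberships, 1.0)

    def test_memberships_row_normalized(self, rng):
        for c in (2, 3, 5):
            res = fcm_cluster(rng.normal(size=(60, 2)), c=c, seed=1)
            assert np.allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
            assert res.memberships.min() >= 0 and res.memberships.max() <= 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_objective_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        res = fcm_cluster(rng.normal(size=(50, 2)), c=3, seed=seed % 7)
        hist = np.asarray(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_two_blob_centers_recovered(self, rng):
        # independent oracle: (hard) k-means centers on the same data
        blobs = np.vstack(
            [
                rng.normal(loc=(0.0, 0.0), scale=0.1, size=(50, 2)),
                rng.normal(loc=(10.0, 10.0), scale=0.1, size=(50, 2)),
            ]
        )
        res = fcm_cluster(blobs, c=2, seed=0)
        km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(blobs)
        got = sorted(map(tuple, np.round(res.centers, 6)))
        want = sorted(map(tuple, np.round(km.cluster_centers_, 6)))
        for g, w in zip(got, want):
            assert np.allclose(g, w, atol=0.1)

    def test_needs_more_points_than_clusters(self, rng):
        with pytest.raises(InvalidParameterError):
            fcm_cluster(rng.normal(size=(3, 2)), c=3)


class TestInitFromFcm:
    def test_single_cluster_moment_recovery(self, rng):
        x = rng.standard_normal((1000, 1))
        y = rng.standard_normal(1000)
        model = init_from_fcm(fcm_cluster(x, 1, seed=0), x, y)
        assert model.n_rules == 1
        assert model.centers[0, 0] == pytest.approx(0.0, abs=0.1)
        assert model.sigmas[0, 0] == pytest.approx(1.0, abs=0.1)

    def test_rule_cardinality(self, rng):
        x = rng.normal(size=(80, 2))
        for c in (1, 2, 4):
            model = init_from_fcm(fcm_cluster(x, c, seed=2), x, rng.normal(size=80))
            assert model.n_rules == c

    def test_constant_column_floors_sigma_with_warning(self, rng):
        x = np.column_stack([rng.normal(size=30), np.full(30, 2.0)])
        with pytest.warns(RuntimeWarning):
            model = init_from_fcm(fcm_cluster(x, 1, seed=0), x, rng.normal(size=30))
        assert model.sigmas[0, 1] == pytest.approx(1e-6)


class TestForward:
    def test_single_rule_is_exactly_linear(self, rng):
        model = random_model(rng, c=1, d=3)
        for _ in range(5):
            x = rng.normal(size=3)
            expect = float(np.dot(model.consequents[0, :3], x) + model.consequents[0, 3])
            assert anfis_forward(model, x) == pytest.approx(expect, abs=1e-12)

    def test_identical_consequents_collapse_to_one_value(self, rng):
        model = random_model(rng, c=2, d=2)
        model.consequents[1] = model.consequents[0]
        x = rng.normal(size=2)
        expect = float(np.dot(model.consequents[0, :2], x) + model.consequents[0, 2])
        assert anfis_forward(model, x) == pytest.approx(expect, abs=1e-12)

    def test_matches_naive_term_by_term_oracle(self, rng):
        for _ in range(20):
            model = random_model(rng, c=3, d=2)
            x = rng.normal(size=2)
            assert anfis_forward(model, x) == pytest.approx(
                naive_forward(model, x), abs=1e-12
            )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_output_bounded_by_rule_outputs(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, c=4, d=2)
        x = rng.normal(size=2)
        f = [float(np.dot(r.consequent[:2], x) + r.consequent[2]) for r in model.rules]
        y = anfis_forward(model, x)
        assert min(f) - 1e-9 <= y <= max(f) + 1e-9

    def test_far_input_falls_back_to_nearest_rule(self, rng):
        model = AnfisModel(
            np.array([[0.0], [100.0]]),
            np.array([[0.5], [0.5]]),
            np.array([[1.0, 0.0], [0.0, 7.0]]),
        )
        with pytest.warns(RuntimeWarning):
            y = anfis_forward(model, [5000.0])
        assert y == pytest.approx(7.0)  # rule 2 is nearest; its consequent is 7


class TestTraining:
    def test_noiseless_linear_target_solved_to_machine_precision(self):
        x = np.linspace(0, 1, 200)[:, None]
        model = fit_anfis(x, 2 * x.ravel() + 1, TrainConfig(n_rules=1, epochs=2))
        assert model.training_history[-1] < 1e-6

    def test_constant_target_gives_zero_rmse(self, rng):
        x = rng.normal(size=(100, 2))
        model = fit_anfis(x, np.full(100, 3.5), TrainConfig(n_rules=2, epochs=2))
        assert model.training_history[-1] == pytest.approx(0.0, abs=1e-10)

    def test_lse_step_never_raises_training_rmse(self, rng):
        x = rng.uniform(0, 2 * np.pi, size=(300, 1))
        y = np.sin(x.ravel()) + 0.05 * rng.normal(size=300)
        fcm = fcm_cluster(x, 3, seed=0)
        model = init_from_fcm(fcm, x, y)
        before = float(np.sqrt(np.mean((anfis_predict(model, x) - y) ** 2)))
        # lr = 0 isolates the least-squares consequent update
        lse_only = train_hybrid(
            model, x, y, TrainConfig(n_rules=3, epochs=1, premise_learning_rate=0.0)
        )
        assert lse_only.training_history[0] <= before + 1e-9
        trained = train_hybrid(model, x, y, TrainConfig(n_rules=3, epochs=12, seed=0))
        hist = trained.training_history
        assert hist[-1] <= hist[0] * 1.05 + 1e-9

    def test_sine_fit_reaches_reference_accuracy(self):
        x = np.linspace(0, 2 * np.pi, 500)[:, None]
        model = fit_anfis(x, np.sin(x.ravel()), TrainConfig(n_rules=5, epochs=50))
        assert model.training_history[-1] < 0.05

    def test_two_rule_generator_recovered_within_noise(self, rng):
        # data from a known 2-rule Sugeno model + noise; test RMSE <= 2 sigma
        sigma = 0.05
        passes = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            truth = AnfisModel(
                np.array([[-1.0], [1.5]]),
                np.array([[0.8], [0.6]]),
                np.array([[0.5, 1.0], [-1.2, 2.0]]),
            )
            x = r.uniform(-3, 4, size=(400, 1))
            y = anfis_predict(truth, x) + sigma * r.normal(size=400)
            tr, te = block_split(400, 0.7)
            model = fit_anfis(
                x[tr], y[tr], TrainConfig(n_rules=2, epochs=20, seed=seed)
            )
            rmse = float(np.sqrt(np.mean((anfis_predict(model, x[te]) - y[te]) ** 2)))
            passes += rmse <= 2 * sigma
        assert passes >= 18  # >= 90% of seeds

    def test_requires_enough_samples_per_rule(self, rng):
        x = rng.normal(size=(15, 1))
        model = random_model(rng, c=2, d=1)
        with pytest.raises(InvalidParameterError):
            train_hybrid(model, x, rng.normal(size=15), TrainConfig(n_rules=2))


class TestSplitAndPrediction:
    def test_block_split_disjoint_contiguous_deterministic(self):
        tr, te = block_split(100, 0.7)
        assert len(tr) == 70 and len(te) == 30
        assert set(tr).isdisjoint(te)
        assert np.array_equal(np.concatenate([tr, te]), np.arange(100))
        tr2, _ = block_split(100, 0.7)
        assert np.array_equal(tr, tr2)

    def test_predict_setup_reproduces_training_targets(self, short_sessions, fast_train_config):
        from respmark.evaluate import fit_axis_models

        sess = short_sessions[:1]
        models = fit_axis_models(sess, ("M1", "M9"), fast_train_config)
        pred = predict_setup(models, sess[0])
        train_rmse = models["ap"].training_history[-1]
        err = np.sqrt(np.mean((pred.ap - sess[0].reference_trace.ap) ** 2))
        assert err <= train_rmse + 1e-9
        assert np.array_equal(pred.timestamps, sess[0].timestamps)

    def test_predict_setup_rejects_subset_mismatch(self, short_sessions, fast_train_config):
        from respmark.evaluate import fit_axis_models

        models = fit_axis_models(short_sessions[:1], ("M1", "M9"), fast_train_config)
        with pytest.raises(SchemaError):
            predict_setup(models, short_sessions[0], labels=("M1", "M3"))
        with pytest.raises(InvalidParameterError):
            predict_setup(models, short_sessions[0], labels=())

    def test_model_serialization_round_trip(self, rng):
        model = random_model(rng)
        model.output_axis = "ap"
        model.marker_labels = ("M1", "M9")
        model.training_history = [1.0, 0.5]
        clone = model_from_dict(model_to_dict(model))
        assert np.allclose(clone.centers, model.centers)
        assert np.allclose(clone.sigmas, model.sigmas)
        assert np.allclose(clone.consequents, model.consequents)
        assert clone.marker_labels == model.marker_labels
        assert clone.output_axis == "ap"
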