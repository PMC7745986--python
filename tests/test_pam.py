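from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from nanopam.pam import (
    PamModel,
    choose_delta,
    classification_error,
    predict,
    predict_labels,
    predict_matrix,
    train_pam,
)

from oracles import nsc_discriminants_oracle, nsc_train_oracle


@pytest.fixture
def hand_instance():
    """2 genes, 4 samples: class A = {(0,0),(2,0)}, class B = {(4,2),(6,2)}."""
    X = pd.DataFrame(
        [[0.0, 2.0, 4.0, 6.0], [0.0, 0.0, 2.0, 2.0]],
        index=["g1", "g2"],
        columns=["a1", "a2", "b1", "b2"],
    )
    labels = ["A", "A", "B", "B"]
    return X, labels


class TestTrainPam:
    def test_hand_computed_quantities(self, hand_instance):
        X, labels = hand_instance
        model = train_pam(X, labels, delta=0.0)
        assert model.centroids["A"].tolist() == [1.0, 0.0]
        assert model.centroids["B"].tolist() == [5.0, 2.0]
        assert model.overall_centroid.tolist() == [3.0, 1.0]
        assert model.s.tolist() == pytest.approx([math.sqrt(2), 0.0])
        assert model.s0 == pytest.approx(math.sqrt(2) / 2)  # midpoint of even-length median
        assert model.m["A"] == pytest.approx(0.5)

    def test_delta_zero_keeps_class_means(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 10)))
        labels = ["A"] * 5 + ["B"] * 5
        model = train_pam(X, labels, delta=0.0)
        pd.testing.assert_frame_equal(model.shrunken_centroids, model.centroids)

    def test_large_delta_collapses_to_overall_mean(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 10)))
        labels = ["A"] * 5 + ["B"] * 5
        model = train_pam(X, labels, delta=1e6)
        for k in model.classes:
            assert np.allclose(model.shrunken_centroids[k], model.overall_centroid)

    def test_single_class_is_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError, match="classes"):
            train_pam(X, ["A"] * 4)

    def test_class_with_one_sample_is_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError, match="< 2 samples"):
            train_pam(X, ["A", "A", "A", "B"])

    def test_constant_gene_handled_via_s0(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 8)))
        X.iloc[0] = 7.0  # constant across all samples
        model = train_pam(X, ["A"] * 4 + ["B"] * 4)
        assert np.isfinite(model.shrunken_centroids.to_numpy()).all()

    def test_priors(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 6)))
        labels = ["A", "A", "B", "B", "B", "B"]
        emp = train_pam(X, labels, priors="empirical")
        assert emp.priors == {"A": pytest.approx(1 / 3), "B": pytest.approx(2 / 3)}
        uni = train_pam(X, labels, priors="uniform")
        assert uni.priors == {"A": 0.5, "B": 0.5}

    def test_shrinkage_monotone_in_delta(self, rng):
        X = pd.DataFrame(rng.normal(size=(8, 12)))
        labels = ["A"] * 6 + ["B"] * 6
        prev = None
        for delta in (0.0, 0.3, 0.6, 1.2, 2.5):
            model = train_pam(X, labels, delta=delta)
            gap = (model.shrunken_centroids.sub(model.overall_centroid, axis=0)).abs()
            if prev is not None:
                assert (gap.to_numpy() <= prev.to_numpy() + 1e-12).all()
            prev = gap


class TestOracleEquivalence:
    def test_training_matches_brute_force_on_random_instances(self, rng):
        for trial in range(100):
            n_genes = int(rng.integers(2, 7))
            n_a = int(rng.integers(2, 7))
            n_b = int(rng.integers(2, 7))
            delta = float(rng.uniform(0, 2))
            X = pd.DataFrame(rng.normal(size=(n_genes, n_a + n_b)))
            labels = ["A"] * n_a + ["B"] * n_b
            model = train_pam(X, labels, delta=delta)
            oracle = nsc_train_oracle(X.to_numpy().tolist(), labels, delta)
            assert model.s0 == pytest.approx(oracle["s0"], abs=1e-9)
            for k in ("A", "B"):
                np.testing.assert_allclose(
                    model.shrunken_centroids[k], oracle["shrunken"][k], atol=1e-9
                )
                np.testing.assert_allclose(model.centroids[k], oracle["centroids"][k], atol=1e-9)
            np.testing.assert_allclose(model.s, oracle["s"], atol=1e-9)

    def test_discriminants_match_brute_force(self, rng):
        for trial in range(100):
            n_genes = int(rng.integers(2, 7))
            X = pd.DataFrame(rng.normal(size=(n_genes, 8)))
            labels = ["A"] * 4 + ["B"] * 4
            delta = float(rng.uniform(0, 1))
            model = train_pam(X, labels, delta=delta, priors="empirical")
            x = rng.normal(size=n_genes)
            call = predict(model, pd.Series(x, index=X.index))
            oracle = nsc_train_oracle(X.to_numpy().tolist(), labels, delta)
            expected = nsc_discriminants_oracle(oracle, list(x), model.priors)
            for k in ("A", "B"):
                assert call.deltas[k] == pytest.approx(expected[k], abs=1e-9)
            if abs(expected["A"] - expected["B"]) > 1e-6:  # skip float-order near-ties
                assert call.label == min(expected, key=expected.get)

    def test_reduces_to_euclidean_nearest_mean(self, rng):
        """delta=0, uniform priors: argmin delta_k = nearer class mean under
        the per-gene scaled metric; with equal scaling it is plain Euclidean."""
        for trial in range(25):
            X = pd.DataFrame(rng.normal(size=(4, 10)))
            labels = ["A"] * 5 + ["B"] * 5
            model = train_pam(X, labels, delta=0.0, priors="uniform")
            x = rng.normal(size=4)
            call = predict(model, pd.Series(x, index=X.index))
            scale = (model.s + model.s0).to_numpy()
            d = {
                k: np.sum(((x - model.centroids[k].to_numpy()) / scale) ** 2)
                for k in model.classes
            }
            assert call.label == min(d, key=d.get)


class TestPredict:
    def test_spec_example_discriminants(self, hand_instance):
        X, labels = hand_instance
        model = train_pam(X, labels, delta=0.0, priors="uniform")
        call = predict(model, pd.Series([2.0, 1.0], index=["g1", "g2"]), "t")
        const = -2.0 * math.log(0.5)
        # hand-evaluated: sum_j ((x_j - centroid)/(s_j+s0))^2 = 2.222... and 4.0
        assert call.deltas["A"] == pytest.approx(20.0 / 9.0 + const, abs=1e-9)
        assert call.deltas["B"] == pytest.approx(4.0 + const, abs=1e-9)
        assert call.label == "A"

    def test_centroid_self_classification(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)])
        labels = ["basal"] * 4 + ["luminal"] * 4
        model = train_pam(X, labels, delta=0.0, priors="uniform")
        call = predict(model, model.shrunken_centroids["basal"], "c")
        assert call.label == "basal"
        assert call.deltas["basal"] == pytest.approx(-2 * math.log(0.5))
        assert call.correlations["basal"] == pytest.approx(1.0)

    def test_exact_tie_labels_luminal(self):
        # perfectly symmetric instance: midpoint is equidistant
        X = pd.DataFrame(
            [[0.0, 1.0, 3.0, 4.0]], index=["g1"], columns=["a1", "a2", "b1", "b2"]
        )
        model = train_pam(X, ["basal", "basal", "luminal", "luminal"], priors="uniform")
        call = predict(model, pd.Series([2.0], index=["g1"]), "mid")
        assert call.tie
        assert call.label == "luminal"
        assert call.posteriors["basal"] == pytest.approx(0.5)
        assert call.posteriors["luminal"] == pytest.approx(0.5)

    def test_posteriors_sum_to_one_and_shift_invariant(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)))
        model = train_pam(X, ["A"] * 4 + ["B"] * 4)
        call = predict(model, pd.Series(rng.normal(size=5), index=X.index))
        assert sum(call.posteriors.values()) == pytest.approx(1.0)
        # softmax of -delta/2 is invariant to adding a constant to all deltas
        d = np.array([call.deltas[k] for k in model.classes])
        for shift in (0.0, 5.0, -17.0):
            w = np.exp(-0.5 * (d + shift - (d + shift).min()))
            np.testing.assert_allclose(
                w / w.sum(), [call.posteriors[k] for k in model.classes], atol=1e-12
            )

    def test_zero_variance_profile_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 8)))
        model = train_pam(X, ["basal"] * 4 + ["luminal"] * 4)
        with pytest.warns(UserWarning, match="zero-variance"):
            call = predict(model, pd.Series(np.ones(5), index=X.index))
        assert call.degenerate_correlation
        assert call.correlations == {"basal": 0.0, "luminal": 0.0}
        assert call.basal_score == pytest.approx(0.5)

    def test_basal_score_bounds(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 10)), index=[f"g{i}" for i in range(6)])
        model = train_pam(X, ["basal"] * 5 + ["luminal"] * 5)
        call = predict(model, model.shrunken_centroids["basal"], "c")
        assert 0.0 <= call.basal_score <= 1.0
        # score 1 requires r_basal - r_luminal == 2 (perfect anticorrelation)
        assert (call.basal_score == 1.0) == (
            call.correlations["basal"] - call.correlations["luminal"] == pytest.approx(2.0)
        )

    def test_missing_gene_refused_then_imputed(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 8)), index=list("wxyz"))
        model = train_pam(X, ["A"] * 4 + ["B"] * 4)
        x = pd.Series(rng.normal(size=3), index=list("wxy"))
        with pytest.raises(ValueError, match="z"):
            predict(model, x)
        with pytest.warns(UserWarning, match="imputing"):
            call = predict(model, x, impute_missing=True)
        assert call.label in {"A", "B"}

    def test_pure_function_and_gene_order_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 8)), index=[f"g{i}" for i in range(6)])
        model = train_pam(X, ["A"] * 4 + ["B"] * 4)
        x = pd.Series(rng.normal(size=6), index=X.index)
        c1 = predict(model, x)
        c2 = predict(model, x.sample(frac=1.0, random_state=7))  # permuted index
        assert c1 == c2

    def test_batch_equals_singles(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 8)), index=[f"g{i}" for i in range(6)])
        model = train_pam(X, ["A"] * 4 + ["B"] * 4)
        Y = pd.DataFrame(rng.normal(size=(6, 5)), index=X.index, columns=list("abcde"))
        batch = predict_matrix(model, Y)
        singles = [predict(model, Y[s], sample_id=s) for s in Y.columns]
        assert batch == singles
        labels = predict_labels(model, Y)
        assert labels.tolist() == [c.label for c in batch]


class TestSerialization:
    def test_round_trip_reproduces_predictions_bit_exactly(self, rng, tmp_path):
        X = pd.DataFrame(rng.normal(size=(6, 10)), index=[f"g{i}" for i in range(6)])
        model = train_pam(X, ["basal"] * 5 + ["luminal"] * 5, delta=0.4)
        model.to_json(tmp_path / "model.json")
        loaded = PamModel.from_json(tmp_path / "model.json")
        for _ in range(10):
            x = pd.Series(rng.normal(size=6), index=X.index)
            assert predict(model, x) == predict(loaded, x)

    def test_schema_version_checked(self, rng, tmp_path):
        X = pd.DataFrame(rng.normal(size=(3, 4)))
        model = train_pam(X, ["A", "A", "B", "B"])
        doc = model.to_dict()
        doc["schema_version"] = 99
        with pytest.raises(ValueError, match="schema"):
            PamModel.from_dict(doc)


class TestChooseDelta:
    def _separable(self, rng, n=20):
        X = pd.DataFrame(rng.normal(size=(6, n)))
        X.iloc[0, : n // 2] += 10  # one decisive gene
        labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        return X, labels

    def test_separable_has_zero_cv_error_at_zero_delta(self, rng):
        X, labels = self._separable(rng)
        _, curve = choose_delta(X, labels, grid=[0.0], folds=5, seed=1)
        assert curve["cv_error_rate"].iloc[0] == 0.0

    def test_grid_of_one_returns_that_value(self, rng):
        X, labels = self._separable(rng)
        delta_star, _ = choose_delta(X, labels, grid=[0.7], folds=5, seed=1)
        assert delta_star == 0.7

    def test_permuted_labels_near_chance(self, rng):
        n = 40
        X = pd.DataFrame(rng.normal(size=(6, n)))
        labels = ["A", "B"] * (n // 2)
        perm = rng.permutation(labels).tolist()
        _, curve = choose_delta(X, perm, grid=[0.0, 0.5, 1.0], folds=5, seed=2)
        # binomial 95% band around 0.5 at n=40 is ~ +/- 3 * 0.079
        assert abs(curve["cv_error_rate"].min() - 0.5) < 3 * math.sqrt(0.25 / n) + 0.1

    def test_prefers_largest_delta_at_min_error(self, rng):
        X, labels = self._separable(rng, n=30)
        delta_star, curve = choose_delta(X, labels, grid=[0.0, 0.1, 0.2], folds=5, seed=3)
        best = curve["cv_error_rate"].min()
        assert delta_star == curve.loc[curve["cv_error_rate"] <= best, "delta"].max()

    def test_empty_grid_is_error(self, rng):
        X, labels = self._separable(rng)
        with pytest.raises(ValueError, match="grid"):
            choose_delta(X, labels, grid=[], folds=3)


class TestClassificationError:
    @pytest.mark.parametrize(
        "errors,n,printed,decimals",
        [
            (7, 52, 13.0, 0),  # training misclassification
            (24, 52, 46.0, 0),  # cross-platform misapplication
            (2, 30, 6.7, 1),  # independent validation
            (0, 17, 0.0, 0),
        ],
    )
    def test_printed_percentages(self, errors, n, printed, decimals):
        truth = ["basal"] * n
        calls = ["luminal"] * errors + ["basal"] * (n - errors)
        result = classification_error(calls, truth)
        assert result.errors == errors
        assert result.n == n
        assert result.rate == pytest.approx(100.0 * errors / n)
        assert result.percent(decimals) == printed

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            classification_error(["a"], ["a", "b"])

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            classification_error([], [])


class TestParameterRecovery:
    def test_holdout_error_below_5_percent(self):
        """Two-class synthetic data, shift 2.0 log2 units on 20 of 47 genes,
        n=60 train, sd 1.0: hold-out error on 500 fresh samples <= 5%."""
        rng = np.random.default_rng(2024)
        n_genes, n_shift = 47, 20
        genes = [f"g{i}" for i in range(n_genes)]

        def draw(n):
            labels = np.where(rng.random(n) < 0.5, "basal", "luminal")
            shift = np.zeros((n_genes, n))
            shift[:n_shift] = np.where(labels == "basal", 1.0, -1.0)
            X = pd.DataFrame(
                8.0 + shift + rng.normal(0, 1.0, size=(n_genes, n)),
                index=genes,
                columns=[f"s{i}" for i in range(n)],
            )
            return X, pd.Series(labels, index=X.columns)

        X_train, y_train = draw(60)
        X_test, y_test = draw(500)
        X_test.columns = [f"t{i}" for i in range(500)]
        y_test.index = X_test.columns
        model = train_pam(X_train, y_train, delta=0.0)
        pred = predict_labels(model, X_test)
        err = classification_error(pred.tolist(), y_test.tolist())
        assert err.rate <= 5.0
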