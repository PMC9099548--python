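"""Shrunken centroids, cross-validation and the MSE centroid validator."""

import itertools

import numpy as np
import pandas as pd
import pytest

import nodalsig as ns


def _frame(arr):
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


def _two_class(rng, n_genes=60, n_info=15, n_a=6, n_b=7, effect=3.0):
    x = rng.normal(size=(n_genes, n_a + n_b))
    x[:n_info, :n_a] += effect
    labels = ["A"] * n_a + ["B"] * n_b
    return _frame(x), pd.Series(labels, index=[f"s{j}" for j in
                                               range(n_a + n_b)])


def brute_force_nearest_centroid(expr, labels, priors, test_expr):
    """Independent diagonal-covariance nearest-centroid oracle (delta=0)."""
    classes = sorted(set(labels))
    x = expr.to_numpy()
    n = x.shape[1]
    cents, n_k = {}, {}
    for c in classes:
        mask = np.array([l == c for l in labels])
        cents[c] = x[:, mask].mean(axis=1)
        n_k[c] = mask.sum()
    pooled = np.zeros(x.shape[0])
    for c in classes:
        mask = np.array([l == c for l in labels])
        pooled += ((x[:, mask] - cents[c][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(pooled / (n - len(classes)))
    s0 = np.median(s)
    out = []
    for j in range(test_expr.shape[1]):
        v = test_expr.to_numpy()[:, j]
        scores = {c: float(np.sum((v - cents[c]) ** 2 / (s + s0) ** 2))
                  - 2 * np.log(priors[c]) for c in classes}
        out.append(min(sorted(classes), key=lambda c: scores[c]))
    return out


class TestFitShrunkenCentroids:
    def test_delta_zero_equals_brute_force(self, rng):
        """At delta=0 predictions match the plain nearest-centroid oracle."""
        for _ in range(20):
            expr, labels = _two_class(rng, effect=float(rng.uniform(0, 2)))
            model = ns.fit_shrunken_centroids(expr, labels, 0.0)
            test = _frame(rng.normal(size=(60, 5)))
            priors = {c: (labels == c).mean() for c in set(labels)}
            assert model.predict(test).tolist() == \
                brute_force_nearest_centroid(expr, labels, priors, test)

    def test_delta_zero_centroids_unshrunk(self, rng):
        expr, labels = _two_class(rng)
        model = ns.fit_shrunken_centroids(expr, labels, 0.0)
        np.testing.assert_allclose(model.shrunken_centroids,
                                   model.class_centroids, atol=1e-10)

    def test_full_shrinkage_majority_class(self, rng):
        expr, labels = _two_class(rng)
        model = ns.fit_shrunken_centroids(expr, labels,
                                          np.abs(model_d(expr, labels)).max()
                                          + 1.0)
        assert model.surviving_genes == []
        preds = model.predict(expr)
        assert set(preds) == {"B"}  # larger prior (7 vs 6)

    def test_signature_monotone_in_delta(self, rng):
        expr, labels = _two_class(rng)
        sizes = [len(ns.fit_shrunken_centroids(expr, labels, d).surviving_genes)
                 for d in np.linspace(0, 6, 25)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_informative_genes_survive_moderate_delta(self, rng):
        expr, labels = _two_class(rng, effect=4.0)
        model = ns.fit_shrunken_centroids(expr, labels, 1.5)
        informative = {f"g{i}" for i in range(15)}
        assert informative <= set(model.surviving_genes)

    def test_validation_errors(self, rng):
        expr, labels = _two_class(rng)
        with pytest.raises(ValueError):
            ns.fit_shrunken_centroids(expr, labels, -0.5)
        lone = pd.Series(["A"] + ["B"] * 12, index=expr.columns)
        with pytest.raises(ValueError):
            ns.fit_shrunken_centroids(expr, lone, 0.0)


def model_d(expr, labels):
    return ns.fit_shrunken_centroids(expr, labels, 0.0).d_ik


class TestCrossValidateNSC:
    def test_separable_data_perfect_accuracy(self, rng):
        expr, labels = _two_class(rng, effect=5.0)
        cv = ns.cross_validate_nsc(expr, labels, np.arange(0, 3, 0.5),
                                   seed=1, positive_label="A")
        assert cv.accuracy == 1.0
        # an interval of deltas achieves zero CV error
        assert (cv.cv_table.cv_errors == 0).sum() >= 2

    def test_permuted_labels_near_majority(self, rng):
        """Null labels give CV accuracy near the majority-class rate."""
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr, labels = _two_class(r, effect=0.0, n_a=6, n_b=8)
            cv = ns.cross_validate_nsc(expr, labels, np.arange(0, 3, 0.5),
                                       seed=seed, positive_label="A")
            accs.append(cv.accuracy)
        assert abs(np.mean(accs) - 8 / 14) < 0.15

    def test_seed_reproducibility(self, rng):
        expr, labels = _two_class(rng, n_a=12, n_b=12)
        cv1 = ns.cross_validate_nsc(expr, labels, [0, 1, 2], n_folds=3,
                                    seed=5, positive_label="A")
        cv2 = ns.cross_validate_nsc(expr, labels, [0, 1, 2], n_folds=3,
                                    seed=5, positive_label="A")
        assert cv1.chosen_delta == cv2.chosen_delta
        assert cv1.signature_genes == cv2.signature_genes
        pd.testing.assert_series_equal(cv1.predictions, cv2.predictions)

    def test_loo_fallback_for_small_classes(self, rng):
        expr, labels = _two_class(rng, n_a=5, n_b=6)
        cv = ns.cross_validate_nsc(expr, labels, [0.0, 1.0], n_folds=10,
                                   seed=0, positive_label="A")
        assert cv.n_folds == 11  # leave-one-out

    def test_empty_grid_rejected(self, rng):
        expr, labels = _two_class(rng)
        with pytest.raises(ValueError):
            ns.cross_validate_nsc(expr, labels, [], seed=0)


class TestCentroidValidator:
    def test_sample_at_centroid(self, rng):
        """A validation sample equal to a group centroid: MSE 0, small p."""
        expr, labels = _two_class(rng, effect=4.0)
        sig = [f"g{i}" for i in range(10)]
        cent_a = expr.loc[sig, (labels == "A").to_numpy()].mean(axis=1)
        valid = pd.DataFrame({"v0": cent_a},
                             index=sig).reindex(expr.index).fillna(0.0)
        rep = ns.centroid_validator(expr, labels, valid,
                                    pd.Series(["A"], index=["v0"]), sig,
                                    n_randomizations=200, seed=0,
                                    positive_label="A")
        assert rep.scores.loc["v0", "mse_A"] == pytest.approx(0.0, abs=1e-12)
        assert rep.scores.loc["v0", "predicted"] == "A"
        assert rep.scores.loc["v0", "randomization_p"] <= 1 / 201 + 1e-12
        assert rep.accuracy == 1.0

    def test_tie_break_to_first_sorted_label(self):
        train = pd.DataFrame(
            {"s0": [0.0, 0.0], "s1": [0.0, 0.0], "s2": [2.0, 2.0],
             "s3": [2.0, 2.0]}, index=["g0", "g1"])
        labels = pd.Series(["B", "B", "A", "A"], index=train.columns)
        valid = pd.DataFrame({"v0": [1.0, 1.0]}, index=["g0", "g1"])
        rep = ns.centroid_validator(train, labels, valid,
                                    pd.Series(["B"], index=["v0"]),
                                    ["g0", "g1"], n_randomizations=10, seed=0)
        assert rep.scores.loc["v0", "predicted"] == "A"
        assert bool(rep.scores.loc["v0", "tie"])

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        """4-gene signature: p equals the 4!-permutation enumeration."""
        expr, labels = _two_class(rng, n_genes=8)
        sig = [f"g{i}" for i in range(4)]
        valid = _frame(rng.normal(size=(8, 3)))
        vlab = pd.Series(["A", "B", "A"], index=valid.columns)
        rep = ns.centroid_validator(expr, labels, valid, vlab, sig,
                                    exhaustive=True, seed=0,
                                    positive_label="A")
        cents = {c: expr.loc[sig, (labels == c).to_numpy()].mean(axis=1)
                 .to_numpy() for c in ("A", "B")}
        for v_id in valid.columns:
            v = valid.loc[sig, v_id].to_numpy()
            obs = min(((v - cents[c]) ** 2).mean() for c in ("A", "B"))
            count = sum(
                min(((np.array(p) - cents[c]) ** 2).mean()
                    for c in ("A", "B")) <= obs
                for p in itertools.permutations(v)
            )
            assert rep.scores.loc[v_id, "randomization_p"] == \
                pytest.approx(count / 24)

    def test_confusion_matrix_sums_and_rates(self, rng):
        expr, labels = _two_class(rng, effect=5.0, n_a=6, n_b=6)
        valid = expr.copy()
        valid.columns = [f"v{j}" for j in range(12)]
        vlab = pd.Series(labels.to_numpy(), index=valid.columns)
        rep = ns.centroid_validator(expr, labels, valid, vlab,
                                    [f"g{i}" for i in range(15)],
                                    n_randomizations=50, seed=1,
                                    positive_label="A")
        assert rep.confusion.to_numpy().sum() == 12
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion.to_numpy()) / 12)

    def test_errors(self, rng):
        expr, labels = _two_class(rng)
        with pytest.raises(ValueError, match="empty signature"):
            ns.centroid_validator(expr, labels, expr, labels, [], seed=0)
        with pytest.raises(ValueError, match="missing"):
            ns.centroid_validator(expr, labels, expr, labels, ["nope"], seed=0)
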