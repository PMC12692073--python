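"""Discriminant modeling: LDA eigenstructure, projection, and stratified
cross-validated accuracy."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from peelfusion import (
    LinearDiscriminantModel,
    MultiBlock,
    autoscale,
    concatenate_blocks,
    cv_accuracy,
    lda_fit,
    lda_transform,
)

from ._oracles import brute_lda_axes


def _two_class_1d(n=20, sep=5.0, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(-sep, sd, n), rng.normal(sep, sd, n)])[:, None]
    y = np.array(["neg"] * n + ["pos"] * n)
    return X, y


class TestLDAFit:
    def test_separable_classes_classified_perfectly(self):
        X, y = _two_class_1d()
        model = LinearDiscriminantModel().fit(X, y)
        assert model.scalings_.shape == (1, 1)
        assert (model.predict(X) == y).all()

    def test_collinear_class_means_put_everything_on_ld1(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal([mu, 0.0], 0.2, size=(15, 2)) for mu in (0.0, 4.0, 8.0)])
        y = np.repeat(["a", "b", "c"], 15)
        res = lda_fit(X, y)
        assert res.explained_variance[0] > 0.99

    def test_eigenvalues_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4)) + np.repeat(np.arange(3)[:, None], 10, axis=0)
        y = np.repeat(["a", "b", "c"], 10)
        ev1 = LinearDiscriminantModel().fit(X, y).eigenvalues_
        perm = [2, 0, 3, 1]
        ev2 = LinearDiscriminantModel().fit(X[:, perm], y).eigenvalues_
        assert np.allclose(ev1, ev2, rtol=1e-8)

    def test_explained_variance_fractions_valid(self, citrus_blocks):
        fused = concatenate_blocks(
            MultiBlock([autoscale(citrus_blocks[b]).block for b in ("spectro", "physico")])
        )
        res = lda_fit(fused.data, fused.labels)
        ev = res.model.explained_variance_ratio_
        assert len(ev) == 5  # six classes -> at most five discriminants
        assert (ev >= 0).all() and ev.sum() <= 1 + 1e-9
        assert (np.diff(ev) <= 1e-12).all()  # non-increasing

    def test_singleton_class_rejected(self):
        X = np.arange(10, dtype=float)[:, None]
        y = np.array(["a"] * 9 + ["b"])
        with pytest.raises(ValueError, match="at least 2 samples"):
            LinearDiscriminantModel().fit(X, y)

    def test_too_many_components_rejected(self):
        X, y = _two_class_1d()
        with pytest.raises(ValueError, match="n_components"):
            LinearDiscriminantModel(n_components=2).fit(X, y)


class TestLDATransform:
    def test_training_scores_match_stored_scores(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(24, 3)) + np.repeat([[0], [3]], 12, axis=0)
        y = np.repeat(["a", "b"], 12)
        res = lda_fit(X, y)
        again = lda_transform(res, X)
        assert np.allclose(again[:, 0], res.scores["LD1"].to_numpy())

    def test_duplicated_row_duplicates_score(self):
        X, y = _two_class_1d()
        model = LinearDiscriminantModel().fit(X, y)
        S = model.transform(np.vstack([X[0], X[0]]))
        assert np.allclose(S[0], S[1])

    def test_affine_shift_moves_scores_by_projected_shift(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 3)) + np.repeat([[0], [2], [4]], 10, axis=0)
        y = np.repeat(["a", "b", "c"], 10)
        model = LinearDiscriminantModel().fit(X, y)
        shift = np.array([1.0, -2.0, 0.5])
        expected = model.transform(X) + shift @ model.scalings_
        assert np.allclose(model.transform(X + shift), expected)

    def test_dimension_mismatch_rejected(self):
        X, y = _two_class_1d()
        model = LinearDiscriminantModel().fit(X, y)
        with pytest.raises(ValueError, match="features"):
            model.transform(np.zeros((3, 2)))


class TestEigenOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_discriminant_subspace_matches_bruteforce_eigensolver(self, seed):
        """On full-rank problems the eigh-based subspace agrees with a dense
        inv(Sw) @ Sb eigensolver to < 1e-6 rad principal angle."""
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 11))
        means = rng.normal(scale=3.0, size=(6, p))
        X = np.vstack([rng.normal(m, 1.0, size=(10, p)) for m in means])
        y = np.repeat(np.arange(6), 10)
        model = LinearDiscriminantModel().fit(X, y)
        _, ref_axes = brute_lda_axes(X, y)
        # largest principal angle between the two 5-D subspaces
        Q1, _ = np.linalg.qr(model.scalings_)
        Q2, _ = np.linalg.qr(ref_axes)
        sv = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
        angle = np.arccos(np.clip(sv.min(), -1, 1))
        assert angle < 1e-6

    def test_predictions_match_sklearn_on_well_conditioned_problem(self):
        rng = np.random.default_rng(21)
        means = rng.normal(scale=4.0, size=(4, 6))
        X = np.vstack([rng.normal(m, 1.0, size=(15, 6)) for m in means])
        y = np.repeat(list("abcd"), 15)
        ours = LinearDiscriminantModel().fit(X, y).predict(X)
        ref = LinearDiscriminantAnalysis(solver="eigen").fit(X, y).predict(X)
        assert (ours == ref).mean() > 0.97


class TestCVAccuracy:
    def test_perfectly_separated_classes_score_one(self):
        X, y = _two_class_1d(n=15)
        res = cv_accuracy(X, y, folds=5, seed=0)
        assert res.mean == 1.0
        assert res.sd == 0.0

    def test_stratified_folds_hold_two_of_each_class(self, citrus_blocks):
        from sklearn.model_selection import StratifiedKFold

        y = citrus_blocks.labels.to_numpy()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test in skf.split(np.zeros((60, 1)), y):
            _, counts = np.unique(y[test], return_counts=True)
            assert (counts == 2).all()

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        X = rng.normal(size=(60, 5))
        y = np.repeat(np.arange(6), 10)
        for seed in range(100):
            perm = np.random.default_rng(seed).permutation(60)
            accs.append(cv_accuracy(X, y[perm], folds=5, seed=seed).mean)
        assert np.mean(accs) == pytest.approx(1 / 6, abs=0.04)

    def test_accuracy_invariant_to_feature_order(self, citrus_blocks):
        fused = concatenate_blocks(
            MultiBlock([autoscale(citrus_blocks[b]).block for b in ("spectro", "physico")])
        )
        X = fused.data
        base = cv_accuracy(X, fused.labels, seed=3).mean
        shuffled = cv_accuracy(X[list(X.columns[::-1])], fused.labels, seed=3).mean
        assert base == shuffled

    def test_per_fold_scaling_mode_runs_and_scores_high(self, citrus_blocks):
        fused = concatenate_blocks(citrus_blocks, ["ftir", "spectro"])
        res = cv_accuracy(fused.data, fused.labels, seed=1, scale_mode="per_fold")
        assert res.mean > 0.9

    def test_class_smaller_than_fold_count_rejected(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="folds"):
            cv_accuracy(X, y, folds=5)

    def test_fold_assignment_deterministic_per_seed(self, citrus_blocks):
        fused = concatenate_blocks(citrus_blocks, ["spectro"])
        a = cv_accuracy(fused.data, fused.labels, seed=9)
        b = cv_accuracy(fused.data, fused.labels, seed=9)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
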