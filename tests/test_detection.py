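"""Window defect classifier bank, balanced splitting and defect maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.naive_bayes import GaussianNB

from wetblue import (
    GlcmConfig,
    balanced_split,
    classify_image,
    generate_leather_image,
    generate_window_feature_table,
    kfold_evaluate,
    predict_window,
    train_defect_model,
)
from wetblue.detection import (
    DEFECT,
    NORMAL,
    REJECTED,
    DefectMap,
    WindowDefectClassifier,
    default_grids,
    split_features,
)
from wetblue.imaging import segment_foreground, tile
from wetblue.synthetic import LeatherSpec, TextureSpec


def make_table(n_per_class, n_features=3, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for label in (0, 1):
        X = rng.normal(label * shift, 1.0, (n_per_class, n_features))
        for x in X:
            rows.append(["img", 0, 0, label, *x])
    cols = ["image_id", "x", "y", "label"] + [f"f{i+1}" for i in range(n_features)]
    return pd.DataFrame(rows, columns=cols)


class TestBalancedSplit:
    def test_reproduces_undersampling_arithmetic(self):
        # class sizes 1669 normal / 2250 defect with 1335 per class for
        # training leave exactly 334 normal and 915 defect test rows
        rows = [[f"n{i}", 0, 0, 1, 0.0] for i in range(1669)]
        rows += [[f"d{i}", 0, 0, 0, 0.0] for i in range(2250)]
        table = pd.DataFrame(rows, columns=["image_id", "x", "y", "label", "f1"])
        train, test = balanced_split(table, 1335, seed=0)
        assert train["label"].value_counts().to_dict() == {0: 1335, 1: 1335}
        assert test["label"].value_counts().to_dict() == {1: 334, 0: 915}

    def test_conserves_rows_without_duplication(self):
        table = make_table(40, seed=1)
        train, test = balanced_split(table, 25, seed=2)
        assert len(train) + len(test) == len(table)
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(table.index)

    def test_full_minority_leaves_empty_minority_test(self):
        table = make_table(30, seed=3)
        extra = make_table(10, seed=4)
        extra = extra[extra["label"] == 1]
        table = pd.concat([table, extra], ignore_index=True)  # 30 defect, 40 normal
        train, test = balanced_split(table, 30, seed=0)
        assert (test["label"] == 0).sum() == 0

    def test_same_seed_identical_assignment(self):
        table = make_table(50, seed=5)
        t1, _ = balanced_split(table, 30, seed=9)
        t2, _ = balanced_split(table, 30, seed=9)
        assert t1.index.equals(t2.index)

    def test_oversized_request_names_class(self):
        table = make_table(20, seed=6)
        with pytest.raises(ValueError, match="class"):
            balanced_split(table, 25, seed=0)


_FOLD_SIZES: list[int] = []


class _RecordingNB(GaussianNB):
    def score(self, X, y):
        _FOLD_SIZES.append(len(X))
        return super().score(X, y)


class TestKfold:
    def test_ten_folds_of_267_on_balanced_2670(self):
        table = make_table(1335, shift=1.0, seed=7)
        X, y = split_features(table)
        _FOLD_SIZES.clear()
        report = kfold_evaluate(_RecordingNB(), X, y, K=10, seed=0)
        assert len(report["fold_accuracies"]) == 10
        assert _FOLD_SIZES == [267] * 10
        assert sum(_FOLD_SIZES) == 2670

    def test_separable_clusters_score_one(self):
        table = make_table(50, shift=20.0, seed=8)
        X, y = split_features(table)
        report = kfold_evaluate(WindowDefectClassifier(random_state=0), X, y, K=5, seed=0)
        assert report["mean"] == pytest.approx(1.0)

    def test_shuffled_labels_score_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (2000, 5))
        y = np.repeat([0, 1], 1000)
        rng.shuffle(y)
        report = kfold_evaluate(GaussianNB(), X, y, K=10, seed=0)
        assert report["mean"] == pytest.approx(0.5, abs=0.05)

    def test_k_exceeding_class_count_raises(self):
        table = make_table(5, seed=10)
        X, y = split_features(table)
        with pytest.raises(ValueError, match="smallest class"):
            kfold_evaluate(GaussianNB(), X, y, K=10, seed=0)


class TestTrainDefectModel:
    def test_separable_toy_data_fits_perfectly(self):
        table = make_table(60, shift=15.0, seed=11)
        model = train_defect_model(None, table, seed=0)
        X, y = split_features(table)
        assert model.score(X, y) == 1.0

    def test_gaussian_nb_matches_bayes_rate_of_unit_gaussians(self):
        # classes at -2 and +2 with unit variance: Bayes accuracy = Phi(2)
        rng = np.random.default_rng(12)
        n = 10_000
        X_train = np.concatenate([rng.normal(-2, 1, n), rng.normal(2, 1, n)])[:, None]
        y_train = np.repeat([0, 1], n)
        X_test = np.concatenate([rng.normal(-2, 1, n), rng.normal(2, 1, n)])[:, None]
        y_test = np.repeat([0, 1], n)
        model = WindowDefectClassifier(family="gaussian_nb").fit(X_train, y_train)
        acc = model.score(X_test, y_test)
        assert acc == pytest.approx(norm.cdf(2), abs=0.01)

    def test_perceptron_cannot_solve_xor_clusters(self):
        rng = np.random.default_rng(13)
        centers = [(-3, -3), (3, 3), (-3, 3), (3, -3)]
        X = np.concatenate([rng.normal(c, 0.3, (50, 2)) for c in centers])
        y = np.repeat([0, 0, 1, 1], 50)
        model = WindowDefectClassifier(family="perceptron", random_state=0).fit(X, y)
        assert model.score(X, y) < 1.0

    def test_singular_covariance_fisher_suggests_regularization(self):
        rng = np.random.default_rng(14)
        base = rng.normal(0, 1, (40, 1))
        X = np.hstack([base, 2 * base])  # perfectly collinear features
        y = np.repeat([0, 1], 20)
        with pytest.raises(ValueError, match="regulariz"):
            WindowDefectClassifier(family="fisher").fit(X, y)


@pytest.fixture(scope="module")
def rejection_model():
    table = make_table(80, shift=3.0, seed=15)
    return train_defect_model(
        WindowDefectClassifier(family="logistic_regression"), table, seed=0
    )


class TestRejection:
    @pytest.fixture()
    def model(self, rejection_model):
        return rejection_model

    def test_confident_posterior_is_labelled(self, model):
        fv = np.full(3, 3.0)
        p = model.predict_proba(fv.reshape(1, -1))[0, 1]
        assert p > 0.95
        assert predict_window(model, fv, rejection_band=0.1) == NORMAL

    def test_posterior_near_half_is_rejected(self, model):
        # find the decision boundary region by scanning along the class axis
        ts = np.linspace(-1, 2, 400)
        X = np.stack([np.full(3, t) for t in ts])
        p = model.predict_proba(X)[:, 1]
        i = int(np.argmin(np.abs(p - 0.5)))
        assert abs(p[i] - 0.5) < 0.02
        assert predict_window(model, X[i], rejection_band=0.1) == REJECTED

    def test_zero_band_never_rejects(self, model):
        rng = np.random.default_rng(16)
        X = rng.normal(0.5, 2.0, (200, 3))
        labels = model.predict_with_rejection(X, rejection_band=0.0)
        assert REJECTED not in labels

    def test_widening_band_never_relabels_rejections(self, model):
        rng = np.random.default_rng(17)
        X = rng.normal(0.5, 2.0, (300, 3))
        narrow = model.predict_with_rejection(X, rejection_band=0.05)
        wide = model.predict_with_rejection(X, rejection_band=0.3)
        assert ((narrow == REJECTED) & (wide != REJECTED)).sum() == 0


class _ConstantModel:
    """Stub classifier predicting a fixed label for every window."""

    def __init__(self, label):
        self.label = label
        self.classes_ = np.array([DEFECT, NORMAL])

    def predict_with_rejection(self, X, rejection_band=None):
        return np.full(len(X), self.label)


class TestClassifyImage:
    def test_always_normal_model_yields_all_ones_map(self, small_spec):
        skin = generate_leather_image(small_spec, render=True)
        dmap = classify_image(
            _ConstantModel(NORMAL), skin.image, skin.grid, GlcmConfig()
        )
        assert np.array_equal(dmap.values, skin.grid.validity.astype(int))

    def test_invalid_cells_always_zero(self, small_spec):
        skin = generate_leather_image(small_spec, render=True)
        dmap = classify_image(
            _ConstantModel(NORMAL), skin.image, skin.grid, GlcmConfig()
        )
        assert (dmap.values[~skin.grid.validity] == 0).all()

    def test_planted_defects_recovered_exactly(self, small_spec, defect_model_small):
        from dataclasses import replace

        spec = replace(small_spec, n_defects=2, seed=21)
        skin = generate_leather_image(spec, render=True)
        dmap = classify_image(defect_model_small, skin.image, skin.grid, GlcmConfig())
        valid = skin.grid.validity
        assert np.array_equal(dmap.values[valid], skin.true_map.values[valid])
        assert (dmap.values == 0).sum() == (~valid).sum() + 2

    def test_defect_map_values_binary(self):
        with pytest.raises(ValueError, match="0 or 1"):
            DefectMap(values=np.array([[0, 2]]))


class TestEndToEndSeparability:
    def test_default_pipeline_exceeds_90pct_on_separable_textures(self):
        # premise check: >= 2 pooled-SD GLCM-contrast margin between textures
        table = generate_window_feature_table(300, T=51, seed=22)
        contrast = table["f2"]
        by = table.groupby("label")["f2"]
        pooled = np.sqrt(by.var().mean())
        margin = abs(by.mean().diff().iloc[-1]) / pooled
        assert margin >= 2.0
        train, test = balanced_split(table, 200, seed=1)
        model = train_defect_model(None, train, seed=0)
        X, y = split_features(test)
        assert model.score(X, y) >= 0.90


def test_default_grids_cover_the_bank():
    grids = default_grids()
    assert set(grids) == {
        "perceptron", "logistic_regression", "knn", "fisher",
        "gaussian_nb", "mlp", "svm",
    }
    assert [g["n_neighbors"] for g in grids["knn"]] == [3, 5, 7, 9, 11]
    assert {g["C"] for g in grids["logistic_regression"]} == {0.01, 0.1, 1.0, 10.0}
    assert {g["kernel"] for g in grids["svm"]} == {"linear", "rbf", "poly", "sigmoid"}
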