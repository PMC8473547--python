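"""Binary window classifier bank: defect vs. normal leather windows.

The training design mirrors a class-balanced undersampling protocol: an equal
number of windows per class is drawn for training (balance avoids a bias
toward the majority class in the binary decision) and every remaining window
goes to the test set.  Model selection uses stratified 10-fold
cross-validation on the training set.

Seven classifier families are available; the default configuration is the
strongest one found for this problem — GLCM features on 51-pixel windows fed
to an RBF-kernel SVM with C = 10.  An optional rejection band lets the
classifier abstain when the posterior is too close to 0.5; rejected windows
are treated as defects downstream, the conservative choice for grading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, Perceptron
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.multiclass import check_classification_targets
from sklearn.utils.validation import check_is_fitted, validate_data

from .imaging import WindowGrid
from .texture import ExtractorConfig, LABEL_DEFECT, LABEL_NORMAL, extract_features

__all__ = [
    "DEFECT",
    "NORMAL",
    "REJECTED",
    "FAMILIES",
    "DefectMap",
    "WindowDefectClassifier",
    "balanced_split",
    "kfold_evaluate",
    "train_defect_model",
    "predict_window",
    "classify_image",
    "default_grids",
]

DEFECT = LABEL_DEFECT  # 0
NORMAL = LABEL_NORMAL  # 1
REJECTED = -1

FAMILIES = (
    "perceptron",
    "logistic_regression",
    "knn",
    "fisher",
    "gaussian_nb",
    "mlp",
    "svm",
)

#: Iterative families stop after 2000 iterations or when the error improvement
#: falls below 1e-5.
MAX_ITER = 2000
TOL = 1e-5

#: Families whose decision is sensitive to feature scale and therefore get a
#: train-set standardization step in front.
_SCALE_SENSITIVE = {"perceptron", "logistic_regression", "knn", "mlp", "svm"}


@dataclass(frozen=True)
class DefectMap:
    """Per-window defect map of one skin sample.

    ``values[i, j]`` is 1 for a window classified as normal leather and 0 for
    a defect, rejected or background (invalid) window.
    """

    values: np.ndarray
    image_id: Optional[str] = None
    window_size: Optional[int] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=int)
        if vals.ndim != 2:
            raise ValueError(f"defect map must be 2-D, got shape {vals.shape}")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("defect map values must be 0 or 1")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def balanced_split(
    table: pd.DataFrame,
    n_train_per_class: int,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-balanced train/test split of a labelled feature table.

    Exactly ``n_train_per_class`` rows per class are drawn without replacement
    (seeded) for the training set; every remaining row forms the test set.
    E.g. with class sizes 1669/2250 and 1335 per class for training, the test
    set holds 334 and 915 rows respectively.
    """
    if label_col not in table.columns:
        raise ValueError(f"table has no {label_col!r} column")
    classes = table[label_col].unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present in the table")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    for cls in sorted(classes):
        idx = table.index[table[label_col] == cls].to_numpy()
        if n_train_per_class > idx.size:
            raise ValueError(
                f"n_train_per_class={n_train_per_class} exceeds the "
                f"{idx.size} rows of class {cls!r}"
            )
        train_idx.append(rng.choice(idx, size=n_train_per_class, replace=False))
    train_idx = np.concatenate(train_idx)
    train = table.loc[np.sort(train_idx)]
    test = table.drop(index=train_idx)
    return train, test


def _make_family_estimator(
    family: str,
    *,
    C: float = 10.0,
    kernel: str = "rbf",
    degree: int = 3,
    n_neighbors: int = 5,
    hidden_units: int = 65,
    activation: str = "logistic",
    learning_rate: float = 0.5,
    learning_rate_decay: str = "linear",
    random_state: Optional[int] = None,
):
    """Instantiate the underlying sklearn estimator for a classifier family."""
    if family == "perceptron":
        return Perceptron(
            eta0=learning_rate, max_iter=MAX_ITER, tol=TOL, random_state=random_state
        )
    if family == "logistic_regression":
        return LogisticRegression(C=C, max_iter=MAX_ITER, tol=TOL)
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=n_neighbors, metric="euclidean")
    if family == "fisher":
        return LinearDiscriminantAnalysis()
    if family == "gaussian_nb":
        return GaussianNB()
    if family == "mlp":
        # sklearn's SGD solver offers inverse-scaling decay, the closest
        # available schedule to a linear/exponential learning-rate decay.
        return MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            activation=activation,
            solver="sgd",
            learning_rate="invscaling" if learning_rate_decay else "constant",
            learning_rate_init=learning_rate,
            max_iter=MAX_ITER,
            tol=TOL,
            random_state=random_state,
        )
    if family == "svm":
        # posterior for the rejection band comes from a separate Platt
        # calibration on the margins (see WindowDefectClassifier.fit)
        return SVC(
            kernel=kernel,
            C=C,
            degree=degree,
            gamma="scale",
            random_state=random_state,
        )
    raise ValueError(f"unknown classifier family {family!r}; choose from {FAMILIES}")


class WindowDefectClassifier(ClassifierMixin, BaseEstimator):
    """Binary defect/normal window classifier with an optional rejection band.

    Parameters
    ----------
    family : str
        One of ``perceptron, logistic_regression, knn, fisher, gaussian_nb,
        mlp, svm``.
    C : float
        Penalty parameter for SVM / logistic regression.
    kernel : str
        SVM kernel (``linear, rbf, poly, sigmoid``).
    n_neighbors : int
        K for the KNN family (Euclidean distance).
    hidden_units, activation, learning_rate, learning_rate_decay
        MLP / perceptron settings.
    rejection_band : float
        Total width of the abstention interval around posterior 0.5; a sample
        is rejected when ``|p(normal) - 0.5| < rejection_band / 2``.  0
        disables rejection.
    standardize : bool
        Standardize features (train-set mean/variance) before scale-sensitive
        families.

    Attributes
    ----------
    model_ : fitted sklearn estimator (possibly a Pipeline)
    classes_ : ndarray of the two class labels
    """

    def __init__(
        self,
        family: str = "svm",
        C: float = 10.0,
        kernel: str = "rbf",
        degree: int = 3,
        n_neighbors: int = 5,
        hidden_units: int = 65,
        activation: str = "logistic",
        learning_rate: float = 0.5,
        learning_rate_decay: str = "linear",
        rejection_band: float = 0.0,
        standardize: bool = True,
        random_state: Optional[int] = None,
    ):
        self.family = family
        self.C = C
        self.kernel = kernel
        self.degree = degree
        self.n_neighbors = n_neighbors
        self.hidden_units = hidden_units
        self.activation = activation
        self.learning_rate = learning_rate
        self.learning_rate_decay = learning_rate_decay
        self.rejection_band = rejection_band
        self.standardize = standardize
        self.random_state = random_state

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.classifier_tags.multi_class = False
        return tags

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        check_classification_targets(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "training data holds only 1 class; both defect and normal "
                "windows are required"
            )
        if classes.size > 2:
            raise ValueError(
                "Only binary classification is supported. The type of the "
                f"target has {classes.size} classes."
            )
        if not 0 <= self.rejection_band < 1:
            raise ValueError(
                f"rejection_band must be in [0, 1), got {self.rejection_band}"
            )
        if self.family == "fisher":
            self._check_within_class_covariance(X, y, classes)
        est = _make_family_estimator(
            self.family,
            C=self.C,
            kernel=self.kernel,
            degree=self.degree,
            n_neighbors=self.n_neighbors,
            hidden_units=self.hidden_units,
            activation=self.activation,
            learning_rate=self.learning_rate,
            learning_rate_decay=self.learning_rate_decay,
            random_state=self.random_state,
        )
        if self.standardize and self.family in _SCALE_SENSITIVE:
            est = Pipeline([("scale", StandardScaler()), ("clf", est)])
        est.fit(X, y)
        self.model_ = est
        self.classes_ = classes
        if self.family in ("svm", "perceptron") and classes.size == 2:
            # Platt scaling: logistic map from the signed distance to the
            # margin to a posterior; used only for the rejection band.
            margins = est.decision_function(X).reshape(-1, 1)
            self.calibrator_ = LogisticRegression().fit(margins, y)
        return self

    @staticmethod
    def _check_within_class_covariance(X, y, classes) -> None:
        Xc = np.vstack([X[y == c] - X[y == c].mean(axis=0) for c in classes])
        cov = Xc.T @ Xc / max(len(Xc) - len(classes), 1)
        if np.linalg.matrix_rank(cov) < X.shape[1]:
            raise ValueError(
                "within-class covariance is singular; remove collinear "
                "features or add shrinkage regularization"
            )

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if hasattr(self, "calibrator_"):
            # keep predictions consistent with the calibrated posterior
            p_pos = self.predict_proba(X)[:, 1]
            return np.where(p_pos >= 0.5, self.classes_[1], self.classes_[0])
        return self.model_.predict(X)

    def predict_proba(self, X):
        """Posterior probabilities ordered by ``classes_``.

        Margin-based families without a native posterior (SVM, perceptron)
        use a Platt-calibrated logistic map of the decision function fitted on
        the training margins.
        """
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if hasattr(self, "calibrator_"):
            margin = self.model_.decision_function(X).reshape(-1, 1)
            return self.calibrator_.predict_proba(margin)
        return self.model_.predict_proba(X)

    def predict_with_rejection(self, X, rejection_band: Optional[float] = None):
        """Labels in {0 defect, 1 normal, -1 rejected}.

        A window is rejected when its posterior for the normal class lies
        within ``rejection_band / 2`` of 0.5; otherwise the argmax label is
        returned.  Widening the band can only convert labelled windows to
        rejected, never the reverse.
        """
        band = self.rejection_band if rejection_band is None else rejection_band
        proba = self.predict_proba(X)
        # classes_ is sorted, so with the canonical 0/1 labels the second
        # column is the posterior of the normal class
        p_normal = proba[:, 1]
        labels = np.where(p_normal >= 0.5, self.classes_[1], self.classes_[0])
        if band > 0:
            labels = np.where(np.abs(p_normal - 0.5) < band / 2, REJECTED, labels)
        return labels


def kfold_evaluate(
    clf: BaseEstimator,
    X,
    y,
    K: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified K-fold cross-validation accuracies of an (unfitted) classifier.

    Folds are of near-equal size; each row is held out exactly once.  Returns
    ``{"fold_accuracies": [...], "mean": m, "std": s}``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    _, counts = np.unique(y, return_counts=True)
    if K > counts.min():
        raise ValueError(
            f"K={K} exceeds the smallest class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        model = clone(clf).fit(X[train_idx], y[train_idx])
        accs.append(float(model.score(X[test_idx], y[test_idx])))
    accs = np.asarray(accs)
    return {
        "fold_accuracies": accs.tolist(),
        "mean": float(accs.mean()),
        "std": float(accs.std()),
    }


def train_defect_model(
    cfg: Optional[WindowDefectClassifier],
    train: pd.DataFrame,
    seed: Optional[int] = None,
    label_col: str = "label",
) -> WindowDefectClassifier:
    """Fit a window defect classifier on a labelled feature table.

    ``cfg`` is an unfitted :class:`WindowDefectClassifier` used as a template
    (``None`` selects the default SVM-RBF, C=10).  A copy is fitted and
    returned, with ``seed`` installed as its ``random_state``.
    """
    if cfg is None:
        cfg = WindowDefectClassifier()
    model = clone(cfg)
    if seed is not None:
        model.set_params(random_state=seed)
    X, y = split_features(train, label_col=label_col)
    return model.fit(X, y)


def split_features(
    table: pd.DataFrame, label_col: str = "label"
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from a feature table: columns f1..fK and the label."""
    feat_cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    if not feat_cols:
        raise ValueError("table has no feature columns f1..fK")
    X = table[feat_cols].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    return X, y


def predict_window(
    model: WindowDefectClassifier, fv: np.ndarray, rejection_band: float = 0.0
) -> int:
    """Label a single feature vector: 0 defect, 1 normal, -1 rejected."""
    fv = np.asarray(fv, dtype=float).reshape(1, -1)
    return int(model.predict_with_rejection(fv, rejection_band=rejection_band)[0])


def classify_image(
    model: WindowDefectClassifier,
    img: np.ndarray,
    grid: WindowGrid,
    extractor: ExtractorConfig,
    image_id: Optional[str] = None,
) -> DefectMap:
    """Per-window defect map of a tiled skin image.

    Every valid grid cell is featurized and classified; rejected windows count
    as defect (0), and invalid (background) cells are always 0.
    """
    if not grid.validity.any():
        return DefectMap(
            values=np.zeros((grid.rows, grid.cols), dtype=int),
            image_id=image_id,
            window_size=grid.window_size,
        )
    cells = np.argwhere(grid.validity)
    feats = []
    for i, j in cells:
        ys, xs = grid.cell_slices(i, j)
        feats.append(extract_features(img[ys, xs], extractor))
    labels = model.predict_with_rejection(np.asarray(feats))
    values = np.zeros((grid.rows, grid.cols), dtype=int)
    for (i, j), lab in zip(cells, labels):
        values[i, j] = 1 if lab == NORMAL else 0
    return DefectMap(values=values, image_id=image_id, window_size=grid.window_size)


def default_grids() -> dict[str, list[dict]]:
    """Hyperparameter grids of the classifier bank for the comparison harness."""
    grids: dict[str, list[dict]] = {
        "perceptron": [
            {"learning_rate": lr, "learning_rate_decay": d}
            for lr in (0.01, 0.05, 0.1, 0.5)
            for d in ("linear", "exponential")
        ],
        "logistic_regression": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
        "knn": [{"n_neighbors": k} for k in (3, 5, 7, 9, 11)],
        "fisher": [{}],
        "gaussian_nb": [{}],
        "mlp": [
            {"hidden_units": h, "activation": a, "learning_rate": lr}
            for h in (2, 10, 35, 65, 100)
            for a in ("logistic", "tanh")
            for lr in (0.1, 0.3, 0.5)
        ],
        "svm": [
            {"kernel": k, "C": c}
            for k in ("linear", "rbf", "poly", "sigmoid")
            for c in (0.01, 0.1, 1.0, 10.0)
        ],
    }
    return grids
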