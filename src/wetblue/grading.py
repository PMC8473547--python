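"""Seven-level quality grading of whole skins and inter-expert agreement.

Quality labels run from 1 (best) to 7 (worst).  Because manual grading is
subjective, the training set is restricted to skins that two independent
experts graded identically (coincident labelling); the grader is then trained
on a class-balanced undersample — 75% of the smallest class's count drawn from
every class — and evaluated on the remainder.  The default grader is Gaussian
Naive Bayes over the seven region attributes, the family that generalizes
best on this small-sample problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.multiclass import check_classification_targets
from sklearn.utils.validation import check_is_fitted, validate_data

from . import imaging
from .detection import DefectMap, WindowDefectClassifier, _make_family_estimator, classify_image
from .imaging import WindowGrid
from .regions import DEFAULT_K, Region, quality_attributes, top_k_regions
from .texture import ExtractorConfig, GlcmConfig

__all__ = [
    "QUALITY_LEVELS",
    "AgreementReport",
    "QualityGrader",
    "QualityResult",
    "filter_coincident",
    "expert_agreement",
    "undersample_quality",
    "train_quality_model",
    "build_quality_table",
    "qualify_sample",
]

QUALITY_LEVELS = tuple(range(1, 8))


@dataclass(frozen=True)
class AgreementReport:
    """Cross-tabulation of two graders' labels and their coincidence rate."""

    matrix: pd.DataFrame  # rows: grader A levels, cols: grader B levels
    percent_agreement: float
    n: int


def filter_coincident(samples: pd.DataFrame) -> pd.DataFrame:
    """Keep only samples graded identically by both experts.

    ``samples`` must carry ``label_expert_a`` and ``label_expert_b`` columns
    with no missing values; a missing label raises, naming the sample.
    """
    for col in ("label_expert_a", "label_expert_b"):
        if col not in samples.columns:
            raise ValueError(f"samples are missing the {col!r} column")
        bad = samples.index[samples[col].isna()]
        if len(bad):
            raise ValueError(f"sample {bad[0]!r} has no {col} label")
    keep = samples["label_expert_a"] == samples["label_expert_b"]
    return samples.loc[keep]


def expert_agreement(labels_a: Sequence[int], labels_b: Sequence[int]) -> AgreementReport:
    """7x7 label cross-tabulation and the diagonal (coincidence) percentage."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.size != b.size:
        raise ValueError(
            f"label lists must be non-empty and of equal length, "
            f"got {a.size} and {b.size}"
        )
    levels = list(QUALITY_LEVELS)
    matrix = (
        pd.crosstab(pd.Series(a, name="expert_a"), pd.Series(b, name="expert_b"))
        .reindex(index=levels, columns=levels, fill_value=0)
    )
    diag = int(np.trace(matrix.to_numpy()))
    return AgreementReport(
        matrix=matrix,
        percent_agreement=100.0 * diag / a.size,
        n=int(a.size),
    )


def undersample_quality(
    samples: pd.DataFrame,
    train_fraction_of_min: float = 0.75,
    seed: int = 0,
    label_col: str = "level",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-balanced train/test split for the 7-class grading problem.

    Every class contributes ``floor(train_fraction_of_min * smallest class
    size)`` training samples (seeded, without replacement); the remainder is
    the test set.  E.g. a smallest class of 8 at 75% gives 6 per class — 42
    training samples over 7 classes — and 131 coincident samples leave 89 for
    testing.  All 7 levels must be present.
    """
    if not 0 < train_fraction_of_min < 1:
        raise ValueError(
            f"train_fraction_of_min must be in (0, 1), got {train_fraction_of_min}"
        )
    counts = samples[label_col].value_counts()
    for level in QUALITY_LEVELS:
        if counts.get(level, 0) == 0:
            raise ValueError(f"quality level {level} is absent from the samples")
    n_per_class = int(np.floor(train_fraction_of_min * counts.min()))
    if n_per_class < 1:
        raise ValueError("smallest class too small for the requested fraction")
    rng = np.random.default_rng(seed)
    train_idx = np.concatenate(
        [
            rng.choice(
                samples.index[samples[label_col] == level].to_numpy(),
                size=n_per_class,
                replace=False,
            )
            for level in QUALITY_LEVELS
        ]
    )
    train = samples.loc[np.sort(train_idx)]
    test = samples.drop(index=train_idx)
    return train, test


class QualityGrader(ClassifierMixin, BaseEstimator):
    """Multiclass (7-level) skin-quality classifier over the 7 region attributes.

    The ``family`` parameter selects the underlying model from the same bank
    as the window classifier; the default, Gaussian Naive Bayes, assumes
    conditionally independent Gaussian attributes per level — crude, but
    robust for the few dozen coincidently-labelled training skins available.
    """

    def __init__(
        self,
        family: str = "gaussian_nb",
        C: float = 10.0,
        kernel: str = "rbf",
        hidden_units: int = 65,
        random_state: Optional[int] = None,
    ):
        self.family = family
        self.C = C
        self.kernel = kernel
        self.hidden_units = hidden_units
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        check_classification_targets(y)
        if np.unique(y).size < 2:
            raise ValueError(
                "training data holds only 1 class; at least 2 quality levels "
                "are required"
            )
        self.model_ = _make_family_estimator(
            self.family,
            C=self.C,
            kernel=self.kernel,
            hidden_units=self.hidden_units,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.model_.predict(X)


def train_quality_model(
    train: pd.DataFrame,
    cfg: Optional[QualityGrader] = None,
    seed: Optional[int] = None,
    label_col: str = "level",
) -> QualityGrader:
    """Fit a quality grader on a table with columns ``a1..a7`` and ``level``."""
    if cfg is None:
        cfg = QualityGrader()
    model = clone(cfg)
    if seed is not None:
        model.set_params(random_state=seed)
    X = train[[f"a{i}" for i in range(1, 8)]].to_numpy(dtype=float)
    y = train[label_col].to_numpy()
    return model.fit(X, y)


def build_quality_table(
    maps: Sequence,
    levels: Optional[Sequence[int]] = None,
    k: int = DEFAULT_K,
    image_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Attribute table ``image_id, a1..a7[, level]`` from defect maps."""
    rows = []
    for idx, m in enumerate(maps):
        attrs = quality_attributes(m, k=k)
        image_id = image_ids[idx] if image_ids is not None else getattr(m, "image_id", idx)
        row = {"image_id": image_id}
        row.update({f"a{i + 1}": attrs[i] for i in range(7)})
        if levels is not None:
            row["level"] = int(levels[idx])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QualityResult:
    """End-to-end grading output with every intermediate kept for audit."""

    level: int
    defect_map: DefectMap
    regions: list[Region]
    attributes: np.ndarray
    grid: WindowGrid
    mask: np.ndarray


def qualify_sample(
    img: np.ndarray,
    defect_model: WindowDefectClassifier,
    quality_model: QualityGrader,
    T: int = 51,
    k: int = DEFAULT_K,
    extractor: Optional[ExtractorConfig] = None,
    threshold: int = imaging.DEFAULT_THRESHOLD,
    min_fg_fraction: float = imaging.DEFAULT_MIN_FG_FRACTION,
    image_id: Optional[str] = None,
) -> QualityResult:
    """Grade one skin photograph end to end.

    Deterministic composition: segment the leather from the dark background,
    tile it into ``T``-pixel windows, classify each window, extract the ``k``
    largest defect-free rectangles, compute the seven attributes and predict
    the quality level.  Stage failures are re-raised tagged with the stage
    name.
    """
    extractor = extractor if extractor is not None else GlcmConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"qualification failed at stage '{name}': {exc}") from exc

    mask = stage("segmentation", imaging.segment_foreground, img, threshold)
    grid = stage("tiling", imaging.tile, img, mask, T, min_fg_fraction)
    dmap = stage(
        "detection", classify_image, defect_model, img, grid, extractor, image_id
    )
    regions = stage("region_extraction", top_k_regions, dmap, k)
    attrs = stage("attributes", quality_attributes, dmap, regions, k)
    level = int(stage("grading", quality_model.predict, attrs.reshape(1, -1))[0])
    return QualityResult(
        level=level,
        defect_map=dmap,
        regions=regions,
        attributes=attrs,
        grid=grid,
        mask=mask,
    )
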