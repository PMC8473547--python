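"""Shared fixtures: small trained models and synthetic corpora.

The "small" geometry (24-pixel windows on a ~312x408 image) keeps end-to-end
tests fast while exercising the identical code paths as the default 51-pixel
configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from wetblue import (
    GlcmConfig,
    LeatherSpec,
    QualityGrader,
    balanced_split,
    build_quality_table,
    generate_corpus,
    generate_window_feature_table,
    train_defect_model,
    train_quality_model,
    undersample_quality,
)
from wetblue.detection import WindowDefectClassifier


def brute_force_max_area(grid: np.ndarray) -> int:
    """Exhaustive maximal all-ones rectangle area (independent oracle).

    Enumerates every (top, left, height, width) rectangle and checks the cell
    sum against an integral image; O(rows^2 * cols^2).
    """
    grid = np.asarray(grid, dtype=int)
    rows, cols = grid.shape
    # summed-area table with a zero border
    sat = np.zeros((rows + 1, cols + 1), dtype=int)
    sat[1:, 1:] = grid.cumsum(axis=0).cumsum(axis=1)
    best = 0
    for top in range(rows):
        for left in range(cols):
            for bottom in range(top, rows):
                for right in range(left, cols):
                    area = (bottom - top + 1) * (right - left + 1)
                    if area <= best:
                        continue
                    s = (
                        sat[bottom + 1, right + 1]
                        - sat[top, right + 1]
                        - sat[bottom + 1, left]
                        + sat[top, left]
                    )
                    if s == area:
                        best = area
    return best


@pytest.fixture(scope="session")
def rectangle_oracle():
    return brute_force_max_area


SMALL_T = 24

SMALL_SPEC = LeatherSpec(
    height=312,
    width=408,
    blob_axes=(130, 180),
    window_size=SMALL_T,
    defect_size=SMALL_T,
)


@pytest.fixture(scope="session")
def small_spec() -> LeatherSpec:
    return SMALL_SPEC


@pytest.fixture(scope="session")
def glcm_cfg() -> GlcmConfig:
    return GlcmConfig()


@pytest.fixture(scope="session")
def defect_table_small():
    """Labelled GLCM feature table of 120 normal + 120 defect 24-px windows."""
    return generate_window_feature_table(120, T=SMALL_T, seed=11)


@pytest.fixture(scope="session")
def defect_model_small(defect_table_small):
    """Default SVM-RBF window classifier trained on the small window table."""
    train, _ = balanced_split(defect_table_small, 100, seed=1)
    return train_defect_model(WindowDefectClassifier(), train, seed=0)


@pytest.fixture(scope="session")
def quality_corpus_small():
    """140 synthetic skins (ground-truth maps only) over all 7 levels."""
    return generate_corpus(SMALL_SPEC, n_images=140, seed=7, render=False)


@pytest.fixture(scope="session")
def quality_table_small(quality_corpus_small):
    corpus = quality_corpus_small
    return build_quality_table(
        [s.true_map for s in corpus.skins],
        corpus.grades["level"].to_numpy(),
        image_ids=corpus.grades["image_id"],
    )


@pytest.fixture(scope="session")
def quality_model_small(quality_table_small):
    train, _ = undersample_quality(quality_table_small, seed=3)
    return train_quality_model(train, QualityGrader(), seed=0)
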