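"""Per-window texture descriptors: 13 Haralick GLCM measures and LBP histograms.

The gray-level co-occurrence matrix (GLCM) counts how often pairs of quantized
gray levels co-occur at a fixed pixel offset; the Haralick statistics condense
the normalized matrix into texture measures (energy, contrast, correlation,
entropies, ...).  Of the classic 14 measures only the first 13 are computed —
the maximal correlation coefficient (f14) is numerically unstable and is
conventionally dropped.

Local binary patterns (LBP) threshold a circular pixel neighborhood against
its center pixel and pool the resulting codes into a normalized histogram.
Three variants are supported: ``uniform`` (non-rotation-invariant uniform
patterns, 59 bins at P=8), ``rotation_invariant`` (minimum circular rotation
of the raw code) and ``uniform_rotation_invariant`` (P+2 bins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, local_binary_pattern

from .imaging import Patch, extract_window

__all__ = [
    "GlcmConfig",
    "LbpConfig",
    "HARALICK_NAMES",
    "glcm_features",
    "lbp_features",
    "feature_names",
    "build_feature_table",
]

logger = logging.getLogger(__name__)

_VALID_ANGLES = (0, 45, 90, 135)

HARALICK_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_correlation_1",
    "info_measure_correlation_2",
)


@dataclass(frozen=True)
class GlcmConfig:
    """GLCM accumulation parameters.

    256 gray values are quantized into ``levels`` bins; co-occurrences are
    counted for every (distance, angle) pair, symmetrized and normalized, and
    the 13 Haralick measures are averaged over the pairs so the descriptor is
    always length 13.  32 levels keep 51-pixel windows from producing sparse
    matrices.
    """

    levels: int = 32
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if not self.distances or any(d < 1 for d in self.distances):
            raise ValueError(f"distances must all be >= 1, got {self.distances}")
        if not self.angles or any(a not in _VALID_ANGLES for a in self.angles):
            raise ValueError(
                f"angles must be drawn from {_VALID_ANGLES}, got {self.angles}"
            )


@dataclass(frozen=True)
class LbpConfig:
    """LBP parameters: P sampling points on a circle of radius R."""

    neighbors: int = 8
    radius: int = 1
    variant: str = "uniform"

    def __post_init__(self) -> None:
        if self.neighbors < 4:
            raise ValueError(f"neighbors must be >= 4, got {self.neighbors}")
        if self.neighbors > 16:
            raise ValueError(
                f"neighbors > 16 makes the raw-code histogram impractical, "
                f"got {self.neighbors}"
            )
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.variant not in _LBP_METHODS:
            raise ValueError(
                f"variant must be one of {sorted(_LBP_METHODS)}, got {self.variant!r}"
            )


ExtractorConfig = Union[GlcmConfig, LbpConfig]

_LBP_METHODS = {
    "uniform": "nri_uniform",
    "rotation_invariant": "ror",
    "uniform_rotation_invariant": "uniform",
}


def _patch_pixels(patch) -> np.ndarray:
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    if pixels.ndim != 2:
        raise ValueError(f"patch must be 2-D, got shape {pixels.shape}")
    return pixels


def glcm_features(patch, cfg: GlcmConfig = GlcmConfig()) -> np.ndarray:
    """Length-13 Haralick descriptor of a patch.

    The patch is quantized to ``cfg.levels`` gray bins; one co-occurrence
    matrix is accumulated per (distance, angle), normalized to sum to one, the
    13 measures are computed per matrix and averaged across matrices.

    Measures whose denominator vanishes on degenerate (e.g. constant) patches
    are defined as 0 rather than raising.
    """
    pixels = _patch_pixels(patch)
    if pixels.shape[0] < 2 or pixels.shape[1] < 2:
        raise ValueError(f"patch must be at least 2x2, got {pixels.shape}")
    q = quantize(pixels, cfg.levels)
    rad = np.deg2rad(cfg.angles)
    mats = graycomatrix(
        q,
        distances=list(cfg.distances),
        angles=list(rad),
        levels=cfg.levels,
        symmetric=cfg.symmetric,
        normed=False,
    ).astype(np.float64)
    feats = []
    for di in range(mats.shape[2]):
        for ai in range(mats.shape[3]):
            P = mats[:, :, di, ai]
            total = P.sum()
            if cfg.normalize and total > 0:
                P = P / total
            feats.append(haralick_measures(P))
    return np.mean(feats, axis=0)


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize uint8 intensities into ``levels`` bins."""
    return ((np.asarray(pixels, dtype=np.int64) * levels) // 256).astype(np.uint8)


def haralick_measures(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of a normalized co-occurrence matrix.

    ``P`` must be square and sum to 1 (an all-zero matrix yields all zeros).
    Natural logarithms are used for the entropy-based measures.
    """
    P = np.asarray(P, dtype=np.float64)
    L = P.shape[0]
    idx = np.arange(L, dtype=np.float64)
    I, J = np.meshgrid(idx, idx, indexing="ij")

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sd_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))

    # Sum (i+j in 0..2L-2) and absolute-difference (|i-j| in 0..L-1) marginals.
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (np.arange(L)[:, None] + np.arange(L)[None, :]).ravel(), P.ravel())
    p_dif = np.zeros(L)
    np.add.at(
        p_dif, np.abs(np.arange(L)[:, None] - np.arange(L)[None, :]).ravel(), P.ravel()
    )
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_dif = idx

    f1 = float((P**2).sum())
    f2 = float((k_dif**2) @ p_dif)
    if sd_x > 0 and sd_y > 0:
        f3 = float(((I * J * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        f3 = 0.0
    f4 = float((((I - mu_x) ** 2) * P).sum())
    f5 = float((P / (1.0 + (I - J) ** 2)).sum())
    f6 = float(k_sum @ p_sum)
    f7 = float(((k_sum - f6) ** 2) @ p_sum)
    f8 = _entropy(p_sum)
    f9 = _entropy(P)
    mu_d = float(k_dif @ p_dif)
    f10 = float(((k_dif - mu_d) ** 2) @ p_dif)
    f11 = _entropy(p_dif)

    # Information measures of correlation.
    pxpy = np.outer(px, py)
    nz = pxpy > 0
    hxy = f9
    hxy1 = -float((P[nz] * np.log(pxpy[nz])).sum())
    hxy2 = _entropy(pxpy)
    hx = _entropy(px)
    hy = _entropy(py)
    denom = max(hx, hy)
    f12 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13])


def _entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=np.float64).ravel()
    nz = p > 0
    return -float((p[nz] * np.log(p[nz])).sum())


@lru_cache(maxsize=None)
def _lbp_bin_codes(neighbors: int, variant: str) -> tuple[int, ...]:
    """The achievable LBP code values for a variant, in ascending order."""
    P = neighbors
    if variant == "uniform":  # skimage 'nri_uniform': indices 0 .. P*(P-1)+2
        return tuple(range(P * (P - 1) + 3))
    if variant == "uniform_rotation_invariant":  # skimage 'uniform': 0 .. P+1
        return tuple(range(P + 2))
    # rotation_invariant: minimum over circular bit rotations of each raw code
    codes = set()
    mask = (1 << P) - 1
    for c in range(1 << P):
        codes.add(min(((c >> r) | (c << (P - r))) & mask for r in range(P)))
    return tuple(sorted(codes))


def lbp_features(patch, cfg: LbpConfig = LbpConfig()) -> np.ndarray:
    """Normalized LBP histogram of a patch.

    Codes are computed only for pixels with a complete neighborhood (an
    ``R``-pixel border is cropped), so the patch must be larger than ``2R``
    in both dimensions.  The bin layout is fixed by the variant and P, e.g.
    59 bins for the uniform variant at P=8.
    """
    pixels = _patch_pixels(patch)
    R = cfg.radius
    if pixels.shape[0] <= 2 * R or pixels.shape[1] <= 2 * R:
        raise ValueError(
            f"patch of shape {pixels.shape} is too small for LBP radius {R}"
        )
    codes = local_binary_pattern(
        pixels, P=cfg.neighbors, R=R, method=_LBP_METHODS[cfg.variant]
    )
    interior = codes[R:-R, R:-R].astype(np.int64)
    bins = _lbp_bin_codes(cfg.neighbors, cfg.variant)
    counts = np.bincount(interior.ravel(), minlength=bins[-1] + 1)[list(bins)]
    return counts / counts.sum()


def extract_features(patch, cfg: ExtractorConfig) -> np.ndarray:
    """Dispatch to the configured extractor (GLCM or LBP)."""
    if isinstance(cfg, GlcmConfig):
        return glcm_features(patch, cfg)
    if isinstance(cfg, LbpConfig):
        return lbp_features(patch, cfg)
    raise TypeError(f"unsupported extractor config: {type(cfg).__name__}")


def feature_names(cfg: ExtractorConfig) -> list[str]:
    if isinstance(cfg, GlcmConfig):
        return [f"f{i + 1}" for i in range(13)]
    n = len(_lbp_bin_codes(cfg.neighbors, cfg.variant))
    return [f"f{i + 1}" for i in range(n)]


#: Annotation rows with this defect type are treated as defect-free windows.
NORMAL_TYPE = "normal"

LABEL_DEFECT = 0
LABEL_NORMAL = 1


def build_feature_table(
    images: Mapping[str, np.ndarray],
    annotations: pd.DataFrame,
    T: int,
    extractor: ExtractorConfig = GlcmConfig(),
) -> pd.DataFrame:
    """One labelled feature row per annotated window.

    ``annotations`` follows the defect-report layout with columns
    ``image_id, defect_type, x, y``; rows whose ``defect_type`` equals
    ``"normal"`` are labelled defect-free (1), everything else defect (0).
    Annotations whose window would cross the image border are dropped and the
    drop count is logged.

    Returns a DataFrame with columns ``image_id, x, y, label, f1..fK``.
    """
    required = {"image_id", "defect_type", "x", "y"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation report is missing columns {sorted(missing)}")
    rows = []
    dropped = 0
    names = feature_names(extractor)
    for rec in annotations.itertuples(index=False):
        image_id = str(rec.image_id)
        if image_id not in images:
            raise KeyError(f"annotation references missing image {image_id!r}")
        img = images[image_id]
        try:
            patch = extract_window(img, int(rec.x), int(rec.y), T)
        except ValueError:
            dropped += 1
            continue
        fv = extract_features(patch, extractor)
        label = LABEL_NORMAL if str(rec.defect_type) == NORMAL_TYPE else LABEL_DEFECT
        rows.append([image_id, int(rec.x), int(rec.y), label, *fv])
    if dropped:
        logger.info("dropped %d annotation(s) with out-of-bounds windows", dropped)
    return pd.DataFrame(rows, columns=["image_id", "x", "y", "label", *names])
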