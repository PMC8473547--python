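"""Synthetic leather-like fixtures: textured skin blobs with planted defects.

No public corpus of graded wet-blue goat skin photographs exists, so every
stage of the pipeline is exercised on generated images: an elliptical "skin"
blob of smoothed-Gaussian base texture on a dark background, with square
defect patches of a distinctly different texture planted on known window
cells.  The generator emits the same annotation-report format as a manual
defect survey (``image_id, defect_type, x, y`` window centers) plus the
ground-truth defect map and quality level, so detection and grading can be
scored exactly.

Texture model: intensity = mean + Gaussian noise smoothed by a Gaussian
kernel.  Shifting the defect patch's mean/noise/smoothing away from the base
triple shifts its co-occurrence statistics (e.g. GLCM contrast) controllably;
real leather texture modelling is out of scope.

Quality levels follow the defective-window fraction of the skin: level 1
(best) under 10% defective windows, then 10% bands up to level 5, with levels
6 and 7 covering 50-65% and above 65%.  Good skins get edge-placed defects
and bad skins centrally-placed ones, mirroring how human graders weight
defect location.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import imaging
from .detection import DefectMap
from .texture import ExtractorConfig, GlcmConfig, NORMAL_TYPE, extract_features, feature_names

__all__ = [
    "TextureSpec",
    "LeatherSpec",
    "SyntheticSkin",
    "SyntheticCorpus",
    "LEVEL_BANDS",
    "PLACEMENT_BY_LEVEL",
    "DEFECT_TYPES",
    "generate_leather_image",
    "generate_corpus",
    "generate_window_feature_table",
    "level_for_fraction",
]

#: Defect-type tags cycled through the annotations (labels only; the generator
#: does not model distinct defect morphologies).
DEFECT_TYPES = ("scratch", "tick_bite", "hole", "scar", "brand")

#: Defective-window fraction band per quality level (half-open [lo, hi);
#: level 7 is unbounded above).
LEVEL_BANDS = {
    1: (0.00, 0.10),
    2: (0.10, 0.20),
    3: (0.20, 0.30),
    4: (0.30, 0.40),
    5: (0.40, 0.50),
    6: (0.50, 0.65),
    7: (0.65, 1.00),
}

#: Defect placement per level: edge defects barely matter on good skins,
#: central defects dominate bad ones.
PLACEMENT_BY_LEVEL = {1: "edge", 2: "edge", 3: "uniform", 4: "uniform",
                      5: "uniform", 6: "central", 7: "central"}

#: Highest defective fraction the corpus generator targets for level 7.
_MAX_TARGET_FRACTION = 0.82


@dataclass(frozen=True)
class TextureSpec:
    """Smoothed-noise texture: mean plateau, pre-smoothing noise SD, kernel SD."""

    mean: float = 130.0
    noise_sigma: float = 25.0
    smoothing: float = 1.2


@dataclass(frozen=True)
class LeatherSpec:
    """Parameters of one synthetic skin image.

    The defaults give a 612x816 image whose elliptical blob tiles into a
    roughly 9x13 grid of 51-pixel windows (about 90 leather windows).
    """

    height: int = 612
    width: int = 816
    blob_axes: tuple[int, int] = (250, 350)  # semi-axes (y, x) in pixels
    blob_center: Optional[tuple[int, int]] = None  # (y, x); default image center
    base_texture: TextureSpec = field(default_factory=TextureSpec)
    defect_texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(mean=95.0, noise_sigma=60.0, smoothing=0.4)
    )
    n_defects: int = 5
    defect_size: int = 51
    placement: str = "uniform"
    window_size: int = 51
    min_fg_fraction: float = imaging.DEFAULT_MIN_FG_FRACTION
    background_level: int = 10
    threshold: int = imaging.DEFAULT_THRESHOLD
    target_level: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        cy, cx = self.center
        ay, ax = self.blob_axes
        if not (0 < cy - ay and cy + ay < self.height and 0 < cx - ax and cx + ax < self.width):
            raise ValueError("blob ellipse must fit strictly inside the image")
        if self.placement not in ("central", "edge", "uniform"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.n_defects < 0 or self.defect_size < 1:
            raise ValueError("n_defects must be >= 0 and defect_size >= 1")
        if self.background_level >= self.threshold:
            raise ValueError("background_level must stay below the segmentation threshold")
        b, d = self.base_texture, self.defect_texture
        if (
            abs(b.mean - d.mean) < 5
            and abs(b.noise_sigma - d.noise_sigma) < 5
            and abs(b.smoothing - d.smoothing) < 0.2
        ):
            raise ValueError(
                "defect texture must differ from the base texture by a clear margin"
            )

    @property
    def center(self) -> tuple[int, int]:
        if self.blob_center is not None:
            return self.blob_center
        return (self.height // 2, self.width // 2)


@dataclass(frozen=True)
class SyntheticSkin:
    """One generated sample: image (may be None), annotations, ground truth."""

    image: Optional[np.ndarray]
    annotations: pd.DataFrame  # image_id, defect_type, x, y
    true_map: DefectMap
    grid: imaging.WindowGrid
    mask: np.ndarray
    spec: LeatherSpec

    @property
    def defect_fraction(self) -> float:
        """Fraction of valid windows that are defective."""
        n_valid = int(self.grid.validity.sum())
        n_free = int(self.true_map.values.sum())
        return (n_valid - n_free) / n_valid if n_valid else 0.0


@dataclass(frozen=True)
class SyntheticCorpus:
    """A generated multi-skin corpus with manifest-style ground truth."""

    skins: list[SyntheticSkin]
    annotations: pd.DataFrame  # image_id, defect_type, x, y (one row per defect)
    grades: pd.DataFrame  # image_id, level, defect_fraction, n_valid


def _ellipse_mask(spec: LeatherSpec) -> np.ndarray:
    cy, cx = spec.center
    ay, ax = spec.blob_axes
    yy = (np.arange(spec.height) - cy)[:, None] / ay
    xx = (np.arange(spec.width) - cx)[None, :] / ax
    return yy**2 + xx**2 <= 1.0


def _render_texture(shape, tex: TextureSpec, rng, floor: int) -> np.ndarray:
    noise = gaussian_filter(rng.normal(0.0, tex.noise_sigma, shape), tex.smoothing)
    return np.clip(np.round(tex.mean + noise), floor, 255).astype(np.uint8)


def _candidate_cells(
    grid: imaging.WindowGrid, mask: np.ndarray, placement: str
) -> np.ndarray:
    """Preferred (i, j) cells for a placement policy, as an (n, 2) array."""
    valid = grid.validity
    if placement == "uniform":
        return np.argwhere(valid)
    if placement == "edge":
        padded = np.pad(valid, 1, constant_values=False)
        interior = (
            padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
        )
        return np.argwhere(valid & ~interior)
    # central: cell centers within the central third of the mask's bounding box
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    hy, hx = (y1 - y0) / 3.0, (x1 - x0) / 3.0
    out = []
    for i, j in np.argwhere(valid):
        cx_, cy_ = grid.cell_center(i, j)
        if y0 + hy <= cy_ < y1 - hy and x0 + hx <= cx_ < x1 - hx:
            out.append((i, j))
    return np.asarray(out, dtype=int).reshape(-1, 2)


def _choose_cells(
    grid: imaging.WindowGrid,
    mask: np.ndarray,
    spec: LeatherSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick ``n_defects`` distinct valid cells honoring placement and spacing."""
    n = spec.n_defects
    if n == 0:
        return np.empty((0, 2), dtype=int)
    preferred = _candidate_cells(grid, mask, spec.placement)
    all_valid = np.argwhere(grid.validity)
    if n > len(all_valid):
        raise ValueError(
            f"cannot place {n} defects on {len(all_valid)} leather windows; "
            f"use fewer or smaller defects"
        )
    # Preferred cells first (shuffled), then the remaining valid cells.
    pref_set = {tuple(c) for c in preferred}
    rest = np.array([c for c in all_valid if tuple(c) not in pref_set], dtype=int)
    order = list(rng.permutation(len(preferred)))
    ordered = [tuple(preferred[i]) for i in order]
    ordered += [tuple(rest[i]) for i in rng.permutation(len(rest))]

    spacing = int(np.ceil(spec.defect_size / grid.window_size))
    chosen: list[tuple[int, int]] = []
    for cell in ordered:
        if len(chosen) == n:
            break
        if spacing > 1 and any(
            max(abs(cell[0] - c[0]), abs(cell[1] - c[1])) < spacing for c in chosen
        ):
            continue
        chosen.append(cell)
    if len(chosen) < n:
        raise ValueError(
            f"could not place {n} non-overlapping defects of size "
            f"{spec.defect_size}; use fewer or smaller defects"
        )
    return np.asarray(chosen, dtype=int)


def generate_leather_image(
    spec: LeatherSpec, image_id: str = "sample_0", render: bool = True
) -> SyntheticSkin:
    """Generate one synthetic skin: image, annotations and true defect map.

    Deterministic given ``spec`` (including ``spec.seed``).  The background
    stays strictly below the segmentation threshold and the blob strictly
    above it, so foreground segmentation recovers the ellipse exactly and the
    tiling reproduces the ground-truth window grid.  With ``render=False``
    only the geometry and ground truth are produced (``image`` is None).
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipse_mask(spec)
    shape = (spec.height, spec.width)
    grid = imaging.tile(
        np.zeros(shape, dtype=np.uint8), mask, spec.window_size, spec.min_fg_fraction
    )
    cells = _choose_cells(grid, mask, spec, rng)

    img = None
    if render:
        img = rng.integers(0, spec.background_level, size=shape, dtype=np.uint8)
        floor = spec.threshold + 15
        base = _render_texture(shape, spec.base_texture, rng, floor)
        img = np.where(mask, base, img).astype(np.uint8)
        half = spec.defect_size // 2
        for i, j in cells:
            cx, cy = grid.cell_center(i, j)
            y0, y1 = max(0, cy - half), min(spec.height, cy - half + spec.defect_size)
            x0, x1 = max(0, cx - half), min(spec.width, cx - half + spec.defect_size)
            tex = _render_texture((y1 - y0, x1 - x0), spec.defect_texture, rng, floor)
            patch_mask = mask[y0:y1, x0:x1]
            img[y0:y1, x0:x1][patch_mask] = tex[patch_mask]
    else:
        # keep the random stream layout identical whether or not we render
        pass

    ann_rows = []
    for idx, (i, j) in enumerate(cells):
        cx, cy = grid.cell_center(i, j)
        ann_rows.append(
            {
                "image_id": image_id,
                "defect_type": DEFECT_TYPES[idx % len(DEFECT_TYPES)],
                "x": int(cx),
                "y": int(cy),
            }
        )
    annotations = pd.DataFrame(ann_rows, columns=["image_id", "defect_type", "x", "y"])

    values = grid.validity.astype(int)
    for i, j in cells:
        values[i, j] = 0
    true_map = DefectMap(values=values, image_id=image_id, window_size=spec.window_size)
    return SyntheticSkin(
        image=img, annotations=annotations, true_map=true_map, grid=grid,
        mask=mask, spec=spec,
    )


def level_for_fraction(fraction: float) -> int:
    """Quality level whose defective-window band contains ``fraction``."""
    for level, (lo, hi) in LEVEL_BANDS.items():
        if lo <= fraction < hi or (level == 7 and fraction >= lo):
            return level
    raise ValueError(f"fraction {fraction} outside [0, 1]")


def _defect_count_for_level(
    level: int, n_valid: int, rng: np.random.Generator
) -> int:
    lo, hi = LEVEL_BANDS[level]
    hi_target = min(hi, _MAX_TARGET_FRACTION)
    # sample strictly inside the band to keep rounding from crossing an edge
    span = hi_target - lo
    target = rng.uniform(lo + 0.1 * span, hi_target - 0.1 * span)
    n = int(round(target * n_valid))
    while n > 0 and n / n_valid >= hi:
        n -= 1
    while n < n_valid and n / n_valid < lo:
        n += 1
    f = n / n_valid
    if not (lo <= f < hi or (level == 7 and f >= lo)):
        raise ValueError(
            f"level-{level} band [{lo}, {hi}) infeasible with {n_valid} windows"
        )
    return n


def generate_corpus(
    base_spec: LeatherSpec,
    n_images: int,
    level_mix: Optional[Sequence[float]] = None,
    seed: int = 0,
    out_dir: Optional[Path] = None,
    render: bool = True,
    axis_jitter: float = 0.08,
) -> SyntheticCorpus:
    """Generate a corpus of graded skins with manifest-style ground truth.

    Each image draws a target quality level from ``level_mix`` (probabilities
    over levels 1-7, default uniform), jitters the blob axes by up to
    ``axis_jitter`` relative, and plants enough defects — placed per the
    level's policy — that the true defective-window fraction falls inside the
    level's band.  Deterministic given ``seed``.

    With ``out_dir`` set, writes ``images/<id>.png`` (when rendering),
    ``manifest.csv`` (``image_id,defect_type,x,y``), ``grades.csv``
    (``image_id,level,defect_fraction,n_valid``) and ``maps/<id>.csv``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if level_mix is None:
        probs = np.full(7, 1.0 / 7.0)
    else:
        probs = np.asarray(level_mix, dtype=float)
        if probs.shape != (7,) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("level_mix must be 7 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    ay0, ax0 = base_spec.blob_axes

    skins: list[SyntheticSkin] = []
    ann_frames: list[pd.DataFrame] = []
    grade_rows = []
    for idx in range(n_images):
        image_id = f"skin_{idx:04d}"
        level = int(rng.choice(np.arange(1, 8), p=probs))
        jit = rng.uniform(-axis_jitter, axis_jitter, size=2)
        axes = (int(round(ay0 * (1 + jit[0]))), int(round(ax0 * (1 + jit[1]))))
        probe = replace(
            base_spec,
            blob_axes=axes,
            placement=PLACEMENT_BY_LEVEL[level],
            target_level=level,
            n_defects=0,
            seed=int(rng.integers(2**31)),
        )
        n_valid = int(
            imaging.tile(
                np.zeros((probe.height, probe.width), dtype=np.uint8),
                _ellipse_mask(probe),
                probe.window_size,
                probe.min_fg_fraction,
            ).validity.sum()
        )
        spec = replace(probe, n_defects=_defect_count_for_level(level, n_valid, rng))
        skin = generate_leather_image(spec, image_id=image_id, render=render)
        skins.append(skin)
        ann_frames.append(skin.annotations)
        grade_rows.append(
            {
                "image_id": image_id,
                "level": level,
                "defect_fraction": skin.defect_fraction,
                "n_valid": n_valid,
            }
        )
    annotations = pd.concat(ann_frames, ignore_index=True) if ann_frames else pd.DataFrame(
        columns=["image_id", "defect_type", "x", "y"]
    )
    grades = pd.DataFrame(grade_rows)
    corpus = SyntheticCorpus(skins=skins, annotations=annotations, grades=grades)
    if out_dir is not None:
        _write_corpus(corpus, Path(out_dir), render)
    return corpus


def _write_corpus(corpus: SyntheticCorpus, out_dir: Path, render: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "maps").mkdir(exist_ok=True)
    if render:
        (out_dir / "images").mkdir(exist_ok=True)
        for skin in corpus.skins:
            Image.fromarray(skin.image).save(
                out_dir / "images" / f"{skin.true_map.image_id}.png"
            )
    for skin in corpus.skins:
        np.savetxt(
            out_dir / "maps" / f"{skin.true_map.image_id}.csv",
            skin.true_map.values,
            fmt="%d",
            delimiter=",",
        )
    corpus.annotations.to_csv(out_dir / "manifest.csv", index=False)
    corpus.grades.to_csv(out_dir / "grades.csv", index=False)


def generate_window_feature_table(
    n_per_class: int,
    T: int = 51,
    base_texture: TextureSpec = TextureSpec(),
    defect_texture: TextureSpec = TextureSpec(mean=95.0, noise_sigma=60.0, smoothing=0.4),
    extractor: Optional[ExtractorConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled feature table of standalone texture windows (no blob geometry).

    Generates ``n_per_class`` windows of the base (normal, label 1) and defect
    (label 0) textures, featurizes each, and returns the standard feature
    table (``image_id, x, y, label, f1..fK``) ready for
    :func:`wetblue.detection.balanced_split` and model training.
    """
    extractor = extractor if extractor is not None else GlcmConfig()
    rng = np.random.default_rng(seed)
    rows = []
    names = feature_names(extractor)
    for label, tex, tag in ((1, base_texture, NORMAL_TYPE), (0, defect_texture, "defect")):
        for i in range(n_per_class):
            patch = _render_texture((T, T), tex, rng, floor=0)
            fv = extract_features(patch, extractor)
            rows.append([f"{tag}_{i}", T // 2, T // 2, label, *fv])
    return pd.DataFrame(rows, columns=["image_id", "x", "y", "label", *names])
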