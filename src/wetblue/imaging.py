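"""Image loading, foreground segmentation and window tiling.

Skins are photographed one per image on a dark background, so the leather can be
separated from the background by a simple intensity threshold followed by a
largest-connected-component filter (glare specks and dust reflections on the
table are discarded).  The foreground is then tiled into non-overlapping ``T``
by ``T`` square windows anchored at the mask's bounding box; each window is the
unit of the downstream defect classification.

Coordinate convention: 0-based, row-major; ``x`` indexes columns, ``y`` rows;
pixel intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

__all__ = [
    "Patch",
    "WindowGrid",
    "load_gray",
    "segment_foreground",
    "extract_window",
    "tile",
]

#: Default background threshold (dark-table rig: leather intensity is far above it).
DEFAULT_THRESHOLD = 30

#: Default minimum fraction of foreground pixels for a window to count as leather.
DEFAULT_MIN_FG_FRACTION = 0.9


@dataclass(frozen=True)
class Patch:
    """A square ``T``-by-``T`` intensity window cut from a grayscale image."""

    pixels: np.ndarray
    center_x: int
    center_y: int
    window_size: int


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping window tiling of a foreground mask's bounding box.

    Cell ``(i, j)`` covers pixel rows ``[origin_y + i*T, origin_y + (i+1)*T)``
    and columns ``[origin_x + j*T, origin_x + (j+1)*T)``.  ``validity[i, j]``
    is True when the cell contains enough foreground to count as leather.
    """

    rows: int
    cols: int
    origin_x: int
    origin_y: int
    window_size: int
    validity: np.ndarray

    def cell_slices(self, i: int, j: int) -> tuple[slice, slice]:
        T = self.window_size
        return (
            slice(self.origin_y + i * T, self.origin_y + (i + 1) * T),
            slice(self.origin_x + j * T, self.origin_x + (j + 1) * T),
        )

    def cell_center(self, i: int, j: int) -> tuple[int, int]:
        """(x, y) pixel coordinates of the center of cell ``(i, j)``."""
        T = self.window_size
        return (self.origin_x + j * T + T // 2, self.origin_y + i * T + T // 2)


def load_gray(path) -> np.ndarray:
    """Load a JPEG/PNG photograph as a 2-D uint8 intensity array.

    RGB inputs are converted to luminance with the standard ITU-R BT.601
    weights (Pillow mode ``"L"``).

    Raises
    ------
    FileNotFoundError, ValueError
        If the file is missing or not a readable image.
    """
    try:
        with Image.open(path) as im:
            gray = im.convert("L")
            arr = np.asarray(gray, dtype=np.uint8)
    except FileNotFoundError:
        raise
    except (UnidentifiedImageError, OSError) as exc:
        raise ValueError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"image {path!r} did not decode to a 2-D intensity grid")
    return arr


def segment_foreground(
    img: np.ndarray, threshold: int = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Boolean leather-vs-background mask of ``img``.

    Pixels strictly brighter than ``threshold`` are foreground; only the
    largest 8-connected component is kept, which suppresses isolated glare
    specks on the dark table.

    Raises
    ------
    ValueError
        If no pixel exceeds the threshold ("empty sample").
    """
    img = _as_gray(img)
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    fg = img > threshold
    if not fg.any():
        raise ValueError(
            f"empty sample: no pixel exceeds background threshold {threshold}"
        )
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    if n == 1:
        return fg
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background label
    return labels == int(np.argmax(sizes))


def extract_window(img: np.ndarray, center_x: int, center_y: int, T: int) -> Patch:
    """Cut the ``T``-by-``T`` window centered at pixel ``(center_x, center_y)``.

    The window's top-left corner is ``(center_y - T//2, center_x - T//2)``; it
    must lie entirely inside the image — no padding is performed.
    """
    img = _as_gray(img)
    if T < 1:
        raise ValueError(f"window size must be >= 1, got {T}")
    top = center_y - T // 2
    left = center_x - T // 2
    h, w = img.shape
    if top < 0 or left < 0 or top + T > h or left + T > w:
        raise ValueError(
            f"window of size {T} centered at ({center_x}, {center_y}) "
            f"crosses the bounds of a {h}x{w} image"
        )
    return Patch(
        pixels=img[top : top + T, left : left + T].copy(),
        center_x=int(center_x),
        center_y=int(center_y),
        window_size=int(T),
    )


def tile(
    img: np.ndarray,
    mask: np.ndarray,
    T: int,
    min_fg_fraction: float = DEFAULT_MIN_FG_FRACTION,
) -> WindowGrid:
    """Tile the mask's bounding box into non-overlapping ``T``-by-``T`` windows.

    The grid is anchored at the top-left corner of the mask's bounding box and
    uses stride ``T`` (windows never overlap and never extend past the image).
    A cell is valid when at least ``min_fg_fraction`` of its pixels are
    foreground; border windows mixing in background would otherwise
    contaminate the texture statistics.

    Raises
    ------
    ValueError
        If the bounding box is smaller than ``T`` in either dimension
        ("sample too small").
    """
    img = _as_gray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {img.shape}"
        )
    if T < 2:
        raise ValueError(f"window size must be >= 2, got {T}")
    if not 0 < min_fg_fraction <= 1:
        raise ValueError(
            f"min_fg_fraction must be in (0, 1], got {min_fg_fraction}"
        )
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty sample: mask has no foreground pixel")
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    rows = (y1 - y0) // T
    cols = (x1 - x0) // T
    if rows < 1 or cols < 1:
        raise ValueError(
            f"sample too small: foreground bounding box {(y1 - y0)}x{(x1 - x0)} "
            f"cannot hold a {T}-pixel window"
        )
    # Per-cell foreground fraction via a block sum over the cropped mask.
    crop = mask[y0 : y0 + rows * T, x0 : x0 + cols * T]
    block = crop.reshape(rows, T, cols, T).sum(axis=(1, 3))
    validity = block >= min_fg_fraction * T * T
    return WindowGrid(
        rows=rows,
        cols=cols,
        origin_x=x0,
        origin_y=y0,
        window_size=int(T),
        validity=validity,
    )


def _as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D intensity array, got shape {arr.shape}")
    return arr
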