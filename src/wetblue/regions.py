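"""Defect-free region extraction and the seven quality attributes.

A graded skin is summarized by the largest defect-free convex regions of its
defect map — implemented as maximal axis-aligned all-ones rectangles, found
with the classic dynamic program (per-row histogram of consecutive ones plus a
monotonic stack, O(rows x cols)).  The detector is applied recursively: the
best rectangle is recorded, its cells are zeroed, and the search repeats until
``k`` regions (default 5) are found or no free cell remains.

Seven attributes are then derived from the region areas; they feed the
7-level quality grader.  Areas are measured in window cells by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .detection import DefectMap

__all__ = [
    "Region",
    "ATTRIBUTE_NAMES",
    "DEFAULT_K",
    "max_rectangle",
    "top_k_regions",
    "quality_attributes",
]

#: Number of defect-free regions extracted recursively by default.
DEFAULT_K = 5

ATTRIBUTE_NAMES = (
    "total_free_area",  # a1: count of defect-free windows
    "topk_area",        # a2: summed area of the k extracted regions
    "largest_area",     # a3: area of the largest region
    "largest_pct",      # a4: 100 * a3 / a1
    "smallest_area",    # a5: area of the smallest extracted region
    "smallest_pct",     # a6: 100 * a5 / a1
    "area_std",         # a7: population std of the k (zero-padded) region areas
)


@dataclass(frozen=True)
class Region:
    """An axis-aligned all-ones rectangle in defect-map grid coordinates."""

    top_row: int
    left_col: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.top_row, self.top_row + self.height),
            slice(self.left_col, self.left_col + self.width),
        )


_EMPTY = Region(0, 0, 0, 0)


def _map_values(map_) -> np.ndarray:
    vals = map_.values if isinstance(map_, DefectMap) else np.asarray(map_)
    vals = np.asarray(vals, dtype=int)
    if vals.ndim != 2 or vals.size == 0:
        raise ValueError(f"defect map must be a non-empty 2-D grid, got {vals.shape}")
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("defect map values must be 0 or 1")
    return vals


def max_rectangle(map_) -> Region:
    """Largest all-ones axis-aligned rectangle of a binary map.

    Ties on area are broken by smallest top row, then smallest left column,
    then largest height.  An all-zeros map yields a zero-area region.
    """
    grid = _map_values(map_)
    rows, cols = grid.shape
    heights = np.zeros(cols + 1, dtype=int)  # sentinel bar of height 0 at the end
    best = _EMPTY
    best_key = (0, 0, 0, 0)
    for bottom in range(rows):
        heights[:cols] = np.where(grid[bottom] == 1, heights[:cols] + 1, 0)
        stack: list[int] = []  # column indices with increasing heights
        for j in range(cols + 1):
            while stack and heights[stack[-1]] > heights[j]:
                h = int(heights[stack.pop()])
                left = stack[-1] + 1 if stack else 0
                width = j - left
                area = h * width
                # key: larger area, then smaller top row, smaller left col,
                # larger height
                key = (area, -(bottom - h + 1), -left, h)
                if key > best_key:
                    best_key = key
                    best = Region(bottom - h + 1, left, h, width)
            stack.append(j)
    return best


def top_k_regions(map_, k: int = DEFAULT_K) -> list[Region]:
    """The ``k`` largest defect-free rectangles, extracted recursively.

    After each extraction the region's cells are zeroed, so regions are
    disjoint and their areas non-increasing.  Extraction stops early when no
    free cell remains; an all-zeros map yields an empty list.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    work = _map_values(map_).copy()
    regions: list[Region] = []
    for _ in range(k):
        region = max_rectangle(work)
        if region.area == 0:
            break
        regions.append(region)
        work[region.slices()] = 0
    return regions


def quality_attributes(
    map_,
    regions: Optional[Sequence[Region]] = None,
    k: int = DEFAULT_K,
    units: str = "cells",
    window_size: Optional[int] = None,
) -> np.ndarray:
    """The seven quality attributes of a defect map.

    a1  total defect-free area (count of 1-cells in the original map)
    a2  summed area of the extracted regions
    a3  area of the largest region
    a4  100 * a3 / a1 (0 when a1 = 0)
    a5  area of the smallest of the ``k`` regions, counting zero-padding when
        fewer than ``k`` were found (so 0 unless the map splits into >= k
        non-empty regions)
    a6  100 * a5 / a1
    a7  population standard deviation of the same zero-padded region areas

    ``regions`` must come from :func:`top_k_regions` on the same map with the
    same ``k`` (recomputed when omitted); an inconsistent list raises.  With
    ``units="pixels"`` the area attributes are scaled by ``window_size ** 2``.
    """
    grid = _map_values(map_)
    if regions is None:
        regions = top_k_regions(grid, k=k)
    _check_consistent(grid, regions)
    if units not in ("cells", "pixels"):
        raise ValueError(f"units must be 'cells' or 'pixels', got {units!r}")
    scale = 1.0
    if units == "pixels":
        if window_size is None:
            if isinstance(map_, DefectMap) and map_.window_size:
                window_size = map_.window_size
            else:
                raise ValueError("units='pixels' requires window_size")
        scale = float(window_size) ** 2

    areas = np.array([r.area for r in regions], dtype=float)
    padded = np.concatenate([areas, np.zeros(max(0, k - len(areas)))])
    a1 = float(grid.sum())
    a2 = float(areas.sum())
    a3 = float(areas.max()) if len(areas) else 0.0
    a5 = float(padded.min()) if len(padded) else 0.0
    a4 = 100.0 * a3 / a1 if a1 > 0 else 0.0
    a6 = 100.0 * a5 / a1 if a1 > 0 else 0.0
    a7 = float(padded.std()) if len(padded) else 0.0
    return np.array(
        [a1 * scale, a2 * scale, a3 * scale, a4, a5 * scale, a6, a7 * scale]
    )


def _check_consistent(grid: np.ndarray, regions: Sequence[Region]) -> None:
    coverage = np.zeros_like(grid)
    for r in regions:
        if r.area == 0:
            continue
        if (
            r.top_row < 0
            or r.left_col < 0
            or r.top_row + r.height > grid.shape[0]
            or r.left_col + r.width > grid.shape[1]
        ):
            raise ValueError(f"region {r} lies outside the {grid.shape} map")
        coverage[r.slices()] += 1
    if (coverage > 1).any():
        raise ValueError("regions overlap; they must come from top_k_regions")
    if ((coverage == 1) & (grid == 0)).any():
        raise ValueError("a region covers defect cells of the map")
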