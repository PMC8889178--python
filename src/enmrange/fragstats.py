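"""Habitat-patch labelling and landscape fragmentation metrics.

Connected habitat pixels in a binary map form patches (8-neighbour
connectivity by default for patch identity).  Patch areas are geodesic
(per-row spherical cell areas) or unit squares in Cartesian mode.
Patches smaller than a minimum area (default 0.1 km²) are excluded
from the metrics.

Metrics follow the standard landscape-ecology (FRAGSTATS) definitions:

* splitting index SPLIT = A² / Σ aᵢ², with A the total landscape
  (masked-in) area and aᵢ the patch areas; 1 when a single patch fills
  the landscape, growing as habitat fragments.
* aggregation index AI = 100·g/g_max, where g counts like (habitat to
  habitat) rook adjacencies once, and g_max is the largest g achievable
  by A habitat pixels packed into a square-ish block: with n = ⌊√A⌋ and
  m = A − n², g_max = 2n(n−1) if m = 0; 2n(n−1)+2m−1 if m ≤ n; else
  2n(n−1)+2m−2.  Note AI adjacencies are rook (4-neighbour) regardless
  of the patch-identity connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .range_dynamics import BinaryMap, _structure


@dataclass
class PatchSet:
    labels: np.ndarray          # 0 = background, 1..n = patch ids
    pixel_counts: np.ndarray    # per patch, index 0 unused
    areas: np.ndarray           # km² (or unit areas), index 0 unused
    connectivity: int

    @property
    def n_patches(self) -> int:
        return int((self.pixel_counts[1:] > 0).sum())

    @property
    def patch_areas(self) -> np.ndarray:
        a = self.areas[1:]
        return a[self.pixel_counts[1:] > 0]

    @property
    def total_area(self) -> float:
        return float(self.patch_areas.sum())


@dataclass
class FragReport:
    n_patches: int
    total_area: float
    mean_patch_area: float
    splitting_index: float
    aggregation_index: float
    min_patch_filter: float
    landscape_area: float

    def to_row(self, **labels) -> dict:
        return {**labels, "n_patches": self.n_patches,
                "total_area": self.total_area,
                "mean_patch_area": self.mean_patch_area,
                "splitting_index": self.splitting_index,
                "aggregation_index": self.aggregation_index,
                "min_patch_filter": self.min_patch_filter,
                "landscape_area": self.landscape_area}


def label_patches(binary: BinaryMap, connectivity: int = 8,
                  cell_areas: np.ndarray | None = None) -> PatchSet:
    """Connected-component patch labels with deterministic ordering.

    Labels are renumbered so patch 1 has the row-major-first pixel, patch
    2 the next, and so on; an empty habitat yields an empty PatchSet.
    """
    habitat = binary.habitat
    raw, n = ndimage.label(habitat, structure=_structure(connectivity))
    if n == 0:
        return PatchSet(labels=raw, pixel_counts=np.zeros(1, int),
                        areas=np.zeros(1), connectivity=connectivity)
    # renumber by row-major first occurrence
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=int)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=int)
    remap[1 + order] = np.arange(1, n + 1)
    labels = remap[raw]

    counts = np.bincount(labels.ravel(), minlength=n + 1)
    counts[0] = 0
    if cell_areas is None:
        areas = counts.astype(float)
    else:
        areas = np.bincount(labels.ravel(), weights=cell_areas.ravel(),
                            minlength=n + 1)
        areas[0] = 0.0
    return PatchSet(labels=labels, pixel_counts=counts, areas=areas,
                    connectivity=connectivity)


def filter_small_patches(patches: PatchSet, min_area: float = 0.1) -> PatchSet:
    """Drop patches with area strictly below ``min_area`` (km²)."""
    keep = patches.areas >= min_area
    keep[0] = False
    labels = np.where(keep[patches.labels], patches.labels, 0)
    counts = patches.pixel_counts.copy()
    areas = patches.areas.copy()
    counts[~keep] = 0
    areas[~keep] = 0.0
    return PatchSet(labels=labels, pixel_counts=counts, areas=areas,
                    connectivity=patches.connectivity)


def splitting_index(patches: PatchSet, landscape_area: float) -> float:
    """SPLIT = A²/Σaᵢ² over retained patches; NaN for empty habitat."""
    a = patches.patch_areas
    if a.size == 0:
        return float("nan")
    return float(landscape_area**2 / np.sum(a**2))


def _like_adjacencies(habitat: np.ndarray) -> int:
    h = habitat.astype(bool)
    horiz = int((h[:, :-1] & h[:, 1:]).sum())
    vert = int((h[:-1, :] & h[1:, :]).sum())
    return horiz + vert


def _max_adjacencies(n_pixels: int) -> int:
    n = int(np.floor(np.sqrt(n_pixels)))
    m = n_pixels - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def aggregation_index(binary: BinaryMap | np.ndarray) -> float:
    """AI = 100·g/g_max over rook adjacencies; 0 for a single pixel."""
    habitat = binary.habitat if isinstance(binary, BinaryMap) else np.asarray(
        binary, dtype=bool)
    n_pixels = int(habitat.sum())
    if n_pixels == 0:
        return float("nan")
    g_max = _max_adjacencies(n_pixels)
    if g_max == 0:
        return 0.0
    return 100.0 * _like_adjacencies(habitat) / g_max


def frag_report(binary: BinaryMap, connectivity: int = 8,
                min_area: float = 0.1, cell_areas: np.ndarray | None = None,
                landscape_area: float | None = None) -> FragReport:
    """Full fragmentation summary for one binary habitat map.

    ``cell_areas`` supplies per-pixel km² (geodesic); omitted, every cell
    counts 1 (Cartesian mode).  ``landscape_area`` defaults to the summed
    area of all masked-in cells.  The AI is computed on the habitat map
    *after* the small-patch filter, so filtered fragments affect neither
    numerator nor denominator.
    """
    if cell_areas is None:
        cell_areas = np.ones(binary.grid.shape)
    if landscape_area is None:
        landscape_area = float(cell_areas[binary.mask].sum())
    patches = label_patches(binary, connectivity, cell_areas)
    patches = filter_small_patches(patches, min_area)
    n = patches.n_patches
    total = patches.total_area
    retained = BinaryMap(grid=(patches.labels > 0).astype(float),
                         mask=binary.mask)
    return FragReport(
        n_patches=n,
        total_area=total,
        mean_patch_area=total / n if n else 0.0,
        splitting_index=splitting_index(patches, landscape_area),
        aggregation_index=aggregation_index(retained) if n else float("nan"),
        min_patch_filter=min_area,
        landscape_area=landscape_area,
    )


def compare_reports(reports: dict[str, FragReport]) -> pd.DataFrame:
    """Scenario comparison table: metric deltas relative to the first entry."""
    names = list(reports)
    base = reports[names[0]]
    rows = []
    for name in names:
        r = reports[name]
        rows.append({
            "scenario": name, **r.to_row(),
            "d_total_area": r.total_area - base.total_area,
            "d_n_patches": r.n_patches - base.n_patches,
            "d_mean_patch_area": r.mean_patch_area - base.mean_patch_area,
            "d_splitting_index": r.splitting_index - base.splitting_index,
            "d_aggregation_index": r.aggregation_index - base.aggregation_index,
        })
    return pd.DataFrame(rows)
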