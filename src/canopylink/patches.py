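"""Patch delineation from a year-of-disturbance raster.

A disturbance patch is the set of pixels opened in the same calendar year
that touch under queen contiguity (8-neighborhood, shared edge or corner).
Because satellite change detection can split a single event that spans two
vegetation peaks into two consecutive annual patches, patches of consecutive
years that share an edge (4-adjacency, corners excluded) are merged, the
merged patch taking the majority-vote year of its pixels (ties go to the
earlier year).  Merging is transitive: chains spanning more than two
consecutive years collapse into one event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components as _graph_components
from scipy.sparse import coo_matrix
from skimage.measure import label as _sklabel


@dataclass
class DisturbanceMap:
    """Gridded year of disturbance plus optional co-registered spectral bands.

    year_grid: 2-D integer grid, 0 = undisturbed, else calendar year.
    pre_grid / mag_grid: pre-disturbance spectral index and disturbance
    magnitude; NaN marks missing observations.
    """

    year_grid: np.ndarray
    pixel_size: float = 30.0
    pre_grid: np.ndarray | None = None
    mag_grid: np.ndarray | None = None
    year_range: tuple[int, int] | None = None

    def __post_init__(self):
        self.year_grid = np.asarray(self.year_grid)
        if self.year_grid.ndim != 2:
            raise ValueError("year_grid must be 2-D")
        nz = self.year_grid[self.year_grid != 0]
        if self.year_range is None:
            self.year_range = (
                (int(nz.min()), int(nz.max())) if nz.size else (0, 0)
            )
        else:
            lo, hi = self.year_range
            if nz.size and (nz.min() < lo or nz.max() > hi):
                raise ValueError("year_grid holds years outside year_range")
        for name in ("pre_grid", "mag_grid"):
            g = getattr(self, name)
            if g is not None and np.asarray(g).shape != self.year_grid.shape:
                raise ValueError(f"{name} shape differs from year_grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.year_grid.shape


@dataclass
class Patch:
    """A contiguous disturbance event."""

    patch_id: int
    year: int
    pixels: np.ndarray  # (n, 2) array of (row, col)
    pixel_size: float = 30.0
    merged_from: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if len(self.pixels) == 0:
            raise ValueError("a patch needs at least one pixel")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def area_m2(self) -> float:
        return self.n_pixels * self.pixel_size**2

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) in meters, pixel-center based."""
        r, c = self.pixels[:, 0].mean(), self.pixels[:, 1].mean()
        return ((c + 0.5) * self.pixel_size, (r + 0.5) * self.pixel_size)


def _first_pixel_order(pixels: np.ndarray) -> tuple[int, int]:
    i = np.lexsort((pixels[:, 1], pixels[:, 0]))[0]
    return int(pixels[i, 0]), int(pixels[i, 1])


def label_patches(dmap: DisturbanceMap) -> list[Patch]:
    """Queen-contiguity connected components within each disturbance year.

    Patch ids are assigned in (year, row, col of first pixel) order so the
    labeling is reproducible.  An all-zero raster yields an empty list.
    """
    patches = []
    years = np.unique(dmap.year_grid)
    for year in years[years != 0]:
        mask = dmap.year_grid == year
        lab, n = _sklabel(mask, connectivity=2, return_num=True)
        if n == 0:
            continue
        flat = lab.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        bounds = np.searchsorted(sorted_labels, np.arange(1, n + 2))
        ncols = lab.shape[1]
        comps = []
        for k in range(n):
            idx = order[bounds[k] : bounds[k + 1]]
            pix = np.column_stack((idx // ncols, idx % ncols))
            comps.append(pix)
        # within a component argsort is stable, so pix[0] is the raster-scan
        # first pixel; order components by it for reproducible ids
        comps.sort(key=lambda pix: (pix[0, 0], pix[0, 1]))
        for pix in comps:
            patches.append(
                Patch(
                    patch_id=len(patches),
                    year=int(year),
                    pixels=pix,
                    pixel_size=dmap.pixel_size,
                )
            )
    return patches


def patch_index_grid(patches: list[Patch], shape) -> np.ndarray:
    """int32 grid mapping each pixel to the index of its patch, -1 elsewhere."""
    grid = np.full(shape, -1, dtype=np.int32)
    for i, p in enumerate(patches):
        grid[p.pixels[:, 0], p.pixels[:, 1]] = i
    return grid


def _consecutive_pairs_4(idx_grid: np.ndarray, year_grid: np.ndarray) -> np.ndarray:
    """Unique pairs of patch indices joined by a 4-adjacent pixel pair whose
    pixel years differ by exactly one.

    Working at the pixel level (rather than with whole-patch years) makes
    merging idempotent: re-running it on already-merged patches rebuilds the
    same graph.
    """
    pairs = []
    for (a, b), (ya, yb) in (
        ((idx_grid[:, :-1], idx_grid[:, 1:]), (year_grid[:, :-1], year_grid[:, 1:])),
        ((idx_grid[:-1, :], idx_grid[1:, :]), (year_grid[:-1, :], year_grid[1:, :])),
    ):
        ok = (
            (a >= 0)
            & (b >= 0)
            & (a != b)
            & (np.abs(ya.astype(np.int64) - yb.astype(np.int64)) == 1)
        )
        if ok.any():
            pairs.append(np.column_stack((a[ok], b[ok])))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.concatenate(pairs).astype(np.int64)
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def merge_consecutive(patches: list[Patch], dmap: DisturbanceMap) -> list[Patch]:
    """Merge patches of consecutive years that share an edge.

    Two patches connect iff |year difference| == 1 and some pixel of one is
    4-adjacent to a pixel of the other; merged events are the connected
    components of this graph, so chains across >2 years merge transitively.
    The merged year is the modal pixel year, ties resolved to the earlier
    year.  Pixel sets stay disjoint and the total pixel count is conserved.
    """
    if not patches:
        return []
    idx_grid = patch_index_grid(patches, dmap.shape)
    pairs = _consecutive_pairs_4(idx_grid, dmap.year_grid)
    n = len(patches)
    if len(pairs):
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, comp = _graph_components(g, directed=False)
    else:
        comp = np.arange(n)

    merged = []
    for cid in np.unique(comp):
        members = np.flatnonzero(comp == cid)
        pix = np.concatenate([patches[i].pixels for i in members])
        # majority vote over pixels; ties -> earlier year
        yrs = dmap.year_grid[pix[:, 0], pix[:, 1]]
        uniq, counts = np.unique(yrs, return_counts=True)
        year = int(uniq[np.flatnonzero(counts == counts.max())[0]])
        merged.append(
            Patch(
                patch_id=-1,
                year=year,
                pixels=pix,
                pixel_size=dmap.pixel_size,
                merged_from=sorted(int(patches[i].patch_id) for i in members),
            )
        )
    merged.sort(key=lambda p: (p.year, _first_pixel_order(p.pixels)))
    for i, p in enumerate(merged):
        p.patch_id = i
    return merged


def delineate(dmap: DisturbanceMap) -> list[Patch]:
    """label_patches followed by merge_consecutive."""
    return merge_consecutive(label_patches(dmap), dmap)


def patch_table(patches: list[Patch]):
    """Patch attribute table (patch_id, year, n_pixels, area_m2, centroid)."""
    import pandas as pd

    rows = []
    for p in patches:
        cx, cy = p.centroid
        rows.append((p.patch_id, p.year, p.n_pixels, p.area_m2, cx, cy))
    return pd.DataFrame(
        rows,
        columns=["patch_id", "year", "n_pixels", "area_m2", "centroid_x", "centroid_y"],
    )
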