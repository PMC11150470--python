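"""Per-patch predictors and training-table assembly.

Predictors cover four groups: patch size, patch shape, spectral
characteristics before and during the canopy opening, and landscape context
(whether the patch co-occurred in space and time with other patches).  The
eleven model features are listed in FEATURE_COLUMNS; centroids travel along
as metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .patches import DisturbanceMap, Patch, patch_index_grid

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "n_pixels",
    "area_m2",
    "perimeter_m",
    "shape_index",
    "core_fraction",
    "pre_mean",
    "pre_sd",
    "mag_mean",
    "mag_sd",
    "ctx_count",
    "ctx_area_m2",
    "ctx_nn_dist_m",
]

# priority used to break label ties when conflicting agent points share a patch
AGENT_PRIORITY = {"wind": 0, "fire": 1, "bark_beetle": 2}
UNPLANNED_AGENTS = ("wind", "bark_beetle", "fire")


def _mask_geometry(pixels: np.ndarray):
    """Perimeter edge count and core-pixel count from a padded bbox mask."""
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    mask = np.zeros((r1 - r0 + 3, c1 - c0 + 3), dtype=bool)
    mask[pixels[:, 0] - r0 + 1, pixels[:, 1] - c0 + 1] = True
    edges = 0
    core = np.ones_like(mask)
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rolled = np.roll(mask, shift, axis=(0, 1))
        edges += np.count_nonzero(mask & ~rolled)
        core &= rolled
    n_core = np.count_nonzero(mask & core)
    return edges, n_core


def _spectral_stats(grid, pixels):
    if grid is None:
        return np.nan, np.nan, 0
    vals = grid[pixels[:, 0], pixels[:, 1]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan, np.nan, 1
    return float(vals.mean()), float(vals.std(ddof=0)), 0


def compute_features(
    patches: list[Patch],
    dmap: DisturbanceMap,
    radius_m: float = 2000.0,
    t_window: int = 1,
) -> pd.DataFrame:
    """One feature vector per patch, indexed by patch_id.

    Landscape context counts other patches whose centroid lies within
    ``radius_m`` and whose year differs by at most ``t_window``; a patch with
    no such neighbor gets ctx_count 0, ctx_area 0 and nearest-neighbor
    distance capped at ``radius_m``.  Patches with no valid spectral pixels
    receive the global mean and a missingness flag.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    if t_window < 0:
        raise ValueError("t_window must be >= 0")
    px = dmap.pixel_size
    rows = []
    for p in patches:
        edges, n_core = _mask_geometry(p.pixels)
        perimeter_m = edges * px
        area = p.area_m2
        pre_mean, pre_sd, pre_miss = _spectral_stats(dmap.pre_grid, p.pixels)
        mag_mean, mag_sd, mag_miss = _spectral_stats(dmap.mag_grid, p.pixels)
        cx, cy = p.centroid
        rows.append(
            dict(
                patch_id=p.patch_id,
                year=p.year,
                n_pixels=p.n_pixels,
                area_m2=area,
                perimeter_m=perimeter_m,
                shape_index=perimeter_m / (4.0 * np.sqrt(area)),
                core_fraction=n_core / p.n_pixels,
                pre_mean=pre_mean,
                pre_sd=pre_sd,
                pre_missing=pre_miss,
                mag_mean=mag_mean,
                mag_sd=mag_sd,
                mag_missing=mag_miss,
                centroid_x=cx,
                centroid_y=cy,
            )
        )
    feats = pd.DataFrame(rows).set_index("patch_id")

    # all-missing spectra fall back to the global mean across patches
    for band in ("pre", "mag"):
        for stat in ("mean", "sd"):
            col = f"{band}_{stat}"
            if feats[col].isna().any():
                fill = feats[col].mean()
                feats[col] = feats[col].fillna(0.0 if np.isnan(fill) else fill)

    # landscape context via KD-tree on centroids
    xy = feats[["centroid_x", "centroid_y"]].to_numpy()
    years = feats["year"].to_numpy()
    areas = feats["area_m2"].to_numpy()
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(xy, r=radius_m)
    ctx_count = np.zeros(len(feats), dtype=int)
    ctx_area = np.zeros(len(feats))
    ctx_nn = np.full(len(feats), float(radius_m))
    for i, nbrs in enumerate(neighbor_lists):
        nbrs = [j for j in nbrs if j != i and abs(years[j] - years[i]) <= t_window]
        if not nbrs:
            continue
        ctx_count[i] = len(nbrs)
        ctx_area[i] = areas[nbrs].sum()
        d = np.hypot(xy[nbrs, 0] - xy[i, 0], xy[nbrs, 1] - xy[i, 1])
        ctx_nn[i] = min(float(d.min()), float(radius_m))
    feats["ctx_count"] = ctx_count
    feats["ctx_area_m2"] = ctx_area
    feats["ctx_nn_dist_m"] = ctx_nn
    return feats


@dataclass
class LinkReport:
    n_points: int
    n_linked: int
    n_on_undisturbed: int
    n_year_mismatch: int


def link_reference_points(
    points: pd.DataFrame, patches: list[Patch], dmap: DisturbanceMap
) -> tuple[dict[int, str], LinkReport]:
    """Link agent-labeled point occurrences to the patches that contain them.

    A point links to the patch covering its pixel when the patch year is
    within +/-1 year of the point year (the map's stated temporal
    inaccuracy).  Several points in one patch collapse to a single label;
    conflicting agents resolve by point-count majority, ties by the fixed
    priority wind > fire > bark_beetle.  Points on undisturbed pixels or
    failing the year tolerance are dropped and counted, not fatal.
    """
    idx_grid = patch_index_grid(patches, dmap.shape)
    px = dmap.pixel_size
    nrows, ncols = dmap.shape
    votes: dict[int, dict[str, int]] = {}
    n_undist = n_year = n_linked = 0
    for _, pt in points.iterrows():
        r = int(pt["y"] // px)
        c = int(pt["x"] // px)
        if not (0 <= r < nrows and 0 <= c < ncols) or idx_grid[r, c] < 0:
            n_undist += 1
            continue
        p = patches[idx_grid[r, c]]
        if abs(p.year - int(pt["year"])) > 1:
            n_year += 1
            continue
        votes.setdefault(p.patch_id, {}).setdefault(pt["agent"], 0)
        votes[p.patch_id][pt["agent"]] += 1
        n_linked += 1
    labels = {}
    for pid, counts in votes.items():
        best = max(counts.items(), key=lambda kv: (kv[1], -AGENT_PRIORITY[kv[0]]))
        labels[pid] = best[0]
    report = LinkReport(len(points), n_linked, n_undist, n_year)
    if n_undist or n_year:
        log.info(
            "dropped %d points on undisturbed pixels and %d outside the "
            "+/-1 yr tolerance (of %d)",
            n_undist,
            n_year,
            len(points),
        )
    return labels, report


def sample_background(
    all_patch_ids, labeled_ids, n: int, seed: int
) -> np.ndarray:
    """Uniform sample of n unlabeled patch ids, without replacement."""
    pool = np.setdiff1d(np.asarray(all_patch_ids), np.asarray(list(labeled_ids)))
    if n > pool.size:
        raise ValueError(
            f"requested {n} background patches but only {pool.size} are unlabeled"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(pool, size=n, replace=False))


def build_training_table(
    features: pd.DataFrame,
    agent_labels: dict[int, str],
    seed: int,
    n_background: int | None = None,
) -> pd.DataFrame:
    """Balanced table: unplanned reference patches vs a background sample.

    Background patches are drawn uniformly from all patches not labeled
    unplanned and treated as planned (label 0), matching the count of
    unplanned rows unless ``n_background`` overrides it.
    """
    labeled = sorted(agent_labels)
    if n_background is None:
        n_background = len(labeled)
    bg = sample_background(features.index.to_numpy(), labeled, n_background, seed)
    rows_pos = features.loc[labeled].copy()
    rows_pos["label"] = 1
    rows_pos["agent"] = [agent_labels[i] for i in labeled]
    rows_bg = features.loc[bg].copy()
    rows_bg["label"] = 0
    rows_bg["agent"] = "background"
    table = pd.concat([rows_pos, rows_bg])
    table.index.name = "patch_id"
    return table
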