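"""Per-patch predictors: geometry, spectra, landscape context, training table."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import canopylink as cl
from canopylink.patches import DisturbanceMap, Patch
from _oracles import pairwise_context


def _single_patch_map(pixels, year=2000, shape=(10, 10), pixel_size=30.0):
    grid = np.zeros(shape, dtype=np.uint16)
    pix = np.asarray(pixels)
    grid[pix[:, 0], pix[:, 1]] = year
    dmap = DisturbanceMap(
        year_grid=grid,
        pixel_size=pixel_size,
        pre_grid=np.zeros(shape),
        mag_grid=np.zeros(shape),
    )
    patch = Patch(patch_id=0, year=year, pixels=pix, pixel_size=pixel_size)
    return patch, dmap


class TestGeometry:
    def test_single_pixel(self):
        patch, dmap = _single_patch_map([(3, 3)])
        f = cl.compute_features([patch], dmap).iloc[0]
        assert f["area_m2"] == 900.0
        assert f["perimeter_m"] == 120.0
        assert f["shape_index"] == pytest.approx(1.0)
        assert f["core_fraction"] == 0.0

    def test_two_by_two_square(self):
        patch, dmap = _single_patch_map([(2, 2), (2, 3), (3, 2), (3, 3)])
        f = cl.compute_features([patch], dmap).iloc[0]
        assert f["perimeter_m"] == 240.0
        assert f["shape_index"] == pytest.approx(240.0 / (4 * np.sqrt(3600.0)))
        assert f["core_fraction"] == 0.0

    def test_plus_shape_has_core_pixel_and_inner_perimeter(self):
        pixels = [(2, 3), (3, 2), (3, 3), (3, 4), (4, 3)]
        patch, dmap = _single_patch_map(pixels)
        f = cl.compute_features([patch], dmap).iloc[0]
        assert f["core_fraction"] == pytest.approx(1 / 5)
        assert f["perimeter_m"] == 12 * 30.0
        assert f["shape_index"] > 1.0

    def test_shape_index_invariant_to_rotation(self):
        rng = np.random.default_rng(4)
        base = [(0, 0)]
        for _ in range(15):  # random connected blob
            r, c = base[int(rng.integers(len(base)))]
            base.append((r + int(rng.integers(-1, 2)), c + int(rng.integers(-1, 2))))
        pix = np.unique(np.asarray(base) + 10, axis=0)
        rotated = np.column_stack([pix[:, 1], 30 - pix[:, 0]])  # 90 degrees
        vals = []
        for pset in (pix, rotated):
            patch, dmap = _single_patch_map(pset, shape=(40, 40))
            vals.append(cl.compute_features([patch], dmap).iloc[0]["shape_index"])
        assert vals[0] == pytest.approx(vals[1])

    def test_translation_invariance(self, small_landscape, small_patches):
        dmap = small_landscape.dmap
        feats = cl.compute_features(small_patches, dmap)
        shift = 7
        pad = ((shift, 0), (shift, 0))
        shifted_map = DisturbanceMap(
            year_grid=np.pad(dmap.year_grid, pad),
            pixel_size=dmap.pixel_size,
            pre_grid=np.pad(dmap.pre_grid, pad),
            mag_grid=np.pad(dmap.mag_grid, pad, constant_values=np.nan),
        )
        shifted_patches = [
            Patch(p.patch_id, p.year, p.pixels + shift, p.pixel_size)
            for p in small_patches
        ]
        feats2 = cl.compute_features(shifted_patches, shifted_map)
        cols = [c for c in cl.FEATURE_COLUMNS]
        pd.testing.assert_frame_equal(feats[cols], feats2[cols], atol=1e-9, rtol=0)


def test_context_matches_pairwise_oracle():
    rng = np.random.default_rng(21)
    grid = np.zeros((48, 48), dtype=np.uint16)
    mask = rng.random((48, 48)) < 0.15
    grid[mask] = rng.choice([2000, 2001, 2002, 2003], size=int(mask.sum()))
    dmap = DisturbanceMap(
        year_grid=grid,
        pre_grid=rng.normal(size=(48, 48)),
        mag_grid=rng.normal(size=(48, 48)),
    )
    patches = cl.delineate(dmap)
    feats = cl.compute_features(patches, dmap, radius_m=1500.0, t_window=1)
    xy = feats[["centroid_x", "centroid_y"]].to_numpy()
    want = pairwise_context(
        xy, feats["year"].to_numpy(), feats["area_m2"].to_numpy(), 1500.0, 1
    )
    got = feats[["ctx_count", "ctx_area_m2", "ctx_nn_dist_m"]].to_numpy()
    assert np.allclose(got, np.asarray(want))


def test_context_defaults_when_isolated():
    patch, dmap = _single_patch_map([(5, 5)])
    f = cl.compute_features([patch], dmap, radius_m=2000.0).iloc[0]
    assert f["ctx_count"] == 0
    assert f["ctx_area_m2"] == 0.0
    assert f["ctx_nn_dist_m"] == 2000.0


def test_invalid_radius_rejected(small_landscape, small_patches):
    with pytest.raises(ValueError):
        cl.compute_features(small_patches, small_landscape.dmap, radius_m=-1.0)


def test_all_missing_spectra_get_global_mean_and_flag():
    grid = np.zeros((6, 6), dtype=np.uint16)
    grid[0, 0] = grid[3, 3] = 2000
    mag = np.full((6, 6), np.nan)
    mag[0, 0] = 2.5  # only the first patch observed
    dmap = DisturbanceMap(year_grid=grid, pre_grid=np.zeros((6, 6)), mag_grid=mag)
    patches = cl.delineate(dmap)
    feats = cl.compute_features(patches, dmap)
    flagged = feats[feats["mag_missing"] == 1]
    assert len(flagged) == 1
    assert flagged.iloc[0]["mag_mean"] == pytest.approx(2.5)  # global mean fill


class TestLinkReferencePoints:
    def test_multiple_same_agent_points_collapse(self, small_landscape):
        dmap = small_landscape.dmap
        patches = cl.delineate(dmap)
        p = next(p for p in patches if p.n_pixels >= 3)
        px = dmap.pixel_size
        pts = pd.DataFrame(
            {
                "x": (p.pixels[:3, 1] + 0.5) * px,
                "y": (p.pixels[:3, 0] + 0.5) * px,
                "year": p.year,
                "agent": "wind",
            }
        )
        labels, report = cl.link_reference_points(pts, patches, dmap)
        assert labels == {p.patch_id: "wind"}
        assert report.n_linked == 3

    def test_year_tolerance_of_one(self, small_landscape):
        dmap = small_landscape.dmap
        patches = cl.delineate(dmap)
        p = patches[0]
        px = dmap.pixel_size
        base = dict(
            x=(p.pixels[0, 1] + 0.5) * px, y=(p.pixels[0, 0] + 0.5) * px, agent="fire"
        )
        ok = pd.DataFrame([{**base, "year": p.year - 1}])
        labels, _ = cl.link_reference_points(ok, patches, dmap)
        assert p.patch_id in labels
        far = pd.DataFrame([{**base, "year": p.year - 2}])
        labels, report = cl.link_reference_points(far, patches, dmap)
        assert labels == {}
        assert report.n_year_mismatch == 1

    def test_conflicting_agents_majority_then_priority(self, small_landscape):
        dmap = small_landscape.dmap
        patches = cl.delineate(dmap)
        p = next(p for p in patches if p.n_pixels >= 3)
        px = dmap.pixel_size

        def pt(i, agent):
            return {
                "x": (p.pixels[i, 1] + 0.5) * px,
                "y": (p.pixels[i, 0] + 0.5) * px,
                "year": p.year,
                "agent": agent,
            }

        majority = pd.DataFrame([pt(0, "fire"), pt(1, "fire"), pt(2, "bark_beetle")])
        labels, _ = cl.link_reference_points(majority, patches, dmap)
        assert labels[p.patch_id] == "fire"
        tie = pd.DataFrame([pt(0, "bark_beetle"), pt(1, "wind")])
        labels, _ = cl.link_reference_points(tie, patches, dmap)
        assert labels[p.patch_id] == "wind"  # wind > fire > bark_beetle

    def test_point_on_undisturbed_pixel_dropped_not_fatal(self, small_landscape):
        dmap = small_landscape.dmap
        patches = cl.delineate(dmap)
        bg = np.argwhere(dmap.year_grid == 0)[0]
        px = dmap.pixel_size
        pts = pd.DataFrame(
            [{"x": (bg[1] + 0.5) * px, "y": (bg[0] + 0.5) * px, "year": 2000, "agent": "wind"}]
        )
        labels, report = cl.link_reference_points(pts, patches, dmap)
        assert labels == {}
        assert report.n_on_undisturbed == 1

    def test_emitted_points_link_to_matching_truth(self, default_500_landscape):
        """>= 99% of generator points land in a patch whose majority cause
        is unplanned (mismatches are small events swallowed by merges)."""
        from canopylink.patches import patch_index_grid

        land = default_500_landscape
        dmap = land.dmap
        patches = cl.delineate(dmap)
        _, report = cl.link_reference_points(land.points, patches, dmap)
        assert report.n_linked / report.n_points >= 0.99
        true_cls = land.truth.patch_class(patches)
        idx = patch_index_grid(patches, dmap.shape)
        px = dmap.pixel_size
        match = 0
        for _, pt in land.points.iterrows():
            pid = patches[idx[int(pt["y"] // px), int(pt["x"] // px)]].patch_id
            match += true_cls[pid] == "unplanned"
        assert match / len(land.points) >= 0.99


class TestTrainingTable:
    def test_balanced_table(self, small_landscape, small_patches, small_features):
        labels, _ = cl.link_reference_points(
            small_landscape.points, small_patches, small_landscape.dmap
        )
        table = cl.build_training_table(small_features, labels, seed=3)
        counts = table["label"].value_counts()
        assert counts[0] == counts[1] == len(labels)
        assert table.index.is_unique

    def test_background_excludes_labeled_and_is_deterministic(self, small_features):
        ids = small_features.index.to_numpy()
        labeled = set(ids[:10])
        a = cl.sample_background(ids, labeled, 25, seed=5)
        b = cl.sample_background(ids, labeled, 25, seed=5)
        assert np.array_equal(a, b)
        assert not labeled & set(a)

    def test_background_pool_exhausted_raises(self, small_features):
        ids = small_features.index.to_numpy()
        with pytest.raises(ValueError, match="unlabeled"):
            cl.sample_background(ids, set(), len(ids) + 1, seed=0)

    def test_zero_background(self, small_features):
        table = cl.build_training_table(
            small_features, {int(small_features.index[0]): "wind"}, seed=0, n_background=0
        )
        assert (table["label"] == 1).all()


def test_class_conditional_feature_signal(default_500_landscape):
    """Patch size and area-weighted landscape context differ between true
    classes, guaranteeing the classifier has signal to work with.  (Raw
    neighbor counts do not separate at this extent: dispersed planned
    patches dominate every neighborhood's count.)"""
    land = default_500_landscape
    patches = cl.delineate(land.dmap)
    feats = cl.compute_features(patches, land.dmap)
    true_cls = land.truth.patch_class(patches)
    unp = feats[true_cls.reindex(feats.index) == "unplanned"]
    pla = feats[true_cls.reindex(feats.index) == "planned"]
    for col in ("n_pixels", "ctx_area_m2"):
        p = mannwhitneyu(unp[col], pla[col]).pvalue
        assert p < 0.01, col
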