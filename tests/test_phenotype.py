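"""Mask post-processing and body-parameter extraction."""

import numpy as np
import pytest
from scipy.sparse.csgraph import dijkstra
from skimage import measure, morphology

from wormseg import phenotype as ph
from wormseg import synthetic_data as sd


def bmask(grid, px=1.0):
    return ph.BinaryMask(np.asarray(grid, bool), px)


class TestBinarize:
    def test_threshold_at_half(self):
        probs = np.array([[0.4, 0.6], [0.5, 0.49]])
        mask = ph.binarize(probs, 1.0)
        np.testing.assert_array_equal(
            mask.grid, [[False, True], [True, False]])  # 0.50 -> foreground

    def test_all_zero_gives_empty(self):
        assert not ph.binarize(np.zeros((4, 4)), 1.0).grid.any()

    def test_padding_columns_removed(self):
        probs = np.ones((4, 10))
        mask = ph.binarize(probs, 1.0, pad=(3, 2))
        assert mask.grid.shape == (4, 5)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ph.binarize(np.full((2, 2), 1.5), 1.0)


class TestFilterComponents:
    def test_keeps_blob_removes_specks(self):
        grid = np.zeros((200, 200), bool)
        grid[20:120, 20:120] = True          # 10,000 px worm
        grid[150:157, 150:157] = True        # ~50 px specks
        grid[5:12, 180:187] = True
        grid[180:187, 5:12] = True
        out, flags = ph.filter_components(bmask(grid), min_area_px=500)
        assert out.area_px == 10000
        assert "small_objects_removed" in flags

    def test_empty_mask_flagged(self):
        out, flags = ph.filter_components(bmask(np.zeros((8, 8))), 10)
        assert not out.grid.any() and flags == ["no_worm_detected"]

    def test_largest_only_rule_matches_labeling_oracle(self):
        grid = np.zeros((60, 60), bool)
        grid[5:35, 5:35] = True     # 900 px
        grid[40:50, 5:45] = False
        grid[40:56, 40:56] = True   # 256 px
        out, _ = ph.filter_components(bmask(grid), min_area_px=10)
        labels = measure.label(grid, connectivity=2)
        sizes = np.bincount(labels.ravel())[1:]
        assert out.area_px == sizes.max()

    def test_below_floor_flagged_empty(self):
        grid = np.zeros((20, 20), bool)
        grid[5:10, 5:10] = True
        out, flags = ph.filter_components(bmask(grid), min_area_px=100)
        assert not out.grid.any() and "no_worm_detected" in flags


def _diameter_all_pairs(grid):
    """Brute-force oracle: full all-pairs shortest paths on the skeleton."""
    skel = morphology.skeletonize(grid)
    if skel.sum() <= 1:
        return 0.0
    graph, _ = ph._skeleton_graph(skel)
    d = dijkstra(graph)
    d[~np.isfinite(d)] = -1
    return float(d.max())


class TestSkeletonLength:
    def test_axis_aligned_bar(self):
        grid = np.zeros((20, 220), bool)
        grid[5:15, 10:210] = True
        length = ph.skeleton_length(bmask(grid, px=1.0))
        assert 190 <= length <= 200

    def test_single_pixel_is_zero(self):
        grid = np.zeros((5, 5), bool)
        grid[2, 2] = True
        assert ph.skeleton_length(bmask(grid)) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ph.skeleton_length(bmask(np.zeros((4, 4))))

    def test_sinuous_worm_within_three_percent_of_arc_length(self):
        scene = sd.SceneConfig.tiny()
        rng = np.random.default_rng(4)
        for _ in range(4):
            length = rng.uniform(600, 1100)
            spec = sd.make_worm(rng, length, 0.06 * length, scene=scene)
            grid = sd.rasterize_worm(spec, scene)
            got = ph.skeleton_length(bmask(grid, scene.pixel_size_um))
            assert got == pytest.approx(length, rel=0.03)

    def test_matches_all_pairs_oracle(self):
        """The two-sweep geodesic search equals the brute-force graph
        diameter on small masks."""
        rng = np.random.default_rng(5)
        scene = sd.SceneConfig.tiny(fov_height_px=64, pixel_size_um=8.0,
                                    channel_pitch_um=256.0)
        cases = []
        for seed in range(4):
            spec = sd.make_worm(np.random.default_rng(seed), 400, 40,
                                scene=scene)
            cases.append(sd.rasterize_worm(spec, scene))
        blob = np.zeros((40, 40), bool)
        blob[5:35, 18:23] = True
        blob[18:23, 5:35] = True  # crossing bars -> branched skeleton
        cases.append(blob)
        for grid in cases:
            got = ph.skeleton_length(bmask(grid, 1.0))
            assert got == pytest.approx(_diameter_all_pairs(grid), abs=1e-9)


class TestAreaVolume:
    def test_area_arithmetic(self):
        grid = np.zeros((20, 20), bool)
        grid[:10, :10] = True
        assert ph.body_area(bmask(grid, px=0.5)) == pytest.approx(25.0)
        assert ph.body_area(bmask(np.zeros((4, 4)), px=0.5)) == 0.0

    def test_uniform_layer_volume(self):
        geom = ph.ChannelGeometry((0.0, 1000.0), (30.0,))
        grid = np.zeros((100, 10), bool)
        grid[10:60, :] = True
        mask = bmask(grid, px=2.0)
        assert ph.body_volume(mask, geom) == pytest.approx(
            ph.body_area(mask) * 30.0)

    def test_two_layer_piecewise_sum(self):
        """60% of a 1,000 um^2 mask in a 30-um layer plus 40% in a 20-um
        layer totals 26,000 um^3."""
        geom = ph.ChannelGeometry((0.0, 60.0, 200.0), (30.0, 20.0))
        grid = np.zeros((100, 10), bool)
        grid[0:60, :] = True   # 600 um^2 in layer 1 (1 um pixels)
        grid[60:100, :] = True  # 400 um^2 in layer 2
        vol = ph.body_volume(bmask(grid, px=1.0), geom)
        assert vol == pytest.approx(0.6 * 1000 * 30 + 0.4 * 1000 * 20)

    def test_empty_mask_zero_volume(self):
        geom = ph.ChannelGeometry.preset("3L")
        assert ph.body_volume(bmask(np.zeros((4, 4))), geom) == 0.0

    def test_pixels_outside_geometry_rejected(self):
        geom = ph.ChannelGeometry((0.0, 10.0), (30.0,))
        grid = np.ones((40, 4), bool)
        with pytest.raises(ValueError, match="outside"):
            ph.body_volume(bmask(grid, px=1.0), geom)

    def test_geometry_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            ph.ChannelGeometry((0.0, 5.0, 4.0), (30.0, 20.0))
        with pytest.raises(ValueError, match="decrease"):
            ph.ChannelGeometry((0.0, 5.0, 10.0), (20.0, 30.0))

    def test_presets_load_from_config_files(self):
        for name, n_layers in (("3L", 3), ("4L", 4)):
            geom = ph.ChannelGeometry.preset(name)
            assert len(geom.heights_um) == n_layers


class TestScalingProperties:
    def test_dilation_never_decreases_area_or_volume(self):
        from scipy import ndimage
        geom = ph.ChannelGeometry.preset("4L")
        grid = np.zeros((60, 20), bool)
        grid[10:40, 5:12] = True
        big = ndimage.binary_dilation(grid, iterations=2)
        assert ph.body_area(bmask(big)) >= ph.body_area(bmask(grid))
        assert ph.body_volume(bmask(big, 2.0), geom) >= \
            ph.body_volume(bmask(grid, 2.0), geom)

    def test_pixel_size_scale_equivariance(self):
        grid = np.zeros((40, 40), bool)
        grid[5:35, 15:25] = True
        l1 = ph.skeleton_length(bmask(grid, px=1.0))
        l2 = ph.skeleton_length(bmask(grid, px=2.0))
        assert l2 == pytest.approx(2 * l1)
        assert ph.body_area(bmask(grid, px=2.0)) == \
            pytest.approx(4 * ph.body_area(bmask(grid, px=1.0)))


class TestInference:
    def test_empty_channel_gives_class_only_record(self, labeled8,
                                                   overfit_model):
        geom = ph.ChannelGeometry.preset("4L")
        empty_rec = next(r for r in labeled8 if r.class_label == "empty")
        rec = ph.infer_channel(empty_rec.stack, overfit_model, geom,
                               min_area_px=100)
        assert rec.class_label in ("empty", "partial")
        assert not np.isfinite(rec.length_um)
        assert "no_full_worm" in rec.qc_flags

    def test_full_worm_measures_close_to_ground_truth(self, labeled8,
                                                      overfit_model):
        """End to end with a near-perfect (overfit) network, all three
        body measures land within 5% of the ground-truth-mask values."""
        geom = ph.ChannelGeometry.preset("4L")
        checked = 0
        for rec in labeled8:
            if rec.class_label != "full":
                continue
            got = ph.infer_channel(rec.stack, overfit_model, geom,
                                   min_area_px=100)
            assert got.class_label == "full"
            truth = ph.BinaryMask(rec.mask, rec.stack.pixel_size_um)
            assert got.length_um == pytest.approx(
                ph.skeleton_length(truth), rel=0.05)
            assert got.area_um2 == pytest.approx(
                ph.body_area(truth), rel=0.05)
            assert got.volume_um3 == pytest.approx(
                ph.body_volume(truth, geom), rel=0.05)
            checked += 1
        assert checked >= 5

    def test_device_records_partition_by_class(self, labeled8,
                                               overfit_model):
        geom = ph.ChannelGeometry.preset("4L")
        phenos = ph.infer_device(labeled8, overfit_model, geom,
                                 min_area_px=100)
        assert len(phenos) == len(labeled8)
        full = [p for p in phenos if p.class_label == "full"]
        rest = [p for p in phenos if p.class_label != "full"]
        assert all(np.isfinite(p.length_um) for p in full)
        assert all(not np.isfinite(p.length_um) for p in rest)
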