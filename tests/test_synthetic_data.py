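"""The synthetic channel-device generator: geometry, rendering, determinism."""

import numpy as np
import pytest
from scipy import ndimage, stats

from wormseg import synthetic_data as sd


@pytest.fixture()
def scene():
    return sd.SceneConfig.tiny()


class TestSceneConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            sd.SceneConfig(class_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            sd.SceneConfig(n_z=0)
        with pytest.raises(ValueError):
            sd.SceneConfig(pixel_size_um=0)

    def test_default_channel_width_matches_published_crops(self):
        """One 150-um pitch spans 340-360 px at the default pixel size."""
        assert 340 <= sd.SceneConfig().channel_width_px <= 360


class TestMakeWorm:
    def test_straight_worm_spans_requested_length(self, scene):
        spec = sd.make_worm(np.random.default_rng(0), 1000, 60,
                            sinuosity=0.0, scene=scene, taper=0.0)
        mask = sd.rasterize_worm(spec, scene)
        ys = np.nonzero(mask)[0]
        height_px = ys.max() - ys.min() + 1
        # capsule geometry: rounded end caps add half a width at each tip
        assert height_px == pytest.approx(
            (1000 + 60) / scene.pixel_size_um, rel=0.03
        )

    @pytest.mark.parametrize("sinuosity", [0.1, 0.3])
    def test_arc_length_matches_request(self, scene, sinuosity):
        spec = sd.make_worm(np.random.default_rng(7), 1000, 60,
                            sinuosity=sinuosity, scene=scene)
        assert abs(spec.arc_length_um - 1000) <= 5.0

    def test_deterministic_under_fixed_seed(self, scene):
        a = sd.make_worm(np.random.default_rng(3), 800, 50, scene=scene)
        b = sd.make_worm(np.random.default_rng(3), 800, 50, scene=scene)
        np.testing.assert_array_equal(a.centerline, b.centerline)
        assert a.contrast == b.contrast

    def test_too_wide_worm_rejected(self, scene):
        channel_w = scene.channel_width_px * scene.pixel_size_um
        with pytest.raises(ValueError, match="wide"):
            sd.make_worm(np.random.default_rng(0), 500, channel_w + 1,
                         scene=scene)


class TestRasterize:
    def test_constant_width_area(self, scene):
        spec = sd.make_worm(np.random.default_rng(1), 900, 50,
                            sinuosity=0.0, scene=scene, taper=0.0)
        mask = sd.rasterize_worm(spec, scene)
        area = mask.sum() * scene.pixel_size_um**2
        assert area == pytest.approx(900 * 50, rel=0.05)

    def test_truncated_touches_border(self, scene):
        spec = sd.make_worm(np.random.default_rng(2), 900, 50, scene=scene,
                            truncated=True)
        mask = sd.rasterize_worm(spec, scene)
        assert mask[0, :].any() or mask[-1, :].any()
        assert sd.classify_mask(mask) == "partial"

    def test_empty_spec_gives_empty_mask(self, scene):
        assert not sd.rasterize_worm(None, scene).any()

    def test_single_connected_component(self, scene):
        spec = sd.make_worm(np.random.default_rng(5), 900, 50, scene=scene)
        mask = sd.rasterize_worm(spec, scene)
        _, n = ndimage.label(mask)
        assert n == 1


class TestRenderChannelStack:
    def test_focus_slice_has_max_laplacian_energy(self, scene):
        rng = np.random.default_rng(4)
        for z_focus in range(scene.n_z):
            spec = sd.make_worm(rng, 800, 50, scene=scene)
            stack = sd.render_channel_stack(sd.rasterize_worm(spec, scene),
                                            spec, scene, rng, z_focus=z_focus)
            energies = [ndimage.laplace(stack.volume[0, z].astype(float)).var()
                        for z in range(scene.n_z)]
            assert int(np.argmax(energies)) == z_focus

    def test_no_noise_no_blur_slices_identical(self):
        scene = sd.SceneConfig.tiny(noise_sd=0.0, defocus_um_per_um=0.0)
        rng = np.random.default_rng(0)
        spec = sd.make_worm(rng, 800, 50, scene=scene)
        stack = sd.render_channel_stack(sd.rasterize_worm(spec, scene), spec,
                                        scene, rng)
        for z in range(1, scene.n_z):
            np.testing.assert_array_equal(stack.volume[0, z],
                                          stack.volume[0, 0])

    def test_byte_identical_for_fixed_seed(self, scene):
        def render(seed):
            rng = np.random.default_rng(seed)
            spec = sd.make_worm(rng, 800, 50, scene=scene)
            return sd.render_channel_stack(sd.rasterize_worm(spec, scene),
                                           spec, scene, rng).volume
        np.testing.assert_array_equal(render(11), render(11))

    def test_debris_stays_below_area_cap(self):
        scene = sd.SceneConfig.tiny(debris_rate=3.0, noise_sd=0.0)
        rng = np.random.default_rng(9)
        stack = sd.render_channel_stack(sd.rasterize_worm(None, scene), None,
                                        scene, rng)
        img = stack.volume[0, scene.n_z // 2].astype(float)
        interior = img[:, 2:-2]
        labels, n = ndimage.label(interior < 0.5 * interior.max())
        sizes = np.bincount(labels.ravel())[1:]
        assert n == 0 or sizes.max() <= scene.debris_max_px


class TestMakeFov:
    def test_spec_count_mismatch_rejected(self, scene):
        with pytest.raises(ValueError, match="expected"):
            sd.make_fov([None] * 3, scene, np.random.default_rng(0))

    def test_all_empty_specs_classify_empty(self, scene):
        _, truth = sd.make_fov([None] * 8, scene, np.random.default_rng(0))
        assert [label for _, label in truth] == ["empty"] * 8

    def test_channel_centers_at_pitch(self, scene):
        fov, _ = sd.make_fov([None] * 8, scene, np.random.default_rng(0))
        diffs = np.diff(fov.channel_centers_px)
        pitch = scene.channel_pitch_um / scene.pixel_size_um
        assert np.all(np.abs(diffs - pitch) <= 1)

    def test_class_mix_frequencies(self):
        """Sampled occupancy over 1,000 channels lands within 3 pp of the
        81/14/5 full/partial/empty mix."""
        labels = sd.sample_class_labels(1000, (0.81, 0.14, 0.05),
                                        np.random.default_rng(0))
        freq = {c: labels.count(c) / 1000 for c in sd.CLASS_LABELS}
        assert abs(freq["full"] - 0.81) < 0.03
        assert abs(freq["partial"] - 0.14) < 0.03
        assert abs(freq["empty"] - 0.05) < 0.03


class TestFluorescence:
    def test_dose_monotone_in_mask_intensity(self, scene):
        plan = sd.DosePlan()
        rng = np.random.default_rng(0)
        spec = sd.make_worm(rng, 800, 50, scene=scene)
        mask = sd.rasterize_worm(spec, scene)
        lo = sd.render_fluorescence_stack(mask, spec, 0.0, plan, scene,
                                          np.random.default_rng(5))
        hi = sd.render_fluorescence_stack(mask, spec, max(plan.doses_um),
                                          plan, scene,
                                          np.random.default_rng(5))
        assert hi.max(axis=0)[mask].mean() > lo.max(axis=0)[mask].mean()

    def test_zero_granule_density_indistinguishable_from_background(self,
                                                                    scene):
        plan = sd.DosePlan()
        rng = np.random.default_rng(1)
        spec = sd.make_worm(rng, 800, 50, scene=scene, granule_density=0.0)
        mask = sd.rasterize_worm(spec, scene)
        stack = sd.render_fluorescence_stack(mask, spec, 9.0, plan, scene,
                                             np.random.default_rng(2))
        proj = stack.max(axis=0).astype(float)
        inside = proj[mask]
        outside = proj[~mask]
        # two-sample location test: means differ by < noise scale
        t = stats.ttest_ind(inside, outside, equal_var=False)
        assert abs(inside.mean() - outside.mean()) < 0.5 * outside.std() \
            or t.pvalue > 0.01

    def test_empty_mask_background_only(self, scene):
        plan = sd.DosePlan()
        stack = sd.render_fluorescence_stack(
            np.zeros(scene.channel_shape, bool), None, 9.0, plan, scene,
            np.random.default_rng(3))
        assert stack.max() < 0.05 * 50000


@pytest.fixture(scope="module")
def device():
    scene = sd.SceneConfig.tiny()
    return sd.make_device_dataset(sd.DosePlan(), scene,
                                  np.random.default_rng(11),
                                  with_fluorescence=False,
                                  render_images=False)


class TestDeviceDataset:

    def test_emits_960_channel_records(self, device):
        assert len(device.records) == 960
        assert len(device.layout) == 960

    def test_layout_deterministic(self, device):
        scene = sd.SceneConfig.tiny()
        again = sd.make_device_dataset(sd.DosePlan(), scene,
                                       np.random.default_rng(11),
                                       with_fluorescence=False,
                                       render_images=False)
        assert device.layout.equals(again.layout)

    def test_ground_truth_consistency(self, device):
        """Each sidecar label matches its mask geometry: empty = no
        foreground, partial touches a channel end, full does neither."""
        for rec in device.records[:200]:
            assert rec.class_label == sd.classify_mask(rec.mask)

    def test_lengths_follow_dose_response(self, device):
        """Mean generated body length is non-increasing in dose."""
        by_dose = {}
        for rec in device.records:
            if rec.worm is not None and not rec.worm.truncated:
                by_dose.setdefault(rec.dose_um, []).append(
                    rec.worm.body_length_um)
        doses = sorted(by_dose)
        means = [np.mean(by_dose[d]) for d in doses]
        # allow sampling noise: compare smoothed ends
        assert np.mean(means[:3]) > np.mean(means[-3:])
        assert means[0] == pytest.approx(1100, rel=0.05)


class TestDosePlan:
    def test_invariants(self):
        with pytest.raises(ValueError):
            sd.DosePlan(doses_um=(1.0, 2.0))  # no control
        with pytest.raises(ValueError):
            sd.DosePlan(biological_cv=0.0)

    def test_hill_curve_endpoints(self):
        plan = sd.DosePlan()
        assert plan.mean_length_um(0.0) == plan.hill_top
        assert plan.mean_length_um(1e9) == pytest.approx(plan.hill_bottom,
                                                         rel=1e-3)
        assert plan.af_level(0.0) == pytest.approx(plan.af_hill[0])
        assert plan.af_level(1e9) == pytest.approx(plan.af_hill[1], rel=1e-3)
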