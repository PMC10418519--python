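import numpy as np
import pytest
from scipy import stats

from vpaseg.augment import (
    AugmentConfig,
    RandomStream,
    SpatialTransform,
    add_uniform_noise,
    ambient_light,
    apply_lighting,
    augment_once,
    blend,
    crop_sphere,
    diffuse_light,
    identity_config,
    map_coordinate,
    perlin_field,
    perlin_texture,
    sample_transform,
    sample_transform_params,
    stamp_texture,
    subsample_blur,
    transform_from_params,
    warp_pair,
)
from vpaseg.volume_io import LabelVolume, ScalarVolume, TemplatePair


def make_pair(rng, shape=(16, 16, 16)):
    img = rng.random(shape)
    img /= img.max()
    lab = np.zeros(shape, dtype=np.int16)
    core = tuple(slice(s // 4, 3 * s // 4) for s in shape)
    lab[core] = rng.integers(1, 6, tuple(s // 2 for s in shape))
    return TemplatePair(ScalarVolume(img), LabelVolume(lab))


class TestSubsample:
    def test_no_axis_selected_is_identity(self, rng_np):
        img = rng_np.random((8, 8, 8))
        cfg = AugmentConfig(p_subsample_per_dim=0.0)
        np.testing.assert_array_equal(subsample_blur(img, RandomStream(0), cfg), img)

    def test_constant_image_unchanged(self):
        img = np.full((8, 8, 8), 0.7)
        cfg = AugmentConfig(p_subsample_per_dim=1.0)
        out = subsample_blur(img, RandomStream(0), cfg)
        np.testing.assert_allclose(out, 0.7, rtol=1e-12)

    def test_profile_matches_two_step_interpolation_oracle(self):
        profile = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        img = np.tile(profile[:, None, None], (1, 1, 1))  # axes y,z have size 1
        cfg = AugmentConfig(p_subsample_per_dim=1.0)
        out = subsample_blur(img, RandomStream(3), cfg)
        # independent oracle: two explicit np.interp passes, endpoints pinned
        down_x = np.linspace(0, 7, 4)
        down = np.interp(down_x, np.arange(8), profile)
        up_x = np.linspace(0, 3, 8)
        expected = np.interp(up_x, np.arange(4), down)
        np.testing.assert_allclose(out[:, 0, 0], expected, atol=1e-12)


class TestUniformNoise:
    def test_zero_range_identity(self, rng_np):
        img = rng_np.random((6, 6, 6))
        cfg = AugmentConfig(noise_high=0.0)
        np.testing.assert_array_equal(add_uniform_noise(img, RandomStream(0), cfg), img)

    def test_mean_and_support(self):
        img = np.zeros((64, 64, 64))
        out = add_uniform_noise(img, RandomStream(7), AugmentConfig())
        delta = out - img
        n = delta.size
        se = (0.2 / np.sqrt(12)) / np.sqrt(n)
        assert abs(delta.mean() - 0.1) < 3 * se
        assert delta.min() >= 0.0 and delta.max() <= 0.2


class TestCropSphere:
    def test_disabled_is_identity(self, rng_np):
        pair = make_pair(rng_np)
        out = crop_sphere(pair, RandomStream(0), AugmentConfig(crop_enabled=False))
        np.testing.assert_array_equal(out.image.data, pair.image.data)
        np.testing.assert_array_equal(out.label.data, pair.label.data)

    def test_cropped_count_matches_brute_force_ball(self, rng_np):
        pair = make_pair(rng_np, (24, 24, 24))
        cfg = AugmentConfig(crop_enabled=True)
        seed = 11
        out = crop_sphere(pair, RandomStream(seed), cfg)
        # mirror the documented draw order: radius, center (3 draws), fill
        mirror = RandomStream(seed)
        radius = mirror.uniform(*cfg.crop_radius_range) * 24
        center = np.array([mirror.uniform(0.0, 23.0) for _ in range(3)])
        changed = out.label.data != pair.label.data
        count = 0
        for idx in np.ndindex(24, 24, 24):
            if sum((i - c) ** 2 for i, c in zip(idx, center)) <= radius**2:
                count += 1
                assert out.label.data[idx] == 0
        fg_inside = (pair.label.data != 0) & (out.label.data == 0)
        assert fg_inside.sum() <= count
        analytic = 4.0 / 3.0 * np.pi * radius**3
        # voxelized ball vs continuous volume: surface-layer discretization bound
        assert abs(count - analytic) <= 4.0 * np.pi * radius**2 + 10

    def test_label_zero_inside(self, rng_np):
        pair = make_pair(rng_np)
        cfg = AugmentConfig(crop_enabled=True, crop_fill_range=(5.0, 5.0))
        out = crop_sphere(pair, RandomStream(2), cfg)
        inside = out.image.data == 5.0
        assert inside.any()
        assert (out.label.data[inside] == 0).all()


class TestLighting:
    def test_all_gated_off_identity(self, rng_np):
        img = rng_np.random((6, 6, 6))
        cfg = AugmentConfig(p_each_light=0.0)
        np.testing.assert_array_equal(apply_lighting(img, RandomStream(0), cfg), img)

    def test_ambient_only_adds_one_constant(self, rng_np):
        img = rng_np.random((6, 6, 6))
        cfg = AugmentConfig(p_each_light=1.0, diffuse_enabled=False,
                            specular_enabled=False)
        out = apply_lighting(img, RandomStream(4), cfg)
        delta = out - img
        assert np.allclose(delta, delta.flat[0])
        assert 0.0 <= delta.flat[0] <= 2.0

    def test_diffuse_center_voxel_fixed_point(self):
        img = np.random.default_rng(0).random((7, 7, 7))
        direction = np.array([1.0, 0.0, 0.0])
        out = diffuse_light(img, direction, gain=0.2)
        assert out[3, 3, 3] == pytest.approx(img[3, 3, 3])

    def test_ambient_light_formula(self):
        img = np.zeros((3, 3, 3))
        np.testing.assert_array_equal(ambient_light(img, 1.5), 1.5)


class TestSampleTransform:
    def test_bounds_over_1000_draws(self):
        cfg = AugmentConfig()
        rng = RandomStream(0)
        for _ in range(1000):
            p = sample_transform_params(rng, cfg, (32, 32, 32))
            assert (0 <= p["angles"]).all() and (p["angles"] <= 0.2).all()
            assert 0.8 <= p["scale"] <= 1.25
            assert 1.0 <= p["aspect"] <= 1.25
            assert (0 <= p["translation_frac"]).all()
            assert (p["translation_frac"] <= 0.2).all()
            assert (np.abs(p["perspective"]) <= 0.5).all()
            assert 0 <= p["distortion_frac"] <= 0.1

    def test_fixed_seed_reproducible(self):
        cfg = AugmentConfig()
        a = sample_transform(RandomStream(9), cfg, (20, 20, 20))
        b = sample_transform(RandomStream(9), cfg, (20, 20, 20))
        np.testing.assert_array_equal(a.R, b.R)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.p, b.p)
        assert a.m == b.m

    def test_scale_uniformity_ks(self):
        cfg = AugmentConfig()
        rng = RandomStream(1)
        scales = np.array([sample_transform_params(rng, cfg, (16,) * 3)["scale"]
                           for _ in range(10_000)])
        stat, pval = stats.kstest(scales, stats.uniform(0.8, 0.45).cdf)
        assert pval > 1e-3


def oracle_map(T, u):
    """Independent stage-by-stage re-implementation of the coordinate map."""
    u = np.asarray(u, dtype=float).copy()
    # stage 1: lens distortion
    nu = (T.c - u) / T.h
    u = u + T.m * nu * float(nu @ nu)
    # stage 2: perspective
    d = u - T.c
    u = T.c + d * (1.0 + float(T.p @ d))
    # stage 3: linear part about the center
    return T.R @ (u - T.c) + T.c + T.t


class TestMapCoordinate:
    def test_identity_transform(self, rng_np):
        T = SpatialTransform.identity((16, 16, 16))
        u = rng_np.random((3, 20)) * 15
        np.testing.assert_allclose(map_coordinate(T, u), u, atol=1e-12)

    def test_center_fixed_under_distortion_and_perspective(self):
        T = SpatialTransform.identity((17, 17, 17))
        T.m = 3.0
        T.p = np.array([0.01, -0.02, 0.015])
        np.testing.assert_allclose(map_coordinate(T, T.c), T.c, atol=1e-12)

    def test_matches_stage_by_stage_oracle(self):
        cfg = AugmentConfig()
        rng = RandomStream(21)
        for _ in range(1000):
            T = sample_transform(rng, cfg, (24, 20, 28))
            u = rng.uniform(-4, 30, 3)
            np.testing.assert_allclose(map_coordinate(T, u), oracle_map(T, u),
                                       rtol=1e-10, atol=1e-10)


class TestWarpPair:
    def test_identity_warp(self, rng_np):
        pair = make_pair(rng_np)
        out = warp_pair(pair, SpatialTransform.identity(pair.shape))
        np.testing.assert_allclose(out.image.data, pair.image.data, atol=1e-6)
        np.testing.assert_array_equal(out.label.data, pair.label.data)

    def test_integer_translation_shifts_exactly(self, rng_np):
        pair = make_pair(rng_np)
        T = SpatialTransform.identity(pair.shape)
        T.t = np.array([2.0, 0.0, 1.0])
        out = warp_pair(pair, T)
        # dest u samples source u+t: output is input shifted by -t
        src = pair.image.data[2:, :, 1:]
        got = out.image.data[: 16 - 2, :, : 16 - 1]
        np.testing.assert_allclose(got, src, atol=1e-5)

    def test_label_values_closed(self, rng_np):
        pair = make_pair(rng_np)
        cfg = AugmentConfig()
        T = sample_transform(RandomStream(5), cfg, pair.shape)
        out = warp_pair(pair, T)
        assert set(np.unique(out.label.data)) <= set(range(6))

    def test_label_matches_per_voxel_oracle(self, rng_np):
        pair = make_pair(rng_np)
        cfg = AugmentConfig(scale_range=(1.0, 1.0), aspect_range=(1.0, 1.0),
                            perspective_range=(0.0, 0.0), distortion_max=0.0)
        T = sample_transform(RandomStream(8), cfg, pair.shape)  # pure rigid
        out = warp_pair(pair, T)
        lab = pair.label.data
        for idx in np.ndindex(pair.shape):
            v = map_coordinate(T, np.array(idx, dtype=float))
            nearest = np.round(v).astype(int)
            if all(0 <= nearest[i] < pair.shape[i] for i in range(3)):
                assert out.label.data[idx] == lab[tuple(nearest)]
            else:
                assert out.label.data[idx] == 0


class TestBlend:
    @pytest.mark.parametrize("s,b,expected", [
        (0.5, 0.2, 0.6),
        (0.95, 1.0, 1.05),
        (0.0, 1.0, 1.0),
    ])
    def test_examples(self, s, b, expected):
        assert blend(s, b) == pytest.approx(expected)

    def test_piecewise_definition_on_grid(self):
        s = np.linspace(0.0, 1.0, 101)
        b = 0.37
        expected = np.array([si + b * (0.1 if 1 - si < 0.1 else 1 - si) for si in s])
        np.testing.assert_allclose(blend(s, np.full_like(s, b)), expected, atol=1e-12)


class TestTextures:
    def test_stamp_preserves_foreground(self, rng_np):
        pair = make_pair(rng_np)
        out = stamp_texture(pair, RandomStream(0), AugmentConfig())
        fg = pair.label.data != 0
        np.testing.assert_array_equal(out.image.data[fg], pair.image.data[fg])
        np.testing.assert_array_equal(out.label.data, pair.label.data)

    def test_stamp_zero_background_stays_zero(self, rng_np):
        img = np.zeros((12, 12, 12))
        lab = np.zeros((12, 12, 12), dtype=np.int16)
        lab[4:8, 4:8, 4:8] = 1
        img[4:8, 4:8, 4:8] = 1.0
        pair = TemplatePair(ScalarVolume(img), LabelVolume(lab))
        out = stamp_texture(pair, RandomStream(3), AugmentConfig())
        assert (out.image.data[lab == 0] == 0).all()

    def test_stamp_bounded_accumulation(self, rng_np):
        pair = make_pair(rng_np)
        cfg = AugmentConfig()
        out = stamp_texture(pair, RandomStream(1), cfg)
        bg = pair.label.data == 0
        # each of the 5 passes adds at most max(b)*max(f) <= 1*1
        assert out.image.data[bg].max() <= pair.image.data[bg].max() + cfg.stamp_repeats

    def test_perlin_deterministic_and_foreground_safe(self, rng_np):
        pair = make_pair(rng_np)
        a = perlin_texture(pair, RandomStream(5), AugmentConfig())
        b = perlin_texture(pair, RandomStream(5), AugmentConfig())
        np.testing.assert_array_equal(a.image.data, b.image.data)
        fg = pair.label.data != 0
        np.testing.assert_array_equal(a.image.data[fg], pair.image.data[fg])
        np.testing.assert_array_equal(a.label.data, pair.label.data)

    def test_perlin_spatially_correlated(self):
        field = perlin_field((24, 24, 24), RandomStream(2), res=4)
        white = np.random.default_rng(2).random((24, 24, 24))

        def lag1_corr(f):
            a = f[:-1].ravel() - f.mean()
            b = f[1:].ravel() - f.mean()
            return (a * b).mean() / f.var()

        assert lag1_corr(field) > lag1_corr(white) + 0.3


class TestAugmentOnce:
    def test_output_range_and_label_closure(self, template24):
        out = augment_once(template24, RandomStream(0))
        assert out.image.data.min() >= 0.0
        assert out.image.data.max() == 1.0
        assert set(np.unique(out.label.data)) <= set(range(6))

    def test_seed_determinism(self, template24):
        a = augment_once(template24, RandomStream(42))
        b = augment_once(template24, RandomStream(42))
        c = augment_once(template24, RandomStream(43))
        np.testing.assert_array_equal(a.image.data, b.image.data)
        np.testing.assert_array_equal(a.label.data, b.label.data)
        assert not np.array_equal(a.image.data, c.image.data)

    def test_identity_limit(self, template24):
        out = augment_once(template24, RandomStream(17), identity_config())
        assert np.abs(out.image.data - template24.image.data).max() < 1e-4
        np.testing.assert_array_equal(out.label.data, template24.label.data)

    def test_photometric_steps_never_touch_label(self, template24, rng_np):
        cfg = AugmentConfig()
        lab_before = template24.label.data.copy()
        img = template24.image.data
        subsample_blur(img, RandomStream(1), cfg)
        add_uniform_noise(img, RandomStream(1), cfg)
        apply_lighting(img, RandomStream(1), cfg)
        stamped = stamp_texture(template24, RandomStream(1), cfg)
        perlined = perlin_texture(template24, RandomStream(1), cfg)
        np.testing.assert_array_equal(template24.label.data, lab_before)
        np.testing.assert_array_equal(stamped.label.data, lab_before)
        np.testing.assert_array_equal(perlined.label.data, lab_before)

    def test_gate_rates_within_binomial_interval(self, rng_np):
        # gates are content-independent, so a tiny pair keeps this cheap
        pair = make_pair(rng_np, (8, 8, 8))
        cfg = AugmentConfig(crop_enabled=True)
        n = 2000
        counts: dict[str, int] = {}
        rng = RandomStream(123)
        for i in range(n):
            trace: dict = {}
            augment_once(pair, rng.child(i), cfg, trace=trace)
            for k, v in trace.items():
                if isinstance(v, (bool, np.bool_)):
                    counts[k] = counts.get(k, 0) + bool(v)
        lo = 0.5 * n - 2.576 * np.sqrt(n * 0.25)
        hi = 0.5 * n + 2.576 * np.sqrt(n * 0.25)
        gates = {"subsample_x", "subsample_y", "subsample_z", "noise", "crop",
                 "ambient", "diffuse", "specular", "stamp", "perlin"}
        assert gates <= set(counts)
        for k in gates:
            assert lo <= counts[k] <= hi, (k, counts[k])
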