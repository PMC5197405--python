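import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.special import erfc

from borderown import stimuli as st


def _uniform_scene(point_shape=(33, 33), c1=(0.2, 0.4, 0.6), c2=(0.6, 0.2, 0.2)):
    """Piecewise-constant scene split along the vertical midline."""
    h, w = point_shape
    img = np.empty((h, w, 3))
    img[:, : w // 2] = c1
    img[:, w // 2 + 1 :] = c2
    img[:, w // 2] = 0.5
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    disc = np.hypot(rr - h // 2, cc - w // 2) <= 8
    point = st.ScenePoint(
        center=(h // 2, w // 2),
        orientation_deg=90.0,
        object_side=(0.0, -1.0),
        radius_px=8.0,
        mask1=disc & (cc < w // 2),
        mask2=disc & (cc > w // 2),
    )
    return img, point


class TestRegionMeans:
    def test_piecewise_constant_scene_returns_region_colors(self):
        img, point = _uniform_scene()
        m1, m2 = st.region_means(img, point)
        assert np.allclose(m1, (0.2, 0.4, 0.6))
        assert np.allclose(m2, (0.6, 0.2, 0.2))

    def test_uniform_scene_both_sides_equal(self):
        img, point = _uniform_scene(c1=(0.3, 0.3, 0.3), c2=(0.3, 0.3, 0.3))
        m1, m2 = st.region_means(img, point)
        assert np.allclose(m1, m2)

    def test_textured_scene_matches_per_pixel_oracle(self, scene_fixture):
        fx = scene_fixture
        m1, m2 = st.region_means(fx.image, fx.point)
        for mean, mask in ((m1, fx.point.mask1), (m2, fx.point.mask2)):
            acc = np.zeros(3)
            n = 0
            for r in range(mask.shape[0]):
                for c in range(mask.shape[1]):
                    if mask[r, c]:
                        acc += fx.image[r, c]
                        n += 1
            assert np.allclose(mean, acc / n)

    def test_empty_mask_error_names_side(self):
        img, point = _uniform_scene()
        with pytest.raises(ValueError, match="side-1"):
            object.__setattr__(point, "mask1", np.zeros_like(point.mask1))
            st.region_means(img, point)


class TestInvertColors:
    def test_region_means_swap(self, scene_fixture):
        fx = scene_fixture
        m1, m2 = st.region_means(fx.image, fx.point)
        inv, _ = st.invert_colors(fx.image, fx.point)
        n1, n2 = st.region_means(inv, fx.point)
        assert np.allclose(n1, m2, atol=1e-12)
        assert np.allclose(n2, m1, atol=1e-12)

    def test_mean_color_is_fixed_point_and_arithmetic(self):
        img, point = _uniform_scene()
        m1, m2 = st.region_means(img, point)
        mid = (m1 + m2) / 2
        img2 = img.copy()
        img2[0, 0] = mid
        img2[0, 1] = (0.1, 0.1, 0.1)
        inv, _ = st.invert_colors(img2, point)
        assert np.allclose(inv[0, 0], mid)
        assert np.allclose(inv[0, 1], (0.7, 0.5, 0.7))

    def test_involution_where_no_clipping(self, scene_fixture):
        fx = scene_fixture
        inv, n1 = st.invert_colors(fx.image, fx.point)
        back, _ = st.invert_colors(inv, fx.point)
        if n1 == 0:
            assert np.allclose(back, fx.image, atol=1e-12)
        else:
            m1, m2 = st.region_means(fx.image, fx.point)
            raw = (m1 + m2) - fx.image
            ok = ((raw >= 0) & (raw <= 1)).all(axis=2)
            assert np.allclose(back[ok], fx.image[ok], atol=1e-9)

    def test_clipping_is_counted(self):
        img, point = _uniform_scene(c1=(0.9, 0.9, 0.9), c2=(0.8, 0.8, 0.8))
        img[0, 0] = 0.0  # T sends it to 1.7 -> clipped
        _, n_clipped = st.invert_colors(img, point)
        assert n_clipped >= 1


class TestRotate180:
    def test_center_pixel_fixed_and_involution(self, scene_fixture):
        fx = scene_fixture
        bg = st.background_color(fx.image, fx.point)
        rot = st.rotate_180(fx.image, fx.point, bg)
        r0, c0 = fx.point.center
        assert np.allclose(rot[r0, c0], fx.image[r0, c0])
        back = st.rotate_180(rot, fx.point, bg)
        # involution on the mutually covered region (square image, interior)
        assert np.allclose(back, fx.image)

    def test_3x3_grid_index_oracle(self):
        img = np.arange(27, dtype=float).reshape(3, 3, 3) / 27.0
        point = st.ScenePoint(
            center=(1, 1),
            orientation_deg=0.0,
            object_side=(-1.0, 0.0),
            radius_px=1.5,
            mask1=np.array([[1, 1, 1], [0, 0, 0], [0, 0, 0]], bool),
            mask2=np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1]], bool),
        )
        rot = st.rotate_180(img, point, background=np.zeros(3))
        for r in range(3):
            for c in range(3):
                assert np.allclose(rot[r, c], img[2 - r, 2 - c])

    def test_uncovered_area_filled_with_background(self):
        img, point = _uniform_scene()
        off_point = st.ScenePoint(
            center=(2, 2),
            orientation_deg=point.orientation_deg,
            object_side=point.object_side,
            radius_px=2.0,
            mask1=np.pad(np.ones((1, 2), bool), ((2, 30), (0, 31))),
            mask2=np.pad(np.ones((1, 2), bool), ((2, 30), (3, 28))),
        )
        bg = np.array([0.1, 0.2, 0.3])
        rot = st.rotate_180(img, off_point, background=bg)
        assert np.allclose(rot[10:, :], bg)  # beyond the rotated footprint


class TestPatchAlpha:
    def test_continuity_and_reference_value(self):
        assert st.patch_alpha(10.0, 10.0, 1.8) == pytest.approx(1.0)
        assert st.patch_alpha(11.0, 10.0, 1.8) == pytest.approx(
            float(erfc(1.8)), rel=1e-12
        )
        assert float(erfc(1.8)) == pytest.approx(0.01091, abs=5e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            st.patch_alpha(1.0, -1.0, 1.8)
        with pytest.raises(ValueError):
            st.patch_alpha(1.0, 1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        d=st_.floats(0, 50),
        d2=st_.floats(0, 50),
        r=st_.floats(0.5, 20),
        k=st_.floats(0.1, 5),
    )
    def test_monotone_nonincreasing(self, d, d2, r, k):
        lo, hi = sorted([d, d2])
        assert st.patch_alpha(lo, r, k) >= st.patch_alpha(hi, r, k)


class TestMakePatch:
    def test_identity_inside_r_background_far(self, scene_fixture):
        fx = scene_fixture
        bg = st.background_color(fx.image, fx.point)
        patch = st.make_patch(fx.image, fx.point)
        d = st._distance_grid(fx.image.shape[:2], fx.point.center)
        assert np.allclose(patch[d < fx.point.radius_px], fx.image[d < fx.point.radius_px])
        assert np.allclose(patch[d > fx.point.radius_px + 5], bg, atol=1e-9)

    def test_matches_per_pixel_loop_oracle(self, scene_fixture):
        fx = scene_fixture
        bg = st.background_color(fx.image, fx.point)
        patch = st.make_patch(fx.image, fx.point, k=1.8)
        r0, c0 = fx.point.center
        rr = fx.point.radius_px
        for r in range(0, fx.image.shape[0], 7):
            for c in range(0, fx.image.shape[1], 7):
                d = np.hypot(r - r0, c - c0)
                a = 1.0 if d < rr else erfc(1.8 * (d - rr))
                assert np.allclose(patch[r, c], a * fx.image[r, c] + (1 - a) * bg)


class TestBackgroundColor:
    def test_midpoint(self):
        img, point = _uniform_scene()
        assert np.allclose(
            st.background_color(img, point), (0.4, 0.3, 0.4)
        )


class TestVariantSet:
    def test_eight_distinct_condition_keys(self, scene_fixture):
        fx = scene_fixture
        vs = st.build_variant_set(fx.image, fx.point, scene_id=fx.scene_id)
        assert len(vs) == 8
        keys = {(v.key.side, v.key.polarity, v.key.extent) for v in vs}
        assert len(keys) == 8

    def test_full_patch_identity_inside_radius(self, scene_fixture):
        fx = scene_fixture
        vs = st.build_variant_set(fx.image, fx.point, scene_id=fx.scene_id)
        d = st._distance_grid(fx.image.shape[:2], fx.point.center)
        inside = d < fx.point.radius_px
        for side, pol in itertools.product(st.SIDES, st.POLARITIES):
            pair = {
                v.key.extent: v
                for v in vs
                if v.key.side == side and v.key.polarity == pol
            }
            assert np.allclose(
                pair["full"].image[inside], pair["patch"].image[inside]
            )

    def test_double_rotation_restores_original_content(self, scene_fixture):
        fx = scene_fixture
        vs = st.build_variant_set(fx.image, fx.point, scene_id=fx.scene_id)
        rot = next(
            v
            for v in vs
            if v.key == st.ConditionKey("rotated", "original", "full", fx.scene_id)
        )
        back = st.rotate_180(rot.image, fx.point, rot.background)
        orig = next(
            v
            for v in vs
            if v.key == st.ConditionKey("original", "original", "full", fx.scene_id)
        )
        assert np.allclose(back, orig.image)

    def test_shared_background(self, scene_fixture):
        fx = scene_fixture
        vs = st.build_variant_set(fx.image, fx.point, scene_id=fx.scene_id)
        bgs = np.array([v.background for v in vs])
        assert np.allclose(bgs, bgs[0])


class TestSquareTest:
    def test_eight_displays_and_pixel_counts(self):
        spec = st.SquareStimulusSpec(orientation_deg=90.0, pitch=0.1, shape=(201, 201))
        vs = st.build_square_test_set(spec)
        assert len(vs) == 8
        v3 = next(v for v in vs if v.key.scene_id == "square3" and v.key.side == "original"
                  and v.key.polarity == "original")
        inside = np.all(v3.image == spec.preferred, axis=2)
        # 3 deg at 0.1 deg/px -> 30 px on a side (within rasterization slack)
        assert abs(np.sqrt(inside.sum()) - 30) <= 1.5

    @pytest.mark.parametrize("orientation", [0.0, 90.0, 45.0])
    def test_paired_displays_identical_within_swept_band(self, orientation):
        spec = st.SquareStimulusSpec(
            orientation_deg=orientation, pitch=0.1, shape=(201, 201)
        )
        vs = st.build_square_test_set(spec)
        theta = np.deg2rad(orientation)
        n_vec = np.array([-np.cos(theta), -np.sin(theta)])
        t_vec = np.array([-np.sin(theta), np.cos(theta)])
        rr, cc = np.meshgrid(np.arange(201), np.arange(201), indexing="ij")
        d_n = (rr - 100) * n_vec[0] + (cc - 100) * n_vec[1]
        d_t = (rr - 100) * t_vec[0] + (cc - 100) * t_vec[1]
        for size in (3.0, 8.0):
            w = size / spec.pitch
            band = (np.abs(d_n) <= w - 1) & (np.abs(d_t) <= w / 2 - 1)
            a = next(v for v in vs if v.key.scene_id == f"square{size:g}"
                     and v.key.side == "original" and v.key.polarity == "original")
            b = next(v for v in vs if v.key.scene_id == f"square{size:g}"
                     and v.key.side == "rotated" and v.key.polarity == "inverted")
            assert np.allclose(a.image[band], b.image[band])


class TestGamma:
    def test_reference_values_and_roundtrip(self):
        assert st.gamma_encode(0.0) == 0.0
        assert st.gamma_encode(1.0) == 1.0
        assert st.gamma_encode(0.5) == pytest.approx(0.5**2.2)
        assert float(st.gamma_encode(0.5)) == pytest.approx(0.2176, abs=5e-5)
        x = np.linspace(0, 1, 11)
        assert np.allclose(st.gamma_decode(st.gamma_encode(x)), x, atol=1e-9)
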