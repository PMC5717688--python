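"""Sphere geometry, shading maps, motion conditions and animation."""

import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate

from specularcue.design import TrialSpec
from specularcue.scene import (
    DYNAMIC_DURATION_S,
    ROTATION_SPEED_DEG_S,
    SPECULARITY_LEVELS,
    SceneConfig,
    SceneState,
    ShadingMaps,
    SurfaceMaterial,
    TurbulenceField,
    animate_trial,
    apply_motion,
    marble_texture,
    max_image_speed_va,
    max_image_speed_pa,
    recompose_pixel_spectrum,
    render_chromaticity_image,
    render_shading_maps,
    sphere_geometry,
)
from specularcue.spectra import chromaticity_of, cone_excitations


@pytest.fixture()
def material(gray_reflectance):
    return SurfaceMaterial(gray_reflectance, specularity=0.1)


def fib_sphere(n, seed=0):
    """Roughly uniform unit-sphere sample points."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestGeometry:
    def test_exactly_three_lights_required(self):
        with pytest.raises(ValueError, match="three"):
            SceneConfig(light_directions=((0, 0, 1.0), (0, 1.0, 0)))

    def test_center_pixel_normal_equals_view(self, small_config, material):
        n, _, mask = sphere_geometry(small_config, material, SceneState())
        c = small_config.image_size // 2
        assert mask[c, c]
        np.testing.assert_allclose(n[c, c], [0, 0, 1], atol=0.03)

    def test_zero_amplitude_bump_is_smooth_sphere(self, small_config, gray_reflectance):
        smooth = SurfaceMaterial(gray_reflectance, specularity=0.1)
        flatb = SurfaceMaterial(gray_reflectance, specularity=0.1,
                                bump=TurbulenceField(seed=1, amplitude=0.0))
        n0, p0, m0 = sphere_geometry(small_config, smooth, SceneState())
        n1, p1, m1 = sphere_geometry(small_config, flatb, SceneState())
        np.testing.assert_array_equal(n0, n1)
        np.testing.assert_array_equal(m0, m1)

    def test_bumpy_normals_match_finite_difference_oracle(self, gray_reflectance):
        """Analytic displaced-sphere normals vs the numerical gradient of
        the displaced surface-position map."""
        cfg = SceneConfig(image_size=200)
        bump = TurbulenceField(seed=4, amplitude=0.05, base_freq=6.0)
        mat = SurfaceMaterial(gray_reflectance, specularity=0.1, bump=bump)
        n, pts, mask = sphere_geometry(cfg, mat, SceneState())
        dx = np.gradient(pts, axis=1)
        dy = np.gradient(pts, axis=0)
        nf = np.cross(dy, dx)
        nf /= np.linalg.norm(nf, axis=-1, keepdims=True) + 1e-30
        coords = (np.arange(cfg.image_size) + 0.5) / cfg.image_size * 2 - 1
        px, py = np.meshgrid(coords, coords)
        inner = mask & (np.hypot(px, py) < 0.9)  # rim excluded: FD degrades there
        dots = np.abs(np.einsum("...i,...i->...", n, nf)[inner])
        assert np.median(dots) > 0.999
        assert np.mean(dots > 0.99) > 0.98


class TestMarbleTexture:
    def test_zero_amplitude_constant_one(self):
        pts = fib_sphere(500)
        out = marble_texture(pts, TurbulenceField(seed=0, amplitude=0.0))
        np.testing.assert_array_equal(out, np.ones(500))

    def test_deterministic_given_seed(self):
        pts = fib_sphere(200, seed=3)
        a = marble_texture(pts, TurbulenceField(seed=9))
        b = marble_texture(pts, TurbulenceField(seed=9))
        np.testing.assert_array_equal(a, b)

    def test_bounded_and_variable(self):
        pts = fib_sphere(4000, seed=5)
        out = marble_texture(pts, TurbulenceField(seed=2))
        assert out.min() >= 0.3 - 1e-12 and out.max() <= 1.0 + 1e-12
        cv = out.std() / out.mean()
        assert 0.05 < cv < 0.6  # Monte-Carlo band for the default pattern


class TestShading:
    def test_matte_surface_has_zero_specular_map(self, small_config, gray_reflectance):
        mat = SurfaceMaterial(gray_reflectance, specularity=0.0)
        maps = render_shading_maps(small_config, mat, SceneState())
        assert maps.a.sum() == 0.0

    def test_off_mask_coefficients_zero(self, small_config, material):
        maps = render_shading_maps(small_config, material, SceneState())
        assert np.all(maps.a[~maps.mask] == 0) and np.all(maps.b[~maps.mask] == 0)

    def test_light_along_view_peaks_specular_at_center(self, gray_reflectance):
        cfg = SceneConfig(image_size=97,
                          light_directions=((0, 0, 1.0), (0, 0, 1.0), (0, 0, 1.0)))
        mat = SurfaceMaterial(gray_reflectance, specularity=0.1)
        maps = render_shading_maps(cfg, mat, SceneState())
        peak = np.unravel_index(np.argmax(maps.a), maps.a.shape)
        assert peak == (48, 48)

    def test_specular_map_linear_in_specularity(self, small_config, gray_reflectance):
        lo = render_shading_maps(
            small_config, SurfaceMaterial(gray_reflectance, specularity=0.05),
            SceneState())
        hi = render_shading_maps(
            small_config, SurfaceMaterial(gray_reflectance, specularity=0.1),
            SceneState())
        assert hi.a.sum() == pytest.approx(2 * lo.a.sum(), rel=1e-12)


class TestChromaticityRendering:
    def test_matte_untextured_sphere_is_chromatically_uniform(
            self, small_config, illuminant_pair, gray_reflectance):
        I, _ = illuminant_pair
        mat = SurfaceMaterial(gray_reflectance, specularity=0.0)
        maps = render_shading_maps(small_config, mat, SceneState())
        img = render_chromaticity_image(maps, I, gray_reflectance)
        assert np.ptp(img.l_mb[img.mask]) < 1e-12
        assert np.ptp(img.s_mb[img.mask]) < 1e-12

    def test_pure_specular_pixel_is_illuminant_chromaticity(
            self, illuminant_pair, gray_reflectance):
        I, _ = illuminant_pair
        maps = ShadingMaps(a=np.array([[1.0]]), b=np.array([[0.0]]),
                           mask=np.array([[True]]))
        img = render_chromaticity_image(maps, I, gray_reflectance)
        ill = chromaticity_of(I)
        assert img.l_mb[0, 0] == pytest.approx(ill.l_mb, abs=1e-12)
        assert img.s_mb[0, 0] == pytest.approx(ill.s_mb, abs=1e-12)

    def test_all_zero_pixel_flagged_not_nan_poisoned(self, illuminant_pair,
                                                     gray_reflectance):
        I, _ = illuminant_pair
        maps = ShadingMaps(a=np.zeros((2, 2)), b=np.zeros((2, 2)),
                           mask=np.ones((2, 2), bool))
        img = render_chromaticity_image(maps, I, gray_reflectance)
        assert not img.mask.any()
        assert np.all(img.lum == 0)

    def test_brightest_pixel_moves_toward_illuminant_with_specularity(
            self, small_config, illuminant_pair, library):
        """Render sweep over the five levels: the brightest pixel's
        chromaticity approaches the illuminant monotonically."""
        I, _ = illuminant_pair
        R = library[2]
        ill = chromaticity_of(I)
        dists = []
        for s in SPECULARITY_LEVELS:
            mat = SurfaceMaterial(R, specularity=s)
            maps = render_shading_maps(small_config, mat, SceneState())
            img = render_chromaticity_image(maps, I, R)
            k = np.nanargmax(np.where(img.mask, img.lum, -np.inf))
            i, j = np.unravel_index(k, img.lum.shape)
            dists.append(np.hypot(img.l_mb[i, j] - ill.l_mb,
                                  img.s_mb[i, j] - ill.s_mb))
        assert all(d1 > d2 - 1e-12 for d1, d2 in zip(dists, dists[1:]))
        assert dists[-1] < 0.8 * dists[0]

    def test_energy_additivity_against_per_pixel_recomposition(
            self, small_config, illuminant_pair, library):
        """The fast LMS path equals integrating the recomposed per-pixel
        spectrum a*I + b*I*R, pixel by pixel."""
        I, _ = illuminant_pair
        R = library[1]
        tex = TurbulenceField(seed=6)
        mat = SurfaceMaterial(R, specularity=0.1, texture=tex)
        maps = render_shading_maps(small_config, mat, SceneState())
        img = render_chromaticity_image(maps, I, R)
        rng = np.random.default_rng(0)
        on = np.argwhere(img.mask)
        for i, j in on[rng.choice(len(on), 12, replace=False)]:
            lms = cone_excitations(recompose_pixel_spectrum(maps, I, R, i, j))
            c = chromaticity_of(recompose_pixel_spectrum(maps, I, R, i, j))
            assert c.l_mb == pytest.approx(img.l_mb[i, j], abs=1e-12)
            assert c.s_mb == pytest.approx(img.s_mb[i, j], abs=1e-12)
            assert lms.L + lms.M == pytest.approx(img.lum[i, j], abs=1e-12)


class TestMotion:
    def test_no_motion_is_identity(self):
        st = SceneState()
        assert apply_motion(st, "NoMotion", 30.0) is st

    def test_image_rotation_inverts(self, small_config, material):
        st = apply_motion(SceneState(), "ImageVA", 30.0)
        st = apply_motion(st, "ImageVA", -30.0)
        m0 = render_shading_maps(small_config, material, SceneState())
        m1 = render_shading_maps(small_config, material, st)
        np.testing.assert_allclose(m0.a, m1.a, atol=1e-12)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown motion"):
            apply_motion(SceneState(), "Sideways", 10.0)

    def test_angle_beyond_thirty_degrees_rejected(self):
        with pytest.raises(ValueError):
            apply_motion(SceneState(), "ObjectVA", 45.0)

    def test_object_rotation_leaves_marbled_specular_map_fixed(
            self, small_config, gray_reflectance):
        """Object rotation moves the surface pattern but, for a radially
        symmetric sphere, cannot move the highlights."""
        tex = TurbulenceField(seed=3)
        mat = SurfaceMaterial(gray_reflectance, specularity=0.1, texture=tex)
        m0 = render_shading_maps(small_config, mat, SceneState())
        for cond in ("ObjectVA", "ObjectPA"):
            m1 = render_shading_maps(small_config, mat,
                                     apply_motion(SceneState(), cond, 30.0))
            np.testing.assert_array_equal(m0.a, m1.a)
            corr = np.corrcoef(m0.b[m0.mask], m1.b[m0.mask])[0, 1]
            assert corr < 0.999  # texture moved

    def test_lights_rotation_moves_specular_map_not_texture(
            self, small_config, gray_reflectance):
        tex = TurbulenceField(seed=3)
        mat = SurfaceMaterial(gray_reflectance, specularity=0.1, texture=tex)
        m0 = render_shading_maps(small_config, mat, SceneState())
        for cond in ("LightsVA", "LightsPA"):
            m1 = render_shading_maps(small_config, mat,
                                     apply_motion(SceneState(), cond, 30.0))
            a_corr = np.corrcoef(m0.a[m0.mask], m1.a[m0.mask])[0, 1]
            assert a_corr < 0.9  # highlights moved
            # the diffuse texture factor is unchanged: b ratio field equal
            tex0 = marble_texture(sphere_geometry(small_config, mat,
                                                  SceneState())[1], tex)
            tex1 = marble_texture(sphere_geometry(
                small_config, mat, apply_motion(SceneState(), cond, 30.0))[1], tex)
            np.testing.assert_array_equal(tex0, tex1)

    def test_image_rotation_is_rigid(self, small_config, gray_reflectance):
        """Rendering a rotated image state equals rotating the rendered
        composite (scipy rotates array axes in the opposite angular
        convention, hence the sign flip)."""
        tex = TurbulenceField(seed=3)
        mat = SurfaceMaterial(gray_reflectance, specularity=0.1, texture=tex)
        m0 = render_shading_maps(small_config, mat, SceneState())
        m1 = render_shading_maps(small_config, mat,
                                 apply_motion(SceneState(), "ImageVA", 30.0))
        rotated = nd_rotate(m0.a, -30.0, reshape=False, order=1)
        ok = m0.mask & m1.mask & (rotated > 0)
        corr = np.corrcoef(m1.a[ok], rotated[ok])[0, 1]
        assert corr > 0.999


class TestAnimation:
    def _trial(self, illuminant_pair, gray_reflectance, condition="NoMotion"):
        I1, I2 = illuminant_pair
        return TrialSpec("illuminant", I1, I2, gray_reflectance,
                         gray_reflectance, motion_condition=condition)

    def test_no_motion_first_last_geometry_identical(self, illuminant_pair,
                                                     gray_reflectance):
        cfg = SceneConfig(image_size=32)
        trial = self._trial(illuminant_pair, gray_reflectance)
        frames, first, last = animate_trial(trial, cfg)
        assert first.state == last.state
        assert not np.allclose(first.I.values, last.I.values)

    def test_frame_count_and_timing(self, illuminant_pair, gray_reflectance):
        cfg = SceneConfig(image_size=32)
        frames, first, last = animate_trial(
            self._trial(illuminant_pair, gray_reflectance, "ObjectVA"), cfg)
        # 0.5 s static + 1/3 s dynamic + 0.5 s static at 60 Hz
        assert len(frames) == 30 + 20 + 30
        assert last.time_s == pytest.approx((len(frames) - 1) / 60.0)

    def test_total_rotation_is_thirty_degrees(self, illuminant_pair,
                                              gray_reflectance):
        assert ROTATION_SPEED_DEG_S * DYNAMIC_DURATION_S == pytest.approx(30.0)
        cfg = SceneConfig(image_size=32)
        frames, first, last = animate_trial(
            self._trial(illuminant_pair, gray_reflectance, "ImageVA"), cfg)
        assert last.state.image_angle_deg == pytest.approx(30.0)

    def test_inconsistent_kinematics_rejected(self, illuminant_pair,
                                              gray_reflectance):
        cfg = SceneConfig(image_size=32)
        with pytest.raises(ValueError, match="inconsistent"):
            animate_trial(self._trial(illuminant_pair, gray_reflectance),
                          cfg, dynamic_s=1.0)  # 90 deg total: off-design

    def test_edge_speed_for_visual_axis_rotation(self):
        cfg = SceneConfig()
        assert max_image_speed_va(cfg) == pytest.approx(5.58, abs=0.05)
        assert max_image_speed_pa(cfg) > 0
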