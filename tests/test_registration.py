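"""Registration chain: similarity metric, stage recovery, field resolution,
demons, inversion round trips, and dCT stitching."""

import numpy as np
import pytest
import SimpleITK as sitk
from scipy.ndimage import distance_transform_edt

import ddalab as dl
from ddalab.core import ImageGrid, VectorField, warp_image
from ddalab.registration import (RegistrationConfig, TransformChain, chain_mi,
                                 demons_register, entropy, mutual_information,
                                 register_bspline, register_linear, resolve_dvf,
                                 stitch_dct)
from conftest import landmark_errors


def textured_box(shape=(40, 40, 30), spacing=2.5, seed=0):
    """Smoothly textured test volume with an embedded bright ellipsoid."""
    rng = np.random.default_rng(seed)
    g = ImageGrid(np.zeros(shape), spacing * np.ones(3),
                  -(np.array(shape) - 1) / 2.0 * spacing)
    p = g.voxel_centers()
    data = 30 * np.sin(p[..., 0] / 11.0) + 25 * np.cos(p[..., 1] / 9.0 + 1.0) \
        + 20 * np.sin(p[..., 2] / 13.0 + 2.0)
    ell = ((p / np.array([20.0, 16.0, 14.0])) ** 2).sum(-1) <= 1
    data[ell] += 80
    return g.like(data)


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self):
        img = textured_box()
        assert mutual_information(img, img, 32) == pytest.approx(entropy(img, 32), abs=1e-9)

    def test_shuffled_image_is_nearly_independent(self):
        img = textured_box()
        rng = np.random.default_rng(4)
        shuffled = img.like(rng.permutation(img.data.ravel()).reshape(img.shape))
        assert img.data.size >= 10_000
        assert mutual_information(img, shuffled, 32) < 0.05 * entropy(img, 32)

    def test_invariant_to_additive_shift(self):
        img = textured_box()
        shifted = img.like(img.data + 137.0)
        assert mutual_information(img, shifted, 32) == pytest.approx(
            mutual_information(img, img, 32), abs=1e-9)

    def test_constant_image_defined_as_zero(self):
        img = textured_box()
        const = img.like(np.zeros(img.shape))
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(img, const, 32) == 0.0


class TestResolveDvf:
    def test_identity_chain_resolves_to_zero(self):
        g = textured_box((10, 10, 10))
        f = resolve_dvf(TransformChain(), g)
        np.testing.assert_allclose(f.data, 0.0, atol=1e-9)

    def test_pure_translation_resolves_to_constant(self):
        g = textured_box((10, 10, 10))
        tx = sitk.TranslationTransform(3)
        tx.SetOffset((4.0, -1.5, 2.0))
        f = resolve_dvf(TransformChain(translation=tx), g)
        np.testing.assert_allclose(f.data, np.broadcast_to([4.0, -1.5, 2.0],
                                                           g.shape + (3,)), atol=1e-9)

    def test_affine_field_matches_matrix_evaluation(self):
        g = textured_box((12, 12, 12))
        a = np.eye(3) + 0.02 * np.random.default_rng(0).normal(size=(3, 3))
        t = np.array([1.0, -2.0, 0.5])
        tx = sitk.AffineTransform(3)
        tx.SetMatrix(a.ravel())
        tx.SetTranslation(t)
        f = resolve_dvf(TransformChain(affine=tx), g)
        rng = np.random.default_rng(1)
        for _ in range(10):
            ijk = tuple(rng.integers(0, s) for s in g.shape)
            x = g.origin + np.array(ijk) * g.spacing
            np.testing.assert_allclose(f.data[ijk], a @ x + t - x, atol=1e-6)


class TestLinearStages:
    def test_identity_problem_recovers_identity(self):
        img = textured_box()
        cfg = RegistrationConfig(intensity_window_hu=None)
        ch = register_linear(img, img, "translation", None, cfg)
        assert np.abs(ch.translation_mm).max() < 0.1
        ch = register_linear(img, img, "euler", None, cfg)
        assert np.abs(ch.euler_angles_rad).max() < np.deg2rad(0.1)

    def test_translation_recovered_within_half_mm(self):
        moving = textured_box()
        tx = sitk.TranslationTransform(3)
        tx.SetOffset((5.0, -3.0, 2.0))
        fixed = ImageGrid.from_sitk(sitk.Resample(moving.to_sitk(), moving.to_sitk(), tx,
                                                  sitk.sitkLinear, 0.0))
        cfg = RegistrationConfig(intensity_window_hu=None)
        ch = register_linear(fixed, moving, "translation", None, cfg)
        np.testing.assert_allclose(ch.translation_mm, [5.0, -3.0, 2.0], atol=0.5)

    def test_rotation_recovered_within_tolerance(self):
        moving = textured_box()
        center = tuple(moving.origin + (np.array(moving.shape) - 1) / 2 * moving.spacing)
        tx = sitk.Euler3DTransform()
        tx.SetCenter(center)
        tx.SetRotation(0.0, 0.0, np.deg2rad(3.0))
        fixed = ImageGrid.from_sitk(sitk.Resample(moving.to_sitk(), moving.to_sitk(), tx,
                                                  sitk.sitkLinear, 0.0))
        cfg = RegistrationConfig(intensity_window_hu=None)
        ch = register_linear(fixed, moving, "euler", None, cfg)
        assert abs(ch.euler_angles_rad[2] - np.deg2rad(3.0)) < np.deg2rad(0.3)

    def test_stage_results_are_deterministic(self, spec, anatomy, noiseless_day):
        pct, _ = anatomy
        fixed = noiseless_day.images["iterative_like"]
        cfg = RegistrationConfig()
        a = register_linear(fixed, pct, "translation", None, cfg, noiseless_day.fov_mask)
        b = register_linear(fixed, pct, "translation", None, cfg, noiseless_day.fov_mask)
        np.testing.assert_array_equal(a.translation_mm, b.translation_mm)


class TestBsplineChain:
    def test_near_identity_stays_near_identity(self, spec, anatomy):
        pct, _ = anatomy
        f = dl.sample_daily_dvf(spec, 1, magnitude_mm=0.0)
        img, fov, _ = dl.phantom.render_daily_image(
            spec, f, dl.ReconStyle("iterative_like", 0.0), seed=0)
        cfg = RegistrationConfig()
        ch = register_bspline(img, pct, None, cfg, fov)
        dvf = resolve_dvf(TransformChain(bspline=ch.bspline), img)
        assert dvf.max_magnitude() < 0.5

    def test_ground_truth_recovered_below_one_voxel(self, noiseless_day, registered_noiseless):
        err = landmark_errors(noiseless_day, registered_noiseless["dvf"])
        assert err.mean() < 2.5   # one voxel

    def test_mi_non_decreasing_along_chain(self, anatomy, noiseless_day, registered_noiseless):
        pct, _ = anatomy
        cfg = registered_noiseless["cfg"]
        fixed = cfg.windowed(registered_noiseless["fixed"])
        moving = cfg.windowed(pct)
        full = registered_noiseless["chain"]
        tol = 0.02
        prev = None
        sub = TransformChain()
        for stage in ("translation", "euler", "affine", "bspline"):
            setattr(sub, stage, getattr(full, stage))
            mi = chain_mi(fixed, moving, sub, noiseless_day.fov_mask, cfg)
            if prev is not None:
                assert mi >= prev - tol
            prev = mi


class TestDemons:
    def test_identical_images_give_null_field(self):
        img = textured_box()
        f = demons_register(img, img, iterations=20, intensity_window_hu=None)
        assert f.max_magnitude() < 0.1

    def test_small_translation_recovered_inside_object(self):
        moving = textured_box()
        shift = np.array([0.0, 5.0, 0.0])       # two voxels
        tx = sitk.TranslationTransform(3)
        tx.SetOffset(tuple(shift))
        fixed = ImageGrid.from_sitk(sitk.Resample(moving.to_sitk(), moving.to_sitk(), tx,
                                                  sitk.sitkLinear, 0.0))
        f = demons_register(fixed, moving, iterations=80, smoothing_sigma=1.0,
                            intensity_window_hu=None)
        p = fixed.voxel_centers()
        obj = ((p / np.array([16.0, 12.0, 10.0])) ** 2).sum(-1) <= 1   # interior probe
        med = np.median(f.data[obj], axis=0)
        assert np.linalg.norm(med - shift) < 1.25   # half a voxel

    def test_strong_smoothing_flattens_the_field(self):
        moving = textured_box()
        tx = sitk.TranslationTransform(3)
        tx.SetOffset((3.0, 0.0, 0.0))
        fixed = ImageGrid.from_sitk(sitk.Resample(moving.to_sitk(), moving.to_sitk(), tx,
                                                  sitk.sitkLinear, 0.0))
        rough = demons_register(fixed, moving, iterations=30, smoothing_sigma=1.0,
                                intensity_window_hu=None)
        smooth = demons_register(fixed, moving, iterations=30, smoothing_sigma=8.0,
                                 intensity_window_hu=None)
        spread = lambda f: np.linalg.norm(f.data - f.data.mean(axis=(0, 1, 2)), axis=-1).max()
        assert spread(smooth) < 0.5 * spread(rough)


class TestStitch:
    def grid(self):
        g = textured_box((20, 20, 16))
        region = np.zeros(g.shape, bool)
        region[5:15, 5:15, 4:12] = True
        return g, region

    def test_identical_patch_reproduces_pct(self):
        pct, region = self.grid()
        out = stitch_dct(pct, pct.copy(), region, feather_mm=0.0)
        np.testing.assert_allclose(out.data, pct.data, atol=1e-12)

    def test_hard_stitch_is_exact_switch(self):
        pct, region = self.grid()
        patch = pct.like(pct.data + 100.0)
        out = stitch_dct(pct, patch, region, feather_mm=0.0)
        np.testing.assert_allclose(out.data[region], pct.data[region] + 100.0)
        np.testing.assert_allclose(out.data[~region], pct.data[~region])

    def test_feather_band_blends_monotonically_with_depth(self):
        pct, region = self.grid()
        patch = pct.like(pct.data + 100.0)
        out = stitch_dct(pct, patch, region, feather_mm=6.0)
        depth = distance_transform_edt(region, sampling=pct.spacing)
        band = region & (depth < 6.0) & (depth > 0)
        lift = out.data - pct.data
        assert (lift[band] > 0).all() and (lift[band] < 100).all()
        # deeper voxels lift at least as much (monotone in distance)
        d, l = depth[band], lift[band]
        order = np.argsort(d)
        assert (np.diff(l[order][np.searchsorted(d[order], np.unique(d[order]))]) >= -1e-9).all()

    def test_empty_region_warns_and_returns_pct(self):
        pct, _ = self.grid()
        with pytest.warns(UserWarning, match="empty"):
            out = stitch_dct(pct, pct.like(pct.data + 1), np.zeros(pct.shape, bool))
        np.testing.assert_allclose(out.data, pct.data)


class TestRoundTrip:
    def test_warp_then_inverse_warp_restores_image(self, spec, anatomy):
        pct, _ = anatomy
        f = dl.sample_daily_dvf(spec, 3)
        from ddalab.core import invert_dvf
        warped, ok1 = warp_image(pct, f, "linear")
        inv, reliable = invert_dvf(f, tol_mm=0.001)
        back, ok2 = warp_image(warped, inv, "linear")
        off = np.round((back.origin - pct.origin) / pct.spacing).astype(int)
        sl = tuple(slice(o, o + n) for o, n in zip(off, back.shape))
        good = ok2 & reliable & ok1
        # interpolation smoothing at the sharp air/bone edges dominates; the
        # mean must stay below the noisier variant's noise floor (40 HU)
        err = np.abs(back.data - pct.data[sl])[good]
        assert err.mean() < 40.0
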