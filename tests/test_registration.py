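"""Rigid transforms, warping and pairwise registration accuracy."""

import numpy as np
import pytest
from scipy import ndimage

from cnvquant.errors import DegenerateImageError, RegistrationFailure
from cnvquant.io_formats import ImageFrame
from cnvquant.registration import (
    RigidTransform,
    masked_ncc,
    overlay_composite,
    register_pair,
    warp,
)
from cnvquant.synthetic import (
    OCTA_NOISE,
    SimulationConfig,
    grow_tree,
    rasterize,
    render_modality,
)

SHAPE = (256, 256)


def scene(seed, weeks=2):
    cfg = SimulationConfig()
    return grow_tree(cfg, weeks, np.random.default_rng(seed)), cfg


class TestRigidTransform:
    @pytest.mark.parametrize("seed", range(5))
    def test_compose_then_inverse_is_identity_on_points(self, seed):
        rng = np.random.default_rng(seed)
        a = RigidTransform(*rng.uniform(-10, 10, 2), rng.uniform(-5, 5))
        b = RigidTransform(*rng.uniform(-10, 10, 2), rng.uniform(-5, 5))
        pts = rng.uniform(0, 255, (20, 2))
        via_compose = a.compose(b).apply(pts, SHAPE)
        sequential = a.apply(b.apply(pts, SHAPE), SHAPE)
        assert np.allclose(via_compose, sequential)
        back = a.inverse().apply(a.apply(pts, SHAPE), SHAPE)
        assert np.allclose(back, pts)

    def test_identity_has_zero_parameters(self):
        t = RigidTransform()
        assert t.is_identity
        pts = np.array([[3.0, 4.0], [100.0, 200.0]])
        assert np.allclose(t.apply(pts, SHAPE), pts)

    def test_serialization_round_trip(self):
        t = RigidTransform(1.5, -2.25, 3.125)
        assert RigidTransform.from_dict(t.to_dict()) == t


class TestWarp:
    def test_identity_transform_keeps_image_and_validity(self, rng):
        img = rng.random(SHAPE)
        out, valid = warp(img, RigidTransform())
        assert np.allclose(out, img)
        assert valid.all()

    def test_integer_shift_is_exact_on_valid_region(self, rng):
        img = rng.random(SHAPE)
        out, valid = warp(img, RigidTransform(dx=3.0, dy=0.0))
        assert np.allclose(out[:, 3:], img[:, :-3])
        assert valid[:, 3:].all() and not valid[:, :3].any()

    def test_warp_inverse_warp_round_trip(self, rng):
        # smooth image: interpolation error bounded on the doubly-valid region
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.random(SHAPE), 3.0)
        img = (img - img.min()) / np.ptp(img)
        t = RigidTransform(dx=5.3, dy=-2.7, rotation_deg=3.0)
        fwd, v1 = warp(img, t)
        back, v2 = warp(fwd, t.inverse())
        both = v2 & (warp(v1.astype(float), t.inverse(), order=0)[0] > 0.5)
        # stay clear of the validity boundary, where interpolation mixes
        # in the zeroed invalid pixels
        both = ndimage.binary_erosion(both, iterations=2)
        assert np.abs(back - img)[both].max() <= 0.02

    def test_boolean_mask_stays_boolean(self, rng):
        mask = rng.random(SHAPE) > 0.7
        out, _ = warp(mask, RigidTransform(dx=2.0, dy=1.0, rotation_deg=1.0), order=0)
        assert out.dtype == bool


class TestRegisterPair:
    def _render(self, mask, seed):
        return render_modality(mask, "OCTA", OCTA_NOISE, np.random.default_rng(seed))

    def test_self_registration_is_identity(self):
        tree, cfg = scene(0)
        img = self._render(rasterize(tree, cfg.canvas), 1)
        res = register_pair(img, img)
        assert abs(res.transform.dx) <= 0.5 and abs(res.transform.dy) <= 0.5
        assert abs(res.transform.rotation_deg) <= 0.25
        assert res.score >= 0.99

    def test_known_pure_shift_recovered(self):
        tree, cfg = scene(1)
        applied = RigidTransform(dx=7.0, dy=-4.0)
        fixed = self._render(rasterize(tree, cfg.canvas), 2)
        moving = self._render(rasterize(tree.transformed(applied), cfg.canvas), 3)
        res = register_pair(moving, fixed)
        # registration maps moving back onto fixed: the inverse of the pose
        expect = applied.inverse()
        assert abs(res.transform.dx - expect.dx) <= 0.5
        assert abs(res.transform.dy - expect.dy) <= 0.5

    def test_known_shift_and_rotation_recovered(self):
        tree, cfg = scene(2)
        applied = RigidTransform(dx=6.0, dy=5.0, rotation_deg=3.0)
        fixed = self._render(rasterize(tree, cfg.canvas), 4)
        moving = self._render(rasterize(tree.transformed(applied), cfg.canvas), 5)
        res = register_pair(moving, fixed)
        expect = applied.inverse()
        assert np.hypot(res.transform.dx - expect.dx, res.transform.dy - expect.dy) <= 0.5
        assert abs(res.transform.rotation_deg - expect.rotation_deg) <= 0.5

    def test_flat_image_is_degenerate(self):
        flat = np.full(SHAPE, 0.5)
        with pytest.raises(DegenerateImageError):
            register_pair(flat, flat)

    def test_unrelated_images_fail_score_floor(self, rng):
        a = rng.random(SHAPE)
        b = rng.random(SHAPE)
        with pytest.raises(RegistrationFailure) as exc:
            register_pair(a, b, score_floor=0.5)
        assert exc.value.score < 0.5

    def test_common_mask_symmetric_between_orderings(self):
        tree, cfg = scene(3)
        applied = RigidTransform(dx=8.0, dy=-6.0, rotation_deg=2.0)
        a = self._render(rasterize(tree, cfg.canvas), 6)
        b = self._render(rasterize(tree.transformed(applied), cfg.canvas), 7)
        res_ab = register_pair(b, a)
        res_ba = register_pair(a, b)
        # map res_ba's mask into a's frame for comparison
        mask_ba, _ = warp(res_ba.common_mask, res_ba.transform.inverse(), order=0)
        inter = (res_ab.common_mask & mask_ba).sum()
        union = (res_ab.common_mask | mask_ba).sum()
        assert inter / union >= 0.98


class TestOverlayComposite:
    def test_identical_images_render_gray(self, rng):
        img = rng.random(SHAPE)
        rgb = overlay_composite(img, img)
        assert np.array_equal(rgb[..., 0], rgb[..., 1])
        assert np.array_equal(rgb[..., 0], rgb[..., 2])

    def test_zero_moving_renders_pure_magenta(self, rng):
        img = rng.random(SHAPE)
        rgb = overlay_composite(img, np.zeros(SHAPE))
        assert np.array_equal(rgb[..., 0], img)
        assert not rgb[..., 1].any()
        assert np.array_equal(rgb[..., 2], img)

    def test_disjoint_vessels_never_mix_channels(self):
        a = np.zeros(SHAPE)
        b = np.zeros(SHAPE)
        a[40:60, :] = 1.0
        b[80:100, :] = 1.0
        rgb = overlay_composite(a, b)
        both_bright = (rgb[..., 0] > 0.5) & (rgb[..., 1] > 0.5)
        assert not both_bright.any()


def test_masked_ncc_of_identical_signal_is_one(rng):
    img = rng.random(SHAPE)
    mask = np.ones(SHAPE, dtype=bool)
    assert masked_ncc(img, img, mask) == pytest.approx(1.0)
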