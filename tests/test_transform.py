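"""Similarity transforms, resampling, landmark estimation and stack alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelcorr import (
    AlignmentSet,
    SimilarityTransform,
    align_stack,
    apply_transform,
    compose,
    estimate_from_landmarks,
    invert,
    render_overlay,
)
from gelcorr.errors import EstimationError, ParameterError
from .conftest import make_stack

finite_angles = st.floats(-180, 180, allow_nan=False)
scales = st.floats(0.5, 2.0, allow_nan=False)
shifts = st.floats(-10, 10, allow_nan=False)


def smooth_image(h=48, w=48, seed=0):
    """Band-limited random image: low-frequency cosines + small noise."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w] / max(h, w)
    img = np.zeros((h, w))
    for _ in range(6):
        fx, fy = rng.uniform(0.5, 3, 2)
        ph = rng.uniform(0, 2 * np.pi)
        img += rng.uniform(0.3, 1) * np.cos(2 * np.pi * (fx * xx + fy * yy) + ph)
    return img


class TestApplyTransform:
    def test_identity_bit_identical(self, rng):
        img = rng.random((16, 16))
        out, mask = apply_transform(img, SimilarityTransform.identity())
        assert np.array_equal(out, img)
        assert mask.all()

    def test_integer_translation_nearest(self, rng):
        img = rng.random((10, 10))
        out, mask = apply_transform(
            img, SimilarityTransform(0, 1, 3, 0), interpolation="nearest"
        )
        assert np.array_equal(out[:, 3:], img[:, :-3])
        assert not mask[:, :3].any() and mask[:, 3:].all()
        assert np.all(out[:, :3] == 0)

    def test_rotation_90_matches_array_rotation(self, rng):
        """On a square grid, 90 deg CCW maps grid to grid: exact vs np.rot90."""
        img = rng.random((9, 9))
        out, mask = apply_transform(img, SimilarityTransform(90, 1, 0, 0))
        assert mask.all()
        assert np.abs(out - np.rot90(img)).max() < 1e-9

    def test_mask_marks_exact_footprint(self):
        img = np.ones((8, 8))
        _, mask = apply_transform(img, SimilarityTransform(0, 1, 2.5, 0))
        # source coord = x - 2.5; valid needs x >= 2.5 -> columns 3..7
        assert not mask[:, :3].any() and mask[:, 3:].all()

    @pytest.mark.parametrize("bad", [
        dict(scale=0.0), dict(scale=-1.0),
        dict(rotation_deg=np.nan), dict(tx=np.inf),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ParameterError):
            SimilarityTransform(**{"rotation_deg": 0, "scale": 1.0,
                                   "tx": 0, "ty": 0, **bad})


class TestInvertCompose:
    def test_invert_identity(self):
        assert invert(SimilarityTransform.identity()) == SimilarityTransform.identity()

    def test_invert_pure_scale(self):
        assert invert(SimilarityTransform(0, 2, 0, 0)) == SimilarityTransform(0, 0.5, 0, 0)

    @given(r=finite_angles, s=scales, tx=shifts, ty=shifts)
    @settings(max_examples=50, deadline=None)
    def test_compose_with_inverse_is_identity(self, r, s, tx, ty):
        t = SimilarityTransform(r, s, tx, ty)
        c = compose(invert(t), t)
        assert abs(c.rotation_deg) < 1e-9
        assert abs(c.scale - 1) < 1e-12
        assert abs(c.tx) < 1e-9 and abs(c.ty) < 1e-9

    def test_roundtrip_error_below_2pct_dynamic_range(self):
        img = smooth_image(seed=3)
        t = SimilarityTransform(12.0, 1.05, 2.3, -1.7)
        fwd, m1 = apply_transform(img, t)
        back, m2 = apply_transform(fwd, invert(t))
        # exclude pixels whose bilinear stencil touched zero-filled invalid pixels
        carried, _ = apply_transform(m1.astype(float), invert(t))
        both = m2 & (carried > 1 - 1e-9)
        dr = img.max() - img.min()
        assert np.abs(back - img)[both].max() < 0.02 * dr

    @given(tx1=st.integers(-3, 3), ty1=st.integers(-3, 3),
           tx2=st.integers(-3, 3), ty2=st.integers(-3, 3))
    @settings(max_examples=25, deadline=None)
    def test_composition_consistency_integer_translations(self, tx1, ty1, tx2, ty2):
        """Applying t1 then t2 equals the composed transform (exact for nearest)."""
        img = np.random.default_rng(1).random((12, 12))
        t1 = SimilarityTransform(0, 1, tx1, ty1)
        t2 = SimilarityTransform(0, 1, tx2, ty2)
        step1, m1 = apply_transform(img, t1, "nearest")
        step2, m2 = apply_transform(step1, t2, "nearest")
        once, m12 = apply_transform(img, compose(t2, t1), "nearest")
        joint = m12 & m2
        assert np.array_equal(step2[joint], once[joint])


class TestEstimateFromLandmarks:
    src = np.array([[10.0, 10.0], [40.0, 12.0], [25.0, 35.0], [8.0, 30.0]])

    def test_identity_when_dst_equals_src(self):
        t = estimate_from_landmarks(self.src, self.src)
        assert abs(t.rotation_deg) < 1e-9 and abs(t.scale - 1) < 1e-12
        assert abs(t.tx) < 1e-9 and abs(t.ty) < 1e-9

    def test_pure_translation_exact(self):
        t = estimate_from_landmarks(self.src[:3], self.src[:3] + [5.0, -2.0])
        assert np.allclose([t.rotation_deg, t.scale, t.tx, t.ty], [0, 1, 5, -2])

    def test_rotation_scale_about_center_recovered(self):
        center = (31.5, 31.5)
        truth = SimilarityTransform(30.0, 1.5, 0.0, 0.0)
        dst = truth.apply_to_points(self.src, center=center)
        est = estimate_from_landmarks(self.src, dst, center=center)
        assert abs(est.rotation_deg - 30) < 1e-6
        assert abs(est.scale - 1.5) < 1e-6
        assert abs(est.tx) < 1e-6 and abs(est.ty) < 1e-6

    def test_least_squares_beats_perturbed_alternatives(self, rng):
        dst = SimilarityTransform(10, 1.2, 3, -1).apply_to_points(self.src)
        dst = dst + rng.normal(0, 0.5, dst.shape)
        est = estimate_from_landmarks(self.src, dst)

        def rss(t):
            return np.sum((t.apply_to_points(self.src) - dst) ** 2)

        base = rss(est)
        for dr in (-0.5, 0.5):
            for ds in (-0.02, 0.02):
                alt = SimilarityTransform(est.rotation_deg + dr, est.scale + ds,
                                          est.tx, est.ty)
                assert base <= rss(alt) + 1e-9

    @pytest.mark.parametrize("src,dst", [
        ([(0, 0)], [(1, 1)]),                       # < 2 pairs
        ([(2, 2), (2, 2), (2, 2)], [(0, 0), (1, 1), (2, 2)]),  # coincident src
    ])
    def test_degenerate_inputs_raise(self, src, dst):
        with pytest.raises(EstimationError):
            estimate_from_landmarks(src, dst)


class TestAlignStack:
    def test_all_identity_unchanged(self, noise_stack):
        aset = AlignmentSet("s0", {}).completed(noise_stack.sample_ids)
        out = align_stack(noise_stack, aset)
        assert np.array_equal(out.data, noise_stack.data)
        assert out.valid.all()

    def test_known_shift_realigned_to_reference(self):
        img = smooth_image(seed=7)
        shifted, _ = apply_transform(img, SimilarityTransform(0, 1, 4, 0), "nearest")
        stack = make_stack([img, shifted], ids=["ref", "moved"])
        aset = AlignmentSet("ref", {"moved": SimilarityTransform(0, 1, -4, 0)})
        out = align_stack(stack, aset.completed(stack.sample_ids), "nearest")
        joint = out.valid.all(axis=0)
        assert np.array_equal(out.data[1][joint], img[joint])
        # columns that left and re-entered the canvas are masked, not zero-filled
        assert not out.valid[1, :, -4:].any()

    def test_fully_offcanvas_image_all_invalid(self, noise_stack):
        aset = AlignmentSet(
            "s0", {"s1": SimilarityTransform(0, 1, 500, 0)}
        ).completed(noise_stack.sample_ids)
        out = align_stack(noise_stack, aset)
        assert not out.valid[1].any()
        assert out.valid[0].all()

    def test_missing_transform_names_sample(self, noise_stack):
        with pytest.raises(ParameterError, match="s3"):
            align_stack(noise_stack, AlignmentSet("s0", {
                sid: SimilarityTransform.identity()
                for sid in noise_stack.sample_ids if sid != "s3"
            }))

    def test_reference_must_be_identity(self):
        with pytest.raises(ParameterError, match="identity"):
            AlignmentSet("s0", {"s0": SimilarityTransform(1, 1, 0, 0)})

    def test_json_roundtrip(self, tmp_path):
        aset = AlignmentSet("ref", {
            "ref": SimilarityTransform.identity(),
            "a": SimilarityTransform(3.5, 1.01, -2, 4),
        })
        path = aset.to_json(tmp_path / "a.json")
        back = AlignmentSet.from_json(path)
        assert back.reference_id == "ref"
        assert back.transforms == aset.transforms


class TestRenderOverlay:
    def test_alpha_extremes_and_midpoint(self, rng):
        a = rng.random((6, 6)) * 50
        b = np.zeros((6, 6))
        b[0, 0] = 7.0  # max
        scaled_a = (a - a.min()) / (a.max() - a.min())
        assert np.allclose(render_overlay(a, b, 0.0), scaled_a)
        assert np.allclose(render_overlay(a, np.full((6, 6), 3.0), 1.0), 1.0)
        uniform = render_overlay(np.zeros((6, 6)), np.full((6, 6), 9.0), 0.5)
        assert np.allclose(uniform, 0.5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ParameterError, match="mismatch"):
            render_overlay(np.zeros((4, 4)), np.zeros((4, 5)), 0.5)
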