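"""Texture warping and combined appearance-model contracts."""

import dataclasses

import numpy as np
import pytest

from kneestudy.appearance import (
    build_combined_model,
    build_reference_frame,
    build_texture_model,
    extract_appearance_features,
    normalize_texture,
    train_appearance_model,
    warp_to_reference,
)
from kneestudy.landmarks import PA, LandmarkSet
from kneestudy.render import template_landmarks
from kneestudy.shape import build_shape_model, procrustes_align


@pytest.fixture(scope="module")
def frame():
    mean = template_landmarks(PA, 128)
    # normalise like the shape model frame would
    c = mean.points - mean.points.mean(axis=0)
    c /= np.sqrt((c**2).sum() / len(c))
    return build_reference_frame(LandmarkSet(PA, c), frame_width=96)


class TestWarp:
    def test_identity_warp_reads_pixels_directly(self, frame):
        h, w = frame.frame_shape
        rng = np.random.default_rng(0)
        img = rng.random((h, w))
        ref_lms = LandmarkSet(PA, frame.ref_points)
        g = warp_to_reference(img, ref_lms, frame)
        direct = img[frame.sample_pixels[:, 1], frame.sample_pixels[:, 0]]
        assert np.abs(g - direct).max() <= 1e-6

    def test_constant_image_gives_constant_texture(self, frame, rng):
        lms = template_landmarks(PA, 128)
        img = np.full((128, 128), 0.37)
        g = warp_to_reference(img, lms, frame)
        np.testing.assert_allclose(g, 0.37, atol=1e-12)

    def test_affine_ramp_matches_closed_form(self, frame):
        # intensity = a*x + b*y + c composed with an affine landmark map is
        # again affine in the reference frame: predict it in closed form
        a, b, c = 0.003, 0.005, 0.1
        size = 256
        yy, xx = np.mgrid[0:size, 0:size]
        img = a * xx + b * yy + c
        scale, theta, t = 0.9, 0.05, np.array([30.0, 20.0])
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        lms = LandmarkSet(PA, frame.ref_points @ (scale * rot).T + t)
        g = warp_to_reference(img, lms, frame)
        ref = frame.sample_pixels.astype(float)
        src = ref @ (scale * rot).T + t
        expected = a * src[:, 0] + b * src[:, 1] + c
        assert np.abs(g - expected).max() < 1e-3

    def test_degenerate_triangle_identified(self, frame):
        pts = frame.ref_points.copy()
        tri0 = frame.triangles[0]
        pts[tri0] = pts[tri0[0]]  # collapse one triangle
        img = np.zeros((128, 128))
        with pytest.raises(ValueError, match="degenerate source triangle"):
            warp_to_reference(img, LandmarkSet(PA, pts), frame)


class TestTextureModel:
    def test_photometric_invariance_of_normalisation(self, frame, rng):
        lms = template_landmarks(PA, 128)
        img = rng.random((128, 128))
        g1 = normalize_texture(warp_to_reference(img, lms, frame))
        g2 = normalize_texture(warp_to_reference(3.7 * img + 0.4, lms, frame))
        np.testing.assert_allclose(g1, g2, atol=1e-8)

    def test_known_eigenstructure_recovery(self, rng):
        m = 200
        q, _ = np.linalg.qr(rng.standard_normal((m, 2)))
        texs = [
            3.0 * rng.standard_normal() * q[:, 0]
            + 1.0 * rng.standard_normal() * q[:, 1]
            for _ in range(400)
        ]
        model = build_texture_model(texs, variance_retained=0.999, normalized=True)
        assert model.eigenvalues[0] == pytest.approx(9.0, rel=0.2)
        assert model.eigenvalues[1] == pytest.approx(1.0, rel=0.2)

    def test_full_variance_exact_reconstruction(self, rng):
        texs = [rng.standard_normal(50) for _ in range(10)]
        model = build_texture_model(texs, variance_retained=1.0, normalized=True)
        for t in texs:
            rec = model.reconstruct(model.project(t))
            np.testing.assert_allclose(rec, t, atol=1e-8)

    def test_identical_textures_degenerate(self):
        t = np.linspace(0, 1, 30)
        model = build_texture_model([t] * 6, variance_retained=0.95, normalized=True)
        assert model.n_modes == 0


class TestCombinedModel:
    def test_shape_weight_definition_arithmetic(self, rendered_cohort):
        knees, _ = rendered_cohort
        lms = [k.true_landmarks for k in knees]
        aligned, _, _ = procrustes_align(lms)
        sm = build_shape_model(aligned, 0.95)
        frame = build_reference_frame(sm.mean_shape, 96)
        tex = [
            normalize_texture(warp_to_reference(k.image, l, frame))
            for k, l in zip(knees, lms)
        ]
        tm = build_texture_model(tex, 0.95, normalized=True)
        # doctor the eigenvalues to the fixture values 4.0 / 16.0
        sm2 = dataclasses.replace(sm, eigenvalues=np.array([3.0, 1.0]), modes=sm.modes[:, :2])
        tm2 = dataclasses.replace(tm, eigenvalues=np.array([10.0, 6.0]), modes=tm.modes[:, :2])
        cm = build_combined_model(
            sm2, tm2, np.zeros((5, 2)), np.ones((5, 2)), frame, 1.0
        )
        assert cm.shape_weight == pytest.approx(2.0)

    def test_zero_texture_variance_reduces_to_shape_modes(self, rendered_cohort):
        knees, _ = rendered_cohort
        lms = [k.true_landmarks for k in knees]
        aligned, _, _ = procrustes_align(lms)
        # moderate retention keeps the mode spectrum well-conditioned
        sm = build_shape_model(aligned, 0.98)
        frame = build_reference_frame(sm.mean_shape, 96)
        const = np.zeros(frame.n_samples)
        tm = build_texture_model([const] * len(knees), 1.0, normalized=True)
        assert tm.n_modes == 0
        from kneestudy.shape import shape_to_params

        bs = np.stack([shape_to_params(l, sm)[0] for l in lms])
        bg = np.zeros((len(knees), 0))
        cm = build_combined_model(sm, tm, bs, bg, frame, 1.0)
        assert cm.n_params == sm.n_modes

    def test_unpaired_inputs_rejected(self, rendered_cohort):
        knees, _ = rendered_cohort
        lms = [k.true_landmarks for k in knees]
        aligned, _, _ = procrustes_align(lms)
        sm = build_shape_model(aligned, 0.95)
        frame = build_reference_frame(sm.mean_shape, 96)
        tm = build_texture_model([np.zeros(frame.n_samples)] * 4, 1.0, normalized=True)
        with pytest.raises(ValueError, match="unpaired"):
            build_combined_model(sm, tm, np.zeros((3, 2)), np.zeros((4, 0)), frame)

    def test_combined_eigenvalue_sum_matches_covariance_oracle(self, rng):
        # brute-force covariance of the concatenated training vectors
        bs = rng.standard_normal((60, 3)) * np.array([3.0, 2.0, 1.0])
        bg = rng.standard_normal((60, 4))
        sm_eigs = np.var(bs, axis=0, ddof=1)
        tg_eigs = np.var(bg, axis=0, ddof=1)
        import kneestudy.appearance as app

        class _S:  # minimal stand-ins carrying eigenvalues only
            eigenvalues = sm_eigs

        class _T:
            eigenvalues = tg_eigs

        w = np.sqrt(tg_eigs.sum() / sm_eigs.sum())
        concat = np.hstack([w * bs, bg])
        oracle_total = np.trace(np.cov(concat.T, ddof=1))
        cm = app.build_combined_model(_S(), _T(), bs, bg, frame=None, variance_retained=1.0)
        assert cm.eigenvalues.sum() == pytest.approx(oracle_total, rel=1e-10)


@pytest.fixture(scope="module")
def trained(rendered_cohort):
    knees, _ = rendered_cohort
    return knees, train_appearance_model(
        [k.image for k in knees],
        [k.true_landmarks for k in knees],
        variance_retained=1.0,
        frame_width=96,
    )


class TestFeatureExtraction:

    def test_round_trip_on_training_example(self, trained):
        knees, model = trained
        k = knees[0]
        f = extract_appearance_features(k.image, k.true_landmarks, model)
        concat = np.concatenate([model.shape_weight * f.b_s, f.b_g])
        rec = model.mean + model.modes @ f.c
        assert np.abs(rec - concat).max() < 1e-6

    def test_feature_determinism_and_dimension(self, trained):
        knees, model = trained
        dims = set()
        for k in knees[:5]:
            f1 = extract_appearance_features(k.image, k.true_landmarks, model)
            f2 = extract_appearance_features(k.image, k.true_landmarks, model)
            np.testing.assert_array_equal(f1.c, f2.c)
            dims.add(len(f1.c))
        assert dims == {model.n_params}

    def test_synthesized_appearance_recovered(self, trained, rng):
        # build an (image, landmarks) pair with known parameters — a flat
        # image (texture params exactly zero) under a model-synthesised
        # shape — and check extraction recovers the predicted c
        from kneestudy.shape import SimilarityTransform, params_to_shape

        from kneestudy.shape import shape_to_params

        _, model = trained
        sm = model.shape_model
        b_s = 0.5 * np.sqrt(sm.eigenvalues) * rng.uniform(-1, 1, sm.n_modes)
        pose = SimilarityTransform(60.0, 0.1, np.array([80.0, 80.0]))
        lms = params_to_shape(b_s, pose, sm)
        img = np.full((160, 160), 0.5)
        f = extract_appearance_features(img, lms, model)
        # a flat image normalises to the zero texture vector, whose
        # projection is the known value -P^T mean
        expected_bg = model.texture_model.project(
            np.zeros_like(model.texture_model.mean)
        )
        np.testing.assert_allclose(f.b_g, expected_bg, atol=1e-8)
        # the recovered shape parameters regenerate the synthesised
        # geometry (the (pose, b) pair itself is only unique up to the
        # mean's component inside the mode span)
        _, pose_f = shape_to_params(lms, sm)
        rec = params_to_shape(f.b_s, pose_f, sm)
        assert np.abs(rec.points - lms.points).max() < 1e-3
        # c is the projection of the recovered concatenation (the model's
        # span is rank-limited by the training count, so only the in-span
        # component can round-trip)
        concat = np.concatenate([model.shape_weight * f.b_s, f.b_g])
        expected_c = model.modes.T @ (concat - model.mean)
        scale = 1.0 + float(np.abs(expected_c).max())
        np.testing.assert_allclose(f.c, expected_c, atol=1e-3 * scale)

    def test_serialization_round_trip(self, trained, tmp_path):
        knees, model = trained
        path = tmp_path / "model.apm.npz"
        model.save(path)
        from kneestudy.appearance import CombinedModel

        back = CombinedModel.load(path)
        k = knees[1]
        f1 = extract_appearance_features(k.image, k.true_landmarks, model)
        f2 = extract_appearance_features(k.image, k.true_landmarks, back)
        np.testing.assert_allclose(f1.c, f2.c, atol=1e-10)
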