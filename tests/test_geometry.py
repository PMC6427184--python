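"""Projective algebra, warping and estimation from correspondences."""

import numpy as np
import pytest
from scipy import optimize
from skimage import transform as sktf

from evireg.evaluation import aaid
from evireg.geometry import (
    DegenerateConfigurationError,
    GeometryError,
    ProjectiveTransform,
    RigidParams,
    estimate_projective_exact,
    estimate_projective_ls,
    identity,
    image_center,
    matrix_to_rigid,
    reprojection_errors,
    rigid_to_matrix,
    translation,
    warp_image,
)


def random_projective(rng) -> ProjectiveTransform:
    m = np.eye(3)
    m[:2, :2] += 0.2 * rng.standard_normal((2, 2))
    m[2, :2] = rng.uniform(-5, 5, 2)
    m[:2, 2] = rng.uniform(-1e-3, 1e-3, 2)
    return ProjectiveTransform(m)


class TestAlgebra:
    def test_identity_maps_points_unchanged(self):
        pts = [(0.0, 0.0), (3.5, -2.0), (10.0, 7.0)]
        assert np.allclose(identity().apply(pts), pts)

    def test_translation_closed_form(self):
        T = translation(2.0, -3.0)
        assert np.allclose(T.apply([(1.0, 1.0)]), [(3.0, -2.0)])
        assert np.allclose(T.inverse().matrix, translation(-2.0, 3.0).matrix)

    def test_quarter_turn_row_vector_convention(self):
        T = rigid_to_matrix(RigidParams(90.0, 0.0, 0.0))
        assert np.allclose(T.apply([(1.0, 0.0)]), [(0.0, 1.0)], atol=1e-12)

    def test_compose_then_invert_is_identity(self, rng):
        T = random_projective(rng)
        assert T.compose(T.inverse()).almost_equals(identity(), tol=1e-9)

    def test_scale_freedom_normalized_away(self):
        assert ProjectiveTransform(2.0 * np.eye(3)).almost_equals(identity())

    def test_composition_matches_sequential_application(self, rng):
        T1, T2 = random_projective(rng), random_projective(rng)
        pts = rng.uniform(0, 50, (6, 2))
        assert np.allclose(
            T1.compose(T2).apply(pts), T2.apply(T1.apply(pts)), atol=1e-8
        )

    def test_singular_matrix_rejected(self):
        with pytest.raises(GeometryError):
            ProjectiveTransform(np.zeros((3, 3)))

    def test_serialization_requires_convention_tag(self, rng, tmp_path):
        T = random_projective(rng)
        path = tmp_path / "t.json"
        T.save(path)
        assert ProjectiveTransform.load(path).almost_equals(T)
        import json

        broken = T.to_json_dict()
        del broken["convention"]
        with pytest.raises(GeometryError):
            ProjectiveTransform.from_json_dict(broken)


class TestRigid:
    def test_zero_params_is_identity(self):
        assert rigid_to_matrix(RigidParams(0.0, 0.0, 0.0)).almost_equals(identity())

    def test_pure_translation_structure(self):
        T = rigid_to_matrix(RigidParams(0.0, -10.0, 5.0))
        assert T.matrix[2, 0] == -10.0 and T.matrix[2, 1] == 5.0
        assert np.allclose(T.matrix[:2, :2], np.eye(2))

    @pytest.mark.parametrize("theta", [-90.0, -10.0, 0.0, 10.0, 90.0])
    def test_round_trip_params(self, theta):
        p = RigidParams(theta, 2.5, -7.0)
        back = matrix_to_rigid(rigid_to_matrix(p))
        assert back.theta == pytest.approx(theta, abs=1e-12)
        assert (back.tv, back.th) == (pytest.approx(2.5), pytest.approx(-7.0))

    def test_center_rotation_fixes_center(self):
        center = (10.0, 20.0)
        T = rigid_to_matrix(RigidParams(30.0, 0.0, 0.0), center=center)
        assert np.allclose(T.apply([center]), [center], atol=1e-12)
        back = matrix_to_rigid(T, center=center)
        assert back.theta == pytest.approx(30.0)
        assert abs(back.tv) < 1e-12 and abs(back.th) < 1e-12

    def test_theta_range_enforced(self):
        with pytest.raises(GeometryError):
            RigidParams(181.0, 0.0, 0.0)


class TestWarp:
    def test_identity_warp_is_exact(self, texture):
        warped, mask = warp_image(texture, identity())
        assert np.array_equal(warped, texture)
        assert mask.all()

    def test_integer_translation_nearest_is_exact_shift(self, texture):
        warped, mask = warp_image(texture, translation(3, 2), interpolation="nearest")
        # output pixel (v, w) samples source (v+3, w+2)
        assert np.array_equal(warped[:-2, :-3], texture[2:, 3:])
        assert warped[:, -3:].sum() == 0.0
        assert mask[:-2, :-3].all() and not mask[:, -3:].any()

    def test_round_trip_interpolation_bound(self, texture):
        T = rigid_to_matrix(RigidParams(7.0, 1.5, -2.5),
                            center=image_center(texture.shape))
        once, _ = warp_image(texture, T)
        back, _ = warp_image(once, T.inverse())
        interior = (slice(12, -12), slice(12, -12))
        assert aaid(back[interior], texture[interior]) < 0.02


class TestEstimation:
    def test_exact_identity_square(self):
        corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
        T = estimate_projective_exact(corners, corners)
        assert T.almost_equals(identity(), tol=1e-9)

    def test_exact_translated_square(self):
        ref = [(0, 0), (1, 0), (1, 1), (0, 1)]
        sen = [(v + 2, w - 1) for v, w in ref]
        T = estimate_projective_exact(ref, sen)
        assert T.almost_equals(translation(2, -1), tol=1e-9)

    def test_exact_collinear_reference_rejected(self):
        ref = [(0, 0), (1, 1), (2, 2), (0, 1)]
        with pytest.raises(DegenerateConfigurationError):
            estimate_projective_exact(ref, ref)

    def test_exact_recovery_random_trials(self, rng):
        for _ in range(100):
            T = random_projective(rng)
            ref = rng.uniform(0, 100, (4, 2))
            got = estimate_projective_exact(ref, T.apply(ref))
            assert np.allclose(got.matrix, T.matrix, atol=1e-8)

    def test_ls_agrees_with_exact_on_four_pairs(self, rng):
        T = random_projective(rng)
        ref = rng.uniform(0, 100, (4, 2))
        sen = T.apply(ref)
        exact = estimate_projective_exact(ref, sen)
        ls = estimate_projective_ls(ref, sen)
        assert np.allclose(ls.matrix, exact.matrix, atol=1e-8)

    def test_ls_noise_free_recovery(self, rng):
        for _ in range(100):
            T = random_projective(rng)
            ref = rng.uniform(0, 100, (20, 2))
            got = estimate_projective_ls(ref, T.apply(ref))
            assert np.allclose(got.matrix, T.matrix, atol=1e-6)

    def test_ls_matches_reference_library_estimator(self, rng):
        """Cross-check against scikit-image's DLT (column-vector convention:
        related to ours by transposition at the adapter boundary)."""
        T = random_projective(rng)
        ref = rng.uniform(0, 100, (15, 2))
        sen = T.apply(ref) + 0.2 * rng.standard_normal((15, 2))
        ours = estimate_projective_ls(ref, sen, refine=False)
        sk = sktf.ProjectiveTransform.from_estimate(ref, sen)  # (x, y) = our (v, w)
        theirs = ProjectiveTransform(sk.params.T)
        assert np.allclose(ours.matrix, theirs.matrix, atol=1e-6)

    def test_ls_noisy_beats_pixel_and_matches_nonlinear_oracle(self, rng):
        """With 0.5 px coordinate noise the refined LS fit stays within
        1.5 px mean reprojection error and is no worse than a direct
        nonlinear minimisation of the same cost."""
        errors = []
        for _ in range(10):
            T = random_projective(rng)
            ref = rng.uniform(0, 100, (20, 2))
            sen = T.apply(ref) + 0.5 * rng.standard_normal((20, 2))
            got = estimate_projective_ls(ref, sen)
            err = reprojection_errors(got, ref, sen).mean()
            errors.append(err)

            def cost(x):
                m = ProjectiveTransform(np.append(x, 1.0).reshape(3, 3))
                return float((reprojection_errors(m, ref, sen) ** 2).sum())

            oracle = optimize.minimize(cost, got.matrix.ravel()[:8], method="Nelder-Mead")
            got_cost = float((reprojection_errors(got, ref, sen) ** 2).sum())
            assert got_cost <= oracle.fun * (1 + 1e-6) + 1e-9
        assert np.mean(errors) <= 1.5

    def test_ls_invariant_to_global_coordinate_translation(self, rng):
        T = random_projective(rng)
        ref = rng.uniform(0, 100, (12, 2))
        sen = T.apply(ref) + 0.3 * rng.standard_normal((12, 2))
        base = estimate_projective_ls(ref, sen)
        shifted = estimate_projective_ls(ref + 50.0, sen + 50.0)
        # compare by action on points, in the shifted frame
        pts = rng.uniform(0, 100, (8, 2))
        assert np.allclose(
            base.apply(pts) + 50.0, shifted.apply(pts + 50.0), atol=1e-5
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(GeometryError):
            estimate_projective_ls([(0, 0)] * 3, [(0, 0)] * 3)
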