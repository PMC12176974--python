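import math

import numpy as np
import pytest

from affinerf import (
    AffineMap,
    RFSpec,
    SampledField,
    SpatialCovariance,
    SpatioTemporalRFSpec,
    StimulusSpec,
    cascade_smooth,
    covariance_from_shape,
    decompose,
    make_stimulus,
    match_responses,
    rotation_matrix,
    sample_kernel,
    shape_from_covariance,
    smooth,
    steer_coefficients,
    svd_form,
    transform_covariance,
    transform_gradient,
    verify_affine_covariance,
    verify_spatiotemporal_covariance,
    warp_image,
)
from affinerf.covariance import (
    _derivative_weights,
    _smooth_with_kernel,
    directional_basis_vector,
)
from affinerf.errors import (
    CascadeInfeasibleError,
    ConfigurationError,
    DegenerateBasisError,
    ExtentError,
    InvalidMapError,
)

IDENTITY = AffineMap(1, 0, 0, 1)


def interior(values, band=16):
    return values[band:-band, band:-band]


def rms_rel(diff, ref):
    return np.sqrt(np.mean(diff**2)) / np.sqrt(np.mean(ref**2))


class TestTransforms:
    def test_identity_fixes_covariance(self):
        cov = SpatialCovariance(3.0, 1.0, 0.5)
        out = transform_covariance(cov, IDENTITY)
        np.testing.assert_allclose(out.matrix, cov.matrix)

    def test_diagonal_stretch_of_identity_covariance(self):
        out = transform_covariance(SpatialCovariance.isotropic(1.0), AffineMap(2, 0, 0, 1))
        np.testing.assert_allclose(out.matrix, [[4, 0], [0, 1]])

    def test_rotation_conjugates_eigensystem(self):
        theta = 0.6
        cov = covariance_from_shape(2.0, 1.0, 0.3)
        rot = AffineMap.from_matrix(rotation_matrix(theta))
        out = transform_covariance(cov, rot)
        expect = covariance_from_shape(2.0, 1.0, 0.3 + theta)
        np.testing.assert_allclose(out.matrix, expect.matrix, atol=1e-12)

    def test_singular_map_rejected(self):
        with pytest.raises(InvalidMapError):
            transform_covariance(SpatialCovariance.isotropic(1.0), AffineMap(1, 0, 0, 0))

    def test_gradient_identity(self):
        np.testing.assert_allclose(transform_gradient(IDENTITY).matrix, np.eye(2))

    def test_gradient_diagonal(self):
        np.testing.assert_allclose(
            transform_gradient(AffineMap(2, 0, 0, 1)).matrix, [[0.5, 0], [0, 1]]
        )

    def test_gradient_rotation_is_rotation(self):
        r = rotation_matrix(1.1)
        out = transform_gradient(AffineMap.from_matrix(r))
        np.testing.assert_allclose(out.matrix, r, atol=1e-14)

    def test_decomposition_consistency_with_covariance_transform(self, rng):
        """eigen-scales of A (sigma^2 I) A^T are (sigma rho_i), oriented at alpha."""
        for _ in range(25):
            a = 1.2 * (np.eye(2) + rng.uniform(-0.25, 0.25, (2, 2)))
            amap = AffineMap.from_matrix(a)
            factors = decompose(amap)
            sigma = 1.4
            out = transform_covariance(SpatialCovariance.isotropic(sigma), amap)
            s1, s2, phi = shape_from_covariance(out)
            assert s1 == pytest.approx(sigma * factors.rho1, rel=1e-10)
            assert s2 == pytest.approx(sigma * factors.rho2, rel=1e-10)
            alpha, _, _ = svd_form(factors)
            if factors.stretch > 1.001:
                assert abs(math.remainder(phi - alpha, math.pi)) < 1e-8


class TestSmooth:
    def test_constant_preserved(self):
        img = make_stimulus(StimulusSpec("constant", size=32, value=2.5))
        out = smooth(img, SpatialCovariance.isotropic(2.0))
        np.testing.assert_allclose(out.values, 2.5, rtol=1e-12)

    def test_impulse_reproduces_kernel(self):
        img = make_stimulus(StimulusSpec("impulse", size=33))
        cov = covariance_from_shape(2.0, 1.0, 0.5)
        out = smooth(img, cov, normalize=False)
        s1, s2, phi = shape_from_covariance(cov)
        kernel = sample_kernel(RFSpec(s1, s2, phi), size=17, spacing=1.0)
        c = 16  # impulse at centre index
        np.testing.assert_allclose(
            out.values[c - 8 : c + 9, c - 8 : c + 9], kernel.values, atol=1e-12
        )

    def test_semigroup_two_steps_match_one(self, noise_image_96):
        l_two = smooth(
            smooth(noise_image_96, SpatialCovariance.isotropic(1.0)),
            SpatialCovariance.isotropic(1.0),
        )
        l_one = smooth(noise_image_96, SpatialCovariance(2.0, 2.0, 0.0))
        d = interior(l_two.values - l_one.values)
        r = interior(l_one.values)
        assert rms_rel(d, r) < 0.005

    def test_oversized_kernel_rejected(self):
        img = make_stimulus(StimulusSpec("constant", size=32))
        with pytest.raises(ExtentError):
            smooth(img, SpatialCovariance.isotropic(10.0))

    def test_fft_path_matches_direct(self, noise_image_96):
        cov = covariance_from_shape(3.0, 2.0, 0.4)
        a = smooth(noise_image_96, cov, method="direct")
        b = smooth(noise_image_96, cov, method="fft")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestVerifyAffineCovariance:
    def test_identity_map_zero_error(self, noise_image_128):
        rep = verify_affine_covariance(
            noise_image_128, IDENTITY, SpatialCovariance.isotropic(6.0)
        )
        assert rep.interior_rms_relative_error == 0.0
        assert rep.max_relative_error == 0.0

    def test_exact_quarter_rotation(self, noise_image_128):
        rot = AffineMap.from_matrix(rotation_matrix(math.pi / 2))
        rep = verify_affine_covariance(
            noise_image_128, rot, SpatialCovariance.isotropic(6.0)
        )
        assert rep.max_relative_error < 1e-3

    def test_diagonal_stretch_within_one_percent(self, noise_image_128):
        rep = verify_affine_covariance(
            noise_image_128, AffineMap(1.5, 0, 0, 1), SpatialCovariance.isotropic(6.0)
        )
        assert rep.interior_rms_relative_error < 0.01
        assert rep.interior_rms_relative_error <= rep.max_relative_error

    def test_error_halves_under_grid_refinement(self, noise_image_128):
        amap = AffineMap(1.5, 0, 0, 1)
        cov = SpatialCovariance.isotropic(6.0)
        coarse = verify_affine_covariance(noise_image_128, amap, cov)
        fine_img = make_stimulus(
            StimulusSpec("band_limited_noise", size=256, cutoff=8.0, seed=1),
            spacing=0.5,
        )
        fine = verify_affine_covariance(fine_img, amap, cov)
        assert fine.interior_rms_relative_error < 0.5 * coarse.interior_rms_relative_error

    def test_gradient_covariance(self, noise_image_128):
        rep = verify_affine_covariance(
            noise_image_128,
            AffineMap(1.4, 0.1, -0.05, 0.95),
            SpatialCovariance.isotropic(6.0),
            deriv_spec=RFSpec(6.0, 6.0),
        )
        assert rep.details["gradient_rms_relative_error"] < 0.01

    def test_excessive_stretch_rejected(self, noise_image_128):
        with pytest.raises(ConfigurationError, match="stretch"):
            verify_affine_covariance(
                noise_image_128, AffineMap(8.0, 0, 0, 1),
                SpatialCovariance.isotropic(4.0),
            )


@pytest.fixture(scope="module")
def grating_video():
    return make_stimulus(
        StimulusSpec(
            "grating", size=64, wavelength=12.0, orientation=0.5,
            frames=16, drift_velocity=(1.0, 0.5),
        )
    )


class TestVerifySpatioTemporal:
    def test_identity_zero_error(self, grating_video):
        spec = SpatioTemporalRFSpec(SpatialCovariance.isotropic(4.0), tau=1.0)
        rep = verify_spatiotemporal_covariance(grating_video, IDENTITY, spec)
        assert rep.interior_rms_relative_error == 0.0

    def test_diagonal_stretch(self, grating_video):
        spec = SpatioTemporalRFSpec(SpatialCovariance.isotropic(4.0), tau=1.0)
        rep = verify_spatiotemporal_covariance(
            grating_video, AffineMap(1.5, 0, 0, 1), spec
        )
        assert rep.interior_rms_relative_error < 0.02

    def test_static_video_reduces_to_spatial_check(self):
        frames = [
            make_stimulus(
                StimulusSpec("band_limited_noise", size=64, cutoff=8.0, seed=7)
            )
        ] * 12
        cov = SpatialCovariance.isotropic(3.0)
        spec = SpatioTemporalRFSpec(cov, tau=1.0, velocity=(0.0, 0.0))
        amap = AffineMap(1.2, 0, 0, 1)
        rep_st = verify_spatiotemporal_covariance(frames, amap, spec)
        rep_sp = verify_affine_covariance(frames[0], amap, cov, truncation=4.0)
        # same interior residual: temporal smoothing of identical frames
        # is the identity (weights sum to one)
        assert rep_st.interior_rms_relative_error == pytest.approx(
            rep_sp.interior_rms_relative_error, rel=1e-6
        )


class TestSteering:
    def test_first_order_axis_basis(self):
        theta = 0.7
        sol = steer_coefficients(1, theta, [0.0, math.pi / 2])
        assert sol.coefficients[0] == pytest.approx(math.cos(theta), abs=1e-14)
        assert sol.coefficients[1] == pytest.approx(math.sin(theta), abs=1e-14)
        assert sol.residual < 1e-12

    def test_target_on_basis_angle_selects_it(self):
        sol = steer_coefficients(2, math.pi / 3, [0.0, math.pi / 3, 2 * math.pi / 3])
        np.testing.assert_allclose(sol.coefficients, [0, 1, 0], atol=1e-12)

    def test_second_order_three_angles(self):
        sol = steer_coefficients(
            2, math.pi / 4, [0.0, math.pi / 3, 2 * math.pi / 3], (2.0, 1.0, 0.3)
        )
        assert sol.residual < 1e-10

    def test_repeated_angle_rejected(self):
        with pytest.raises(DegenerateBasisError, match="coincide"):
            steer_coefficients(2, 0.5, [0.2, 0.2 + math.pi, 1.0])

    def test_too_few_angles_rejected(self):
        with pytest.raises(DegenerateBasisError):
            steer_coefficients(2, 0.5, [0.0, 1.0])

    def test_nearly_parallel_angles_rejected(self):
        with pytest.raises(DegenerateBasisError):
            steer_coefficients(2, 0.5, [0.0, 1e-8, 1.0])

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_exactness_any_order_minimal_basis(self, m, rng):
        """m + 1 well-spread angles steer exactly at any order."""
        angles = np.pi / (m + 1) * np.arange(m + 1) + rng.uniform(0, 0.1)
        target = rng.uniform(-math.pi, math.pi)
        sol = steer_coefficients(m, target, angles, (1.5, 0.8, 0.2))
        assert sol.residual < 1e-10
        recon = sum(
            c * directional_basis_vector(m, a)
            for c, a in zip(sol.coefficients, angles)
        )
        np.testing.assert_allclose(
            recon, directional_basis_vector(m, target), atol=1e-10
        )

    def test_overdetermined_least_squares(self):
        sol = steer_coefficients(1, 0.3, [0.0, math.pi / 3, math.pi / 2])
        assert sol.residual < 1e-10


class TestMatchResponses:
    @staticmethod
    def _derivative_response(image, cov, theta):
        s1, s2, phi = shape_from_covariance(cov)
        w0 = _derivative_weights(cov, 0, image.spacing)
        w1 = _derivative_weights(cov, 1, image.spacing)
        kernel = math.cos(theta) * w0 + math.sin(theta) * w1
        return SampledField(
            _smooth_with_kernel(image, kernel), image.spacing, image.origin
        )

    def test_identity_map_selects_matching_angle(self, noise_image_128):
        cov = SpatialCovariance.isotropic(5.0)
        src = self._derivative_response(noise_image_128, cov, 0.0)
        targets = [
            self._derivative_response(noise_image_128, cov, a)
            for a in (0.0, math.pi / 2)
        ]
        sol = match_responses(src, targets, IDENTITY, 1,
                              basis_angles=[0.0, math.pi / 2], margin=30.0)
        np.testing.assert_allclose(sol.coefficients, [1.0, 0.0], atol=1e-10)
        assert sol.residual < 1e-10

    def test_rotation_first_order(self, noise_image_128):
        theta = 0.6
        rot = AffineMap.from_matrix(rotation_matrix(theta))
        cov = SpatialCovariance.isotropic(5.0)
        cov_t = transform_covariance(cov, rot)
        src = self._derivative_response(noise_image_128, cov, 0.0)
        warped = warp_image(noise_image_128, rot)
        targets = [
            self._derivative_response(warped, cov_t, a)
            for a in (0.0, math.pi / 2)
        ]
        sol = match_responses(src, targets, rot, 1,
                              basis_angles=[0.0, math.pi / 2], margin=40.0)
        # the source x1-derivative direction transforms by A^{-T} = R_theta
        assert sol.coefficients[0] == pytest.approx(math.cos(theta), abs=5e-3)
        assert sol.coefficients[1] == pytest.approx(math.sin(theta), abs=5e-3)
        assert sol.residual < 0.01

    def test_stretch_second_order(self, noise_image_128):
        amap = AffineMap(1.5, 0, 0, 1)
        cov = SpatialCovariance.isotropic(5.0)
        cov_t = transform_covariance(cov, amap)

        def second_derivative_response(image, c, theta):
            w0 = _derivative_weights(c, 0, image.spacing)
            w1 = _derivative_weights(c, 1, image.spacing)
            ct, st = math.cos(theta), math.sin(theta)
            kernel = ct * w0 + st * w1
            smoothed = _smooth_with_kernel(image, kernel)
            return SampledField(
                _smooth_with_kernel(
                    SampledField(smoothed, image.spacing, image.origin), kernel
                )
                / 2.0,
                image.spacing,
                image.origin,
            )

        # NB: applying the first-order kernel twice doubles the smoothing;
        # build source/targets consistently at Sigma and 2 Sigma halves.
        src = second_derivative_response(noise_image_128, cov, 0.3)
        warped = warp_image(noise_image_128, amap)
        targets = [
            second_derivative_response(warped, cov_t, a)
            for a in (0.0, math.pi / 3, 2 * math.pi / 3)
        ]
        sol = match_responses(src, targets, amap, 2,
                              basis_angles=[0.0, math.pi / 3, 2 * math.pi / 3],
                              margin=45.0)
        assert sol.residual < 0.02

    def test_degenerate_target_basis(self, noise_image_128):
        cov = SpatialCovariance.isotropic(5.0)
        src = self._derivative_response(noise_image_128, cov, 0.0)
        same = self._derivative_response(noise_image_128, cov, 0.4)
        with pytest.raises(DegenerateBasisError):
            match_responses(src, [same, same], IDENTITY, 1, margin=30.0)


class TestCascade:
    def test_zero_delta_is_identity(self, noise_image_96):
        out = cascade_smooth(noise_image_96, None)
        assert out is noise_image_96
        out2 = cascade_smooth(noise_image_96, np.zeros((2, 2)))
        np.testing.assert_array_equal(out2.values, noise_image_96.values)

    def test_cascade_matches_direct(self, noise_image_96):
        l1 = smooth(noise_image_96, SpatialCovariance.isotropic(1.0))
        cascaded = cascade_smooth(l1, SpatialCovariance.isotropic(1.0))
        direct = smooth(noise_image_96, SpatialCovariance(2.0, 2.0, 0.0))
        d = interior(cascaded.values - direct.values)
        r = interior(direct.values)
        assert rms_rel(d, r) < 0.005

    def test_cascade_of_derivative_response(self, noise_image_96):
        cov1 = SpatialCovariance.isotropic(1.5)
        resp = SampledField(
            _smooth_with_kernel(noise_image_96, _derivative_weights(cov1, 0, 1.0)),
            1.0,
            noise_image_96.origin,
        )
        cascaded = cascade_smooth(resp, SpatialCovariance(2.75, 2.75, 0.0))
        cov2 = SpatialCovariance.isotropic(math.sqrt(5.0))
        direct = SampledField(
            _smooth_with_kernel(noise_image_96, _derivative_weights(cov2, 0, 1.0)),
            1.0,
            noise_image_96.origin,
        )
        d = interior(cascaded.values - direct.values, 20)
        r = interior(direct.values, 20)
        assert rms_rel(d, r) < 0.005

    def test_indefinite_delta_rejected(self, noise_image_96):
        l1 = smooth(noise_image_96, SpatialCovariance.isotropic(1.0))
        with pytest.raises(CascadeInfeasibleError, match="eigenvalue"):
            cascade_smooth(l1, np.array([[1.0, 0.0], [0.0, -0.5]]))
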