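"""Hessian eigenvalues and the five vesselness responses."""

import numpy as np
import pytest
from scipy import ndimage

from mhmmseg.features import (
    DEFAULT_SCALES_MM,
    FeatureParams,
    HessianEigenvolumes,
    _single_scale_response,
    frangi_feature,
    gamma_from_eigenvalues,
    gamma_from_volume,
    hessian_eigenvalues,
    li_feature,
    manniesing_feature,
    multiscale_features,
    multiscale_max,
    sato_feature,
    shikata_feature,
)
from mhmmseg.volume import Volume

FEATS = ("sato", "frangi", "shikata", "li", "manniesing")


def eig_triple(l1, l2, l3, scale=1.0, shape=(1, 1, 1)):
    full = np.full
    return HessianEigenvolumes(full(shape, float(l1)), full(shape, float(l2)),
                               full(shape, float(l3)), scale)


class TestHessianEigenvalues:
    def test_constant_volume_all_zero(self):
        vol = Volume(np.full((12, 12, 12), 5.0), (1, 1, 1))
        eigs = hessian_eigenvalues(vol, 1.0)
        # tolerance reflects the truncated derivative-of-Gaussian kernel
        for lam in (eigs.lambda1, eigs.lambda2, eigs.lambda3):
            np.testing.assert_allclose(lam, 0.0, atol=1e-3 * vol.data.max())

    def test_quadratic_image_recovers_curvature(self):
        # I = x^2 has d2I/dx2 = 2 regardless of Gaussian smoothing
        sp = 0.5
        x = sp * np.arange(40)
        vol = Volume(np.broadcast_to((x**2)[:, None, None], (40, 40, 40)).copy(),
                     (sp, sp, sp))
        eigs = hessian_eigenvalues(vol, 1.0)
        c = (20, 20, 20)
        assert eigs.lambda1[c] == pytest.approx(2.0, rel=1e-5)
        assert abs(eigs.lambda2[c]) < 1e-5
        assert abs(eigs.lambda3[c]) < 1e-5

    def test_bright_gaussian_tube_eigen_structure(self):
        sp = 0.5
        coords = (np.arange(48) - 24) * sp
        X, Y = np.meshgrid(coords, coords, indexing="ij")
        sigma0 = 1.5
        tube = 100 * np.exp(-(X**2 + Y**2) / (2 * sigma0**2))
        vol = Volume(np.repeat(tube[:, :, None], 32, axis=2), (sp, sp, sp))
        eigs = hessian_eigenvalues(vol, sigma0)
        c = (24, 24, 16)
        assert abs(eigs.lambda1[c]) < 1e-3 * abs(eigs.lambda3[c])
        assert eigs.lambda2[c] < 0 and eigs.lambda3[c] < 0
        assert eigs.lambda2[c] == pytest.approx(eigs.lambda3[c], rel=1e-3)

    def test_matches_independent_pervoxel_solver(self, rng):
        vol = Volume(rng.normal(size=(16, 16, 16)), (1.0, 1.3, 0.8))
        s = 1.2
        eigs = hessian_eigenvalues(vol, s)
        # independent route: scipy eigh on an explicitly assembled Hessian
        sp = np.array(vol.spacing)
        sig = s / sp
        H = {}
        for (a, b), order in zip(
            [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)],
            [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
        ):
            H[(a, b)] = ndimage.gaussian_filter(
                vol.data - vol.data.mean(), sig, order=order, mode="nearest",
                truncate=6.0,
            ) / (sp[a] * sp[b])
        from scipy.linalg import eigh

        for idx in [(3, 4, 5), (8, 8, 8), (12, 3, 9)]:
            Hm = np.array([
                [H[(0, 0)][idx], H[(0, 1)][idx], H[(0, 2)][idx]],
                [H[(0, 1)][idx], H[(1, 1)][idx], H[(1, 2)][idx]],
                [H[(0, 2)][idx], H[(1, 2)][idx], H[(2, 2)][idx]],
            ])
            w = eigh(Hm, eigvals_only=True)[::-1]
            got = [eigs.lambda1[idx], eigs.lambda2[idx], eigs.lambda3[idx]]
            np.testing.assert_allclose(got, w, atol=1e-10)

    def test_ordering_convention(self, rng):
        vol = Volume(rng.normal(size=(10, 10, 10)), (1, 1, 1))
        eigs = hessian_eigenvalues(vol, 0.8)
        assert np.all(eigs.lambda1 >= eigs.lambda2)
        assert np.all(eigs.lambda2 >= eigs.lambda3)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            hessian_eigenvalues(Volume(np.zeros((4, 4, 4))), 0.0)


class TestFormulaValues:
    def test_sato_zero_when_lambda2_zero(self):
        assert sato_feature(eig_triple(-1, 0, -3))[0, 0, 0] == 0.0

    def test_sato_zero_exponent_case(self):
        # lambda1 = 0 kills the exponent, leaving |lambda2|
        assert sato_feature(eig_triple(0, -8, -9))[0, 0, 0] == pytest.approx(8.0)

    def test_sato_direct_evaluation(self):
        val = sato_feature(eig_triple(-1, -2, -3), FeatureParams())[0, 0, 0]
        assert val == pytest.approx(2 * np.exp(-0.5), rel=1e-12)

    def test_sato_uses_alpha2_for_positive_lambda1(self):
        v = sato_feature(eig_triple(1, -2, -3), FeatureParams())[0, 0, 0]
        assert v == pytest.approx(2 * np.exp(-1 / (2 * 4 * 4)), rel=1e-12)

    def test_frangi_zero_guard(self):
        assert frangi_feature(eig_triple(2, 1, -3))[0, 0, 0] == 0.0
        assert frangi_feature(eig_triple(0, -1, 3))[0, 0, 0] == 0.0

    def test_frangi_direct_evaluation(self):
        # lambda = (0, -10, -10): R_A = 1, R_B = 0, S = sqrt(200)
        gamma = 10.0
        val = frangi_feature(eig_triple(0, -10, -10), FeatureParams(), gamma=gamma)
        expect = (1 - np.exp(-1 / 0.5)) * 1.0 * (1 - np.exp(-200 / 200))
        assert val[0, 0, 0] == pytest.approx(expect, rel=1e-12)

    def test_frangi_in_unit_interval(self, rng):
        eigs = HessianEigenvolumes(*np.sort(rng.normal(size=(3, 50)), axis=0)[::-1],
                                   1.0)
        v = frangi_feature(eigs, FeatureParams(), gamma=1.0)
        assert np.all((v >= 0) & (v <= 1))

    def test_shikata_direct_evaluation(self):
        vol = Volume(np.full((1, 1, 1), 2.0))
        assert shikata_feature(vol, eig_triple(-1, -4, -5, scale=1.0))[0, 0, 0] \
            == pytest.approx(2.0)

    def test_shikata_zero_numerator(self):
        vol = Volume(np.full((1, 1, 1), 2.0))
        assert shikata_feature(vol, eig_triple(0, 0, -1))[0, 0, 0] == 0.0

    def test_shikata_s_squared_scaling(self):
        vol = Volume(np.full((1, 1, 1), 2.0))
        v1 = shikata_feature(vol, eig_triple(-1, -4, -5, scale=1.0))[0, 0, 0]
        v2 = shikata_feature(vol, eig_triple(-1, -4, -5, scale=2.0))[0, 0, 0]
        assert v2 == pytest.approx(4 * v1)

    def test_li_guard_positive_lambda1(self):
        assert li_feature(eig_triple(1, -2, -3))[0, 0, 0] == 0.0

    def test_li_direct_evaluation(self):
        assert li_feature(eig_triple(-1, -2, -3))[0, 0, 0] == pytest.approx(2.0)

    def test_li_zero_when_lambda2_equals_lambda3(self):
        assert li_feature(eig_triple(-1, -2, -2))[0, 0, 0] == 0.0

    def test_manniesing_zero_guard_includes_equality(self):
        assert manniesing_feature(eig_triple(-1, 0, -3))[0, 0, 0] == 0.0
        assert manniesing_feature(eig_triple(-1, -2, 0))[0, 0, 0] == 0.0

    def test_manniesing_small_c_limit_recovers_frangi_form(self):
        eigs = eig_triple(0, -10, -10)
        params = FeatureParams(c=1e-9)
        frangi = frangi_feature(eigs, FeatureParams(), gamma=10.0)[0, 0, 0]
        assert manniesing_feature(eigs, params, gamma=10.0)[0, 0, 0] \
            == pytest.approx(frangi, rel=1e-6)

    def test_manniesing_gate_monotone_in_c(self):
        eigs = eig_triple(0, -10, -10)
        lo = manniesing_feature(eigs, FeatureParams(c=1.0), gamma=10.0)[0, 0, 0]
        hi = manniesing_feature(eigs, FeatureParams(c=5.0), gamma=10.0)[0, 0, 0]
        assert hi < lo  # larger sensitivity suppresses the response


class TestGamma:
    def test_constant_volume_gamma_zero(self):
        assert gamma_from_volume(Volume(np.full((8, 8, 8), 3.0)), 1.0) == 0.0

    def test_half_of_max_frobenius_norm(self):
        eigs = eig_triple(-1, -2, -3)
        assert gamma_from_eigenvalues(eigs) == pytest.approx(np.sqrt(14) / 2)

    def test_invariant_to_constant_offset(self, rng):
        data = rng.normal(size=(12, 12, 12))
        g1 = gamma_from_volume(Volume(data), 1.0)
        g2 = gamma_from_volume(Volume(data + 100.0), 1.0)
        assert g1 == pytest.approx(g2, rel=1e-9)

    def test_degenerate_gamma_gives_unit_structureness(self):
        # all-zero Hessian: the S-term is defined as 1, so the response is
        # finite (and zero only through the other factors)
        v = frangi_feature(eig_triple(0, 0, 0), FeatureParams(), gamma=0.0)
        assert np.isfinite(v).all()


def make_tube(radius, ellipticity=1.15, sp=0.35, n=80, nz=28, contrast=100.0):
    coords = (np.arange(n) - n / 2) * sp
    X, Y, Z = np.meshgrid(coords, coords, coords[:nz], indexing="ij")
    tube = contrast * np.exp(-(X**2 + (Y / ellipticity) ** 2) / (2 * radius**2)) + 10
    tube *= np.exp(-((Z - Z.mean()) ** 2) / (2 * 20.0**2))
    return Volume(tube, (sp, sp, sp)), (n // 2, n // 2, nz // 2)


def scale_profile(vol, feature_id, center, params=None):
    """Response at one voxel for every scale, sharing the per-volume gamma."""
    params = params or FeatureParams()
    per_scale, gamma = [], 0.0
    for s in params.scales_mm:
        eigs = hessian_eigenvalues(vol, s)
        per_scale.append(eigs)
        gamma = max(gamma, gamma_from_eigenvalues(eigs.scaled(s**2)))
    return [
        _single_scale_response(vol, eigs, feature_id, params, gamma=gamma)[center]
        for eigs in per_scale
    ]


class TestMultiscale:
    def test_single_scale_schedule_equals_single_operation(self):
        vol, center = make_tube(1.2, n=48, nz=20)
        params = FeatureParams(scales_mm=(1.0,))
        ms = multiscale_max(vol, "sato", params)
        eigs = hessian_eigenvalues(vol, 1.0)
        single = sato_feature(eigs.scaled(1.0), params)
        np.testing.assert_allclose(ms.data, single, atol=1e-12)

    def test_responses_nonnegative_on_random_volumes(self, rng):
        vol = Volume(rng.normal(size=(20, 20, 20)), (0.7, 0.7, 0.7))
        feats = multiscale_features(vol)
        for name, f in feats.items():
            assert np.all(f.data >= 0), name
            assert np.isfinite(f.data).all(), name

    @pytest.mark.parametrize("radius", [0.85, 1.7])
    def test_argmax_scale_tracks_tube_radius(self, radius):
        vol, center = make_tube(radius)
        scales = np.array(DEFAULT_SCALES_MM)
        near = int(np.argmin(np.abs(np.log2(scales / radius))))
        for feat in FEATS:
            best = int(np.argmax(scale_profile(vol, feat, center)))
            assert abs(best - near) <= 1, feat

    def test_rotational_equivariance(self):
        vol, _ = make_tube(1.2, sp=0.5, n=40, nz=40)
        # make the tube's cross-section anisotropic in x-y, then rotate 90°
        resp = multiscale_max(vol, "sato").data
        rot = multiscale_max(Volume(np.rot90(vol.data, axes=(0, 1)).copy(),
                                    vol.spacing), "sato").data
        dyn = resp.max() - resp.min()
        assert np.max(np.abs(np.rot90(resp, axes=(0, 1)) - rot)) < 1e-3 * dyn

    def test_discrimination_on_phantom(self, straight_phantom, feature_volumes):
        labels = straight_phantom.labels.data
        axis_mask = labels == 1
        background = labels == 0
        for name, f in feature_volumes.items():
            assert f.data[axis_mask].mean() > f.data[background].mean(), name

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            multiscale_max(Volume(np.zeros((4, 4, 4))), "hessian2000")
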