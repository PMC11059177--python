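"""Dictionary construction and the regularized NNLS voxel fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from sandilite.dictionary_fit import (
    FitConfig,
    SANDIDictionary,
    SandiFitter,
    build_dictionary,
    default_radii,
    fit_volume,
    fit_voxel,
    soma_radius_estimate,
    spherical_mean,
)
from sandilite.forward_models import NoiseModel, add_rician_noise


class TestDictionary:
    def test_default_radii_grid(self):
        np.testing.assert_allclose(
            default_radii(),
            [1.5, 2.8125, 4.125, 5.4375, 6.75, 8.0625, 9.375, 10.6875, 12.0])

    def test_atom_count_and_classes(self, dict_connectom):
        assert len(dict_connectom.atoms) == 13
        assert dict_connectom.stick_mask.sum() == 1
        assert dict_connectom.sphere_mask.sum() == 9
        assert dict_connectom.ball_mask.sum() == 3

    def test_b0_row_is_all_ones(self, dict_prisma):
        np.testing.assert_array_equal(dict_prisma.matrix[0], 1.0)

    def test_entries_in_unit_interval(self, dict_connectom):
        assert np.all(dict_connectom.matrix > 0)
        assert np.all(dict_connectom.matrix <= 1.0)

    def test_degenerate_single_shell_scheme_rejected(self):
        from sandilite.acquisition import AcquisitionScheme, Measurement

        ms = [Measurement(0.0, (0, 0, 0), 0.0, 19.0, 36.0)]
        with pytest.raises(ValueError, match="2 shells"):
            build_dictionary(AcquisitionScheme(ms))

    def test_csv_cache_round_trip(self, dict_prisma, tmp_path):
        path = tmp_path / "dict.csv"
        dict_prisma.to_csv(path)
        loaded = SANDIDictionary.from_csv(path)
        np.testing.assert_allclose(loaded.matrix, dict_prisma.matrix, rtol=1e-12)
        assert [a.kind for a in loaded.atoms] == [a.kind for a in dict_prisma.atoms]
        assert loaded.scheme_fingerprint == dict_prisma.scheme_fingerprint


class TestSphericalMean:
    def test_constant_signal_maps_to_ones(self, prisma):
        out = spherical_mean(np.full(len(prisma), 0.7), prisma)
        np.testing.assert_allclose(out, 1.0)

    def test_pure_ball_matches_closed_form(self, prisma):
        sig = np.exp(-1e-3 * prisma.bvals * 3.0)
        out = spherical_mean(sig, prisma)
        b = prisma.shell_bvalues()
        np.testing.assert_allclose(out[1:], np.exp(-1e-3 * b[1:] * 3.0), rtol=1e-9)

    def test_within_shell_permutation_invariance(self, prisma, rng):
        sig = rng.uniform(0.2, 1.0, len(prisma))
        base = spherical_mean(sig, prisma)
        perm = sig.copy()
        _, idx = prisma.shells()[-1]
        perm[idx] = perm[np.random.default_rng(0).permutation(idx)]
        np.testing.assert_allclose(spherical_mean(perm, prisma), base, rtol=1e-12)

    def test_zero_b0_rejected(self, prisma):
        sig = np.ones(len(prisma))
        sig[prisma.bvals < 50] = 0.0
        with pytest.raises(ValueError, match="b0"):
            spherical_mean(sig, prisma)


class TestVoxelFit:
    def test_sphere_atoms_recovered_exactly(self, dict_connectom):
        cfg = FitConfig(lambda_l2=0.0)
        for j, atom in enumerate(dict_connectom.atoms):
            if atom.kind != "sphere":
                continue
            res = fit_voxel(dict_connectom.matrix[:, j], dict_connectom, cfg)
            assert res.residual_rmse < 1e-9
            assert res.f_soma == pytest.approx(1.0, abs=1e-9)
            assert res.R_hat == pytest.approx(atom.radius, abs=1e-9)

    def test_ball_atom_recovered(self, dict_connectom):
        cfg = FitConfig(lambda_l2=0.0)
        j = int(np.flatnonzero(dict_connectom.ball_mask)[-1])
        res = fit_voxel(dict_connectom.matrix[:, j], dict_connectom, cfg)
        assert res.f_extra == pytest.approx(1.0, abs=1e-9)
        assert res.f_soma == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(res.R_hat)

    def test_stick_sphere_mixture_low_residual(self, dict_connectom):
        j = int(np.flatnonzero(dict_connectom.sphere_radii == 8.0625)[0])
        sphere_col = dict_connectom.matrix[:, dict_connectom.sphere_mask][:, j]
        stick_col = dict_connectom.matrix[:, dict_connectom.stick_mask][:, 0]
        mix = 0.5 * stick_col + 0.5 * sphere_col
        res = fit_voxel(mix, dict_connectom, FitConfig(lambda_l2=0.0))
        assert res.residual_rmse < 1e-6

    def test_scale_invariance_of_fractions(self, dict_prisma, rng):
        powder = 0.3 * dict_prisma.matrix[:, 2] + 0.7 * dict_prisma.matrix[:, 11]
        a = fit_voxel(powder, dict_prisma)
        b = fit_voxel(powder * 7.3, dict_prisma)
        assert a.f_soma == pytest.approx(b.f_soma, abs=1e-9)
        assert a.f_neurite == pytest.approx(b.f_neurite, abs=1e-9)
        assert a.f_extra == pytest.approx(b.f_extra, abs=1e-9)

    @given(lam=st.floats(1e-4, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_regularization_shrinks_weights(self, dict_connectom, lam):
        powder = (0.4 * dict_connectom.matrix[:, 0]
                  + 0.6 * dict_connectom.matrix[:, 5])
        w0 = fit_voxel(powder, dict_connectom, FitConfig(lambda_l2=0.0)).weights
        w1 = fit_voxel(powder, dict_connectom, FitConfig(lambda_l2=lam)).weights
        assert np.linalg.norm(w1) <= np.linalg.norm(w0) + 1e-12

    def test_fractions_sum_to_one(self, dict_prisma, rng):
        noisy = add_rician_noise(dict_prisma.matrix[:, 6], NoiseModel(50), rng)
        res = fit_voxel(noisy, dict_prisma)
        assert res.f_soma + res.f_neurite + res.f_extra == pytest.approx(1.0,
                                                                         abs=1e-9)

    def test_negative_powder_clamped_with_warning(self, dict_prisma):
        powder = dict_prisma.matrix[:, 3].copy()
        powder[-1] = -0.01
        with pytest.warns(UserWarning, match="clamped"):
            fit_voxel(powder, dict_prisma)

    def test_all_zero_powder_rejected(self, dict_prisma):
        with pytest.raises(ValueError, match="all-zero"):
            fit_voxel(np.zeros(dict_prisma.matrix.shape[0]), dict_prisma)


class TestSomaRadiusEstimate:
    def test_point_mass(self, dict_connectom):
        w = np.zeros(13)
        w[5] = 1.0  # sphere radius 6.75 (atom 0 is the stick)
        assert dict_connectom.atoms[5].radius == 6.75
        assert soma_radius_estimate(w, dict_connectom) == 6.75

    def test_equal_extremes_average_to_midpoint(self, dict_connectom):
        w = np.zeros(13)
        w[1] = w[9] = 0.5  # radii 1.5 and 12.0
        assert soma_radius_estimate(w, dict_connectom) == pytest.approx(6.75)

    def test_weighted_mean(self, dict_connectom):
        w = np.zeros(13)
        w[3] = 0.25   # radius 4.125
        w[6] = 0.75   # radius 8.0625
        assert soma_radius_estimate(w, dict_connectom) == pytest.approx(7.078125)

    def test_undefined_without_sphere_weight(self, dict_connectom):
        w = np.zeros(13)
        w[0] = 1.0  # stick only
        assert np.isnan(soma_radius_estimate(w, dict_connectom))


class TestVolumeFit:
    def test_pure_ball_volume(self, prisma):
        sig = np.exp(-1e-3 * prisma.bvals * 3.0)
        dwi = np.tile(sig, (2, 2, 1, 1))
        mask = np.ones((2, 2, 1), dtype=bool)
        maps = fit_volume(dwi, mask, prisma)
        np.testing.assert_allclose(maps["f_extra"][mask], 1.0, atol=1e-6)
        np.testing.assert_allclose(maps["f_soma"][mask], 0.0, atol=1e-6)

    def test_empty_mask_gives_all_nan(self, prisma):
        dwi = np.ones((2, 2, 1, len(prisma)))
        maps = fit_volume(dwi, np.zeros((2, 2, 1), dtype=bool), prisma)
        for m in maps.values():
            assert np.all(np.isnan(m))

    def test_matches_direct_voxel_fit(self, prisma, dict_prisma, rng):
        dwi = rng.uniform(0.3, 1.0, (2, 1, 1, len(prisma)))
        mask = np.ones((2, 1, 1), dtype=bool)
        maps = fit_volume(dwi, mask, prisma)
        for i in range(2):
            powder = spherical_mean(dwi[i, 0, 0], prisma)
            res = fit_voxel(powder, dict_prisma)
            assert maps["f_soma"][i, 0, 0] == pytest.approx(res.f_soma, abs=1e-12)
            assert maps["residual"][i, 0, 0] == pytest.approx(res.residual_rmse,
                                                              abs=1e-12)

    def test_shape_mismatch_rejected(self, prisma):
        with pytest.raises(ValueError):
            fit_volume(np.ones((2, 2, 1, 3)), np.ones((2, 2, 1), dtype=bool),
                       prisma)


class TestSandiFitterEstimator:
    def test_sklearn_api_round_trip(self, connectom):
        est = SandiFitter(scheme=connectom, lambda_l2=0.01)
        params = est.get_params()
        assert params["lambda_l2"] == 0.01
        cloned = clone(est)
        assert cloned.get_params()["lambda_l2"] == 0.01
        cloned.set_params(lambda_l2=0.0)
        assert cloned.lambda_l2 == 0.0

    def test_fit_builds_dictionary(self, connectom):
        est = SandiFitter(scheme=connectom).fit()
        assert est.dictionary_.matrix.shape == (7, 13)
        assert est.n_shells_ == 7

    def test_transform_matches_fit_voxel(self, connectom, dict_connectom):
        est = SandiFitter(scheme=connectom, lambda_l2=0.0).fit()
        X = dict_connectom.matrix[:, [2, 5]].T
        out = est.transform(X)
        assert out.shape == (2, 5)
        np.testing.assert_allclose(out[:, 0], 1.0, atol=1e-9)   # f_soma
        radii = [dict_connectom.atoms[2].radius, dict_connectom.atoms[5].radius]
        np.testing.assert_allclose(out[:, 3], radii, atol=1e-9)  # R_hat

    def test_predict_returns_soma_fraction(self, connectom, dict_connectom):
        est = SandiFitter(scheme=connectom).fit()
        f = est.predict(dict_connectom.matrix[:, [4]].T)
        assert f[0] == pytest.approx(1.0, abs=1e-6)

    def test_unfitted_transform_raises(self, connectom):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            SandiFitter(scheme=connectom).transform(np.ones((1, 7)))
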