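"""SNR QC, the IVIM stages, the tensor fit and both pipelines."""

import dataclasses

import numpy as np
import pytest

import ivimdti as m
from ivimdti.fitting import (
    FitConfig,
    _c4,
    dti_design,
    estimate_snr,
    fit_dti_nlls,
    fit_ivim_mean,
    fit_ivim_voxelwise,
    qc_exclude,
    subtract_ivim,
)
from ivimdti.signal_model import AcquisitionScheme, DiffusionTensor, IVIMParams, ivim_dti_signal

from conftest import SMALL_GRID


def _uniform_study(scheme, tensor, f, d_star, shape=(3, 3, 2), s0=1.0):
    """Study whose every voxel carries the same noise-free signal."""
    sig = ivim_dti_signal(scheme, tensor, IVIMParams(f=f, d_star=d_star), s0=s0)
    signal = np.broadcast_to(sig, shape + (len(scheme),)).copy()
    return m.DWIStudy(signal, scheme, {"all": np.ones(shape, bool)})


class TestEstimateSnr:
    def test_noise_free_study_returns_infinite_sentinel(self, noise_free_study):
        assert estimate_snr(noise_free_study) == np.inf

    def test_recovers_target_snr_within_ten_percent(self):
        for target in (20.0, 45.0, 68.0):
            study = m.build_phantom(m.PhantomSpec(snr=target, seed=13))
            est = estimate_snr(study)
            assert est == pytest.approx(target, rel=0.10)
            assert study.mask_union().sum() >= 500

    def test_requires_two_b0_volumes(self, scheme):
        one_b0 = scheme.subset(np.r_[0, np.flatnonzero(scheme.bvals > 0)])
        sig = np.ones((2, 2, 2, len(one_b0)))
        study = m.DWIStudy(sig, one_b0, {"all": np.ones((2, 2, 2), bool)})
        with pytest.raises(ValueError, match="b = 0"):
            estimate_snr(study)

    def test_single_corrupted_voxel_drives_estimate_by_its_mask_share(self, scheme):
        shape = (4, 4, 1)
        sig = np.ones(shape + (len(scheme),))
        b0_idx = np.flatnonzero(scheme.bvals == 0)
        sig[0, 0, 0, b0_idx[0]] = 2.0  # only source of variance in the mask
        study = m.DWIStudy(sig, scheme, {"all": np.ones(shape, bool)})
        n_vox = 16
        n_rep = len(b0_idx)
        sd_corrupt = np.std(sig[0, 0, 0, b0_idx], ddof=1) / _c4(n_rep)
        mean_sig = sig[..., b0_idx].mean()
        assert estimate_snr(study) == pytest.approx(mean_sig / (sd_corrupt / n_vox), rel=1e-12)


class TestQcExclude:
    @pytest.mark.parametrize(
        "snr, excluded", [(19.9, True), (20.0, False), (np.inf, False), (0.0, True)]
    )
    def test_threshold_is_strict_less_than_twenty(self, snr, excluded):
        assert qc_exclude(snr) is excluded

    def test_threshold_is_configurable(self):
        cfg = FitConfig(snr_exclusion_threshold=30.0)
        assert qc_exclude(25.0, cfg)


class TestFitIvimMean:
    def test_noise_free_isotropic_recovery_is_exact(self, scheme):
        tensor = DiffusionTensor.from_eigen([1.8e-3] * 3)
        study = _uniform_study(scheme, tensor, f=0.06, d_star=0.03, s0=2.0)
        fit = fit_ivim_mean(study)
        assert fit.s0 == pytest.approx(2.0, rel=1e-6)
        assert fit.f == pytest.approx(0.06, abs=1e-6)
        assert fit.d == pytest.approx(1.8e-3, rel=1e-6)
        assert fit.d_star == pytest.approx(0.03, rel=1e-6)

    def test_zero_perfusion_pins_f_at_lower_bound(self, scheme):
        tensor = DiffusionTensor.from_eigen([2.0e-3, 1.6e-3, 1.3e-3])
        study = _uniform_study(scheme, tensor, f=0.0, d_star=0.03)
        fit = fit_ivim_mean(study)
        assert fit.f < 1e-6
        assert fit.d == pytest.approx(np.trace(tensor.matrix) / 3.0, rel=1e-6)

    def test_too_few_shells_rejected(self):
        scheme = AcquisitionScheme(
            np.array([0.0, 200.0, 600.0]),
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
        )
        sig = np.ones((2, 2, 1, 3))
        study = m.DWIStudy(sig, scheme, {"all": np.ones((2, 2, 1), bool)})
        with pytest.raises(ValueError, match="distinct b-values"):
            fit_ivim_mean(study)

    def test_noisy_fit_beats_grid_search_oracle(self, noisy_study):
        """Bounded NLLS must reach at least the best cost on a (f, D, D*) grid."""
        cfg = FitConfig()
        fit = fit_ivim_mean(noisy_study, config=cfg)
        bu, shell = noisy_study.scheme.shell_average(
            noisy_study.signal[noisy_study.mask_union()].mean(axis=0),
            kind=cfg.shell_average,
        )
        f_grid = np.linspace(0, 0.4, 41)
        d_grid = np.linspace(0.1e-3, 4e-3, 79)
        ds_grid = np.geomspace(3e-3, 300e-3, 61)
        model = (
            (1 - f_grid[:, None, None, None]) * np.exp(-bu * d_grid[None, :, None, None])
            + f_grid[:, None, None, None] * np.exp(-bu * ds_grid[None, None, :, None])
        )
        s0_hat = (model @ shell) / np.sum(model * model, axis=-1)
        cost = 0.5 * np.sum((s0_hat[..., None] * model - shell) ** 2, axis=-1)
        best = np.unravel_index(np.argmin(cost), cost.shape)
        assert fit.cost <= cost[best] + 1e-12
        assert fit.f == pytest.approx(f_grid[best[0]], abs=0.011)
        assert fit.d == pytest.approx(d_grid[best[1]], abs=1.1 * np.diff(d_grid)[0])


class TestFitIvimVoxelwise:
    def test_noise_free_voxel_recovery_is_exact(self, scheme):
        tensor = DiffusionTensor.from_eigen([1.7e-3] * 3)
        study = _uniform_study(scheme, tensor, f=0.08, d_star=0.025, shape=(2, 1, 1))
        maps = fit_ivim_voxelwise(study, d_star_fixed=0.025)
        assert maps.f[0, 0, 0] == pytest.approx(0.08, abs=1e-6)
        assert maps.d[0, 0, 0] == pytest.approx(1.7e-3, rel=1e-6)
        assert maps.s0[0, 0, 0] == pytest.approx(1.0, rel=1e-6)
        assert maps.converged.all()

    def test_zero_perfusion_voxel_sits_at_lower_bound(self, scheme):
        tensor = DiffusionTensor.from_eigen([1.7e-3] * 3)
        study = _uniform_study(scheme, tensor, f=0.0, d_star=0.03, shape=(1, 1, 1))
        maps = fit_ivim_voxelwise(study, d_star_fixed=0.03)
        assert maps.f[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_noisy_voxel_matches_two_parameter_grid_oracle(self, noisy_study):
        cfg = FitConfig()
        d_star = 0.03
        mask = np.zeros(noisy_study.grid_shape, bool)
        vox = tuple(np.argwhere(noisy_study.masks["injured"])[0])
        mask[vox] = True
        maps = fit_ivim_voxelwise(noisy_study, d_star, mask=mask, config=cfg)
        bu, shell = noisy_study.scheme.shell_average(
            noisy_study.signal[vox], kind=cfg.shell_average
        )
        f_grid = np.linspace(0, 0.4, 161)
        d_grid = np.linspace(0.1e-3, 4e-3, 391)
        model = (1 - f_grid[:, None, None]) * np.exp(-bu * d_grid[None, :, None]) + \
            f_grid[:, None, None] * np.exp(-bu * d_star)
        s0_hat = (model @ shell) / np.sum(model * model, axis=-1)
        cost = np.sum((s0_hat[..., None] * model - shell) ** 2, axis=-1)
        best = np.unravel_index(np.argmin(cost), cost.shape)
        assert maps.f[vox] == pytest.approx(f_grid[best[0]], abs=1.1 * np.diff(f_grid)[0])
        assert maps.d[vox] == pytest.approx(d_grid[best[1]], abs=1.1 * np.diff(d_grid)[0])


class TestSubtractIvim:
    def test_zero_fraction_is_identity(self, scheme):
        sig = np.linspace(1, 0.2, len(scheme))
        out = subtract_ivim(sig, scheme, s0_ivim=1.0, f=0.0, d_star=0.03)
        assert np.array_equal(out, sig)

    def test_exact_cancellation_of_generating_perfusion(self, scheme):
        tensor = DiffusionTensor.from_eigen([2.1e-3, 1.6e-3, 1.4e-3])
        f, ds, s0 = 0.07, 0.04, 1.3
        sig = ivim_dti_signal(scheme, tensor, IVIMParams(f=f, d_star=ds), s0=s0)
        out = subtract_ivim(sig, scheme, s0_ivim=s0, f=f, d_star=ds)
        q = np.einsum("mi,ij,mj->m", scheme.bvecs, tensor.matrix, scheme.bvecs)
        assert np.allclose(out, s0 * (1 - f) * np.exp(-scheme.bvals * q), rtol=1e-14)

    def test_matches_elementwise_hand_evaluation(self):
        scheme = AcquisitionScheme(
            np.array([0.0, 100.0, 400.0]),
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float),
        )
        sig = np.array([1.0, 0.9, 0.4])
        out = subtract_ivim(sig, scheme, s0_ivim=1.0, f=0.06, d_star=0.03)
        expected = sig - 0.06 * np.exp(-scheme.bvals * 0.03)
        assert np.allclose(out, expected, rtol=1e-15)


class TestFitDtiNlls:
    def test_noise_free_tensor_recovery_to_1e9(self, scheme):
        tensor = DiffusionTensor.from_eigen(
            [2.19e-3, 1.73e-3, 1.48e-3],
            DiffusionTensor(np.diag([1.0, 2.0, 3.0]) + 0.1).eigenvectors,
        )
        sig = 1.7 * np.exp(-np.einsum("mi,ij,mj->m", scheme.bvecs, tensor.matrix, scheme.bvecs) * scheme.bvals)
        fit = fit_dti_nlls(sig, scheme)
        assert np.allclose(fit.tensor.matrix, tensor.matrix, rtol=0, atol=1e-9 * 2.19e-3)
        assert fit.s0 == pytest.approx(1.7, rel=1e-9)

    def test_isotropic_signal_has_negligible_fa(self, scheme):
        sig = np.exp(-scheme.bvals * 1.8e-3)
        fit = fit_dti_nlls(sig, scheme)
        assert fit.tensor.fa < 1e-6

    def test_nlls_never_worsens_its_loglinear_start(self, noisy_study):
        mask = noisy_study.masks["healthy"]
        for vox in map(tuple, np.argwhere(mask)[:10]):
            fit = fit_dti_nlls(noisy_study.signal[vox], noisy_study.scheme)
            assert fit.cost <= fit.init_cost + 1e-12

    def test_rank_deficient_directions_rejected(self):
        bvals = np.r_[0.0, np.full(9, 400.0)]
        bvecs = np.zeros((10, 3))
        bvecs[1:5] = [1.0, 0.0, 0.0]
        bvecs[5:] = [0.0, 1.0, 0.0]
        scheme = AcquisitionScheme(bvals, bvecs)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_dti_nlls(np.ones(10), scheme)


class TestPipelines:
    def test_noise_free_per_voxel_recovery(self, noise_free_study, noise_free_fits):
        """Both pipelines hit the generating MD to 0.1% in every ROI voxel;
        the full fit recovers f within 0.005."""
        full, highb = noise_free_fits
        mask = noise_free_study.mask_union()
        truth = noise_free_study.truth
        for fit in (full, highb):
            rel = np.abs(fit.maps.md[mask] - truth["md"][mask]) / truth["md"][mask]
            assert np.nanmax(rel) < 1e-3
        for i in (1, 2, 3):
            lam = getattr(full.maps, f"l{i}")
            rel = np.abs(lam[mask] - truth[f"l{i}"][mask]) / truth[f"l{i}"][mask]
            assert np.nanmax(rel) < 1e-3
        assert np.nanmax(np.abs(full.maps.f[mask] - truth["f"][mask])) < 0.005

    def test_methods_coincide_without_perfusion(self):
        inj = m.TissueSpec.injured_baseline(f_mean=0.0, f_sd=0.0)
        heal = m.TissueSpec.healthy_baseline(f_mean=0.0, f_sd=0.0)
        study = m.build_phantom(m.PhantomSpec(snr=np.inf, seed=4, **SMALL_GRID), inj, heal)
        full = m.pipeline_full(study)
        highb = m.pipeline_highb(study)
        mask = study.mask_union()
        rel = np.abs(full.maps.md[mask] - highb.maps.md[mask]) / highb.maps.md[mask]
        assert np.nanmax(rel) < 0.005

    def test_high_b_retains_32_measurements(self, noise_free_fits):
        _, highb = noise_free_fits
        assert highb.flags["n_retained"] == 32

    def test_zero_threshold_equals_uncorrected_all_data_fit(self):
        study = m.build_phantom(m.PhantomSpec(snr=np.inf, seed=4, **SMALL_GRID))
        cfg = dataclasses.replace(FitConfig(), b_high_threshold=0.0)
        naive = m.pipeline_highb(study, config=cfg)
        assert naive.flags["n_retained"] == len(study.scheme)
        vox = tuple(np.argwhere(study.masks["injured"])[0])
        direct = fit_dti_nlls(study.signal[vox], study.scheme)
        assert naive.maps.md[vox] == pytest.approx(direct.tensor.md, rel=1e-12)

    def test_measurement_order_invariance(self):
        study = m.build_phantom(m.PhantomSpec(snr=35.0, seed=9, **SMALL_GRID))
        perm = np.random.default_rng(0).permutation(len(study.scheme))
        permuted = m.DWIStudy(
            study.signal[..., perm],
            study.scheme.subset(perm),
            dict(study.masks),
        )
        for pipeline in (m.pipeline_full, m.pipeline_highb):
            a = pipeline(study)
            b = pipeline(permuted)
            mask = study.mask_union()
            assert np.allclose(a.maps.md[mask], b.maps.md[mask], rtol=0, atol=1e-10)
            assert np.allclose(a.maps.l1[mask], b.maps.l1[mask], rtol=0, atol=1e-10)
            # FA passes the summation reordering through an eigendecomposition,
            # which amplifies float noise past the diffusivity tolerance
            assert np.allclose(a.maps.fa[mask], b.maps.fa[mask], rtol=0, atol=1e-8)

    def test_snr_and_exclusion_recorded(self, noisy_fits):
        full, highb = noisy_fits
        assert full.snr == pytest.approx(45, rel=0.1)
        assert not full.excluded
        assert highb.method == "high_b" and full.method == "full"
        assert highb.maps.f is None
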