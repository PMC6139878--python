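"""Fitting tests: naive fits, convolved fits, NEP ensemble fit, STED scaling."""

import numpy as np
import pytest

from nepfit.fitting import (
    ConvolvedProfileFitter,
    EnsemblePSFFitter,
    NaiveProfileFitter,
    STEDScalingFitter,
    ensemble_objective,
    fit_profile_convolved,
    fit_profile_naive,
    fit_sted_scaling,
    nep_fit,
    save_fit_results,
)
from nepfit.models import GeometrySpec, PhotometricParams, PSFSpec, forward_profile, psf_value
from nepfit.profiles import LineProfile
from nepfit.simulate import SimulationConfig, simulate_ensemble, simulate_profile


def _profile_from_model(geometry, psf, amplitude=100.0, background=2.0,
                        center=0.0, n=64, px=10.0):
    x = (np.arange(n) - (n - 1) / 2.0) * px
    y = forward_profile(x, geometry, psf,
                        PhotometricParams(amplitude, center, background))
    return LineProfile(x, y, px)


class TestNaiveFits:
    def test_recovers_exact_lorentzian(self):
        x = (np.arange(64) - 31.5) * 10.0
        y = 80.0 * psf_value(x - 12.0, PSFSpec("lorentzian", 50.0)) + 5.0
        r = fit_profile_naive(LineProfile(x, y, 10.0), "lorentzian")
        assert r.converged
        assert r.fwhm_reported == pytest.approx(50.0, abs=0.1)
        assert r.phot.center == pytest.approx(12.0, abs=0.1)
        assert r.mse == pytest.approx(0.0, abs=1e-6)

    def test_overestimates_width_of_finite_structures(self, microtubule_ensemble):
        """Bare peak fits absorb the tubule size into the width estimate."""
        gauss = [fit_profile_naive(p, "gaussian").fwhm_reported
                 for p in microtubule_ensemble.profiles]
        lorentz = [fit_profile_naive(p, "lorentzian").fwhm_reported
                   for p in microtubule_ensemble.profiles]
        assert np.mean(lorentz) > 50.0
        assert np.mean(gauss) > np.mean(lorentz)

    def test_flat_profile_does_not_converge(self):
        x = (np.arange(32) - 15.5) * 10.0
        r = fit_profile_naive(LineProfile(x, np.full(32, 9.0), 10.0))
        assert not r.converged


class TestConvolvedFits:
    def test_selffit_recovers_diameter_exactly(self):
        geom = GeometrySpec("filled_circle", 100.0)
        psf = PSFSpec("lorentzian", 50.0)
        p = _profile_from_model(geom, psf, center=3.0)
        r = fit_profile_convolved(p, "filled_circle", psf)
        assert r.converged
        assert r.diameter == pytest.approx(100.0, abs=0.05)
        assert r.phot.center == pytest.approx(3.0, abs=0.05)
        assert r.mse == pytest.approx(0.0, abs=1e-6)

    def test_too_wide_psf_is_compensated_by_smaller_diameter(self):
        """Width compensation, cross-checked against an exhaustive scan of
        the least-squares surface."""
        geom = GeometrySpec("filled_circle", 100.0)
        p = _profile_from_model(geom, PSFSpec("lorentzian", 50.0))
        wide = PSFSpec("lorentzian", 60.0)  # fixed 20% too wide
        r = fit_profile_convolved(p, "filled_circle", wide)
        assert r.converged
        assert r.diameter < 100.0

        # independent oracle: grid-evaluate the SSE over diameter, solving
        # amplitude/background by ordinary linear least squares
        def sse(d):
            shape = forward_profile(
                p.positions, GeometrySpec("filled_circle", d), wide,
                PhotometricParams(1.0, 0.0, 0.0),
            )
            design = np.column_stack([shape, np.ones_like(shape)])
            coef, *_ = np.linalg.lstsq(design, p.intensities, rcond=None)
            return np.sum((design @ coef - p.intensities) ** 2)

        grid = np.arange(70.0, 110.1, 0.5)
        best = grid[np.argmin([sse(d) for d in grid])]
        assert best < 100.0
        assert r.diameter == pytest.approx(best, abs=0.5)

    def test_psf_free_mode_fits_width_per_profile(self):
        geom = GeometrySpec("annulus_fixed_inner", 25.0)
        p = _profile_from_model(geom, PSFSpec("lorentzian", 50.0))
        f = ConvolvedProfileFitter(geometry="annulus_fixed_inner",
                                   psf_fwhm=40.0, psf_free=True).fit(p)
        assert f.converged_
        assert f.psf_fwhm_ == pytest.approx(50.0, abs=0.5)
        assert f.diameter_ == pytest.approx(25.0, abs=0.5)

    def test_diameter_pinned_at_bound_is_flagged(self):
        # data generated with a much narrower PSF than the fit assumes: the
        # only way down in MSE is to collapse the diameter to its bound
        geom = GeometrySpec("filled_circle", 20.0)
        p = _profile_from_model(geom, PSFSpec("lorentzian", 30.0))
        f = ConvolvedProfileFitter(geometry="filled_circle",
                                   psf_fwhm=120.0).fit(p)
        assert f.at_bound_
        assert not f.converged_


class TestEnsembleObjective:
    def test_zero_at_truth_on_noiseless_ensemble(self, noiseless_ensemble):
        mse = ensemble_objective(noiseless_ensemble, "annulus_fixed_inner", 50.0)
        assert mse == pytest.approx(0.0, abs=1e-6)

    def test_larger_away_from_truth(self, noiseless_ensemble):
        """The γ grid itself is the oracle: every off-truth γ costs MSE."""
        at_truth = ensemble_objective(noiseless_ensemble,
                                      "annulus_fixed_inner", 50.0)
        for gamma in (20.0, 35.0, 70.0, 120.0):
            assert ensemble_objective(noiseless_ensemble,
                                      "annulus_fixed_inner", gamma) > at_truth

    def test_single_profile_mean_is_its_mse(self, noiseless_ensemble):
        p = noiseless_ensemble.profiles[0]
        r = fit_profile_convolved(p, "annulus_fixed_inner",
                                  PSFSpec("lorentzian", 60.0))
        mse = ensemble_objective([p], "annulus_fixed_inner", 60.0)
        assert mse == pytest.approx(r.mse, rel=1e-9)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_objective([], "annulus_fixed_inner", 50.0)


class TestNEPFit:
    def test_noiseless_recovery_is_exact(self, noiseless_ensemble):
        res = nep_fit(noiseless_ensemble)
        assert res.psf_fwhm == pytest.approx(50.0, abs=0.2)
        np.testing.assert_allclose(res.diameters, 25.0, atol=0.1)
        assert res.diameter_sd < 0.05

    def test_mse_curve_minimum_is_at_gamma_star(self, noiseless_ensemble):
        fitter = EnsemblePSFFitter().fit(noiseless_ensemble)
        curve = np.array(fitter.mse_curve_)
        at_star = ensemble_objective(noiseless_ensemble,
                                     fitter.geometry_kind_, fitter.psf_fwhm_)
        assert np.all(at_star <= curve[:, 1] + 1e-12)

    def test_minimum_at_bound_raises(self, noiseless_ensemble):
        with pytest.raises(RuntimeError, match="bounds"):
            nep_fit(noiseless_ensemble, gamma_bounds=(80.0, 200.0))

    def test_too_few_profiles_rejected(self, noiseless_ensemble):
        with pytest.raises(ValueError):
            nep_fit(noiseless_ensemble.profiles[:1],
                    geometry_kind="annulus_fixed_inner")

    def test_geometry_mismatch_rejected(self, noiseless_ensemble):
        with pytest.raises(ValueError, match="geometry"):
            EnsemblePSFFitter(geometry="filled_circle").fit(noiseless_ensemble)

    def test_ensemble_constraint_narrows_diameter_spread(self,
                                                         microtubule_ensemble):
        """The global-PSF constraint reduces the diameter scatter relative to
        per-profile fits that free the PSF width."""
        nep = EnsemblePSFFitter().fit(microtubule_ensemble)
        free = ConvolvedProfileFitter(geometry="annulus_fixed_inner",
                                      psf_fwhm=50.0, psf_free=True)
        free_d = []
        for p in microtubule_ensemble.profiles:
            free.fit(p)
            if free.converged_:
                free_d.append(free.diameter_)
        assert nep.diameter_sd_ < np.std(free_d, ddof=1)

    def test_shared_diameter_mode_recovers_truth(self):
        cfg = SimulationConfig(
            geometry=GeometrySpec("annulus_fixed_inner", 25.0),
            psf=PSFSpec("lorentzian", 50.0),
            n_profiles=6, seed=21, shot_noise=False,
        )
        fitter = EnsemblePSFFitter(shared_diameter=True, n_grid=9,
                                   gamma_bounds=(20.0, 90.0))
        fitter.fit(simulate_ensemble(cfg))
        assert fitter.psf_fwhm_ == pytest.approx(50.0, abs=1.0)

    def test_results_persistence(self, tmp_path, noiseless_ensemble):
        import json

        res = nep_fit(noiseless_ensemble)
        save_fit_results(res, h5_path=tmp_path / "r.h5",
                         json_path=tmp_path / "r.json")
        summary = json.loads((tmp_path / "r.json").read_text())
        assert summary["psf_fwhm"] == pytest.approx(res.psf_fwhm)
        assert summary["diameter_mean"] == pytest.approx(res.diameter_mean)
        import h5py

        with h5py.File(tmp_path / "r.h5") as f:
            assert f["per_profile/diameter"].shape[0] == len(res.per_profile)


class TestDiameterPSFCoupling:
    def test_fitted_diameter_decreases_as_assumed_psf_widens(self):
        """Sweeping the fixed PSF width ±30% around truth trades diameter
        against resolution, more steeply for label-filled tubules than for a
        thin membrane shell."""
        gammas = np.arange(35.0, 65.1, 5.0)
        ranges = {}
        for kind in ("filled_circle", "annulus_fixed_shell"):
            cfg = SimulationConfig(
                geometry=GeometrySpec(kind, 100.0),
                psf=PSFSpec("lorentzian", 50.0),
                n_profiles=1, seed=7, n_pixels=96,
            )
            p = simulate_profile(cfg, 0)
            diams = np.array([
                ConvolvedProfileFitter(geometry=kind, psf_fwhm=g)
                .fit(p).diameter_
                for g in gammas
            ])
            assert np.all(np.diff(diams) < 0)
            ranges[kind] = diams.max() - diams.min()
        assert ranges["filled_circle"] > ranges["annulus_fixed_shell"]


class TestRecoveryAcrossReplicates:
    def test_mean_recovery_over_many_seeded_ensembles(self, psf_sweep):
        """Across >= 20 replicate ensembles spanning PSF widths 20-60 nm the
        NEP estimates are unbiased: the grand-mean diameter sits within 2 nm
        of the 25-nm truth and each width's mean γ* within 5% of truth."""
        widths = [w for w in psf_sweep if w <= 60]
        runs = [(w, res) for w in widths for _, res in psf_sweep[w]]
        assert len(runs) >= 20
        diam_means = [res.diameter_mean for _, res in runs]
        assert np.mean(diam_means) == pytest.approx(25.0, abs=2.0)
        for w in widths:
            mean_gamma = np.mean([res.psf_fwhm for _, res in psf_sweep[w]])
            assert abs(mean_gamma / w - 1.0) < 0.05

    def test_mse_curves_are_unimodal(self, psf_sweep):
        """The sampled mean-MSE-vs-γ curves have a single interior valley."""
        for _, res in psf_sweep[50]:
            mse = np.array([m for _, m in res.mse_curve])
            i = int(np.argmin(mse))
            assert 0 < i < mse.size - 1
            assert np.all(np.diff(mse[: i + 1]) < 0)
            assert np.all(np.diff(mse[i:]) > 0)


class TestSTEDScaling:
    def test_exact_recovery_of_scaling_constants(self):
        powers = np.array([0.0, 28.0, 56.0, 111.0])
        fwhms = 250.0 / np.sqrt(1.0 + powers / 10.0)
        alpha, i_sat, resid = fit_sted_scaling(powers, fwhms)
        assert alpha == pytest.approx(250.0, rel=1e-6)
        assert i_sat == pytest.approx(10.0, rel=1e-6)
        assert np.max(np.abs(resid)) < 1e-9

    def test_zero_power_gives_confocal_limit(self):
        est = STEDScalingFitter().fit([0.0, 20.0, 80.0],
                                      250.0 / np.sqrt(1.0 + np.array([0.0, 20.0, 80.0]) / 10.0))
        assert est.predict([0.0])[0] == pytest.approx(est.alpha_)

    def test_scale_invariance_of_power_axis(self):
        powers = np.array([5.0, 20.0, 80.0, 160.0])
        fwhms = 250.0 / np.sqrt(1.0 + powers / 10.0)
        a1, i1, _ = fit_sted_scaling(powers, fwhms)
        a2, i2, _ = fit_sted_scaling(2.0 * powers, fwhms)
        assert a2 == pytest.approx(a1, rel=1e-6)
        assert i2 == pytest.approx(2.0 * i1, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sted_scaling([0.0, 10.0], [250.0, 100.0])
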