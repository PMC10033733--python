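"""Forward-model fitting, uncertainty attribution and base-spectrum correction."""

import dataclasses

import numpy as np
import pytest

from qclpas.fitting import (
    CampaignModel,
    FittingError,
    IdentifiabilityError,
    correct_base_spectrum,
    BaseSpectrumCorrection,
    ensemble_check,
    fit_base_correction,
    fit_forward_model,
    parameter_relative_variance,
    residual_spectrum,
)
from qclpas.forward import (
    ForwardModelParams,
    amplification,
    simulate_pa_spectrum,
    sweep_grid,
)
from qclpas.instrument import (
    MatrixComposition,
    current_to_wavenumber,
    optical_power,
)
from qclpas.preprocess import scale_by_background, scaling_curve
from qclpas.spectral import CrossSection, GasComponent, WavenumberGrid, number_density
from qclpas.synthetic import ScenarioSpec, make_campaign


def _plan(seed, noise):
    states = [
        ("bg", MatrixComposition()),
        ("water1", MatrixComposition(x_h2o=0.9)),
        ("water2", MatrixComposition(x_h2o=1.24)),
        ("acetone", MatrixComposition(analytes={"acetone": 3.92})),
        ("ethanol", MatrixComposition(analytes={"ethanol": 7.9})),
    ]
    return [ScenarioSpec(m, lbl, seed * 100 + k, noise_sigma_uv=noise)
            for k, (lbl, m) in enumerate(states)]


def _campaign(seed, noise, library, tuning, power, params):
    return make_campaign(_plan(seed, noise), library, tuning, power, params)


class TestFitForwardModel:
    def test_noiseless_recovery_from_perturbed_init(self, library, tuning, power,
                                                    fwd_params):
        spectra = _campaign(0, 0.0, library, tuning, power, fwd_params)
        init = ForwardModelParams(c0=fwd_params.c0 * 1.1, c1=fwd_params.c1 * 0.9,
                                  c2=fwd_params.c2, d0=fwd_params.d0 * 1.1,
                                  d1=fwd_params.d1 * 0.9)
        tun0 = dataclasses.replace(tuning, t0=tuning.t0 + 0.003, t1=tuning.t1 * 1.01)
        fit = fit_forward_model(spectra, library, tun0, power, init)
        truth = {"c0": fwd_params.c0, "c1": fwd_params.c1, "d0": fwd_params.d0,
                 "d1": fwd_params.d1, "t0": tuning.t0, "t1": tuning.t1}
        for name, value in truth.items():
            assert fit.parameters[name] == pytest.approx(value, rel=1e-6)

    def test_coverage_of_reported_standard_errors(self, library, tuning, power,
                                                  fwd_params):
        # 2-sigma intervals cover the truth in >= 90% of seeded replicates
        truth = {"c0": fwd_params.c0, "c1": fwd_params.c1, "d0": fwd_params.d0,
                 "d1": fwd_params.d1, "t0": tuning.t0, "t1": tuning.t1}
        init = ForwardModelParams(c0=fwd_params.c0 * 1.05, c1=fwd_params.c1 * 0.95,
                                  c2=fwd_params.c2, d0=fwd_params.d0 * 1.05,
                                  d1=fwd_params.d1 * 0.95)
        tun0 = dataclasses.replace(tuning, t0=tuning.t0 + 0.002, t1=tuning.t1 * 1.005)
        cover = {n: 0 for n in truth}
        n_rep = 100
        for seed in range(n_rep):
            spectra = _campaign(seed, 0.5, library, tuning, power, fwd_params)
            fit = fit_forward_model(spectra, library, tun0, power, init)
            se = fit.standard_errors()
            for n, t in truth.items():
                if abs(fit.parameters[n] - t) <= 2 * se[n]:
                    cover[n] += 1
        for n, c in cover.items():
            assert c / n_rep >= 0.90, f"{n}: coverage {c}/{n_rep}"

    def test_flat_absorber_leaves_tuning_unidentifiable(self, library, tuning,
                                                        power, fwd_params):
        # acetone/background only: no spectral structure pins t0/t1
        flat = CrossSection(grid=library["acetone"].grid,
                            sigma=np.full(len(library["acetone"].grid), 1.9e-19),
                            species="acetone")
        lib = dict(library, acetone=flat)
        scens = [ScenarioSpec(MatrixComposition(analytes={"acetone": 3.92}),
                              "a", 1, noise_sigma_uv=0.0),
                 ScenarioSpec(MatrixComposition(), "bg", 2, noise_sigma_uv=0.0)]
        spectra = make_campaign(scens, lib, tuning, power, fwd_params)
        with pytest.raises(IdentifiabilityError, match="t0|t1"):
            fit_forward_model(spectra, lib, tuning, power, fwd_params,
                              free=("t0", "t1"))

    def test_relative_variance_regime(self, library, tuning, power, fwd_params):
        # well-conditioned campaign: background/amplification relative
        # variances sit in the few-percent-at-most regime
        spectra = _campaign(7, 0.5, library, tuning, power, fwd_params)
        fit = fit_forward_model(spectra, library, tuning, power, fwd_params)
        rel = parameter_relative_variance(fit)
        for name in ("c0", "c1", "d0", "d1"):
            assert rel[name] < 0.05

    def test_poorly_resolved_tuning_dominates_relative_variance(
            self, library, tuning, power, fwd_params):
        # weak spectral structure (very dilute water): the linear
        # transfer-function term carries far more relative variance than the
        # amplification terms
        scens = [ScenarioSpec(MatrixComposition(x_h2o=0.002), "w", 3,
                              noise_sigma_uv=0.5),
                 ScenarioSpec(MatrixComposition(), "bg", 4, noise_sigma_uv=0.5),
                 ScenarioSpec(MatrixComposition(analytes={"acetone": 3.92}), "a", 5,
                              noise_sigma_uv=0.5)]
        spectra = make_campaign(scens, library, tuning, power, fwd_params)
        fit = fit_forward_model(spectra, library, tuning, power, fwd_params)
        rel = parameter_relative_variance(fit)
        assert rel["t1"] > 10 * max(rel["d0"], rel["d1"], rel["c1"])

    def test_zero_covariance_gives_zero_relative_variance(self, library, tuning,
                                                          power, fwd_params):
        spectra = _campaign(0, 0.0, library, tuning, power, fwd_params)
        fit = fit_forward_model(spectra, library, tuning, power, fwd_params)
        fit0 = dataclasses.replace(fit, covariance=np.zeros_like(fit.covariance))
        rel = parameter_relative_variance(fit0)
        assert all(v == 0.0 for v in rel.values())


class TestEnsembleCheck:
    def test_linear_config_matches_covariance(self, library, tuning, power,
                                              fwd_params):
        spectra = _campaign(11, 0.5, library, tuning, power, fwd_params)
        free = ("c0", "c1", "d0", "d1")  # linear in the model
        fit = fit_forward_model(spectra, library, tuning, power, fwd_params,
                                free=free)
        model = CampaignModel(spectra, library, tuning, power, fwd_params, free=free)
        theta0 = np.array([fit.parameters[n] for n in free])
        summary = ensemble_check(model, theta0, noise_sigma_uv=fit.noise_sigma_uv,
                                 n_walkers=32, n_steps=3000, seed=5)
        se = fit.standard_errors()
        for i, n in enumerate(free):
            assert summary.std[i] == pytest.approx(se[n], rel=0.10)

    def test_seed_determinism(self, library, tuning, power, fwd_params):
        spectra = _campaign(11, 0.5, library, tuning, power, fwd_params)
        free = ("c0", "d0")
        model = CampaignModel(spectra, library, tuning, power, fwd_params, free=free)
        theta0 = model.x0
        a = ensemble_check(model, theta0, 0.5, n_walkers=8, n_steps=300, seed=9)
        b = ensemble_check(model, theta0, 0.5, n_walkers=8, n_steps=300, seed=9)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.std, b.std)

    def test_transfer_function_pair_strongly_correlated(self, library, tuning,
                                                        power, fwd_params):
        scens = [ScenarioSpec(MatrixComposition(x_h2o=0.9), "w", 21, noise_sigma_uv=0.5),
                 ScenarioSpec(MatrixComposition(), "bg", 22, noise_sigma_uv=0.5)]
        spectra = make_campaign(scens, library, tuning, power, fwd_params)
        free = ("t0", "t1")
        fit = fit_forward_model(spectra, library, tuning, power, fwd_params, free=free)
        model = CampaignModel(spectra, library, tuning, power, fwd_params, free=free)
        theta0 = np.array([fit.parameters[n] for n in free])
        summary = ensemble_check(model, theta0, noise_sigma_uv=fit.noise_sigma_uv,
                                 n_walkers=8, n_steps=500, seed=3)
        assert abs(summary.correlation[0, 1]) > 0.9


class TestBaseSpectrumCorrection:
    def test_identity_correction(self, library):
        base = library["ethanol"]
        out = correct_base_spectrum(base, BaseSpectrumCorrection(factor=1.0))
        np.testing.assert_array_equal(out.sigma, base.sigma)

    def test_global_factor_only(self, library):
        base = library["ethanol"]
        out = correct_base_spectrum(base, BaseSpectrumCorrection(factor=0.965))
        np.testing.assert_allclose(out.sigma, 0.965 * base.sigma, rtol=1e-12)

    def test_values_outside_window_unchanged_bit_exact(self, library):
        base = library["ethanol"]
        corr = BaseSpectrumCorrection(
            factor=1.0, window=(1209.6, 1210.1),
            knots=np.linspace(1209.6, 1210.1, 5),
            knot_values=np.array([1.0, 0.95, 0.9, 0.95, 1.0]))
        out = correct_base_spectrum(base, corr)
        outside = (base.grid.values < 1209.6) | (base.grid.values > 1210.1)
        np.testing.assert_array_equal(out.sigma[outside], base.sigma[outside])
        inside = ~outside
        assert np.any(out.sigma[inside] != base.sigma[inside])

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(Exception):
            BaseSpectrumCorrection(factor=0.0)

    def test_shape_mismatch_correction_improves_mae_tenfold(
            self, library, tuning, power, fwd_params, sweep):
        # synthetic shape-mismatch scenario: the reference ethanol spectrum
        # differs from the instrument's effective spectrum by a tank factor
        # 0.965 and a smooth local dip; fitting the correction shrinks the
        # 1-ppmv-normalized residual MAE by well over 10x
        base = library["ethanol"]
        tun = dataclasses.replace(tuning, emission_fwhm=1e-5)
        lo, hi = 1209.6, 1210.1
        x = base.grid.values
        bump = np.ones_like(x)
        ins = (x >= lo) & (x <= hi)
        bump[ins] = 1 - 0.08 * np.sin(np.pi * (x[ins] - lo) / (hi - lo)) ** 2
        true_xs = CrossSection(grid=base.grid, sigma=base.sigma * 0.965 * bump)

        conc = 7.9e-6
        grid = sweep_grid(tun, sweep, step=0.0005, margin=0.01)
        meas = simulate_pa_spectrum([GasComponent("ethanol", conc, true_xs)],
                                    tun, power, fwd_params, sweep, grid=grid)
        sim0 = simulate_pa_spectrum([GasComponent("ethanol", conc, base)],
                                    tun, power, fwd_params, sweep, grid=grid)
        mae0 = np.mean(np.abs(residual_spectrum(sim0, meas, 7.9)))

        # reconstruct the effective cross-section from the scaled measurement
        bg = simulate_pa_spectrum([], tun, power, fwd_params, sweep, grid=grid)
        scaled = scale_by_background(meas, scaling_curve(bg))
        alpha = ((scaled.magnitudes - bg.magnitudes.max())
                 / (amplification(sweep, fwd_params) * optical_power(495.0, power)))
        n = number_density(conc, 308.15, 101325.0)
        nus = current_to_wavenumber(sweep, tun)
        snapped = grid.values[np.argmin(np.abs(grid.values[None, :] - nus[:, None]),
                                        axis=1)]
        gsel = (x >= snapped.min() - 0.005) & (x <= snapped.max() + 0.005)
        gfit = WavenumberGrid(x[gsel])
        obs = CrossSection(grid=gfit, sigma=np.maximum(
            np.interp(gfit.values, snapped[::-1], (alpha / n)[::-1]), 0.0))
        base_fit = CrossSection(grid=gfit, sigma=base.sigma[gsel])

        corr = fit_base_correction(base_fit, obs, (lo, hi), n_knots=7)
        assert corr.factor == pytest.approx(0.965, abs=1e-3)
        corrected = correct_base_spectrum(base_fit, corr)
        sim1 = simulate_pa_spectrum([GasComponent("ethanol", conc, corrected)],
                                    tun, power, fwd_params, sweep, grid=gfit)
        mae1 = np.mean(np.abs(residual_spectrum(sim1, meas, 7.9)))
        assert mae0 / mae1 >= 10.0


class TestResidualSpectrum:
    def test_identical_spectra_zero(self, library, tuning, power, fwd_params, sweep):
        spec = simulate_pa_spectrum([GasComponent("ethanol", 1e-6, library["ethanol"])],
                                    tuning, power, fwd_params, sweep)
        np.testing.assert_array_equal(residual_spectrum(spec, spec, 1.0), 0.0)

    def test_tank_error_signature_is_constant_offset(self, library, tuning, power,
                                                     fwd_params, sweep):
        # -3.5% concentration error on a flat absorber: constant negative
        # residual after normalization
        flat = CrossSection(grid=library["acetone"].grid,
                            sigma=np.full(len(library["acetone"].grid), 2.0e-20))
        full = simulate_pa_spectrum([GasComponent("ethanol", 1e-6, flat)],
                                    tuning, power, fwd_params, sweep)
        short = simulate_pa_spectrum([GasComponent("ethanol", 0.965e-6, flat)],
                                     tuning, power, fwd_params, sweep)
        res = residual_spectrum(full, short, 1.0)
        assert np.all(res > 0)  # simulation overestimates the weak tank

    def test_normalization_collapses_concentrations(self, library, tuning, power,
                                                    fwd_params, sweep):
        base = library["ethanol"]
        residuals = []
        for ppmv in (1.0, 2.0, 4.0):
            sim = simulate_pa_spectrum([GasComponent("ethanol", ppmv * 1e-6, base)],
                                       tuning, power, fwd_params, sweep)
            meas = simulate_pa_spectrum(
                [GasComponent("ethanol", ppmv * 0.95e-6, base)],
                tuning, power, fwd_params, sweep)
            residuals.append(residual_spectrum(sim, meas, ppmv, normalize_to=1.0))
        np.testing.assert_allclose(residuals[0], residuals[1], rtol=1e-9)
        np.testing.assert_allclose(residuals[0], residuals[2], rtol=1e-9)
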