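import numpy as np
import pytest

from depscreen.bli_kinetics import (align_interstep, analyze_sensorgram_set,
                                    association_response,
                                    derive_rate_constants,
                                    dissociation_response,
                                    double_reference_subtract,
                                    fit_observed_rates,
                                    fit_steady_state, preprocess_set,
                                    smooth_sensorgram, steady_state_response)
from depscreen.errors import (AlignmentError, DegenerateFitError, FitError,
                              InsufficientDataError, ParameterError)
from depscreen.io_formats import Sensorgram
from depscreen.synthetic_data import simulate_sensorgrams


def make_curve(signal, t=None, conc=50e-9, t_assoc=0.0, t_diss=30.0,
               **kw):
    if t is None:
        t = np.arange(-5.0, 60.0, 0.5)
    return Sensorgram(time_s=t, response=signal, analyte_concentration_M=conc,
                      association_start_s=t_assoc, dissociation_start_s=t_diss,
                      **kw)


def model_curve(kobs=0.05, req=1.0, koff=1e-2, t=None):
    if t is None:
        t = np.arange(-5.0, 60.0, 0.5)
    r = np.zeros_like(t)
    assoc = (t >= 0) & (t < 30.0)
    diss = t >= 30.0
    r[assoc] = req * (1 - np.exp(-kobs * t[assoc]))
    rend = req * (1 - np.exp(-kobs * 30.0))
    r[diss] = rend * np.exp(-koff * (t[diss] - 30.0))
    return make_curve(r, t=t)


class TestDoubleReferenceSubtraction:
    def test_identical_curves_cancel_exactly(self):
        c = model_curve()
        out = double_reference_subtract(c, c.with_response(c.response),
                                        c.with_response(c.response),
                                        c.with_response(c.response))
        np.testing.assert_array_equal(out.response, np.zeros_like(c.time_s))

    def test_flat_references_reduce_to_baseline_alignment(self):
        c = model_curve()
        shifted = c.with_response(c.response + 0.7)
        flat = make_curve(np.zeros_like(c.time_s))
        out = double_reference_subtract(shifted, flat, flat, flat)
        np.testing.assert_allclose(out.response, c.response, atol=1e-12)

    def test_constructed_drift_recovered(self):
        ss, truth = simulate_sensorgrams(
            1e5, 1e-2, 1.0, [50e-9], t_assoc_s=60, t_dissoc_s=60, dt_s=0.2,
            noise_sd=0.0, drift_per_s=0.01, rng_seed=4)
        sample = ss.sample_curves()[0]
        corrected = double_reference_subtract(
            sample, ss.reference_for(sample), ss.zero_analyte(False),
            ss.zero_analyte(True))
        clean, _ = simulate_sensorgrams(
            1e5, 1e-2, 1.0, [50e-9], t_assoc_s=60, t_dissoc_s=60, dt_s=0.2,
            noise_sd=0.0, drift_per_s=0.0, rng_seed=4)
        assert np.max(np.abs(corrected.response
                             - clean.sample_curves()[0].response)) < 1e-9

    def test_mismatched_grids_refuse_interpolation(self):
        a = model_curve()
        b = model_curve(t=np.arange(-5.0, 60.0, 0.25))
        with pytest.raises(AlignmentError):
            double_reference_subtract(a, b, b, b)


class TestSmoothing:
    def test_low_order_polynomial_preserved(self):
        t = np.arange(-5.0, 60.0, 0.5)
        sig = 0.3 + 0.02 * t + 0.001 * t**2 - 1e-5 * t**3
        c = make_curve(sig.copy(), t=t)
        out = smooth_sensorgram(c, window_points=11, poly_order=3)
        np.testing.assert_allclose(out.response, sig, atol=1e-10)

    def test_window_one_is_identity(self):
        c = model_curve()
        out = smooth_sensorgram(c, window_points=1, poly_order=0)
        np.testing.assert_array_equal(out.response, c.response)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(6)
        c = make_curve(rng.standard_normal(130))
        out = smooth_sensorgram(c, window_points=11, poly_order=3)
        for phase in ("association", "dissociation"):
            m = c.phase_mask(phase)
            assert out.response[m].var() < c.response[m].var()

    @pytest.mark.parametrize("window, order", [(10, 3), (-1, 0), (5, 7)])
    def test_invalid_parameters_rejected(self, window, order):
        with pytest.raises(ParameterError):
            smooth_sensorgram(model_curve(), window, order)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ParameterError):
            smooth_sensorgram(model_curve(), 1001, 3)


class TestInterstepAlignment:
    def test_step_discontinuity_removed(self):
        c = model_curve()
        stepped = c.response.copy()
        stepped[c.phase_mask("dissociation")] -= 0.25
        out = align_interstep(c.with_response(stepped), edge_points=11)
        np.testing.assert_allclose(out.response, c.response, atol=1e-4)

    def test_continuous_curve_nearly_unchanged(self):
        c = model_curve()
        out = align_interstep(c, edge_points=11)
        assert np.max(np.abs(out.response - c.response)) < 1e-4


class TestObservedRates:
    def test_noiseless_kobs_recovery(self):
        c = model_curve(kobs=0.05, req=1.0)
        fit = fit_observed_rates(c, 20.0, 20.0)
        assert fit.kobs == pytest.approx(0.05, rel=1e-6)
        assert fit.req_window == pytest.approx(1.0, rel=1e-6)

    def test_flat_association_is_degenerate(self):
        c = model_curve(req=0.0)
        with pytest.raises(DegenerateFitError):
            fit_observed_rates(c)

    def test_flat_dissociation_flagged_as_lower_bound(self):
        c = model_curve(koff=0.0)
        fit = fit_observed_rates(c)
        assert abs(fit.koff) < 1e-8
        assert "koff_at_lower_bound" in fit.flags

    def test_noisy_kobs_matches_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        t = np.arange(-5.0, 60.0, 0.1)
        c = model_curve(kobs=0.08, req=1.0, t=t)
        noisy = c.with_response(c.response + 0.01 * rng.standard_normal(t.size))
        fit = fit_observed_rates(noisy, 20.0, 20.0)
        assert fit.kobs == pytest.approx(0.08, rel=0.05)
        # dense 2-D grid search over (Req, kobs) as the independent oracle
        mask = noisy.phase_mask("association")
        tau = noisy.time_s[mask]
        sel = tau <= 20.0
        tau, y = tau[sel], noisy.response[mask][sel]
        reqs = np.linspace(0.5, 1.5, 201)
        kobss = np.linspace(0.01, 0.2, 381)
        sse = ((reqs[:, None, None]
                * (1 - np.exp(-kobss[None, :, None] * tau[None, None, :]))
                - y[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.kobs == pytest.approx(kobss[j], abs=(kobss[1] - kobss[0]))

    def test_too_few_points_in_window(self):
        t = np.arange(-5.0, 60.0, 6.0)
        c = model_curve(t=t)
        with pytest.raises(InsufficientDataError):
            fit_observed_rates(c, assoc_fit_window_s=20.0)


class TestDeriveRateConstants:
    def test_exact_line_recovered(self):
        concs = [25e-9, 50e-9, 100e-9, 200e-9]
        kobs = [(c, 1e5 * c + 0.01) for c in concs]
        fit = derive_rate_constants(kobs, [0.01] * 4)
        assert fit.kon == pytest.approx(1e5, rel=1e-9)
        assert fit.koff_intercept == pytest.approx(0.01, rel=1e-9)
        assert fit.koff == pytest.approx(0.01, rel=1e-12)
        assert fit.kd_kinetic == pytest.approx(1e-7, rel=1e-9)

    def test_kd_equals_koff_over_kon(self):
        concs = [25e-9, 50e-9, 100e-9]
        fit = derive_rate_constants([(c, 2e5 * c + 0.02) for c in concs],
                                    [0.019, 0.021, 0.02])
        assert fit.kd_kinetic == fit.koff / fit.kon

    def test_two_concentrations_insufficient(self):
        with pytest.raises(InsufficientDataError):
            derive_rate_constants([(25e-9, 0.01), (50e-9, 0.02)],
                                  [0.01, 0.01])

    def test_negative_slope_rejected(self):
        concs = [25e-9, 50e-9, 100e-9]
        with pytest.raises(FitError, match="kon"):
            derive_rate_constants([(c, 0.05 - 1e5 * c) for c in concs],
                                  [0.01] * 3)

    def test_inverse_variance_weighting_favors_precise_curves(self):
        concs = [25e-9, 50e-9, 100e-9]
        kobs = [(c, 1e5 * c + 0.01) for c in concs]
        fit = derive_rate_constants(kobs, [0.5, 0.0101, 0.0099],
                                    koff_se=[10.0, 1e-4, 1e-4])
        assert fit.koff == pytest.approx(0.01, rel=1e-2)


class TestSteadyState:
    def test_half_saturation_identity(self):
        kd = 1e-7
        assert steady_state_response(kd, kd, 2.0) == pytest.approx(
            1.0, rel=1e-15)

    def test_exact_hyperbola_recovered(self):
        concs = np.array([25, 50, 100, 200, 400]) * 1e-9
        reqs = steady_state_response(concs, 100e-9, 2.0)
        fit = fit_steady_state(list(zip(concs, reqs)))
        assert fit.kd == pytest.approx(100e-9, rel=1e-8)
        assert fit.rmax == pytest.approx(2.0, rel=1e-8)

    def test_monotone_increasing_and_bounded(self):
        kd, rmax = 5e-8, 1.7
        c = np.logspace(-10, -4, 200)
        resp = steady_state_response(c, kd, rmax)
        assert np.all(np.diff(resp) > 0)
        assert np.all(resp < rmax)
        assert steady_state_response(1e6 * kd, kd, rmax) == pytest.approx(
            rmax, rel=1e-4)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(9)
        concs = np.array([25, 50, 100, 200, 400]) * 1e-9
        reqs = steady_state_response(concs, 100e-9, 2.0)
        noisy = reqs * (1 + 0.02 * rng.standard_normal(concs.size))
        fit = fit_steady_state(list(zip(concs, noisy)))
        assert fit.kd == pytest.approx(100e-9, rel=0.10)
        kds = np.linspace(20e-9, 400e-9, 950)
        rmaxs = np.linspace(1.0, 3.0, 400)
        sse = ((rmaxs[None, :, None] * concs[None, None, :]
                / (kds[:, None, None] + concs[None, None, :])
                - noisy[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.kd == pytest.approx(kds[i], abs=2 * (kds[1] - kds[0]))

    def test_nonpositive_responses_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_steady_state([(25e-9, -0.1), (50e-9, 0.0), (100e-9, -0.2)])

    def test_too_few_concentrations(self):
        with pytest.raises(InsufficientDataError):
            fit_steady_state([(25e-9, 0.1), (50e-9, 0.2)])


class TestPipeline:
    def test_noiseless_recovery_to_1e6(self):
        concs = [12.5e-9, 25e-9, 50e-9, 100e-9, 200e-9]
        sset, _ = simulate_sensorgrams(1e5, 1e-2, 1.0, concs,
                                       noise_sd=0.0, rng_seed=1)
        res = analyze_sensorgram_set(sset)
        assert res.kinetic_global.kon == pytest.approx(1e5, rel=1e-6)
        assert res.kinetic_global.koff == pytest.approx(1e-2, rel=1e-6)
        assert res.steady_state.kd == pytest.approx(1e-7, rel=1e-6)
        assert res.steady_state.rmax == pytest.approx(1.0, rel=1e-6)
        assert res.kinetic_per_curve.kon == pytest.approx(1e5, rel=1e-6)
        assert res.kinetic_per_curve.koff == pytest.approx(1e-2, rel=1e-6)

    def test_kobs_linear_in_concentration_noiseless(self):
        concs = [12.5e-9, 25e-9, 50e-9, 100e-9, 200e-9]
        sset, _ = simulate_sensorgrams(1e5, 1e-2, 1.0, concs,
                                       noise_sd=0.0, rng_seed=1)
        curves = preprocess_set(sset)
        pts = [(c.analyte_concentration_M,
                fit_observed_rates(c).kobs) for c in curves]
        x = np.array([c for c, _ in pts])
        y = np.array([k for _, k in pts])
        r = np.corrcoef(x, y)[0, 1]
        assert r ** 2 > 0.999

    def test_noisy_recovery_within_tolerance(self):
        concs = [12.5e-9, 25e-9, 50e-9, 100e-9, 200e-9]
        sset, _ = simulate_sensorgrams(1e5, 1e-2, 1.0, concs, noise_sd=0.01,
                                       drift_per_s=5e-4, rng_seed=12)
        res = analyze_sensorgram_set(sset)
        assert res.kon == pytest.approx(1e5, rel=0.05)
        assert res.koff == pytest.approx(1e-2, rel=0.05)
        assert res.steady_state.kd == pytest.approx(1e-7, rel=0.10)
        assert res.steady_state.rmax == pytest.approx(1.0, rel=0.10)
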