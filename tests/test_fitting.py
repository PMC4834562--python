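"""Stage-level tests of the characterization pipeline.

Each stage is exercised on data generated from known parameters, so every
expected value is the generating truth (or arithmetic on the stage's own
closed-form model), never a fitted number taken on faith.
"""

import numpy as np
import pytest

from opsinkit import fitting as F
from opsinkit import synthgen as G
from opsinkit.fitting import (
    BiexponentialFit,
    FitConfig,
    RecoveryFit,
    UnidentifiableError,
    fit_activation_rates,
    fit_biexponential,
    fit_conductance,
    fit_models,
    fit_off_curves,
    fit_peak_recovery,
    fit_rectifier,
    weighted_single_rate,
)
from opsinkit.kinetics import f_v, v1_from_constraint
from opsinkit.photodata import align_peaks_to_first_offset
from opsinkit.stimuli import make_protocol


class TestFitRectifier:
    VS = np.array([-100.0, -70.0, -40.0, -10.0, 20.0, 50.0, 80.0])

    def synthetic_iss(self, E, v0, c=-0.01):
        v1 = v1_from_constraint(E, v0)
        return c * f_v(self.VS, E, v0, v1) * (self.VS - E) * -1

    def test_recovers_shape_parameters(self):
        Iss = self.synthetic_iss(E=0.0, v0=43.0)
        E, v0, v1 = fit_rectifier(self.VS, Iss)
        assert E == pytest.approx(0.0, abs=1.0)
        assert v0 == pytest.approx(43.0, rel=0.02)
        assert v1 == pytest.approx(17.1, rel=0.02)

    def test_six_state_synthetic_rectifier(self, chr2_6):
        data = G.generate(chr2_6, make_protocol("rectifier"))
        Vs = [pc.V for _k, pc in data]
        Iss = [pc.ss_ for _k, pc in data]
        E, v0, v1 = fit_rectifier(Vs, Iss)
        assert E == pytest.approx(0.0, abs=1.0)
        assert v0 == pytest.approx(43.0, rel=0.02)

    def test_linear_limit_gives_large_v0(self):
        c = 0.005
        Iss = c * (self.VS - 0.0)  # ohmic, no rectification
        E, v0, _v1 = fit_rectifier(self.VS, Iss)
        assert v0 > 1e3
        # f_v is then flat over the physiological range
        v1 = v1_from_constraint(E, v0)
        vals = f_v(self.VS, E, v0, v1)
        assert np.ptp(vals) / np.mean(vals) < 0.05

    def test_no_reversal_in_range_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_rectifier(self.VS, np.abs(self.synthetic_iss(0.0, 43.0)) + 0.1)

    def test_too_few_voltages_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_rectifier([-70.0, -40.0, 20.0, 50.0], [-1.0, -0.5, 0.3, 0.6])


class TestFitConductance:
    def test_exact_inversion(self):
        E, v0 = 0.0, 43.0
        v1 = v1_from_constraint(E, v0)
        g0_true, fom, v = 2.76e4, 0.71, -70.0
        I_peak = -(g0_true * fom * f_v(v, E, v0, v1) * abs(v - E) * 1e-6)
        assert fit_conductance(I_peak, v, E, v0, v1, f_open_max=fom) == \
            pytest.approx(g0_true, rel=1e-12)

    def test_fallback_path_uses_point_eight(self):
        E, v0 = 0.0, 43.0
        v1 = v1_from_constraint(E, v0)
        I_peak = -1.5
        expect = abs(I_peak) / (0.8 * f_v(-70.0, E, v0, v1) * 70.0 * 1e-6)
        assert fit_conductance(I_peak, -70.0, E, v0, v1) == pytest.approx(expect)

    def test_trial_at_reversal_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_conductance(-1.0, 0.0, 0.0, 43.0, 17.1)


class TestFitPeakRecovery:
    IPIS = np.array([500.0, 1000.0, 2500.0, 5000.0, 10000.0])

    def test_exact_recovery_of_generating_curve(self):
        Ipeak0, a, Gr0 = -1.0, -0.5, 3.3e-4
        I_p = Ipeak0 - a * np.exp(-Gr0 * self.IPIS)
        fit = fit_peak_recovery(self.IPIS, I_p)
        assert fit.Gr0 == pytest.approx(Gr0, rel=1e-6)
        assert fit.Ipeak0 == pytest.approx(Ipeak0, rel=1e-6)
        assert fit.a == pytest.approx(a, rel=1e-6)

    def test_constant_peaks_flagged_unidentifiable(self):
        fit = fit_peak_recovery(self.IPIS, np.full(5, -1.0))
        assert not fit.identifiable

    def test_short_intervals_excluded(self):
        t = np.array([10.0, 50.0, 500.0, 1000.0, 5000.0])
        I_p = -1.0 + 0.5 * np.exp(-3.3e-4 * t)
        fit = fit_peak_recovery(t, I_p, min_ipi=100.0)
        assert fit.Gr0 == pytest.approx(3.3e-4, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_peak_recovery([500.0, 1000.0], [-1.0, -1.1])

    def test_full_synthetic_recovery_protocol(self, chr2_6):
        """End-to-end: simulate the two-pulse protocol, extract second-pulse
        peaks, fit — the dark recovery rate comes back (ChR2: 3.3e-4/ms)."""
        data = G.generate(chr2_6, make_protocol("recovery"))
        t_p, I_p = align_peaks_to_first_offset(data)
        fit = fit_peak_recovery(t_p, I_p)
        assert fit.Gr0 == pytest.approx(0.00033, rel=0.05)
        # two significant figures
        assert float(f"{fit.Gr0:.2g}") == 0.00033


class TestOffCurves:
    T = np.arange(0.0, 300.0, 0.5)

    def test_single_exponential_degenerates_cleanly(self):
        I = -0.8 * np.exp(-0.05 * self.T)
        bf = fit_biexponential(self.T, I)
        assert weighted_single_rate([bf]) == pytest.approx(0.05, rel=1e-3)

    def test_biexponential_rate_recovery(self):
        I = -3.0 * np.exp(-0.02 * self.T) - 1.0 * np.exp(-0.1 * self.T)
        bf = fit_biexponential(self.T, I)
        assert bf.G_slow == pytest.approx(0.02, rel=1e-3)
        assert bf.G_fast == pytest.approx(0.1, rel=1e-3)
        assert abs(bf.I_slow) == pytest.approx(3.0, rel=1e-3)

    def test_amplitude_weighted_collapse_arithmetic(self):
        # One trial, I_slow=3, I_fast=1, Gd1=0.1, Gd2=0.02:
        # (3*0.1 + 1*0.02)/4 = 0.08
        bf = BiexponentialFit(I_slow=3.0, I_fast=1.0, G_slow=0.02, G_fast=0.1)
        # weighting pairs each amplitude with its own rate
        got = weighted_single_rate([BiexponentialFit(
            I_slow=1.0, I_fast=3.0, G_slow=0.02, G_fast=0.1)])
        assert got == pytest.approx((3 * 0.1 + 1 * 0.02) / 4)

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            BiexponentialFit(I_slow=1.0, I_fast=1.0, G_slow=0.5, G_fast=0.1)

    def test_dark_eigenvalue_inversion_round_trip(self):
        # Forward: eigenvalues of [[-(Gd1+Gf0), Gb0], [Gf0, -(Gd2+Gb0)]]
        Gd1, Gd2, Gf0, Gb0 = 0.108, 0.0111, 0.0365, 0.0146
        M = np.array([[-(Gd1 + Gf0), Gb0], [Gf0, -(Gd2 + Gb0)]])
        lam = np.sort(np.linalg.eigvals(M))
        got1, got2 = F._dark_rates_from_eigenvalues(-lam[1], -lam[0], Gf0, Gb0)
        assert got1 == pytest.approx(Gd1, rel=1e-9)
        assert got2 == pytest.approx(Gd2, rel=1e-9)

    def test_non_monotone_trial_excluded(self):
        good = (self.T, -1.0 * np.exp(-0.05 * self.T))
        rising = (self.T, -0.1 - 0.01 * self.T / 300.0 * 50)  # |I| grows
        with pytest.warns(UserWarning):
            Gd, fits = fit_off_curves([good, rising], 3)
        assert len(fits) == 1
        assert Gd == pytest.approx(0.05, rel=1e-3)

    def test_short_segment_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_biexponential(self.T[:10], np.exp(-self.T[:10]))


class TestActivationRates:
    def test_simulate_then_refit(self, chr2_6):
        """Round trip: generate short-pulse data at known Go, recover it."""
        truth = chr2_6.replace(Go1=2.0, Go2=2.0)
        data = G.generate(truth, make_protocol(
            "shortPulse", {"run_values": [1.0, 3.0]}))
        go1, go2, ok = fit_activation_rates(data, truth)
        assert ok
        assert go1 == pytest.approx(2.0, rel=0.10)

    def test_fast_activation_limit_lag_vanishes(self, chr2_6, chr2_4):
        """As Go -> infinity the 6-state trace converges to the 4-state one
        and the observed peak lag goes to zero."""
        from opsinkit.engine import integrate
        from opsinkit.stimuli import stimulus_for_run

        spec = make_protocol("shortPulse", {"run_values": [1.0]})
        stim = stimulus_for_run(spec, 0)
        fast = chr2_6.replace(Go1=1000.0, Go2=1000.0)
        pc6 = integrate(fast, stim, dt=0.01)
        pc4 = integrate(chr2_4, stim, dt=0.01)
        assert abs(pc6.t_peak_ - pc4.t_peak_) <= 0.02
        assert pc6.t_peak_ - stim.pulses[0][1] <= 0.02

    def test_requires_short_pulse(self, chr2_6):
        data = G.generate(chr2_6, make_protocol(
            "shortPulse", {"run_values": [8.0, 10.0]}))
        with pytest.raises(UnidentifiableError):
            fit_activation_rates(data, chr2_6)

    def test_three_state_rejected(self, chr2_3, chr2_6):
        data = G.generate(chr2_6, make_protocol("shortPulse",
                                                {"run_values": [1.0]}))
        with pytest.raises(UnidentifiableError):
            fit_activation_rates(data, chr2_3)


@pytest.fixture(scope="module")
def step3():
    """Noiseless 3-state flux-dependence set (3 fluxes)."""
    truth = G.chr2_fixture(3)
    fluxes = [2.21e15, 2.4e16, 2.65e17]
    return truth, G.generate(truth, make_protocol("step", {"fluxes": fluxes}))


class TestOnCurvesAndPipeline:
    def test_single_flux_fixes_flux_dependence(self, step3):
        truth, _ = step3
        data = G.generate(truth, make_protocol("step", {"fluxes": [2.65e17]}))
        config = FitConfig(model_order=3, refine=False)
        result = fit_models({"step": data}, model_order=3,
                            initial=G.chr2_initial_guess(3), config=config)
        guess = G.chr2_initial_guess(3)
        # flux-dependence parameters stayed at their initial values
        assert result.params.phi_m == guess.phi_m
        assert result.params.p == guess.p
        assert result.params.q == guess.q

    def test_three_state_light_parameter_recovery(self, step3):
        truth, data = step3
        config = FitConfig(model_order=3)
        result = fit_models({"step": data}, model_order=3,
                            initial=G.chr2_initial_guess(3), config=config)
        assert result.params.ka == pytest.approx(truth.ka, rel=0.05)
        assert result.params.p == pytest.approx(truth.p, rel=0.05)
        assert result.params.phi_m == pytest.approx(truth.phi_m, rel=0.05)
        assert result.params.Gd == pytest.approx(truth.Gd, rel=0.02)

    def test_missing_protocols_are_skipped_with_flags(self, step3):
        truth, data = step3
        config = FitConfig(model_order=3, refine=False)
        result = fit_models({"step": data}, model_order=3,
                            initial=G.chr2_initial_guess(3), config=config)
        assert result.flags.get("rectifier_skipped")
        assert result.stage("recovery").skipped
        # E, v0, Gr0 kept at initial values
        guess = G.chr2_initial_guess(3)
        assert result.params.E == guess.E
        assert result.params.Gr0 == guess.Gr0

    def test_empty_or_minimal_dataset_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_models({}, model_order=3)
        with pytest.raises(UnidentifiableError):
            fit_models({"recovery": None}, model_order=3)

    def test_refinement_off_is_bypass(self, step3):
        truth, data = step3
        r1 = fit_models({"step": data}, model_order=3,
                        initial=G.chr2_initial_guess(3),
                        config=FitConfig(model_order=3, refine=False))
        assert r1.stage("refinement").skipped

    def test_pipeline_determinism(self, step3):
        truth, data = step3
        cfg = FitConfig(model_order=3, refine=False)
        r1 = fit_models({"step": data}, model_order=3,
                        initial=G.chr2_initial_guess(3), config=cfg)
        r2 = fit_models({"step": data}, model_order=3,
                        initial=G.chr2_initial_guess(3), config=cfg)
        assert r1.params.to_dict() == r2.params.to_dict()

    def test_sign_robustness_inhibitory_opsin(self, step3):
        """Negating every current (hyperpolarizing opsin) leaves the kinetic
        parameters unchanged."""
        from opsinkit.photodata import PhotoCurrent, ProtocolData

        truth, data = step3
        flipped = ProtocolData(data.protocol, data.n_runs, data.phis, data.Vs)
        for key, pc in data:
            flipped.add_trial(
                PhotoCurrent(-pc.I, pc.t, pc.pulses, pc.phi, pc.V), *key)
        cfg = FitConfig(model_order=3, refine=False)
        r_pos = fit_models({"step": data}, 3, G.chr2_initial_guess(3), cfg)
        r_neg = fit_models({"step": flipped}, 3, G.chr2_initial_guess(3), cfg)
        for name in ("ka", "kr", "p", "q", "phi_m", "Gd", "g0"):
            assert getattr(r_neg.params, name) == pytest.approx(
                getattr(r_pos.params, name), rel=1e-6), name


class TestRefinement:
    def test_perturbed_dark_rate_pulled_back(self, step3):
        """Refinement moves a deliberately perturbed Gd back toward truth and
        reduces the residual."""
        truth, data = step3
        cfg = FitConfig(model_order=3)
        perturbed = truth.replace(Gd=truth.Gd * 1.3)
        refined, diag = F.post_fit_refinement({"step": data}, perturbed, cfg)
        assert abs(refined.Gd - truth.Gd) < abs(perturbed.Gd - truth.Gd)

    def test_perfect_fit_is_fixed_point(self, step3):
        truth, data = step3
        cfg = FitConfig(model_order=3)
        refined, _diag = F.post_fit_refinement({"step": data}, truth, cfg)
        assert refined.Gd == pytest.approx(truth.Gd, rel=0.01)
        assert refined.ka == pytest.approx(truth.ka, rel=0.01)

    def test_invalid_config_fractions_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(refine_lower=1.5)
        with pytest.raises(ValueError):
            FitConfig(refine_upper=0.9)
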