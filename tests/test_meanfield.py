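"""Ricciardi gain, input moments, nullclines, fixed points, regime planning."""

import math

import numpy as np
import pytest

from gridwave.meanfield import (
    MeanFieldModel,
    classify_regime,
    find_fixed_points,
    gain_rates,
    input_moments,
    integrate_meanfield,
    nullclines,
    ricciardi_rate,
    tune_regime,
)
from gridwave.network import ConnectivityKernel, EfficacyMatrix, GridSpec
from gridwave.neuron import NeuronParams
from gridwave.workbench import preset

EXC = NeuronParams(tau_m=20.0, E=0.0, V_theta=20.0, V_r=5.0, tau_arp=2.0,
                   g_c=0.06, alpha_c=1.0, tau_c=120.0)
INH = NeuronParams(tau_m=10.0, E=0.0, V_theta=20.0, V_r=5.0, tau_arp=1.0,
                   inhibitory=True)


def model_from_preset(name):
    cfg = preset(name)
    return MeanFieldModel.from_network_config(cfg.grid, cfg.kernel, cfg.eff,
                                              cfg.params)


class TestRicciardi:
    def test_subthreshold_deterministic_limit_is_zero(self):
        assert ricciardi_rate(15.0, 0.0, EXC) == 0.0

    def test_suprathreshold_deterministic_period(self):
        mu = 32.0
        expected = 1000.0 / (
            EXC.tau_arp
            + EXC.tau_m * math.log((mu - EXC.V_r) / (mu - EXC.V_theta))
        )
        assert ricciardi_rate(mu, 0.0, EXC) == pytest.approx(expected, rel=1e-9)
        assert ricciardi_rate(mu, 1e-14, EXC) == pytest.approx(expected, rel=1e-9)

    def test_monotone_in_mu(self):
        rates = [ricciardi_rate(mu, 3.0, EXC) for mu in np.linspace(-20, 60, 80)]
        assert np.all(np.diff(rates) >= -1e-12)

    def test_deep_subthreshold_is_zero(self):
        assert ricciardi_rate(-100.0, 2.0, EXC) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ricciardi_rate(float("nan"), 1.0, EXC)
        with pytest.raises(ValueError):
            ricciardi_rate(0.0, -1.0, EXC)

    def test_monte_carlo_single_neuron(self):
        """Gain function against a 100 s white-noise LIF simulation."""
        mu, sigma = 16.0, 4.0
        rate_pred = ricciardi_rate(mu, sigma, EXC)
        dt = 0.01  # ms
        n_neurons, T = 100, 1000.0  # 100 x 1 s = 100 s total
        rng = np.random.default_rng(12345)
        V = np.zeros(n_neurons)
        refr = np.zeros(n_neurons)
        n_spikes = 0
        # sigma^2 = tau_m * sum(J^2 nu): the SDE noise term is sigma
        # sqrt(dt/tau_m), giving stationary variance sigma^2 / 2
        drift = dt / EXC.tau_m
        diff = sigma * math.sqrt(dt / EXC.tau_m)
        for _ in range(int(T / dt)):
            noise = rng.standard_normal(n_neurons)
            active = refr <= 0
            V[active] += (mu - V[active]) * drift + diff * noise[active]
            refr[~active] -= dt
            fired = V >= EXC.V_theta
            n_spikes += int(fired.sum())
            V[fired] = EXC.V_r
            refr[fired] = EXC.tau_arp
        rate_mc = n_spikes / (n_neurons * T * 1e-3)
        se = math.sqrt(n_spikes) / (n_neurons * T * 1e-3)
        assert abs(rate_mc - rate_pred) < 3 * se + 0.02 * rate_pred


def uniform_model(J=0.4, J_I=1.0, nu_ext=1500.0, g_c=0.06):
    spec = GridSpec(3, 3, 30, 90, 30)
    kern = ConnectivityKernel(0.5, 0.9)
    row = (J, J, J_I)
    eff = EfficacyMatrix(J=(row, row, row), cv=0.25, J_ext=0.5,
                         delta_J_ext=0.12, nu_ext_hz=nu_ext)
    exc = NeuronParams(tau_m=20, E=0, V_theta=20, V_r=5, tau_arp=2, g_c=g_c,
                       alpha_c=1.0, tau_c=120)
    return MeanFieldModel.from_network_config(
        spec, kern, eff, {"F": exc, "B": exc, "I": INH})


class TestInputMoments:
    def test_zero_rates_only_external_and_adaptation(self):
        m = uniform_model()
        mu, sig = input_moments((0, 0, 0), m, c=(2.0, 0.0))
        p = m.params[0]
        ext = m.eff.J_ext * m.eff.nu_ext_per_pop()[0] * 1e-3
        assert mu[0] == pytest.approx(p.tau_m * ext - p.tau_m * p.adapt_coupling * 2.0)
        assert mu[1] == pytest.approx(p.tau_m * ext)
        var_ext = (m.eff.J_ext**2 + m.eff.delta_J_ext**2) * m.eff.nu_ext_per_pop()[0] * 1e-3
        assert sig[0] == pytest.approx(math.sqrt(p.tau_m * var_ext))

    def test_zero_everything_gives_pure_adaptation(self):
        m = uniform_model(nu_ext=0.0)
        mu, sig = input_moments((0, 0, 0), m, c=(1.5, 0.5))
        p = m.params[0]
        assert mu[0] == pytest.approx(-p.tau_m * p.adapt_coupling * 1.5)
        assert sig[0] == 0.0

    def test_linearity_in_source_rate(self):
        m = uniform_model()
        mu0, _ = input_moments((0, 0, 0), m)
        mu1, _ = input_moments((0, 10, 0), m)
        mu2, _ = input_moments((0, 20, 0), m)
        assert mu2[0] - mu1[0] == pytest.approx(mu1[0] - mu0[0], rel=1e-12)
        # slope equals tau_m * M_B * J_B per unit rate
        p = m.params[0]
        slope = p.tau_m * m.M_array[0, 1] * m.eff.J_array[0, 1] * 1e-3
        assert mu1[0] - mu0[0] == pytest.approx(10 * slope, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            input_moments((-1, 0, 0), uniform_model())

    def test_moments_match_compound_poisson_simulation(self):
        """mu/sigma of the per-ms summed input vs direct event simulation."""
        m = uniform_model()
        rates = (6.0, 3.0, 8.0)
        mu, sig = input_moments(rates, m)
        rng = np.random.default_rng(77)
        n_ms = 200_000
        J = m.signed_J()[0]
        dJ = m.eff.delta_J_array()[0]
        M = m.M_array[0]
        lam_rec = M * np.asarray(rates) * 1e-3
        lam_ext = m.eff.nu_ext_per_pop()[0] * 1e-3
        total = np.zeros(n_ms)
        for s in range(3):
            k = rng.poisson(lam_rec[s], n_ms)
            # per-ms sum of k Gaussian(J_s, dJ_s) amplitudes
            total += k * J[s] + np.sqrt(k) * dJ[s] * rng.standard_normal(n_ms)
        k = rng.poisson(lam_ext, n_ms)
        total += k * m.eff.J_ext + np.sqrt(k) * m.eff.delta_J_ext * rng.standard_normal(n_ms)
        p = m.params[0]
        # mu/tau_m is the mean input per ms; sigma^2/tau_m its variance
        assert total.mean() == pytest.approx(mu[0] / p.tau_m, rel=0.05)
        assert total.var() == pytest.approx(sig[0] ** 2 / p.tau_m, rel=0.05)


class TestNullclines:
    def test_fatigue_nullcline_through_origin(self):
        m = uniform_model()
        nc = nullclines(m, np.linspace(0, 30, 7))
        assert nc["c_fatigue_nullcline"][0] == 0.0
        p = m.params[0]
        assert nc["c_fatigue_nullcline"][-1] == pytest.approx(
            p.alpha_c * p.tau_c * 30 * 1e-3)

    def test_rate_nullcline_residual(self):
        m = model_from_preset("SW-default")
        grid = np.linspace(0.5, 40, 12)
        nc = nullclines(m, grid)
        ok = np.isfinite(nc["c_rate_nullcline"])
        assert ok.sum() >= 8
        for nu, c in zip(grid[ok], nc["c_rate_nullcline"][ok]):
            from gridwave.meanfield import _phi_F_slaved
            phi, *_ = _phi_F_slaved(m, nu, c)
            assert abs(phi - nu) < 1e-6

    def test_sw_nullcline_is_s_shaped(self):
        # non-monotonic c(nu): the fold that underlies Up/Down bistability
        m = model_from_preset("SW-default")
        grid = np.geomspace(0.2, 60, 25)
        nc = nullclines(m, grid)
        c = nc["c_rate_nullcline"]
        ok = np.isfinite(c)
        d = np.diff(c[ok])
        assert (d > 0).any() and (d < 0).any()

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            nullclines(uniform_model(), [-1.0, 2.0])


class TestFixedPoints:
    def test_uncoupled_undriven_near_zero(self):
        spec = GridSpec(2, 2, 30, 90, 30)
        kern = ConnectivityKernel(0.5, 0.9)
        eff = EfficacyMatrix(J=((0.0,) * 3,) * 3, nu_ext_hz=0.0)
        m = MeanFieldModel.from_network_config(
            spec, kern, eff, {"F": EXC, "B": EXC, "I": INH})
        fps = find_fixed_points(m)
        assert len(fps) == 1
        assert np.allclose(fps[0].rates_hz, 0.0, atol=1e-6)
        assert fps[0].stable

    def test_residuals_small(self):
        for fp in find_fixed_points(model_from_preset("SW-default")):
            assert fp.residual < 1e-8

    def test_aw_preset_single_stable_elevated(self):
        fps = find_fixed_points(model_from_preset("AW-default"))
        stable = [fp for fp in fps if fp.stable]
        assert len(stable) == 1
        assert 5.0 < stable[0].rates_hz[0] < 60.0

    def test_sw_preset_low_rate_stable_point(self):
        fps = find_fixed_points(model_from_preset("SW-default"))
        assert any(fp.stable and fp.rates_hz[0] < 5.0 for fp in fps)


class TestIntegration:
    def test_fixed_point_stays_constant(self):
        m = model_from_preset("AW-default")
        fp = [f for f in find_fixed_points(m) if f.stable][0]
        init = np.concatenate([fp.rates_hz, fp.c])
        traj = integrate_meanfield(m, 400.0, init=init)
        assert np.allclose(traj.rates_hz[-1], fp.rates_hz, atol=0.3)

    def test_rates_never_negative(self):
        m = model_from_preset("SW-default")
        traj = integrate_meanfield(m, 1500.0, noise_hz=4.0, seed=2)
        assert np.all(traj.rates_hz >= 0)

    def test_sw_preset_oscillates_aw_does_not(self):
        sw = classify_regime(model_from_preset("SW-default"), seed=0)
        aw = classify_regime(model_from_preset("AW-default"), seed=0)
        assert sw["regime"] == "SW" and sw["oscillation"]["n_cycles"] >= 3
        assert aw["regime"] == "AW"
        # the alternation is in the slow-wave band
        assert 0.5 < sw["oscillation"]["freq_hz"] < 8.0


class TestTuneRegime:
    def test_already_in_target_accepts_multiplier_one(self):
        m = model_from_preset("AW-default")
        eff, diag = tune_regime(m, "AW")
        assert diag["multiplier"] == 1.0

    def test_lowering_ff_abolishes_oscillation(self):
        m = model_from_preset("SW-default")
        eff, diag = tune_regime(m, "AW")
        assert diag["multiplier"] < 1.0
        assert classify_regime(m.with_eff(eff))["regime"] == "AW"

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            tune_regime(uniform_model(), "XX")
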