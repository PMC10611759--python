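"""Urea titrations, temperature extrapolation, rate extrapolation, melts."""

import numpy as np
import pytest

from domaincoupling import equilibrium_stability as eq
from domaincoupling import synthetic_data as sim
from domaincoupling.constants import H_PLANCK, K_B, R_KCAL, T_37C, celsius_to_kelvin
from domaincoupling.types import UnfoldingCurve, ValidationError


def _urea_curve(dG0=3.0, m=1.5, noise=0.0, seed=0, t_k=293.15, n=13):
    spec = sim.StabilitySimSpec(dG0=dG0, m_value=m, noise_sd=noise, seed=seed)
    return sim.simulate_unfolding_curve(spec, np.linspace(0, 6, n),
                                        temperature=t_k)


class TestUreaUnfolding:
    def test_noiseless_exact_inversion(self):
        fit = eq.fit_urea_unfolding(_urea_curve())
        assert fit.dG0 == pytest.approx(3.0, abs=1e-6)
        assert fit.m_value == pytest.approx(1.5, abs=1e-6)

    def test_half_unfolded_point_has_zero_dG(self):
        fit = eq.fit_urea_unfolding(_urea_curve())
        # pointwise dG at the 2.0 M midpoint must be 0 (K = 1)
        idx = np.argmin(np.abs(fit.urea - 2.0))
        assert fit.dG_points[idx] == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_median(self):
        """2% of span noise, 12 points: dG0 within 0.2 kcal/mol (median)."""
        errs = []
        for seed in range(100):
            curve = _urea_curve(noise=0.018, seed=seed, n=12)
            fit = eq.fit_urea_unfolding(curve)
            errs.append(abs(fit.dG0 - 3.0))
        assert np.median(errs) <= 0.2

    def test_no_transition_is_an_error(self):
        curve = UnfoldingCurve(axis_kind="denaturant_molar",
                               axis_values=np.linspace(0, 6, 8),
                               signal=np.linspace(1.0, 1.07, 8)[:, None])
        with pytest.raises(ValidationError):
            eq.fit_urea_unfolding(curve)

    def test_fixed_m_mode(self):
        fit = eq.fit_urea_unfolding(_urea_curve(), fixed_m=1.5)
        assert fit.m_value == 1.5
        assert fit.dG0 == pytest.approx(3.0, abs=1e-6)


class TestTemperatureExtrapolation:
    def test_closed_form_line(self):
        t_c = np.array([20.0, 22.0, 23.0, 28.0, 32.0])
        est = eq.extrapolate_dG_to_temperature(
            celsius_to_kelvin(t_c), 10.0 - 0.2 * t_c, target_k=T_37C)
        assert est.dG0_target == pytest.approx(2.60, abs=1e-9)

    def test_flat_points_stay_flat(self):
        t_c = np.array([20.0, 25.0, 30.0])
        est = eq.extrapolate_dG_to_temperature(
            celsius_to_kelvin(t_c), np.full(3, 2.5), target_k=T_37C)
        assert est.dG0_target == pytest.approx(2.5)
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_prediction_interval_covers_truth(self):
        """PI covers the noise-free extrapolated value ~95% of the time."""
        t_c = np.array([20.0, 22.0, 23.0, 28.0, 32.0])
        truth = 10.0 - 0.2 * 37.0
        rng_hits = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = 10.0 - 0.2 * t_c + rng.normal(0, 0.15, t_c.size)
            est = eq.extrapolate_dG_to_temperature(
                celsius_to_kelvin(t_c), g, target_k=T_37C)
            lo, hi = est.prediction_interval
            rng_hits.append(lo <= truth <= hi)
        assert np.mean(rng_hits) >= 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            eq.extrapolate_dG_to_temperature([293.15, 298.15], [3.0, 2.0])


class TestRateExtrapolation:
    def _table(self, shift=0.0):
        # exact log-linear: log10 k = intercept(T) + 0.5*[urea]
        return {
            289.15: [(u, 10 ** (-5.0 + shift + 0.5 * u)) for u in (1, 2, 3)],
            295.15: [(u, 10 ** (-4.4 + shift + 0.5 * u)) for u in (1, 2, 3)],
            301.15: [(u, 10 ** (-3.8 + shift + 0.5 * u)) for u in (1, 2, 3)],
        }

    def test_exact_inversion_of_water_intercepts(self):
        res = eq.extrapolate_rate(self._table())
        assert res.log10_ku_water[289.15] == pytest.approx(-5.0, abs=1e-10)
        assert res.m_ku[295.15] == pytest.approx(0.5, abs=1e-10)

    def test_dG_value_at_1e4_rate(self):
        # -R*T*ln(1e-4) = 5.67 kcal/mol at 310.15 K
        table = {300.15: [(u, 1e-4 * 10 ** (0.5 * u)) for u in (1, 2, 3)],
                 320.15: [(u, 1e-4 * 10 ** (0.5 * u)) for u in (1, 2, 3)]}
        res = eq.extrapolate_rate(table, target_k=T_37C)
        assert res.k_u_target == pytest.approx(1e-4, rel=1e-8)
        assert res.dG_act_simple == pytest.approx(5.67, abs=0.01)

    def test_doubling_rates_shifts_by_log2(self):
        base = eq.extrapolate_rate(self._table())
        shifted = eq.extrapolate_rate(self._table(shift=np.log10(2)))
        assert shifted.log10_ku_water[289.15] - base.log10_ku_water[289.15] \
            == pytest.approx(np.log10(2), abs=1e-10)
        assert shifted.dG_act_simple - base.dG_act_simple \
            == pytest.approx(-R_KCAL * T_37C * np.log(2), abs=1e-8)

    def test_simple_and_eyring_differ_by_prefactor_term(self):
        res = eq.extrapolate_rate(self._table(), target_k=T_37C)
        expected = R_KCAL * T_37C * np.log(K_B * T_37C / H_PLANCK)
        assert res.dG_act_eyring - res.dG_act_simple \
            == pytest.approx(expected, abs=1e-9)

    def test_negative_m_ku_warns_not_errors(self):
        table = {289.15: [(u, 10 ** (-4.0 - 0.3 * u)) for u in (1, 2, 3)],
                 295.15: [(u, 10 ** (-3.6 - 0.3 * u)) for u in (1, 2, 3)]}
        res = eq.extrapolate_rate(table)
        assert any("negative m_ku" in w for w in res.warnings)


class TestMeltFit:
    def _melt(self, tm_c=45.0, noise=0.0, seed=0):
        # dG0/dG_slope_T chosen so the planted melting point sits at tm_c
        spec = sim.StabilitySimSpec(dG0=3.0, dG_slope_T=-0.2, noise_sd=noise,
                                    seed=seed,
                                    t_ref=celsius_to_kelvin(tm_c) - 3.0 / 0.2)
        return spec, sim.simulate_unfolding_curve(
            spec, celsius_to_kelvin(np.linspace(tm_c - 25, tm_c + 25, 41)),
            axis_kind="temperature_kelvin")

    def test_noiseless_exact_tm(self):
        spec, curve = self._melt()
        fit = eq.fit_melt(curve)
        assert fit.t_m == pytest.approx(45.0, abs=0.01)

    def test_noisy_tm_within_03C_median(self):
        """1% of span noise: T_m recovered within 0.3 degC (median)."""
        errs = []
        for seed in range(100):
            spec, curve = self._melt(noise=0.009, seed=seed)
            errs.append(abs(eq.fit_melt(curve).t_m - 45.0))
        assert np.median(errs) <= 0.3

    def test_temperature_shift_equivariance(self):
        _, base = self._melt(tm_c=45.0)
        _, shifted = self._melt(tm_c=50.0)
        assert eq.fit_melt(shifted).t_m - eq.fit_melt(base).t_m \
            == pytest.approx(5.0, abs=0.02)

    def test_flat_curve_rejected(self):
        curve = UnfoldingCurve(axis_kind="temperature_kelvin",
                               axis_values=celsius_to_kelvin(
                                   np.linspace(25, 65, 9)),
                               signal=np.full((9, 1), 2.0))
        with pytest.raises(ValidationError):
            eq.fit_melt(curve)
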