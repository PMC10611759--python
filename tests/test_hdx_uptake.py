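"""Uptake fitting, differential maps, and opening free-energy differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domaincoupling import hdx_uptake as hdx
from domaincoupling import synthetic_data as sim
from domaincoupling.constants import R_KCAL
from domaincoupling.types import PeptideRecord, UptakeSeries, ValidationError
from conftest import make_uptake


def _fit(peptide, rates, amps=None, order=1):
    amps = amps or tuple(50.0 / len(rates) for _ in rates)
    return hdx.UptakeFit(peptide=peptide, model_order=order, a0=5.0,
                         amplitudes=amps, rates=rates, rss=0.0, aicc=0.0,
                         n_points=5)


class TestFitUptake:
    def test_noiseless_mono_is_exact_inversion(self, noiseless_mono_series):
        fit = hdx.fit_uptake(noiseless_mono_series, order=1)
        assert fit.a0 == pytest.approx(10.0, rel=1e-6, abs=1e-6)
        assert fit.amplitudes[0] == pytest.approx(60.0, rel=1e-6)
        assert fit.rates[0] == pytest.approx(0.01, rel=1e-6)

    def test_noiseless_biexponential_inversion(self):
        spec = sim.UptakeSimSpec(a0=5.0, amplitudes=(30.0, 40.0),
                                 rates=(0.05, 0.002), noise_sd=0.0,
                                 timepoints=(10, 60, 240, 1200, 3600),
                                 n_replicates=1)
        fit = hdx.fit_uptake(sim.simulate_uptake(spec), order=2)
        assert fit.rates[0] == pytest.approx(0.05, rel=1e-4)
        assert fit.rates[1] == pytest.approx(0.002, rel=1e-4)
        assert fit.amplitudes == pytest.approx((30.0, 40.0), rel=1e-3)

    def test_noisy_biexponential_rate_recovery(self):
        """Slow (structured-region) rate within 15% at 1 %D noise.

        The fast rate rests on the two earliest schedule points only, so
        its sampling error is intrinsically larger; the median bound
        asserted here reflects that information limit.
        """
        e_fast, e_slow = [], []
        for seed in range(10):
            spec = sim.UptakeSimSpec(a0=5.0, amplitudes=(30.0, 40.0),
                                     rates=(0.05, 0.002), noise_sd=1.0,
                                     timepoints=(10, 60, 240, 1200, 3600),
                                     n_replicates=3, seed=seed)
            fit = hdx.fit_uptake(sim.simulate_uptake(spec), order=2)
            e_fast.append(abs(fit.rates[0] / 0.05 - 1))
            e_slow.append(abs(fit.rates[1] / 0.002 - 1))
        assert np.median(e_slow) <= 0.15
        assert np.median(e_fast) <= 0.35

    def test_constant_series_flags_unidentifiable_rate(self, peptide):
        series = UptakeSeries(peptide=peptide, timepoints=[10, 240, 1200],
                              percent_d=np.full((3, 2), 50.0))
        fit = hdx.fit_uptake(series, order=1)
        assert fit.model_order == 1
        assert fit.amplitudes[0] == pytest.approx(0.0, abs=1e-3)
        assert not fit.slow_rate_identifiable

    def test_auto_selects_order_one_on_mono_truth(self):
        """Information criterion keeps the simpler model >=90% of seeds."""
        chosen = []
        for seed in range(40):
            series, _ = make_uptake(seed, noise_sd=1.5,
                                    timepoints=(10, 60, 240, 600, 1200))
            chosen.append(hdx.fit_uptake(series, order="auto").model_order)
        assert np.mean(np.array(chosen) == 1) >= 0.9

    def test_too_few_timepoints_rejected(self, peptide):
        series = UptakeSeries(peptide=peptide, timepoints=[10, 240],
                              percent_d=np.array([[20.0], [50.0]]))
        with pytest.raises(ValidationError):
            hdx.fit_uptake(series, order=1)


class TestDifferentialMap:
    def test_identical_states_give_zero_delta_and_p_one(self):
        series = [make_uptake(s, state="X")[0] for s in (1, 2)]
        df = hdx.differential_map(series, series)
        assert np.allclose(df["delta_percentD"], 0.0)
        assert np.allclose(df["p_value"], 1.0)

    def test_planted_shift_recovered_and_significant(self):
        """+10 %D shift at 1 %D noise, n=3: detected in >=95% of cases."""
        hits, deltas = [], []
        for seed in range(200):
            a, spec = make_uptake(seed, noise_sd=1.0)
            shifted = sim.UptakeSimSpec(
                a0=spec.a0 + 10.0, amplitudes=spec.amplitudes,
                rates=spec.rates, noise_sd=1.0, timepoints=spec.timepoints,
                n_replicates=3, seed=seed + 10000)
            b = sim.simulate_uptake(shifted)
            df = hdx.differential_map([a], [b])
            deltas.extend(df["delta_percentD"])
            hits.extend(df["p_value"] < 0.05)
        assert np.mean(deltas) == pytest.approx(10.0, abs=2.0)
        assert np.mean(hits) >= 0.95

    def test_single_replicate_reports_delta_without_p(self, peptide):
        a = UptakeSeries(peptide=peptide, timepoints=[10.0],
                         percent_d=np.array([[20.0, 21.0, 19.0]]))
        b = UptakeSeries(peptide=peptide, timepoints=[10.0],
                         percent_d=np.array([[30.0]]))
        df = hdx.differential_map([a], [b])
        assert df["delta_percentD"].iloc[0] == pytest.approx(10.0)
        assert np.isnan(df["p_value"].iloc[0])

    def test_no_common_peptides_is_an_error(self, peptide):
        other = PeptideRecord(protein_state="WT", start=1, end=3, sequence="AAA")
        a = UptakeSeries(peptide=peptide, timepoints=[10.0],
                         percent_d=np.array([[20.0]]))
        b = UptakeSeries(peptide=other, timepoints=[10.0],
                         percent_d=np.array([[20.0]]))
        with pytest.raises(ValidationError, match="no common"):
            hdx.differential_map([a], [b])

    def test_unmatched_peptides_are_reported(self, peptide):
        other = PeptideRecord(protein_state="WT", start=1, end=3, sequence="AAA")
        a = [UptakeSeries(peptide=peptide, timepoints=[10.0],
                          percent_d=np.array([[20.0]])),
             UptakeSeries(peptide=other, timepoints=[10.0],
                          percent_d=np.array([[20.0]]))]
        b = [UptakeSeries(peptide=peptide, timepoints=[10.0],
                          percent_d=np.array([[25.0]]))]
        df = hdx.differential_map(a, b)
        assert df.attrs["unmatched_A"] == [other.key]


class TestOpeningEnergetics:
    def test_equal_rates_give_zero(self, peptide):
        d = hdx.ddG_from_rates(_fit(peptide, (1e-3,)), _fit(peptide, (1e-3,)))
        assert d.ddG_open == 0.0

    def test_tenfold_protection_is_1418_cal(self, peptide):
        """Slower exchange in state A: +R*T*ln(10) = 1.418 kcal/mol."""
        d = hdx.ddG_from_rates(_fit(peptide, (1e-3,)), _fit(peptide, (1e-2,)),
                               temperature=310.15)
        assert d.ddG_open == pytest.approx(1.418, abs=1e-3)

    def test_gas_constant_value(self):
        assert R_KCAL == pytest.approx(1.986e-3)

    def test_slow_component_used_for_order_two(self, peptide):
        fa = _fit(peptide, (0.05, 1e-3), order=2)
        fb = _fit(peptide, (0.07, 1e-3), order=2)
        assert hdx.ddG_from_rates(fa, fb).ddG_open == 0.0

    def test_unidentifiable_rate_is_an_error(self, peptide):
        bad = _fit(peptide, (1e-3,))
        bad.rate_identifiable = (False,)
        with pytest.raises(ValidationError, match="unidentifiable"):
            hdx.ddG_from_rates(bad, _fit(peptide, (1e-3,)))

    @given(ka=st.floats(1e-6, 1.0), kb=st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric_under_state_swap(self, ka, kb):
        pep = PeptideRecord(protein_state="WT", start=1, end=5, sequence="AAAAA")
        fwd = hdx.ddG_from_rates(_fit(pep, (ka,)), _fit(pep, (kb,)))
        rev = hdx.ddG_from_rates(_fit(pep, (kb,)), _fit(pep, (ka,)))
        assert fwd.ddG_open == pytest.approx(-rev.ddG_open, abs=1e-12)


class TestResidueProjectionConvention:
    def test_mean_over_covering_peptides(self):
        import pandas as pd
        df = pd.DataFrame([
            {"start": 1, "end": 4, "time_s": 10.0, "delta_percentD": 2.0},
            {"start": 3, "end": 6, "time_s": 10.0, "delta_percentD": 4.0},
        ])
        proj = hdx.project_deltas_to_residues(df, 10.0, n_residues=7)
        assert proj[0] == pytest.approx(2.0)      # residue 1: first peptide
        assert proj[2] == pytest.approx(3.0)      # residues 3-4: overlap mean
        assert proj[5] == pytest.approx(4.0)      # residue 6: second peptide
        assert np.isnan(proj[6])                  # residue 7: uncovered
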