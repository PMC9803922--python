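"""Voltage-clamp trace analysis: elicited currents, I-V, charge, fits."""

import numpy as np
import pytest

from boricflux import ephys
from boricflux.constants import DEFAULT_CONSTANTS
from boricflux.ephys import (
    CurrentTrace,
    FitError,
    IVProtocol,
    SolutionSwitch,
    build_iv,
    charge_accounting,
    elicited_current,
    fit_inhibition,
    fit_michaelis_menten,
    integrate_charge,
    ph_slope,
)


def flat_trace(level_uA: float, duration=100.0, rate=1.0, vh=-0.06, noise=0.0, rng=None):
    t = np.arange(1, int(duration * rate) + 1) / rate
    i = np.full_like(t, level_uA * 1e-6)
    if noise and rng is not None:
        i = i + rng.normal(0, noise * 1e-6, t.shape)
    return CurrentTrace(time=t, current=i, holding_potential=vh, sampling_rate=rate)


class TestCurrentTrace:
    def test_rejects_mismatched_sampling_rate(self):
        t = np.arange(1, 101) * 1.0
        with pytest.raises(ValueError):
            CurrentTrace(time=t, current=np.zeros(100), holding_potential=0.0, sampling_rate=2.0)

    def test_rejects_annotation_outside_span(self):
        t = np.arange(1, 101) * 1.0
        with pytest.raises(ValueError):
            CurrentTrace(
                time=t, current=np.zeros(100), holding_potential=0.0, sampling_rate=1.0,
                annotations=[SolutionSwitch(time=500.0, label="late")],
            )

    def test_csv_round_trip(self, tmp_path):
        trace = flat_trace(0.5)
        trace.annotations.append(SolutionSwitch(time=10.0, label="boric", boric_acid=0.02))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = CurrentTrace.from_csv(path)
        assert np.allclose(back.current, trace.current)
        assert back.holding_potential == trace.holding_potential
        assert back.annotations[0].boric_acid == pytest.approx(0.02)


class TestElicitedCurrent:
    def test_step_over_flat_baseline(self):
        # the published exemplar step: +0.27 uA of boric-acid-elicited current
        assert elicited_current(flat_trace(0.27), flat_trace(0.0)) * 1e6 == pytest.approx(0.27)

    def test_identical_traces_give_zero(self):
        trace = flat_trace(0.4)
        assert elicited_current(trace, trace) == 0.0

    def test_noisy_step_recovered_within_sampling_error(self, rng):
        with_b = flat_trace(0.5, noise=0.02, rng=rng)
        without = flat_trace(0.0, noise=0.02, rng=rng)
        n_window = 25  # terminal 25% of 100 samples
        tol = 3 * 0.02e-6 / np.sqrt(n_window) * np.sqrt(2)
        assert abs(elicited_current(with_b, without) - 0.5e-6) < tol

    def test_mismatched_holding_potential_rejected(self):
        with pytest.raises(ValueError):
            elicited_current(flat_trace(0.5, vh=-0.06), flat_trace(0.0, vh=0.0))

    def test_baseline_window_must_precede_switch(self):
        trace = flat_trace(0.5)
        trace.annotations.append(SolutionSwitch(time=50.0, label="boric", boric_acid=0.02))
        with pytest.raises(ValueError):
            elicited_current(trace, baseline_window=(40.0, 60.0))


class TestIV:
    def make_ohmic(self, g_uS=10.0, e_rev_mV=-20.0):
        steps = np.arange(-160, 61, 20) * 1e-3
        traces = [np.full(20, g_uS * 1e-6 * (v - e_rev_mV * 1e-3)) for v in steps]
        return IVProtocol(step_potentials=steps, step_traces=traces)

    def test_linear_reversal(self):
        curve = build_iv(self.make_ohmic())
        assert curve.reversal_potential * 1e3 == pytest.approx(-20.0, abs=1e-9)

    def test_all_positive_currents_have_no_reversal(self):
        steps = np.arange(-160, 61, 20) * 1e-3
        protocol = IVProtocol(step_potentials=steps, step_traces=[np.full(20, 1e-6)] * len(steps))
        assert build_iv(protocol).reversal_potential is None

    def test_paired_subtraction_equals_pointwise_difference(self):
        with_b = self.make_ohmic(g_uS=12.0, e_rev_mV=-40.0)
        without = self.make_ohmic(g_uS=10.0, e_rev_mV=-20.0)
        curve = build_iv(with_b, reference=without)
        expected = build_iv(with_b).currents - build_iv(without).currents
        assert np.allclose(curve.currents, expected)


class TestIntegrateCharge:
    def test_rectangle(self):
        # 1 uA held for 100 s carries 100 uC
        q = integrate_charge(flat_trace(1.0), window=(1.0, 100.0))
        assert q * 1e6 == pytest.approx(99.0)  # trapezoid over samples 1..100 s

    def test_zero_trace(self):
        assert integrate_charge(flat_trace(0.0)) == 0.0

    def test_known_analytic_integral(self):
        # exponential settling current at 9 Hz over 10 min
        rate, duration = 9.0, 600.0
        t = np.arange(1, int(duration * rate) + 1) / rate
        tau, i0 = 60.0, 1e-6
        trace = CurrentTrace(
            time=t, current=i0 * np.exp(-t / tau), holding_potential=0.0, sampling_rate=rate
        )
        q = integrate_charge(trace, window=(t[0], t[-1]))
        analytic = i0 * tau * (np.exp(-t[0] / tau) - np.exp(-t[-1] / tau))
        assert q == pytest.approx(analytic, rel=1e-3)

    def test_reversed_window_rejected(self):
        with pytest.raises(ValueError):
            integrate_charge(flat_trace(1.0), window=(50.0, 10.0))


class TestChargeAccounting:
    def test_printed_mean_counts_ratio(self):
        # ratio of printed mean counts 9.5/9.0 prints as 1.1
        assert round(9.5 / 9.0, 1) == 1.1

    def test_charge_count_from_e_boric(self):
        acc = charge_accounting(e_total=152e-6 + 95e-6, e_leak=95e-6,
                                boron_before=0.0, boron_after=None)
        # 152 uC divided by the elementary charge is ~9.49e14 charges
        assert acc.charge_count == pytest.approx(9.49e14, rel=1e-3)
        assert acc.ratio is None

    def test_full_accounting_fields(self):
        acc = charge_accounting(
            e_total=249e-6, e_leak=95e-6,
            boron_before=0.21e-9, boron_after=1.77e-9,
        )
        assert acc.e_boric_acid == pytest.approx(154e-6)
        assert acc.molecule_count == pytest.approx(1.56e-9 * DEFAULT_CONSTANTS.avogadro, rel=1e-9)
        assert acc.ratio == pytest.approx(1.02, abs=0.01)
        assert not acc.boron_decreased

    def test_boron_decrease_is_flagged_but_computed(self):
        acc = charge_accounting(e_total=100e-6, e_leak=50e-6,
                                boron_before=1e-9, boron_after=0.5e-9)
        assert acc.boron_decreased
        assert acc.ratio is not None

    def test_zero_charge_zero_uptake_ratio_absent(self):
        acc = charge_accounting(e_total=0.0, e_leak=0.0, boron_before=1e-9, boron_after=1e-9)
        assert acc.ratio is None


class TestMichaelisMentenFit:
    doses = np.array([1, 3, 5, 10, 20]) * 1e-3

    def test_noiseless_recovery_is_exact(self):
        currents = ephys.michaelis_menten(self.doses, 1.5e-6, 6.5e-3)
        fit = fit_michaelis_menten(self.doses, currents)
        assert fit.K_m == pytest.approx(6.5e-3, rel=1e-6)
        assert fit.I_max == pytest.approx(1.5e-6, rel=1e-6)

    def test_all_zero_currents_error(self):
        with pytest.raises(FitError):
            fit_michaelis_menten(self.doses, np.zeros_like(self.doses))

    def test_too_few_doses_error(self):
        with pytest.raises(FitError):
            fit_michaelis_menten([1e-3, 2e-3], [0.1e-6, 0.2e-6])

    def test_scale_equivariance(self):
        currents = ephys.michaelis_menten(self.doses, 1.5e-6, 6.5e-3)
        base = fit_michaelis_menten(self.doses, currents)
        scaled = fit_michaelis_menten(self.doses, 3.0 * currents)
        assert scaled.I_max == pytest.approx(3.0 * base.I_max, rel=1e-6)
        assert scaled.K_m == pytest.approx(base.K_m, rel=1e-6)

    def test_monte_carlo_mean_within_published_band(self, rng):
        # 200 noisy replicates at sigma = 0.05 uA: mean K_m inside 6.5 +/- 0.6 mM
        k_ms = []
        for _ in range(200):
            noisy = ephys.michaelis_menten(self.doses, 1.5e-6, 6.5e-3)
            noisy = noisy + rng.normal(0, 0.05e-6, self.doses.shape)
            k_ms.append(fit_michaelis_menten(self.doses, noisy).K_m)
        assert abs(np.mean(k_ms) - 6.5e-3) < 0.6e-3


class TestInhibitionFit:
    doses = np.array([0, 40, 80, 96]) * 1e-3

    def test_noiseless_recovery_is_exact(self):
        currents = ephys.inhibition_model(self.doses, 1.1e-6, 67e-3)
        fit = fit_inhibition(self.doses, currents)
        assert fit.ic50 == pytest.approx(67e-3, rel=1e-6)
        assert fit.I_0 == pytest.approx(1.1e-6, rel=1e-6)

    def test_flat_currents_report_absent_ic50(self):
        fit = fit_inhibition(self.doses, np.full(4, 1e-6))
        assert fit.ic50 is None

    def test_requires_zero_dose(self):
        with pytest.raises(FitError):
            fit_inhibition([10e-3, 40e-3, 80e-3], [1e-6, 0.5e-6, 0.3e-6])

    def test_monte_carlo_mean_within_ten_percent(self, rng):
        ic50s = []
        for _ in range(200):
            noisy = ephys.inhibition_model(self.doses, 1.1e-6, 67e-3)
            noisy = noisy * (1 + rng.normal(0, 0.05, self.doses.shape))
            ic50s.append(fit_inhibition(self.doses, noisy).ic50)
        assert abs(np.mean(ic50s) - 67e-3) / 67e-3 < 0.10


class TestPhSlope:
    def test_exact_linear_recovery(self):
        # alkalinization at the published exemplar rate, 62e-5 pH/s
        t = np.arange(0, 120, 1.0)
        assert ph_slope(t, 7.1 + 62e-5 * t) == pytest.approx(62e-5, rel=1e-9)

    def test_constant_ph_gives_zero(self):
        t = np.arange(0, 60, 1.0)
        assert ph_slope(t, np.full_like(t, 7.2)) == pytest.approx(0.0, abs=1e-15)

    def test_noisy_line_within_ols_ci(self, rng):
        t = np.arange(0, 300, 1.0)
        slope = 62e-5
        ph = 7.1 + slope * t + rng.normal(0, 0.005, t.shape)
        from scipy import stats

        res = stats.linregress(t, ph)
        assert abs(res.slope - slope) < 1.96 * res.stderr * 1.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ph_slope(np.arange(5.0), np.arange(5.0))
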