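"""Stretch-activation and desensitization: simulation and fit round trips."""

import io

import numpy as np
import pytest

from trekleak.channel_gating import (
    MUTANT_DESENS,
    MUTANT_PRESSURE,
    WT_DESENS,
    WT_PRESSURE,
    DesensParams,
    GatingTrace,
    PressureSensitivity,
    StretchProtocol,
    fit_desensitization,
    peak_open_fraction,
    pressure_response_curve,
    simulate_stretch_current,
)
from trekleak.ionic_driving import DegenerateDesignError


class TestPeakOpenFraction:
    def test_midpoint(self):
        assert peak_open_fraction(WT_PRESSURE.p_half_mmH2O, WT_PRESSURE) == pytest.approx(0.5)

    def test_saturation_at_strong_suction(self):
        assert peak_open_fraction(-1e6, WT_PRESSURE) == pytest.approx(1.0)
        assert peak_open_fraction(1e6, WT_PRESSURE) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_suction(self):
        p = np.linspace(-120.0, 20.0, 60)
        f = peak_open_fraction(p, WT_PRESSURE)
        assert np.all(np.diff(f) < 0)

    def test_mutant_hypersensitive_at_weak_suction(self):
        """The mutant's less-negative half-activation pressure means more
        current at −20 mm H2O than wild type."""
        assert peak_open_fraction(-20.0, MUTANT_PRESSURE) > peak_open_fraction(
            -20.0, WT_PRESSURE
        )

    def test_slope_factor_must_be_positive(self):
        with pytest.raises(ValueError):
            PressureSensitivity(p_half_mmH2O=-30.0, k_p_mmH2O=0.0)


class TestDesensParams:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            DesensParams(0.05, 1.0, 0.5, 0.5, 0.5)

    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            DesensParams(1.0, 0.5, 0.5, 0.4, 0.1)


class TestSimulateStretchCurrent:
    protocol = StretchProtocol(steps=((-50.0, 6.0),), sample_rate_Hz=1000.0)

    def test_onset_equals_peak_open_fraction(self):
        trace = simulate_stretch_current(self.protocol, WT_PRESSURE, WT_DESENS)
        assert trace.normalized_current[0] == pytest.approx(
            peak_open_fraction(-50.0, WT_PRESSURE)
        )

    def test_late_plateau_is_persistent_fraction(self):
        long_protocol = StretchProtocol(steps=((-50.0, 60.0),), sample_rate_Hz=1000.0)
        trace = simulate_stretch_current(long_protocol, WT_PRESSURE, WT_DESENS)
        peak = peak_open_fraction(-50.0, WT_PRESSURE)
        assert trace.normalized_current[-1] == pytest.approx(
            peak * WT_DESENS.frac_persistent, rel=1e-3
        )

    def test_seeded_determinism(self):
        a = simulate_stretch_current(self.protocol, WT_PRESSURE, WT_DESENS, seed=3, noise_sd=0.01)
        b = simulate_stretch_current(self.protocol, WT_PRESSURE, WT_DESENS, seed=3, noise_sd=0.01)
        np.testing.assert_array_equal(a.normalized_current, b.normalized_current)

    def test_undersampling_warns(self):
        protocol = StretchProtocol(steps=((-50.0, 2.0),), sample_rate_Hz=100.0)
        fast = DesensParams(0.02, 1.0, 0.5, 0.4, 0.1)  # tau_fast = 2 samples
        with pytest.warns(UserWarning, match="samples per"):
            trace = simulate_stretch_current(protocol, WT_PRESSURE, fast)
        assert trace.metadata["warnings"]

    def test_multi_step_protocol_resets_decay(self):
        protocol = StretchProtocol(
            steps=((-20.0, 2.0), (-50.0, 2.0)), sample_rate_Hz=1000.0
        )
        trace = simulate_stretch_current(protocol, WT_PRESSURE, WT_DESENS)
        onset2 = np.searchsorted(trace.time_s, 2.0)
        assert trace.normalized_current[onset2] == pytest.approx(
            peak_open_fraction(-50.0, WT_PRESSURE), rel=1e-6
        )


class TestFitDesensitization:
    @pytest.mark.parametrize("desens", [WT_DESENS, MUTANT_DESENS], ids=["wt", "mutant"])
    def test_noiseless_round_trip(self, desens):
        duration = max(6.0, 4.0 * desens.tau_slow_s)
        protocol = StretchProtocol(steps=((-50.0, duration),), sample_rate_Hz=1000.0)
        trace = simulate_stretch_current(protocol, WT_PRESSURE, desens)
        fit = fit_desensitization(trace)
        assert fit.params.tau_fast_s == pytest.approx(desens.tau_fast_s, rel=1e-4)
        assert fit.params.tau_slow_s == pytest.approx(desens.tau_slow_s, rel=1e-4)
        assert fit.params.frac_persistent == pytest.approx(
            desens.frac_persistent, rel=1e-3
        )

    def test_noisy_recovery_within_ten_percent(self):
        protocol = StretchProtocol(steps=((-50.0, 6.0),), sample_rate_Hz=1000.0)
        peak = peak_open_fraction(-50.0, WT_PRESSURE)
        trace = simulate_stretch_current(
            protocol, WT_PRESSURE, WT_DESENS, seed=12, noise_sd=0.01 * peak
        )
        fit = fit_desensitization(trace)
        assert fit.params.tau_fast_s == pytest.approx(WT_DESENS.tau_fast_s, rel=0.1)
        assert fit.params.tau_slow_s == pytest.approx(WT_DESENS.tau_slow_s, rel=0.1)

    def test_single_exponential_flagged(self):
        t = np.arange(0, 6.0, 1e-3)
        y = 0.8 * np.exp(-t / 0.5) + 0.1
        trace = GatingTrace(time_s=t, normalized_current=y, pressure_mmH2O=np.full_like(t, -50.0))
        fit = fit_desensitization(trace)
        assert fit.single_exponential_like

    def test_fractions_sum_to_one_and_taus_ordered(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tau_fast = rng.uniform(0.01, 0.3)
            tau_slow = tau_fast * rng.uniform(3.0, 15.0)
            fracs = rng.dirichlet((2.0, 2.0, 1.0))
            if fracs[0] < 0.05 or fracs[1] < 0.05:  # keep both components visible
                continue
            desens = DesensParams(tau_fast, tau_slow, *fracs)
            duration = 4.0 * tau_slow
            rate = max(200.0, 20.0 / tau_fast)
            protocol = StretchProtocol(steps=((-50.0, duration),), sample_rate_Hz=rate)
            trace = simulate_stretch_current(protocol, WT_PRESSURE, desens)
            fit = fit_desensitization(trace)
            total = (
                fit.params.frac_fast + fit.params.frac_slow + fit.params.frac_persistent
            )
            assert total == pytest.approx(1.0, abs=1e-9)
            assert fit.params.tau_slow_s >= fit.params.tau_fast_s
            if not fit.single_exponential_like:
                assert fit.params.tau_fast_s == pytest.approx(tau_fast, rel=1e-3)
                assert fit.params.tau_slow_s == pytest.approx(tau_slow, rel=1e-3)

    def test_too_few_samples_rejected(self):
        t = np.linspace(0, 1, 20)
        trace = GatingTrace(t, np.exp(-t), np.full_like(t, -50.0))
        with pytest.raises(ValueError, match="50 samples"):
            fit_desensitization(trace)


class TestPressureResponseCurve:
    @staticmethod
    def _traces(sens, pressures, duration=8.0):
        protocol_traces = []
        for p in pressures:
            protocol = StretchProtocol(steps=((p, duration),), sample_rate_Hz=500.0)
            protocol_traces.append(
                simulate_stretch_current(protocol, sens, WT_DESENS)
            )
        return protocol_traces

    def test_noiseless_round_trip(self):
        pressures = (-80.0, -60.0, -45.0, -35.0, -25.0, -15.0, -5.0)
        df, fitted = pressure_response_curve(self._traces(WT_PRESSURE, pressures))
        assert fitted.p_half_mmH2O == pytest.approx(WT_PRESSURE.p_half_mmH2O, rel=1e-3)
        assert fitted.k_p_mmH2O == pytest.approx(WT_PRESSURE.k_p_mmH2O, rel=1e-3)
        assert set(df.columns) == {"pressure_mmH2O", "steady_state"}

    def test_mutant_half_pressure_less_negative(self):
        pressures = (-80.0, -60.0, -45.0, -35.0, -25.0, -15.0, -5.0)
        _, wt = pressure_response_curve(self._traces(WT_PRESSURE, pressures))
        _, mut = pressure_response_curve(self._traces(MUTANT_PRESSURE, pressures))
        assert mut.p_half_mmH2O > wt.p_half_mmH2O

    def test_too_few_pressures_rejected(self):
        with pytest.raises(DegenerateDesignError):
            pressure_response_curve(self._traces(WT_PRESSURE, (-50.0, -50.0, -50.0)))


class TestGatingTraceIO:
    def test_csv_round_trip(self):
        protocol = StretchProtocol(steps=((-50.0, 1.0),), sample_rate_Hz=500.0)
        trace = simulate_stretch_current(protocol, WT_PRESSURE, WT_DESENS, seed=1, noise_sd=0.01)
        buf = io.StringIO()
        trace.to_csv(buf)
        buf.seek(0)
        back = GatingTrace.from_csv(buf)
        np.testing.assert_allclose(back.normalized_current, trace.normalized_current)
        np.testing.assert_allclose(back.pressure_mmH2O, trace.pressure_mmH2O)
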