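"""Spike detection and curve fitting against constructed oracles."""

import numpy as np
import pandas as pd
import pytest

from isasim.analysis import (
    SpikeStats,
    detect_spikes,
    fit_boltzmann,
    fit_exponential,
    mp_dependence_curves,
    silencing_map,
)
from isasim.engine import Trace


def _ramp_and_spike_trace(crossing_ms=120.0, dt=0.05):
    """Synthetic trace whose dV/dt crosses 50 mV/ms at a known instant.

    Baseline slope 2 mV/ms; from ``crossing_ms`` onward the slope jumps to
    200 mV/ms for 1 ms (a spike upstroke), then returns to baseline.
    """
    t = np.arange(0, 200, dt)
    dv = np.where((t >= crossing_ms) & (t < crossing_ms + 1.0), 200.0, 2.0)
    v = -70.0 + np.cumsum(dv) * dt
    return Trace(t, v)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 500, 0.05)
        stats = detect_spikes(Trace(t, np.full_like(t, -65.0)))
        assert len(stats.times) == 0
        assert stats.first_delay == np.inf
        assert stats.rate_hz == 0.0

    def test_constructed_crossing_time_recovered_exactly(self):
        tr = _ramp_and_spike_trace(crossing_ms=120.0)
        stats = detect_spikes(tr)
        assert len(stats.times) == 1
        assert stats.times[0] == pytest.approx(120.0, abs=0.1)

    def test_offset_invariance_below_threshold_shift(self):
        tr = _ramp_and_spike_trace()
        shifted = Trace(tr.t, tr.y + 3.0)
        assert np.array_equal(detect_spikes(tr).times, detect_spikes(shifted).times)

    def test_refractory_merging(self):
        # two crossings 1 ms apart must merge into one spike
        t = np.arange(0, 50, 0.05)
        dv = np.where(((t >= 10) & (t < 10.4)) | ((t >= 11) & (t < 11.4)), 300.0, 0.0)
        v = -70 + np.cumsum(dv) * 0.05
        stats = detect_spikes(Trace(t, v))
        assert len(stats.times) == 1

    def test_finer_resampling_preserves_count(self):
        tr = _ramp_and_spike_trace(dt=0.05)
        fine = _ramp_and_spike_trace(dt=0.025)
        assert len(detect_spikes(tr).times) == len(detect_spikes(fine).times)

    def test_coarse_sampling_warns(self):
        t = np.arange(0, 100, 0.2)
        with pytest.warns(UserWarning, match="too coarse"):
            detect_spikes(Trace(t, np.full_like(t, -65.0)))

    def test_simulated_step_rate_matches_calibration(self, rs_cell, calibrated_steps):
        from isasim.engine import CurrentClampStim, holding_current_for, simulate

        ih = holding_current_for(rs_cell, -60.0)
        stim = CurrentClampStim(
            epochs=[(0.0, 3000.0, ih), (3000.0, 4000.0, calibrated_steps["RS"])]
        )
        ts = simulate(rs_cell, stim, duration=4000.0, v_init=-60.0, record_dt=0.05)
        stats = detect_spikes(ts["v_soma"], onset=3000.0, duration=1000.0)
        assert 10 <= len(stats.times) <= 22
        assert stats.bin_counts.sum() == len(stats.times)


class TestExponentialFits:
    def test_noiseless_single_exponential_exact(self):
        x = np.linspace(0, 200, 40)
        y = 5.0 * np.exp(-x / 30.0) + 1.0
        fit = fit_exponential(x, y, 1)
        assert fit.tau == pytest.approx(30.0, rel=1e-6)
        assert fit.offset == pytest.approx(1.0, abs=1e-6)
        assert fit.r_squared > 0.999

    def test_noisy_tau_recovery_within_ten_percent(self):
        x = np.linspace(0, 150, 25)
        errs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = np.exp(-x / 30.0) + rng.normal(0, 0.05, len(x))
            errs.append(abs(fit_exponential(x, y, 1).tau - 30.0) / 30.0)
        assert np.median(errs) < 0.10

    def test_biexponential_recovery(self):
        x = np.linspace(0, 250, 120)
        y = 2.0 * np.exp(-x / 2.0) + 1.0 * np.exp(-x / 50.0)
        fit = fit_exponential(x, y, 2)
        assert fit.taus[0] == pytest.approx(2.0, rel=0.15)
        assert fit.taus[1] == pytest.approx(50.0, rel=0.15)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1, 2, 3], [1, 2, 3], 1)


class TestBoltzmannFit:
    def test_recovers_known_curve(self):
        x = np.arange(-100, -34, 5.0)
        y = 0.97 / (1 + np.exp((x + 64.5) / 6.6)) + 0.02
        fit = fit_boltzmann(x, y, "inact")
        assert fit.v_half == pytest.approx(-64.5, abs=0.1)
        assert fit.k == pytest.approx(6.6, abs=0.1)
        assert fit.r_squared > 0.999

    def test_flat_data_reports_small_amplitude(self):
        x = np.arange(-90, -45, 5.0)
        y = np.full_like(x, 0.8)
        fit = fit_boltzmann(x, y, "inact")
        assert abs(fit.amplitude) < 0.05


class TestMpDependenceCurves:
    def _stats(self, delay, count):
        times = np.array([delay]) if np.isfinite(delay) else np.array([])
        if np.isfinite(delay):
            extra = delay + np.cumsum(np.full(int(count), 60.0))
            times = np.concatenate([[delay], extra[:-1]]) if count > 1 else times
        return SpikeStats(times=times, onset=0.0, duration=1000.0)

    def test_recovers_delay_sigmoid_midpoint(self):
        prepulses = np.arange(-90, -49, 5.0)
        delays = 30 + 220.0 / (1 + np.exp((prepulses + 73.0) / 3.0))
        stats = [self._stats(d, 1) for d in delays]
        delay_fit, _, table = mp_dependence_curves(prepulses, stats)
        assert delay_fit.v_half == pytest.approx(-73.0, abs=1.5)
        assert len(table) == len(prepulses)

    def test_recovers_probability_sigmoid_midpoint(self):
        prepulses = np.arange(-90, -49, 5.0)
        counts = np.round(6 / (1 + np.exp(-(prepulses + 67.4) / 3.0)))
        stats = []
        for c in counts:
            times = np.linspace(20.0, 140.0, int(c)) if c > 0 else np.array([])
            stats.append(SpikeStats(times=times, onset=0.0, duration=1000.0))
        _, prob_fit, _ = mp_dependence_curves(prepulses, stats)
        assert prob_fit.v_half == pytest.approx(-67.4, abs=1.5)

    def test_needs_six_levels(self):
        with pytest.raises(ValueError):
            mp_dependence_curves([-80, -70, -60], [self._stats(50, 3)] * 3)


class TestSilencingMap:
    def _table(self):
        return pd.DataFrame(
            {
                "cell": [0, 0, 0, 1],
                "freq_hz": [10.0, 10.0, 2.0, 30.0],
                "strength": [1, 2, 1, 1],
                "seed": [1, 2, 3, 4],
                "rate_rs": [10.0, 0.0, 8.0, 5.0],
                "rate_tor": [6.0, 0.0, 7.0, 5.5],
            }
        )

    def test_percentage_arithmetic_and_exclusion(self):
        res = silencing_map(self._table())
        assert len(res.table) == 3  # the silent-RS row is excluded
        row = res.table[(res.table.freq_hz == 10.0)].iloc[0]
        assert row["pct_change"] == pytest.approx(40.0)

    def test_band_summary_structure(self):
        res = silencing_map(self._table())
        summary = res.band_summary()
        assert set(summary["band"]) == {"1-6", "8-15", "25-100"}
        row = summary[summary.band == "8-15"].iloc[0]
        assert row.mean_pct_reduction == pytest.approx(40.0)
        # negative change (facilitation) is preserved, not clipped
        row = summary[summary.band == "25-100"].iloc[0]
        assert row.mean_pct_reduction == pytest.approx(-10.0)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            silencing_map(pd.DataFrame({"cell": [0]}))
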