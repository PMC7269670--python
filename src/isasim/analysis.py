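"""Extraction of firing and current statistics from simulated traces.

Covers the measurements used to characterise the two CCK+IN phenotypes: spike
detection at the 50 mV/ms slope criterion, first-AP delay and early-window AP
probability versus preceding membrane potential (with Boltzmann fits),
single/double exponential fits of current decay and recovery, and the
band-resolved summary of how swapping I_SA_RS for the TOR mixture silences
firing under oscillatory drive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .engine import Trace

__all__ = [
    "SpikeStats",
    "BoltzmannFit",
    "ExpFit",
    "SweepResult",
    "detect_spikes",
    "fit_boltzmann",
    "fit_exponential",
    "mp_dependence_curves",
    "silencing_map",
    "BANDS",
]

#: Input-frequency bands of the silencing summary (Hz), and the baseline
#: output-rate restriction applied when averaging (Hz).
BANDS = {"1-6": (1.0, 6.0), "8-15": (8.0, 15.0), "25-100": (25.0, 100.0)}
OUTPUT_RATE_WINDOW = (4.0, 10.0)


@dataclass
class SpikeStats:
    """Spike times and the early-firing measures of one sweep."""

    times: np.ndarray  # ms, relative to stimulus onset
    onset: float  # ms, stimulus onset in trace time
    duration: float  # ms, analysis window length
    bin_ms: float = 50.0
    window_ms: float = 150.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < -1e-9):
            raise ValueError("spike times must be >= stimulus onset")

    @property
    def first_delay(self) -> float:
        """Latency of the first AP from stimulus onset (ms); inf if no spike."""
        return float(self.times[0]) if len(self.times) else np.inf

    @property
    def rate_hz(self) -> float:
        return len(self.times) / self.duration * 1e3

    @property
    def bin_counts(self) -> np.ndarray:
        nbins = int(np.ceil(self.duration / self.bin_ms))
        edges = np.arange(nbins + 1) * self.bin_ms
        counts, _ = np.histogram(self.times, bins=edges)
        return counts

    def early_count(self, window_ms: float | None = None) -> int:
        w = self.window_ms if window_ms is None else window_ms
        return int(np.sum(self.times < w))


def detect_spikes(
    trace: Trace,
    slope_threshold: float = 50.0,
    onset: float = 0.0,
    duration: float | None = None,
    merge_ms: float = 2.0,
    bin_ms: float = 50.0,
    window_ms: float = 150.0,
) -> SpikeStats:
    """Detect action potentials as upward crossings of a dV/dt criterion.

    The spike time is the threshold-crossing time (the instant dV/dt first
    exceeds ``slope_threshold`` mV/ms); crossings closer than ``merge_ms`` are
    merged into one spike. Spikes before ``onset`` are discarded.
    """
    dt = trace.dt
    if dt > 0.1:
        warnings.warn(
            f"sampling interval {dt:.3f} ms is too coarse to resolve a "
            f"{slope_threshold} mV/ms slope criterion reliably",
            stacklevel=2,
        )
    v = np.asarray(trace.y, dtype=float)
    t = np.asarray(trace.t, dtype=float)
    dv = np.diff(v) / dt
    crossing = np.flatnonzero((dv[1:] >= slope_threshold) & (dv[:-1] < slope_threshold)) + 1
    times = []
    for i in crossing:
        ti = t[i]
        if times and ti - times[-1] < merge_ms:
            continue
        times.append(ti)
    times = np.array([ti for ti in times if ti >= onset]) - onset
    if duration is None:
        duration = t[-1] - onset
    return SpikeStats(times=times, onset=onset, duration=duration, bin_ms=bin_ms, window_ms=window_ms)


@dataclass
class BoltzmannFit:
    """Sigmoid fit y = baseline + amplitude / (1 + exp(±(x − v_half)/k))."""

    v_half: float
    k: float
    amplitude: float
    baseline: float
    direction: str
    r_squared: float

    def __call__(self, x):
        sgn = -1.0 if self.direction == "act" else 1.0
        return self.baseline + self.amplitude / (1.0 + np.exp(sgn * (np.asarray(x) - self.v_half) / self.k))


def fit_boltzmann(x, y, direction: str = "inact", p0=None) -> BoltzmannFit:
    """Least-squares Boltzmann fit with free amplitude and baseline."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sgn = -1.0 if direction == "act" else 1.0

    def model(v, vh, k, amp, base):
        return base + amp / (1.0 + np.exp(sgn * (v - vh) / k))

    if p0 is None:
        p0 = (float(np.median(x)), 8.0, float(y.max() - y.min()), float(y.min()))
    popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000,
                        bounds=([x.min() - 50, 0.5, -2 * abs(y).max() - 1e-9, -np.inf],
                                [x.max() + 50, 60.0, 2 * abs(y).max() + 1e-9, np.inf]))
    resid = y - model(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return BoltzmannFit(
        v_half=float(popt[0]), k=float(popt[1]), amplitude=float(popt[2]),
        baseline=float(popt[3]), direction=direction, r_squared=max(0.0, min(1.0, r2)),
    )


@dataclass
class ExpFit:
    """Sum-of-exponentials fit y = offset + sum_i a_i * exp(-x / tau_i)."""

    taus: tuple
    amplitudes: tuple
    offset: float
    r_squared: float
    converged: bool = True

    @property
    def tau(self) -> float:
        """Amplitude-weighted time constant (the single tau for 1 component)."""
        a = np.abs(np.asarray(self.amplitudes))
        return float(np.sum(a * np.asarray(self.taus)) / np.sum(a))

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-x / tau)
        return out


def fit_exponential(x, y, n_components: int = 1) -> ExpFit:
    """Least-squares exponential fit (1 or 2 components), taus > 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points for an exponential fit")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    span = x.max() - x.min()
    amp0 = y[0] - y[-1]

    if n_components == 1:
        def model(xx, a, tau, off):
            return off + a * np.exp(-xx / tau)
        p0 = (amp0, max(span / 3.0, 1e-3), y[-1])
        bounds = ([-np.inf, 1e-6, -np.inf], [np.inf, 100 * span, np.inf])
    else:
        def model(xx, a1, tau1, a2, tau2, off):
            return off + a1 * np.exp(-xx / tau1) + a2 * np.exp(-xx / tau2)
        p0 = (amp0 / 2, max(span / 20.0, 1e-3), amp0 / 2, max(span / 2.0, 1e-3), y[-1])
        bounds = ([-np.inf, 1e-6, -np.inf, 1e-6, -np.inf], [np.inf, 100 * span, np.inf, 100 * span, np.inf])

    converged = True
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=50000)
    except RuntimeError:
        converged = False
        popt = np.asarray(p0)
    resid = y - model(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if n_components == 1:
        taus, amps, off = (float(popt[1]),), (float(popt[0]),), float(popt[2])
    else:
        order = np.argsort([popt[1], popt[3]])
        taus = tuple(float([popt[1], popt[3]][i]) for i in order)
        amps = tuple(float([popt[0], popt[2]][i]) for i in order)
        off = float(popt[4])
    return ExpFit(taus=taus, amplitudes=amps, offset=off,
                  r_squared=max(0.0, min(1.0, r2)), converged=converged)


def mp_dependence_curves(prepulses, stats_list, no_spike_delay: float | None = None):
    """Boltzmann fits of first-AP delay and early AP count versus preceding MP.

    ``stats_list`` holds one SpikeStats per prepulse level. Delays are
    normalised to [0, 1] per cell before fitting (sweeps without spikes take
    ``no_spike_delay``, by default the analysis window length). Returns
    (delay_fit, probability_fit, table).
    """
    prepulses = np.asarray(prepulses, dtype=float)
    if len(prepulses) < 6:
        raise ValueError("need at least 6 prepulse levels spanning the MP range")
    delays = np.array([s.first_delay for s in stats_list])
    window = stats_list[0].window_ms
    cap = no_spike_delay if no_spike_delay is not None else max(
        window, np.max(delays[np.isfinite(delays)], initial=window)
    )
    delays = np.clip(delays, 0.0, cap)
    rng_d = delays.max() - delays.min()
    norm_delay = (delays - delays.min()) / rng_d if rng_d > 0 else np.zeros_like(delays)
    counts = np.array([s.early_count() for s in stats_list], dtype=float)
    prob = counts / counts.max() if counts.max() > 0 else counts

    # fit on the raw scales (ms; fraction): a cell without MP dependence then
    # reports a small amplitude instead of having its noise stretched to [0,1]
    delay_fit = fit_boltzmann(prepulses, delays, direction="inact")
    prob_fit = fit_boltzmann(prepulses, prob, direction="act")
    table = pd.DataFrame(
        {"prepulse_mV": prepulses, "first_delay_ms": [s.first_delay for s in stats_list],
         "norm_delay": norm_delay, "early_count": counts, "ap_probability": prob}
    )
    return delay_fit, prob_fit, table


@dataclass
class SweepResult:
    """Long-format paired-sweep table and its band summaries.

    ``table`` columns: cell, freq_hz, strength, seed, rate_rs, rate_tor,
    pct_change (percentage reduction of the firing rate when I_SA_RS is
    replaced by the TOR mixture, computed only where the RS configuration
    fired).
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def band_summary(self, output_window=OUTPUT_RATE_WINDOW) -> pd.DataFrame:
        rows = []
        for name, (f0, f1) in BANDS.items():
            sel = self._select(name, output_window)
            rows.append(
                {
                    "band": name,
                    "freq_lo": f0,
                    "freq_hi": f1,
                    "n_points": len(sel),
                    "mean_pct_reduction": float(sel["pct_change"].mean()) if len(sel) else np.nan,
                    "sem_pct_reduction": float(sel["pct_change"].sem()) if len(sel) > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def _select(self, band: str, output_window=OUTPUT_RATE_WINDOW) -> pd.DataFrame:
        f0, f1 = BANDS[band]
        t = self.table
        m = (
            (t["freq_hz"] >= f0)
            & (t["freq_hz"] <= f1)
            & (t["rate_rs"] >= output_window[0])
            & (t["rate_rs"] <= output_window[1])
        )
        return t[m]

    def per_cell_band_means(self, output_window=OUTPUT_RATE_WINDOW) -> pd.DataFrame:
        parts = []
        for name in BANDS:
            sel = self._select(name, output_window)
            if len(sel):
                g = sel.groupby("cell")["pct_change"].mean().rename(name)
                parts.append(g)
        return pd.concat(parts, axis=1)


def silencing_map(table: pd.DataFrame, meta: dict | None = None) -> SweepResult:
    """Assemble the paired-run table into a SweepResult.

    Expects per-run rows with columns cell, freq_hz, strength, seed, rate_rs,
    rate_tor. Rows where the RS configuration produced no spikes are excluded
    (the percentage change is undefined there); pct_change = 100 * (rate_rs −
    rate_tor)/rate_rs.
    """
    t = table.copy()
    required = {"cell", "freq_hz", "strength", "seed", "rate_rs", "rate_tor"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    t = t[t["rate_rs"] > 0].reset_index(drop=True)
    t["pct_change"] = 100.0 * (t["rate_rs"] - t["rate_tor"]) / t["rate_rs"]
    return SweepResult(table=t, meta=meta or {})
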