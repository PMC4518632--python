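"""IPSC trace analysis: onset, amplitude, decay, charge, failure
classification and ensemble statistics.

These are the recording-side procedures used on paired-recording data:
amplitudes are measured as a windowed peak minus a windowed pre-spike
baseline (so DC offsets drop out), onsets come from extrapolating a
parabola fitted to the rising phase back to baseline, events smaller than
twice the noise level count as transmission failures, and the charge of an
event is the baseline-subtracted integral of the current. pA·ms = fC, so
charges integrate directly in fC on a ms/pA grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "IPSCTrace",
    "EnsembleStats",
    "detect_onset",
    "measure_amplitude",
    "measure_charge",
    "classify_failures",
    "ensemble_stats",
    "compare_two_sample",
    "stable_period_mask",
]


@dataclass
class IPSCTrace:
    """One recorded or simulated sweep: time grid (ms), current (pA, inward
    negative), the presynaptic spike time and the recording noise sd."""

    time: np.ndarray
    current: np.ndarray
    presyn_spike_time: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape:
            raise ValueError("time and current grids differ in length")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
        if not (self.time[0] <= self.presyn_spike_time <= self.time[-1]):
            raise ValueError("presynaptic spike time outside the record")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class EnsembleStats:
    """Summary of a trial ensemble (amplitudes pA, charges fC)."""

    mean_amplitude: float
    sd_amplitude: float
    max_amplitude: float
    min_amplitude: float
    mean_charge: float
    sd_charge: float
    max_charge: float
    min_charge: float
    success_rate: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "charge_fC": [
                    self.mean_charge, self.sd_charge, self.max_charge,
                    self.min_charge, self.n,
                ],
                "peak_pA": [
                    self.mean_amplitude, self.sd_amplitude, self.max_amplitude,
                    self.min_amplitude, self.n,
                ],
            },
            index=["mean", "sd", "max", "min", "n"],
        )


def _baseline(trace: IPSCTrace, window: float = 4.0) -> float:
    """Mean current in the window preceding the presynaptic spike."""
    sel = (trace.time >= trace.presyn_spike_time - window) & (
        trace.time < trace.presyn_spike_time
    )
    if not np.any(sel):
        raise ValueError("baseline window does not fit inside the record")
    return float(np.mean(trace.current[sel]))


def baseline_noise_sd(trace: IPSCTrace, window: float = 4.0) -> float:
    """Noise level estimate: sd of the current over the pre-spike baseline
    window (the noise estimator used by failure classification)."""
    sel = (trace.time >= trace.presyn_spike_time - window) & (
        trace.time < trace.presyn_spike_time
    )
    return float(np.std(trace.current[sel]))


def detect_onset(
    trace: IPSCTrace,
    rise_fraction: tuple[float, float] = (0.1, 0.9),
    min_snr: float = 4.0,
) -> float | None:
    """Event onset (ms): a parabola is fitted to the rising phase (10-90% of
    peak by default) and extrapolated back to the baseline; returns None
    when no event stands out of the noise."""
    base = _baseline(trace)
    dev = trace.current - base
    after = trace.time >= trace.presyn_spike_time
    if not np.any(after):
        return None
    idx_after = np.flatnonzero(after)
    peak_rel = np.argmax(np.abs(dev[idx_after]))
    peak_idx = idx_after[peak_rel]
    amp = dev[peak_idx]
    noise = max(baseline_noise_sd(trace), 1e-12)
    if abs(amp) < min_snr * noise:
        return None
    lo, hi = rise_fraction
    frac = np.abs(dev) / abs(amp)
    rising = idx_after[
        (idx_after <= peak_idx) & (frac[idx_after] >= lo) & (frac[idx_after] <= hi)
    ]
    if len(rising) < 3:
        # steep rise on a coarse grid: fall back to the last sub-threshold point
        sub = idx_after[(idx_after <= peak_idx) & (frac[idx_after] < lo)]
        return float(trace.time[sub[-1]]) if len(sub) else float(
            trace.time[idx_after[0]]
        )
    coeff = np.polyfit(trace.time[rising], dev[rising], 2)
    roots = np.roots(coeff)  # parabola crosses the (subtracted) baseline at 0
    roots = roots[np.isreal(roots)].real
    t_rise0 = trace.time[rising[0]]
    before = roots[roots <= t_rise0 + 1e-9]
    if len(before):
        return float(before.max())
    return float(roots[np.argmin(np.abs(roots - t_rise0))]) if len(roots) else None


def measure_amplitude(
    trace: IPSCTrace,
    peak_window: float = 1.5,
    baseline_window: float = 4.0,
) -> float:
    """Event amplitude (pA, sign preserved): the peak current measured from
    a 1.5 ms window centred at the peak (the extremum of the running window
    average) minus the mean baseline in the 4 ms window preceding the
    presynaptic spike."""
    base = _baseline(trace, baseline_window)
    n = max(1, int(round(peak_window / trace.dt)) + 1)
    if n > len(trace.current):
        raise ValueError("peak window does not fit inside the record")
    avg = np.convolve(trace.current - base, np.ones(n) / n, mode="valid")
    centers = trace.time[(n - 1) // 2 : (n - 1) // 2 + len(avg)]
    sel = centers >= trace.presyn_spike_time
    if not np.any(sel):
        raise ValueError("peak window does not fit after the presynaptic spike")
    windowed = avg[sel]
    return float(windowed[np.argmax(np.abs(windowed))])


def measure_charge(
    trace: IPSCTrace,
    onset: float | None = None,
    integration_time: float | None = None,
    tau_decay: float = 14.17,
) -> float:
    """Event charge (fC): ∫(I − baseline) dt from onset over
    ``integration_time`` (default 5·tau_decay). Sign follows the current."""
    base = _baseline(trace)
    if onset is None:
        onset = detect_onset(trace)
        if onset is None:
            onset = trace.presyn_spike_time
    span = integration_time if integration_time is not None else 5.0 * tau_decay
    sel = (trace.time >= onset) & (trace.time <= onset + span)
    return float(np.trapezoid(trace.current[sel] - base, trace.time[sel]))


def classify_failures(amplitudes, noise_sd: float) -> float:
    """Success rate: the fraction of events with |amplitude| ≥ 2 × noise
    level. Events exactly at twice the noise count as successes."""
    amps = np.asarray(list(amplitudes), dtype=float)
    if amps.size == 0:
        raise ValueError("empty amplitude list")
    if not noise_sd > 0:
        raise ValueError("noise_sd must be > 0")
    return float(np.mean(np.abs(amps) >= 2.0 * noise_sd))


def _signed_extreme(x: np.ndarray, kind: str) -> float:
    """Max/min by magnitude with sign preserved (|max| ≥ |mean| for
    single-sign event ensembles)."""
    if kind == "max":
        return float(x[np.argmax(np.abs(x))])
    return float(x[np.argmin(np.abs(x))])


def ensemble_stats(
    amplitudes=None,
    charges=None,
    traces_list: list[IPSCTrace] | None = None,
    noise_sd: float | None = None,
    ddof: int = 1,
) -> EnsembleStats:
    """Ensemble summary (mean/sd/max/min of amplitude and charge plus
    success rate). Accepts amplitude/charge lists directly or a list of
    traces to measure."""
    if traces_list is not None:
        amplitudes = [measure_amplitude(tr) for tr in traces_list]
        charges = [measure_charge(tr) for tr in traces_list]
        if noise_sd is None:
            noise_sd = float(np.mean([baseline_noise_sd(tr) for tr in traces_list]))
    if amplitudes is None and charges is None:
        raise ValueError("need amplitudes, charges or traces")
    amps = np.asarray(list(amplitudes if amplitudes is not None else charges), float)
    chg = np.asarray(list(charges if charges is not None else amplitudes), float)
    if amps.size == 0:
        raise ValueError("empty ensemble")
    sd = lambda x: float(np.std(x, ddof=ddof)) if x.size > 1 else 0.0
    rate = (
        classify_failures(amps, noise_sd)
        if noise_sd is not None and noise_sd > 0
        else float(np.mean(amps != 0.0))
    )
    return EnsembleStats(
        mean_amplitude=float(np.mean(amps)),
        sd_amplitude=sd(amps),
        max_amplitude=_signed_extreme(amps, "max"),
        min_amplitude=_signed_extreme(amps, "min"),
        mean_charge=float(np.mean(chg)),
        sd_charge=sd(chg),
        max_charge=_signed_extreme(chg, "max"),
        min_charge=_signed_extreme(chg, "min"),
        success_rate=rate,
        n=int(amps.size),
    )


def compare_two_sample(a, b) -> tuple[float, float]:
    """Plain two-sample comparison (Welch t) of two measurement
    distributions, e.g. event amplitudes against noise; returns (t, p)."""
    res = sstats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=False)
    return float(res.statistic), float(res.pvalue)


def stable_period_mask(amplitudes, p_threshold: float = 0.05) -> np.ndarray:
    """Run-down screen: if amplitude drifts significantly with trial index
    (linear-trend p < threshold), keep the longest suffix-trimmed stretch
    that shows no significant trend; otherwise keep everything."""
    amps = np.asarray(list(amplitudes), dtype=float)
    n = amps.size
    mask = np.ones(n, dtype=bool)
    if n < 10:
        return mask
    idx = np.arange(n)
    res = sstats.linregress(idx, amps)
    if res.pvalue >= p_threshold:
        return mask
    # trim trials from the end until the trend is no longer significant
    for end in range(n - 1, 9, -1):
        res = sstats.linregress(idx[:end], amps[:end])
        if res.pvalue >= p_threshold:
            mask[end:] = False
            return mask
    mask[10:] = False
    return mask
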