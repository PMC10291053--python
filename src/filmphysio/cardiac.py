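"""PPG beat detection, Hampel RR cleaning, and heart-rate-variability features.

Beats are local maxima of the 0.5-8 Hz band-passed pulse wave that exceed a
rolling adaptive threshold (rolling mean + k * rolling SD), with a 300-ms
refractory period. The interbeat (RR) series is cleaned with a Hampel filter
(three points on each side, i.e. window size 6): a point further than
``n_mad * 1.4826 * MAD`` from the window median is replaced by that median.

HRV features use the population-variance convention so the Poincaré identities
``sd1 = rmssd / sqrt(2)`` and ``sd1^2 + sd2^2 = 2 sdnn^2`` hold exactly.
Baseline correction subtracts the 60-s rest segment's feature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

HRV_NAMES = ("hr", "sdnn", "rmssd", "sdsd", "pnn20", "pnn50", "mad", "sd1", "sd2", "sd1_sd2")


@dataclass
class RRSeries:
    rr: np.ndarray  # ms, len = len(beat_times) - 1
    beat_times: np.ndarray  # s, strictly increasing
    flags: np.ndarray = field(default=None)  # per-interval: True = corrected

    def __post_init__(self):
        self.rr = np.asarray(self.rr, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.rr) != len(self.beat_times) - 1:
            raise ValueError("len(rr) must equal len(beat_times) - 1")
        if np.any(self.rr <= 0):
            raise ValueError("all rr intervals must be > 0")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.flags is None:
            self.flags = np.zeros(len(self.rr), dtype=bool)


def detect_beats(
    ppg: np.ndarray,
    sfreq: float,
    k: float = 0.2,
    window_s: float = 3.0,
    refractory_s: float = 0.3,
    min_duration: float = 30.0,
) -> RRSeries:
    """Locate pulse peaks in a PPG waveform and return the RR series.

    ``min_duration`` may be relaxed (to >= 10 s) for short rest baselines.
    """
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < min_duration * sfreq:
        raise ValueError(f"need at least {min_duration:g} s of PPG signal")
    sos = signal.butter(3, [0.5, 8.0], btype="bandpass", fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos, ppg)
    w = int(round(window_s * sfreq))
    rmean = ndimage.uniform_filter1d(x, w, mode="nearest")
    rsq = ndimage.uniform_filter1d(x * x, w, mode="nearest")
    rsd = np.sqrt(np.maximum(rsq - rmean ** 2, 0.0))
    thresh = rmean + k * rsd
    peaks, _ = signal.find_peaks(x, distance=max(int(round(refractory_s * sfreq)), 1))
    peaks = peaks[x[peaks] > thresh[peaks]]
    duration_min = len(ppg) / sfreq / 60.0
    if len(peaks) < 10 * duration_min:
        raise ValueError("no detectable pulsatility")
    beat_times = peaks / sfreq
    rr = np.diff(beat_times) * 1000.0
    return RRSeries(rr=rr, beat_times=beat_times)


def hampel_clean(series: RRSeries, half_window: int = 3, n_mad: int | float = 3) -> RRSeries:
    """Hampel outlier correction of the RR series (window = 3 points per side)."""
    rr = series.rr
    if len(rr) < 2 * half_window + 1:
        raise ValueError("RR series shorter than the Hampel window")
    cleaned = rr.copy()
    flags = np.zeros(len(rr), dtype=bool)
    for i in range(len(rr)):
        lo = max(0, i - half_window)
        hi = min(len(rr), i + half_window + 1)
        window = rr[lo:hi]  # centre included, per the standard Hampel definition
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        sigma = 1.4826 * mad
        if sigma == 0:
            if rr[i] != med:  # majority of the window identical; centre deviates
                cleaned[i] = med
                flags[i] = True
            continue
        if abs(rr[i] - med) > n_mad * sigma:
            cleaned[i] = med
            flags[i] = True
    return RRSeries(rr=cleaned, beat_times=series.beat_times, flags=flags)


@dataclass
class HRVFeatures:
    values: dict  # feature name -> trial value (ms / bpm / proportion)
    baseline_corrected: dict  # feature name -> trial - rest

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _hrv_values(rr: np.ndarray) -> dict:
    rr = np.asarray(rr, dtype=float)
    d = np.diff(rr)
    var_rr = float(np.var(rr))
    var_d = float(np.var(d)) if len(d) else float("nan")
    msd = float(np.mean(d ** 2)) if len(d) else float("nan")
    out = {
        "hr": 60000.0 / float(np.mean(rr)),
        "sdnn": float(np.sqrt(var_rr)),
        "rmssd": float(np.sqrt(msd)),
        "sdsd": float(np.sqrt(var_d)),
        "pnn20": float(np.mean(np.abs(d) > 20.0)) if len(d) else float("nan"),
        "pnn50": float(np.mean(np.abs(d) > 50.0)) if len(d) else float("nan"),
        "mad": float(np.median(np.abs(rr - np.median(rr)))),
    }
    out["sd1"] = float(np.sqrt(var_d / 2.0))
    sd2_sq = 2.0 * var_rr - var_d / 2.0
    out["sd2"] = float(np.sqrt(sd2_sq)) if sd2_sq >= 0 else float("nan")
    out["sd1_sd2"] = out["sd1"] / out["sd2"] if out["sd2"] and out["sd2"] > 0 else float("nan")
    return out


def hrv_features(trial_rr: RRSeries, rest_rr: RRSeries, min_intervals: int = 10) -> HRVFeatures:
    """The ten HRV summary statistics, raw and baseline-corrected."""
    if len(trial_rr.rr) < min_intervals or len(rest_rr.rr) < min_intervals:
        raise ValueError(f"need at least {min_intervals} intervals in each segment")
    trial = _hrv_values(trial_rr.rr)
    rest = _hrv_values(rest_rr.rr)
    corrected = {k: trial[k] - rest[k] for k in trial}
    return HRVFeatures(values=trial, baseline_corrected=corrected)
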