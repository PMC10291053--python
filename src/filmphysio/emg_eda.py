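"""Facial EMG trial means and the electrodermal SCR amplitude-per-time statistic.

EMG: zero-phase FIR band-pass 10-350 Hz at the native sampling rate, full-wave
rectification, arithmetic mean over the trial; baseline-corrected against the
rest segment processed identically.

EDA: the tonic component is a moving median (30-s window, long relative to
the SCR kernel so the median is not pulled up by the responses themselves)
and is subtracted;
skin-conductance responses are detected on the phasic residual as peaks whose
amplitude (peak minus the preceding local-minimum onset) exceeds 0.01 uS; the
statistic is the sum of amplitudes divided by the epoch length in seconds,
which corrects for the films' different durations. EDA is analysed at 20 Hz
(SCRs carry no faster content), after anti-aliased downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from ._filters import decimate_fir, fir_bandpass

EDA_PROC_SFREQ = 20.0


@dataclass
class EMGFeature:
    muscle: str
    rectified_mean: float  # uV
    rest_mean: float
    baseline_corrected: float


@dataclass
class SCRFeature:
    scr_sum_per_s: float  # uS/s
    n_peaks: int
    rest_sum_per_s: float
    baseline_corrected: float


def rectified_mean(emg: np.ndarray, sfreq: float) -> float:
    """Band-passed (10-350 Hz) full-wave-rectified trial mean."""
    if sfreq < 800:
        raise ValueError("sfreq must be >= 800 Hz for the 350 Hz band edge")
    hi = min(350.0, 0.45 * sfreq)
    filtered = fir_bandpass(np.asarray(emg, dtype=float), sfreq, 10.0, hi, numtaps=257)
    return float(np.mean(np.abs(filtered)))


def emg_trial_mean(
    emg: np.ndarray, rest_emg: np.ndarray, sfreq: float, muscle: str = "zygomaticus"
) -> EMGFeature:
    trial = rectified_mean(emg, sfreq)
    rest = rectified_mean(rest_emg, sfreq)
    return EMGFeature(
        muscle=muscle, rectified_mean=trial, rest_mean=rest,
        baseline_corrected=trial - rest,
    )


def _scr_sum_per_s(
    eda: np.ndarray, sfreq: float, tonic_window_s: float, min_amplitude: float,
    min_duration: float = 30.0,
) -> tuple[float, int, np.ndarray]:
    eda = np.asarray(eda, dtype=float)
    if not np.all(np.isfinite(eda)):
        raise ValueError("non-finite samples in EDA input")
    duration = len(eda) / sfreq
    if duration < min_duration:
        raise ValueError(f"need at least {min_duration:g} s of EDA signal")
    q = max(int(round(sfreq / EDA_PROC_SFREQ)), 1)
    x = decimate_fir(eda, q, sfreq) if q > 1 else eda
    fs = sfreq / q
    tonic = ndimage.median_filter(x, size=int(round(tonic_window_s * fs)), mode="nearest")
    phasic = x - tonic
    peaks, _ = signal.find_peaks(phasic, distance=max(int(round(0.5 * fs)), 1))
    total = 0.0
    n = 0
    kept = []
    for p in peaks:
        # onset: last local minimum (or window start) preceding the peak
        seg = phasic[max(0, p - int(10 * fs)) : p + 1]
        rel = seg[::-1]
        drops = np.flatnonzero(np.diff(rel) > 0)
        onset_val = rel[drops[0]] if len(drops) else seg.min()
        amp = phasic[p] - onset_val
        if amp >= min_amplitude:
            total += amp
            n += 1
            kept.append(p / fs)
    return total / duration, n, np.array(kept)


def eda_scr_statistic(
    eda: np.ndarray,
    rest_eda: np.ndarray,
    sfreq: float,
    tonic_window_s: float = 30.0,
    min_amplitude: float = 0.01,
) -> SCRFeature:
    """Sum of SCR amplitudes per second, trial and baseline-corrected.

    The rest baseline is processed identically but with a relaxed minimum
    length (rest segments may be shorter than the 30-s trial minimum).
    """
    trial, n, _ = _scr_sum_per_s(eda, sfreq, tonic_window_s, min_amplitude)
    rest, _, _ = _scr_sum_per_s(rest_eda, sfreq, tonic_window_s, min_amplitude,
                                min_duration=10.0)
    return SCRFeature(
        scr_sum_per_s=trial, n_peaks=n, rest_sum_per_s=rest,
        baseline_corrected=trial - rest,
    )
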