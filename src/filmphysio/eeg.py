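"""EEG preprocessing and band-power / engagement / arousal / valence indices.

Processing chain (mirrors a standard film-viewing pipeline):

1. decimate 1,000 Hz -> 125 Hz with a zero-phase anti-alias FIR;
2. zero-phase band-pass 0.05-30 Hz (gamma is excluded on purpose: scalp
   gamma is not separable from muscle activity);
3. bad-channel repair: a channel whose broadband power is >10x or <0.1x the
   montage median is replaced by the mean of its neighbours in a fixed
   adjacency list;
4. ocular correction by least-squares regression of each channel on the
   identically filtered EOG channel;
5. muscle-artifact masking: samples where any channel's within-trial z-score
   exceeds 10, dilated by +-0.5 s, are excluded from all spectral windows.

Band powers are the *median* across 1-s Hann windows (50% overlap) of the
mean Welch spectral density inside theta (4-8), alpha (8-12) and beta
(12-30 Hz). From them: engagement beta/(alpha+theta) and beta/alpha per
channel, the three pairwise band ratios, and the frontal scalars

    arousal = (beta_F3 + beta_F4) / (alpha_F3 + alpha_F4)
    valence = alpha_F4/beta_F4 - alpha_F3/beta_F3

Baseline correction subtracts the rest-segment value of each derived index
(index_trial - index_rest), not the underlying band powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._filters import decimate_fir, fir_bandpass
from .synth import EEG_CHANNELS

BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}

SFREQ_PROC = 125.0

#: fixed montage adjacency used for deterministic bad-channel repair
ADJACENCY = {
    "F7": ["F3", "T7"], "F3": ["F7", "Fz", "C3"], "Fz": ["F3", "F4", "Cz"],
    "F4": ["Fz", "F8", "C4"], "F8": ["F4", "T8"],
    "T7": ["F7", "C3", "P7"], "C3": ["F3", "T7", "Cz", "P3"],
    "Cz": ["Fz", "C3", "C4", "Pz"], "C4": ["F4", "Cz", "T8", "P4"],
    "T8": ["F8", "C4", "P8"],
    "P7": ["T7", "P3", "O1"], "P3": ["C3", "P7", "Pz", "O1"],
    "Pz": ["Cz", "P3", "P4", "Oz"], "P4": ["C4", "Pz", "P8", "O2"],
    "P8": ["T8", "P4", "O2"],
    "O1": ["P7", "P3", "Oz"], "Oz": ["Pz", "O1", "O2"], "O2": ["P4", "P8", "Oz"],
}


@dataclass
class PreprocessedEEG:
    data: np.ndarray  # (18, n) at 125 Hz
    mask: np.ndarray  # (n,) bool, True = rejected
    sfreq: float
    bad_channels: list


def preprocess_eeg(
    raw: np.ndarray,
    eog: np.ndarray,
    sfreq: float = 1000.0,
    z_thresh: float = 10.0,
    dilate_s: float = 0.5,
    eog_regression: bool = True,
) -> PreprocessedEEG:
    """Clean an 18-channel EEG trial; see module docstring for the chain."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != len(EEG_CHANNELS):
        raise ValueError(f"expected ({len(EEG_CHANNELS)}, n) EEG array, got {raw.shape}")
    if raw.shape[1] < 10 * sfreq:
        raise ValueError("trial shorter than 10 s")
    q = int(round(sfreq / SFREQ_PROC))
    # gross-artifact guard: clamp raw samples beyond 10 robust SDs to the
    # channel median so they cannot smear through the filters; the
    # neighbourhood is flagged in the rejection mask below
    med = np.median(raw, axis=1, keepdims=True)
    mad = np.median(np.abs(raw - med), axis=1, keepdims=True)
    robust_sd = np.maximum(1.4826 * mad, 1e-30)
    gross = np.abs(raw - med) > 10 * robust_sd * 3  # far beyond the z>10 rule
    raw = np.where(gross, med, raw)
    gross_any = gross.any(axis=0)
    x = decimate_fir(raw, q, sfreq, axis=-1)
    e = decimate_fir(np.asarray(eog, dtype=float), q, sfreq)
    # band-pass 0.05-30 Hz: Butterworth high-pass + FIR low-pass, both zero phase
    sos = signal.butter(2, 0.05, btype="highpass", fs=SFREQ_PROC, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    e = signal.sosfiltfilt(sos, e)
    x = fir_bandpass(x, SFREQ_PROC, None, 30.0, numtaps=257, axis=-1)
    e = fir_bandpass(e, SFREQ_PROC, None, 30.0, numtaps=257)

    # deterministic bad-channel repair
    power = np.mean(x ** 2, axis=1)
    med = np.median(power)
    bad = [ch for ch, p in zip(EEG_CHANNELS, power) if med > 0 and (p > 10 * med or p < 0.1 * med)]
    for ch in bad:
        nbrs = [n for n in ADJACENCY[ch] if n not in bad]
        if nbrs:
            idx = [EEG_CHANNELS.index(n) for n in nbrs]
            x[EEG_CHANNELS.index(ch)] = x[idx].mean(axis=0)

    if eog_regression and np.var(e) > 0:
        b = (x @ e) / (e @ e)  # per-channel least-squares coefficient
        x = x - b[:, None] * e[None, :]

    z = (x - x.mean(axis=1, keepdims=True)) / np.maximum(x.std(axis=1, keepdims=True), 1e-30)
    mask = np.any(np.abs(z) > z_thresh, axis=0)
    # carry the raw-domain gross-artifact flags down to the decimated rate
    n_dec = x.shape[1]
    gross_dec = np.zeros(n_dec, dtype=bool)
    gi = np.flatnonzero(gross_any) // q
    gross_dec[gi[gi < n_dec]] = True
    mask |= gross_dec
    if mask.any():
        w = int(round(dilate_s * SFREQ_PROC))
        idx = np.flatnonzero(mask)
        full = np.zeros(x.shape[1], dtype=bool)
        for i in idx:
            full[max(0, i - w) : i + w + 1] = True
        mask = full
    return PreprocessedEEG(data=x, mask=mask, sfreq=SFREQ_PROC, bad_channels=bad)


def welch_band_powers(
    data: np.ndarray,
    mask: np.ndarray | None = None,
    sfreq: float = SFREQ_PROC,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> dict:
    """Median-across-windows band power table.

    Per 1-s Hann window a periodogram (density scaling) is computed; per
    channel and band the *median over windows* of the mean density inside the
    band is returned. Windows overlapping masked samples are dropped.

    Returns ``{channel: {"theta": .., "alpha": .., "beta": ..}}``; a 1-D input
    is treated as a single unnamed channel ``{"ch0": ...}``.
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[None, :]
    n_ch, n = data.shape
    nper = int(round(window_s * sfreq))
    hop = max(int(round(nper * (1.0 - overlap))), 1)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    starts = np.arange(0, n - nper + 1, hop)
    good = [s for s in starts if not mask[s : s + nper].any()]
    if len(good) < 2:
        raise ValueError("fewer than 2 usable windows after masking")
    win = np.hanning(nper)
    scale = 1.0 / (sfreq * (win ** 2).sum())
    freqs = np.fft.rfftfreq(nper, 1.0 / sfreq)
    segs = np.stack([data[:, s : s + nper] for s in good], axis=1)  # (ch, w, nper)
    segs = (segs - segs.mean(axis=-1, keepdims=True)) * win
    psd = (np.abs(np.fft.rfft(segs, axis=-1)) ** 2) * scale
    psd[..., 1:-1] *= 2.0
    names = EEG_CHANNELS if n_ch == len(EEG_CHANNELS) else [f"ch{i}" for i in range(n_ch)]
    table = {}
    for ci, ch in enumerate(names[:n_ch]):
        row = {}
        for band, (lo, hi) in BANDS.items():
            sel = (freqs >= lo) & (freqs < hi)
            per_window = psd[ci][:, sel].mean(axis=1)
            row[band] = float(np.median(per_window))
        table[ch] = row
    return table


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def indices_from_powers(powers: dict) -> dict:
    """All per-channel and scalar indices from one band-power table."""
    out = {}
    for ch, p in powers.items():
        th, al, be = p["theta"], p["alpha"], p["beta"]
        out[f"{ch}_engagement_abt"] = _safe_ratio(be, al + th)
        out[f"{ch}_engagement_ba"] = _safe_ratio(be, al)
        out[f"{ch}_theta_alpha"] = _safe_ratio(th, al)
        out[f"{ch}_theta_beta"] = _safe_ratio(th, be)
        out[f"{ch}_alpha_beta"] = _safe_ratio(al, be)
    if "F3" in powers and "F4" in powers:
        f3, f4 = powers["F3"], powers["F4"]
        out["arousal"] = _safe_ratio(f3["beta"] + f4["beta"], f3["alpha"] + f4["alpha"])
        r4 = _safe_ratio(f4["alpha"], f4["beta"])
        r3 = _safe_ratio(f3["alpha"], f3["beta"])
        out["valence"] = r4 - r3
    return out


def compute_indices(trial_powers: dict, rest_powers: dict) -> dict:
    """Trial, rest, and baseline-corrected (trial - rest) index sets.

    Returns ``{"trial": {...}, "rest": {...}, "corrected": {...}}``; an index
    whose denominator vanishes is NaN (flagged missing, never fabricated).
    Baseline correction applies to the derived index values.
    """
    if set(trial_powers) != set(rest_powers):
        raise ValueError("trial and rest tables must cover the same channels")
    t = indices_from_powers(trial_powers)
    r = indices_from_powers(rest_powers)
    corrected = {k: t[k] - r[k] for k in t}
    return {"trial": t, "rest": r, "corrected": corrected}
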