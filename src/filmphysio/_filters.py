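"""Shared zero-phase filtering primitives.

All FIR filtering in the package goes through :func:`fir_bandpass`, which
convolves with a symmetric (linear-phase) windowed-sinc kernel and compensates
the group delay exactly, so filters are zero-phase without the cost of
forward-backward filtering on long records.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def fir_kernel(
    sfreq: float,
    lo: float | None,
    hi: float | None,
    numtaps: int = 513,
) -> np.ndarray:
    """Symmetric windowed-sinc FIR kernel (Hamming window).

    ``lo``/``hi`` are the band edges in Hz; ``None`` means the edge is open
    (pure low- or high-pass). ``numtaps`` must be odd so the kernel has an
    exact integer group delay.
    """
    if numtaps % 2 == 0:
        numtaps += 1
    if lo is not None and hi is not None:
        return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=sfreq)
    if hi is not None:
        return signal.firwin(numtaps, hi, pass_zero=True, fs=sfreq)
    if lo is not None:
        return signal.firwin(numtaps, lo, pass_zero=False, fs=sfreq)
    raise ValueError("at least one band edge required")


def zero_phase_fir(x: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Zero-phase FIR filtering by FFT convolution with a symmetric kernel.

    Edge handling: the signal is reflected at both ends by half the kernel
    length before convolution, matching filtfilt-style padding.
    """
    x = np.asarray(x, dtype=float)
    pad = len(taps) // 2
    if x.shape[axis] <= pad:
        # short signal: fall back to scipy filtfilt semantics via direct pad
        pad = x.shape[axis] - 1
    xp = np.concatenate(
        [
            np.flip(np.take(x, np.arange(1, pad + 1), axis=axis), axis=axis),
            x,
            np.flip(np.take(x, np.arange(x.shape[axis] - pad - 1, x.shape[axis] - 1), axis=axis), axis=axis),
        ],
        axis=axis,
    )
    y = signal.oaconvolve(xp, _shape_like(taps, xp.ndim, axis), mode="same", axes=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(pad, pad + x.shape[axis])
    return y[tuple(sl)]


def _shape_like(taps: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis % ndim] = len(taps)
    return taps.reshape(shape)


def fir_bandpass(
    x: np.ndarray,
    sfreq: float,
    lo: float | None,
    hi: float | None,
    numtaps: int = 513,
    axis: int = -1,
) -> np.ndarray:
    return zero_phase_fir(x, fir_kernel(sfreq, lo, hi, numtaps), axis=axis)


def decimate_fir(x: np.ndarray, q: int, sfreq: float, axis: int = -1) -> np.ndarray:
    """Anti-aliased integer-factor downsampling (zero-phase FIR then slicing)."""
    if q < 1 or int(q) != q:
        raise ValueError("decimation factor must be a positive integer")
    if q == 1:
        return np.asarray(x, dtype=float)
    taps = signal.firwin(257, 0.8 / q)  # cutoff at 0.8 x the new Nyquist
    return signal.resample_poly(
        np.asarray(x, dtype=float), 1, q, axis=axis, window=taps, padtype="line"
    )
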