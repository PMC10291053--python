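"""Signal complexity and entropy measures used as per-channel EEG features.

Eleven measures, implemented from their defining formulas (N = length, dx =
first differences, population variance throughout for internal consistency):

* Petrosian fractal dimension  PFD = log10 N / (log10 N + log10(N / (N + 0.4 S)))
  with S the number of sign changes of dx.
* Katz fractal dimension       KFD = log10 n / (log10 n + log10(d / L)),
  n = N - 1, L = sum|dx|, d = max_i |x_i - x_1|.
* Sevcik fractal dimension     SFD = 1 + ln(L*) / ln(2 (N - 1)), L* the curve
  length after normalising both axes to [0, 1].
* Permutation entropy (order 3, delay 1), normalised by ln 3!.
* Shannon entropy of a ceil(sqrt(N))-bin value histogram, bits.
* Spectral entropy of the normalised Welch PSD, normalised by log2 K.
* SVD entropy of the (m=3, delay 1) embedding's normalised singular values, bits.
* Fisher information sum_i (s_{i+1} - s_i)^2 / s_i over the same values.
* Hjorth complexity mobility(dx) / mobility(x), mobility(y) = sqrt(var(dy)/var(y)).
* Relative roughness RR = 2 (1 - acov(1)/acov(0)).
* Differential entropy (Gaussian closed form) DE = 0.5 ln(2 pi e var(x)), nats.

Degenerate inputs: a constant series returns the fractal dimensions as 1 by
convention and every variance-based measure as NaN; NaN inputs are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal


@dataclass
class ComplexityFeatures:
    pfd: float
    kfd: float
    sfd: float
    pen: float
    shanen: float
    specen: float
    svden: float
    fi: float
    hjorth: float
    rr: float
    de: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "pfd", "kfd", "sfd", "pen", "shanen", "specen", "svden", "fi",
            "hjorth", "rr", "de",
        )}


def _embed(x: np.ndarray, m: int = 3, delay: int = 1) -> np.ndarray:
    n = len(x) - (m - 1) * delay
    return np.stack([x[i * delay : i * delay + n] for i in range(m)], axis=1)


def petrosian_fd(x: np.ndarray) -> float:
    n = len(x)
    dx = np.diff(x)
    s = int(np.sum(np.signbit(dx[1:]) != np.signbit(dx[:-1])))
    ln = math.log10(n)
    return ln / (ln + math.log10(n / (n + 0.4 * s)))


def katz_fd(x: np.ndarray) -> float:
    dx = np.diff(x)
    length = float(np.sum(np.abs(dx)))
    d = float(np.max(np.abs(x - x[0])))
    if length == 0 or d == 0:
        return 1.0
    n = len(x) - 1
    return math.log10(n) / (math.log10(n) + math.log10(d / length))


def sevcik_fd(x: np.ndarray) -> float:
    n = len(x)
    rng = np.ptp(x)
    if rng == 0:
        return 1.0
    y = (x - x.min()) / rng
    t = np.linspace(0.0, 1.0, n)
    lstar = float(np.sum(np.hypot(np.diff(t), np.diff(y))))
    return 1.0 + math.log(lstar) / math.log(2.0 * (n - 1))


def permutation_entropy(x: np.ndarray, m: int = 3, delay: int = 1) -> float:
    """Normalised permutation entropy; ordinal ties broken by stable argsort."""
    emb = _embed(x, m, delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m - 1, -1, -1))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(m)))


def shannon_entropy(x: np.ndarray) -> float:
    bins = int(np.ceil(np.sqrt(len(x))))
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def spectral_entropy(x: np.ndarray, sfreq: float = 125.0, nperseg: int = 256) -> float:
    nper = min(nperseg, len(x))
    _, psd = _signal.welch(x, fs=sfreq, nperseg=nper)
    total = psd.sum()
    if total <= 0:
        return float("nan")
    q = psd[psd > 0] / total
    return float(-np.sum(q * np.log2(q)) / np.log2(len(psd)))


def _normalized_singular_values(x: np.ndarray, m: int = 3, delay: int = 1) -> np.ndarray:
    sv = np.linalg.svd(_embed(x, m, delay), compute_uv=False)
    return sv / sv.sum()


def svd_entropy(x: np.ndarray, m: int = 3, delay: int = 1) -> float:
    s = _normalized_singular_values(x, m, delay)
    s = s[s > 0]
    return float(-np.sum(s * np.log2(s)))


def fisher_information(x: np.ndarray, m: int = 3, delay: int = 1) -> float:
    s = _normalized_singular_values(x, m, delay)
    return float(np.sum(np.diff(s) ** 2 / s[:-1]))


def hjorth_complexity(x: np.ndarray) -> float:
    def mobility(y: np.ndarray) -> float:
        v = np.var(y)
        if v == 0:
            return float("nan")
        return math.sqrt(np.var(np.diff(y)) / v)

    return mobility(np.diff(x)) / mobility(x)


def relative_roughness(x: np.ndarray) -> float:
    xc = x - x.mean()
    g0 = float(np.mean(xc * xc))
    if g0 == 0:
        return float("nan")
    g1 = float(np.mean(xc[:-1] * xc[1:]))
    return 2.0 * (1.0 - g1 / g0)


def differential_entropy(x: np.ndarray) -> float:
    v = np.var(x)
    if v == 0:
        return float("nan")
    return 0.5 * math.log(2.0 * math.pi * math.e * v)


def compute_complexity(x: np.ndarray, sfreq: float = 125.0) -> ComplexityFeatures:
    """All eleven measures for one channel. Requires N >= 64 finite samples."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("compute_complexity expects a 1-D series")
    if len(x) < 64:
        raise ValueError("series shorter than 64 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input")
    if np.ptp(x) == 0:
        nan = float("nan")
        return ComplexityFeatures(1.0, 1.0, 1.0, nan, 0.0, nan, nan, nan, nan, nan, nan)
    return ComplexityFeatures(
        pfd=petrosian_fd(x),
        kfd=katz_fd(x),
        sfd=sevcik_fd(x),
        pen=permutation_entropy(x),
        shanen=shannon_entropy(x),
        specen=spectral_entropy(x, sfreq=sfreq),
        svden=svd_entropy(x),
        fi=fisher_information(x),
        hjorth=hjorth_complexity(x),
        rr=relative_roughness(x),
        de=differential_entropy(x),
    )
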