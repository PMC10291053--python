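"""Synthetic multimodal cohort generator.

Emulates a film-viewing psychophysiology experiment: each of ``n_subjects``
watches every film in the design while 18-channel EEG, EOG, photoplethysmogram
(PPG), two facial EMG channels (*zygomaticus major*, *corrugator supercilii*)
and skin conductance (EDA) are recorded at 1,000 Hz, with a rest baseline
preceding each film, and afterwards rates the film on an integer 1-10 scale.

Ground-truth effect structure is planted explicitly so every downstream stage
(feature extraction, statistics, prediction) can be validated:

* a per-subject genre effect on facial EMG amplitude (zygomaticus up for
  comedies, corrugator up for dramas) with configurable paired Cohen's d;
* latent per-trial engagement and valence that drive both the EEG spectrum
  (global beta scaling; frontal alpha asymmetry) and, through solved linear
  coefficients, the rating, hitting configured target correlations.

Determinism: every stream of every trial draws from an independent generator
seeded by ``SeedSequence(master_seed, spawn_key=(subject_idx, film_idx,
stream_code))`` (rest segments use ``stream_code + 16``; cohort-level draws use
spawn key ``(999999,)``), so any single trial is regenerable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._filters import fir_bandpass

EEG_CHANNELS = [
    "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P8", "P4", "Pz", "P3", "P7",
    "O1", "Oz", "O2",
]

ALL_STREAMS = ("eeg", "eog", "ppg", "emg_zyg", "emg_corr", "eda")

_STREAM_CODES = {"eeg": 0, "eog": 0, "ppg": 1, "emg_zyg": 2, "emg_corr": 3, "eda": 4}

# relative blink projection onto the scalp (strongest frontally)
_BLINK_GAIN = {
    **{ch: 1.0 for ch in ("F7", "F3", "Fz", "F4", "F8")},
    **{ch: 0.4 for ch in ("T7", "C3", "Cz", "C4", "T8")},
    **{ch: 0.15 for ch in ("P8", "P4", "Pz", "P3", "P7")},
    **{ch: 0.05 for ch in ("O1", "Oz", "O2")},
}

#: time from a beat (pulse onset) to the maximum of the PPG pulse template, s
PULSE_PEAK_OFFSET = 0.15


@dataclass(frozen=True)
class FilmSpec:
    film_id: str
    duration: float  # s
    genre: str  # "comedy" | "drama"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"FilmSpec.duration must be > 0, got {self.duration}")
        if self.genre not in ("comedy", "drama"):
            raise ValueError(f"FilmSpec.genre must be comedy/drama, got {self.genre!r}")


#: the 8-film design: 4 comedies and 4 dramas, durations 261-445 s
DEFAULT_FILMS = (
    FilmSpec("film1", 318.0, "comedy"),
    FilmSpec("film2", 395.0, "comedy"),
    FilmSpec("film3", 364.0, "comedy"),
    FilmSpec("film4", 445.0, "comedy"),
    FilmSpec("film5", 261.0, "drama"),
    FilmSpec("film6", 391.0, "drama"),
    FilmSpec("film7", 346.0, "drama"),
    FilmSpec("film8", 394.0, "drama"),
)


@dataclass
class CohortConfig:
    """Full parameterisation of the synthetic cohort.

    Effect sizes
    ------------
    genre_emg_d
        Target paired Cohen's d of the genre contrast on facial EMG burst
        amplitude (zygomaticus: comedy > drama; corrugator: drama > comedy).
    rating_engagement_r, rating_valence_r
        Target trialwise Pearson correlation between the latent engagement /
        valence variables and the integer rating.
    """

    n_subjects: int = 21
    films: Sequence[FilmSpec] = DEFAULT_FILMS
    sfreq_raw: float = 1000.0
    rest_duration: float = 60.0
    streams: Sequence[str] = ALL_STREAMS
    # planted effects
    genre_emg_d: float = 0.7
    rating_engagement_r: float = 0.4
    rating_valence_r: float = 0.2
    # rating model
    rating_mean: float = 6.2
    subject_mean_sd: float = 0.8
    rating_noise_sd: float = 1.5
    # EEG spectrum
    band_weights: dict = field(default_factory=lambda: {"theta": 1.0, "alpha": 1.5, "beta": 0.8})
    pink_noise_level: float = 1.0
    blink_rate: float = 0.1  # blinks/s during films (subjects asked to limit blinking)
    eeg_engagement_gain: float = 0.4  # log-scale beta modulation per SD of engagement
    eeg_valence_gain: float = 0.3  # log-scale frontal alpha asymmetry per SD of valence
    eeg_arousal_gain: float = 0.2  # log-scale frontal beta modulation, arousal residual
    # EMG
    emg_burst_rate: float = 0.1  # bursts/s
    emg_base_amplitude: float = 1.0  # burst amplitude relative to the tonic envelope
    emg_effect_sd: float = 0.2  # between-subject SD of the relative genre contrast
    # cardiac
    mean_rr_ms: float = 800.0
    between_subject_rr_sd: float = 60.0
    sdnn_ms: float = 50.0
    ar_phi: float = 0.3
    # electrodermal
    scr_rate_per_min: float = 3.0
    scr_amplitude: float = 0.4  # uS
    tonic_level: float = 5.0  # uS
    tonic_drift: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.films) < 2:
            raise ValueError("films must contain at least 2 entries")
        if self.genre_emg_d != 0:
            genres = {f.genre for f in self.films}
            if genres != {"comedy", "drama"}:
                raise ValueError("genre_emg_d != 0 requires at least one film per genre")
        for name in ("genre_emg_d", "rating_engagement_r", "rating_valence_r"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if abs(self.rating_engagement_r) + 0 >= 1 or abs(self.rating_valence_r) >= 1:
            raise ValueError("target correlations must satisfy |r| < 1")
        if self.rating_engagement_r ** 2 + self.rating_valence_r ** 2 >= 1:
            raise ValueError("rating_engagement_r^2 + rating_valence_r^2 must be < 1")
        if self.sfreq_raw <= 0:
            raise ValueError("sfreq_raw must be > 0")
        if self.rest_duration <= 0:
            raise ValueError("rest_duration must be > 0")
        unknown = set(self.streams) - set(ALL_STREAMS)
        if unknown:
            raise ValueError(f"unknown streams: {sorted(unknown)}")
        if not (0 <= self.ar_phi < 1):
            raise ValueError("ar_phi must be in [0, 1)")
        if self.mean_rr_ms <= 0:
            raise ValueError("mean_rr_ms must be > 0")
        if self.sdnn_ms < 0:
            raise ValueError("sdnn_ms must be >= 0")
        if self.scr_rate_per_min < 0:
            raise ValueError("scr_rate_per_min must be >= 0")


@dataclass
class TrialRecording:
    """One subject x film recording with its rest baseline."""

    subject_id: str
    film_id: str
    genre: str
    rating: int
    signals: dict  # stream -> ndarray; 'eeg' has shape (18, n)
    rest: dict  # stream -> ndarray, rest_duration long
    sfreq: dict  # stream -> Hz
    channels: Sequence[str] = tuple(EEG_CHANNELS)
    duration: float = 0.0
    rest_duration: float = 60.0


def _rng(master: int, subj: int, film: int, stream: str, rest: bool = False) -> np.random.Generator:
    code = _STREAM_CODES[stream] + (16 if rest else 0)
    return np.random.default_rng(np.random.SeedSequence(master, spawn_key=(subj, film, code)))


# ---------------------------------------------------------------------------
# per-stream synthesizers
# ---------------------------------------------------------------------------

def _band_shaped_noise(
    n: int,
    sfreq: float,
    band_weights: dict,
    pink_level: float,
    rng: np.random.Generator,
    channel_band_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Multi-channel noise whose PSD is flat at ``w_b`` inside each band.

    Equivalent to summing ideal band-filtered white-noise processes scaled to
    the requested relative band powers, plus a 1/f background. Implemented in
    the frequency domain (one inverse FFT per channel).

    channel_band_scale : (n_channels, 3) multiplicative power scale per channel
    and band (theta, alpha, beta order), or None for all ones.
    """
    bands = [("theta", 4.0, 8.0), ("alpha", 8.0, 12.0), ("beta", 12.0, 30.0)]
    n_ch = 1 if channel_band_scale is None else channel_band_scale.shape[0]
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    base = np.zeros_like(freqs)
    fl = np.maximum(freqs, 0.5)
    base += pink_level ** 2 * (1.0 / fl)  # 1/f background power density shape
    out = np.empty((n_ch, n))
    for c in range(n_ch):
        env2 = base.copy()
        for b, (name, lo, hi) in enumerate(bands):
            w = band_weights.get(name, 0.0)
            if channel_band_scale is not None:
                w = w * channel_band_scale[c, b]
            sel = (freqs >= lo) & (freqs < hi)
            env2[sel] += w / (hi - lo) * (sfreq / 2.0)  # variance w inside the band
        spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) * np.sqrt(env2 / 2.0)
        spec[0] = 0.0
        if n % 2 == 0:
            spec[-1] = spec[-1].real * np.sqrt(2.0)
        out[c] = np.fft.irfft(spec, n=n) * np.sqrt(n * 1.0)
    return out


def blink_template(sfreq: float) -> np.ndarray:
    """Fixed 400-ms biphasic blink transient (unit peak amplitude)."""
    t = np.arange(int(round(0.4 * sfreq))) / sfreq
    tpl = np.sin(2 * np.pi * t / 0.4) * np.hanning(len(t))
    return tpl / np.abs(tpl).max()


def synth_eeg(
    duration: float,
    sfreq: float,
    band_weights: dict,
    pink_noise_level: float = 1.0,
    blink_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    channel_band_scale: np.ndarray | None = None,
    amplitude: float = 10.0,
    eog_noise: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize an 18-channel EEG segment plus a shared-blink EOG channel.

    Returns ``(eeg, eog)`` with ``eeg`` in uV, shape ``(18, duration*sfreq)``.
    """
    if duration <= 0 or sfreq <= 0:
        raise ValueError("duration and sfreq must be > 0")
    if any(w < 0 for w in band_weights.values()):
        raise ValueError("band_weights must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sfreq))
    if channel_band_scale is None:
        channel_band_scale = np.ones((len(EEG_CHANNELS), 3))
    eeg = amplitude * _band_shaped_noise(
        n, sfreq, band_weights, pink_noise_level, rng, channel_band_scale
    )
    eog = eog_noise * rng.standard_normal(n)
    if blink_rate > 0:
        tpl = blink_template(sfreq)
        n_blinks = rng.poisson(blink_rate * duration)
        starts = rng.integers(0, max(1, n - len(tpl)), size=n_blinks)
        gains = np.array([_BLINK_GAIN[ch] for ch in EEG_CHANNELS])
        for s in starts:
            amp = 150.0 * rng.uniform(0.8, 1.2)
            seg = tpl * amp
            eog[s : s + len(tpl)] += seg * 2.0
            eeg[:, s : s + len(tpl)] += gains[:, None] * seg[None, :] * 0.5
    return eeg, eog


def _pulse_template(sfreq: float) -> np.ndarray:
    """Stereotyped PPG pulse, peaking ``PULSE_PEAK_OFFSET`` s after onset."""
    t = np.arange(int(round(0.5 * sfreq))) / sfreq
    tpl = np.exp(-0.5 * ((t - PULSE_PEAK_OFFSET) / 0.05) ** 2)
    tpl += 0.3 * np.exp(-0.5 * ((t - PULSE_PEAK_OFFSET - 0.15) / 0.08) ** 2)  # dicrotic bump
    return tpl


def synth_cardiac(
    duration: float,
    mean_rr: float,
    sdnn_target: float,
    phi: float = 0.3,
    seed: int | np.random.Generator = 0,
    sfreq: float = 1000.0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """AR(1) interbeat intervals and the PPG waveform built from them.

    ``RR_i = mu + phi (RR_{i-1} - mu) + eps`` with eps scaled so the stationary
    SD equals ``sdnn_target`` (ms). Returns ``(rr_ms, beat_times_s, ppg)``.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be > 0")
    if not 0 <= phi < 1:
        raise ValueError("phi must be in [0, 1)")
    if sdnn_target < 0:
        raise ValueError("sdnn_target must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_beats = int(np.ceil(duration * 1000.0 / mean_rr)) + 16
    eps_sd = sdnn_target * np.sqrt(1.0 - phi ** 2)
    rr = np.empty(n_beats)
    x = rng.standard_normal() * sdnn_target
    for i in range(n_beats):
        rr[i] = mean_rr + x
        x = phi * x + eps_sd * rng.standard_normal()
    rr = np.clip(rr, 300.0, None)
    beat_times = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    keep = beat_times < duration
    beat_times = beat_times[keep]
    rr = np.diff(beat_times) * 1000.0
    n = int(round(duration * sfreq))
    ppg = np.zeros(n)
    tpl = _pulse_template(sfreq)
    for bt in beat_times:
        s = int(round(bt * sfreq))
        e = min(s + len(tpl), n)
        ppg[s:e] += tpl[: e - s]
    if noise_sd > 0:
        ppg = ppg + noise_sd * rng.standard_normal(n)
    return rr, beat_times, ppg


def synth_emg(
    duration: float,
    sfreq: float,
    burst_rate: float,
    burst_amplitude: float,
    seed: int | np.random.Generator = 0,
    baseline_level: float = 1.0,
    burst_width: float = 0.5,
) -> np.ndarray:
    """Surface-EMG-like waveform: 10-350 Hz noise carrier modulated by an
    envelope of ``baseline_level`` plus smooth Gaussian bursts."""
    if sfreq < 700:
        raise ValueError("sfreq must be >= 700 Hz to represent 10-350 Hz content")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sfreq))
    carrier = fir_bandpass(rng.standard_normal(n), sfreq, 10.0, min(350.0, 0.45 * sfreq), numtaps=257)
    carrier /= max(carrier.std(), 1e-12)
    env = np.full(n, baseline_level)
    if burst_rate > 0 and burst_amplitude != 0:
        n_bursts = rng.poisson(burst_rate * duration)
        centers = rng.uniform(0, duration, size=n_bursts)
        half = int(round(4 * burst_width * sfreq))
        for c in centers:
            ci = int(round(c * sfreq))
            lo, hi = max(0, ci - half), min(n, ci + half + 1)
            tloc = (np.arange(lo, hi) / sfreq) - c
            env[lo:hi] += burst_amplitude * np.exp(-0.5 * (tloc / burst_width) ** 2)
    return carrier * env


def bateman_kernel(t: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    """Unit-amplitude-parameter biexponential SCR kernel exp(-t/tau_d) - exp(-t/tau_r)."""
    if tau_r >= tau_d:
        raise ValueError("tau_r must be < tau_d")
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    k[t < 0] = 0.0
    return k


def bateman_kernel_max(tau_r: float, tau_d: float) -> float:
    """Analytic maximum of the unit Bateman kernel."""
    if tau_r >= tau_d:
        raise ValueError("tau_r must be < tau_d")
    t_star = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    return float(np.exp(-t_star / tau_d) - np.exp(-t_star / tau_r))


def synth_eda(
    duration: float,
    sfreq: float,
    scr_rate: float,
    scr_amplitude: float,
    tonic_drift: float = 0.1,
    seed: int | np.random.Generator = 0,
    tonic_level: float = 5.0,
    tau_r: float = 0.75,
    tau_d: float = 3.0,
    amplitude_jitter: float = 0.3,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Skin-conductance trace: slow tonic drift plus Poisson SCR events.

    Each event contributes ``A * (exp(-t/tau_d) - exp(-t/tau_r))``. Returns the
    trace (uS) and a ground-truth table of event onsets and amplitude
    parameters ``A``.
    """
    if scr_rate < 0:
        raise ValueError("scr_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * sfreq))
    t = np.arange(n) / sfreq
    # tonic: level + slow sinusoid mixture
    tonic = tonic_level + tonic_drift * (
        np.sin(2 * np.pi * t / max(duration, 60.0) + rng.uniform(0, 2 * np.pi))
        + 0.5 * np.sin(2 * np.pi * t / 37.0 + rng.uniform(0, 2 * np.pi))
    )
    x = tonic.copy()
    n_events = rng.poisson(scr_rate / 60.0 * duration)
    onsets = np.sort(rng.uniform(0, max(duration - 5.0, duration * 0.5), size=n_events))
    amps = scr_amplitude * np.exp(amplitude_jitter * rng.standard_normal(n_events))
    ktime = np.arange(int(round(min(8 * tau_d, duration) * sfreq))) / sfreq
    kern = bateman_kernel(ktime, tau_r, tau_d)
    for onset, a in zip(onsets, amps):
        s = int(round(onset * sfreq))
        e = min(s + len(kern), n)
        x[s:e] += a * kern[: e - s]
    events = pd.DataFrame({"onset_s": onsets, "amplitude": amps})
    return x, events


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def solve_rating_betas(config: CohortConfig) -> tuple[float, float, float]:
    """Coefficients (beta_e, beta_v, latent rating SD) hitting the target
    trialwise correlations on the continuous (pre-rounding) scale."""
    re_, rv = config.rating_engagement_r, config.rating_valence_r
    v0 = config.subject_mean_sd ** 2 + config.rating_noise_sd ** 2
    s2 = v0 / (1.0 - re_ ** 2 - rv ** 2)
    s = np.sqrt(s2)
    return re_ * s, rv * s, s


def cohort_plan(config: CohortConfig) -> dict:
    """Cohort-level draws (latents, ratings, subject parameters) and the
    ground-truth table, without synthesizing any signal."""
    config.validate()
    master = int(config.seed)
    films = list(config.films)
    n_s, n_f = config.n_subjects, len(films)
    crng = np.random.default_rng(np.random.SeedSequence(master, spawn_key=(999999,)))

    # cohort-level draws
    subj_mu = config.rating_mean + config.subject_mean_sd * crng.standard_normal(n_s)
    subj_rr = config.mean_rr_ms + config.between_subject_rr_sd * crng.standard_normal(n_s)
    subj_rr = np.clip(subj_rr, 450.0, 1400.0)
    subj_emg_scale = np.exp(0.3 * crng.standard_normal((n_s, 2)))  # zyg, corr
    # per-subject genre contrast delta_i ~ N(d*sigma_e, sigma_e) added to the
    # tonic envelope (+delta/2 in the preferred genre, -delta/2 otherwise).
    # The contrast is additive, not scaled by the subject's overall amplitude:
    # a multiplicative plant would inflate the between-subject SD of the
    # contrast and attenuate the realized paired Cohen's d below genre_emg_d.
    delta = config.genre_emg_d * config.emg_effect_sd
    subj_genre_delta = delta + config.emg_effect_sd * crng.standard_normal((n_s, 2))

    z_e = crng.standard_normal((n_s, n_f))
    z_v = crng.standard_normal((n_s, n_f))
    z_a_res = crng.standard_normal((n_s, n_f))
    z_a = 0.6 * z_e + 0.8 * z_a_res
    b_e, b_v, _ = solve_rating_betas(config)
    noise = config.rating_noise_sd * crng.standard_normal((n_s, n_f))
    raw_rating = subj_mu[:, None] + b_e * z_e + b_v * z_v + noise
    ratings = np.clip(np.rint(raw_rating), 1, 10).astype(int)

    rows = []
    for si in range(n_s):
        sid = f"s{si + 1:02d}"
        for fi, film in enumerate(films):
            rows.append({
                "subject_id": sid,
                "film_id": film.film_id,
                "genre": film.genre,
                "rating": int(ratings[si, fi]),
                "engagement": z_e[si, fi],
                "valence": z_v[si, fi],
                "arousal": z_a[si, fi],
                "subject_rating_mean": subj_mu[si],
                "subject_mean_rr_ms": subj_rr[si],
                "zyg_genre_delta": subj_genre_delta[si, 0],
                "corr_genre_delta": subj_genre_delta[si, 1],
                "beta_engagement": b_e,
                "beta_valence": b_v,
            })
    return {
        "films": films,
        "ratings": ratings,
        "z_e": z_e, "z_v": z_v, "z_a_res": z_a_res,
        "subj_rr": subj_rr,
        "subj_emg_scale": subj_emg_scale,
        "subj_genre_delta": subj_genre_delta,
        "truth": pd.DataFrame(rows),
    }


def iter_cohort(config: CohortConfig):
    """Yield the cohort's trials one at a time (memory-bounded; a full-length
    multimodal trial holds tens of MB of samples)."""
    plan = cohort_plan(config)
    master = int(config.seed)
    streams = tuple(config.streams)
    for si in range(config.n_subjects):
        sid = f"s{si + 1:02d}"
        for fi, film in enumerate(plan["films"]):
            yield _make_trial(
                config, master, si, fi, film, sid,
                rating=int(plan["ratings"][si, fi]),
                z_e=plan["z_e"][si, fi], z_v=plan["z_v"][si, fi],
                z_a_res=plan["z_a_res"][si, fi],
                subj_rr=plan["subj_rr"][si],
                emg_scale=plan["subj_emg_scale"][si],
                genre_delta=plan["subj_genre_delta"][si],
                streams=streams,
            )


def generate_cohort(config: CohortConfig) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Generate the full cohort and its ground-truth table.

    Returns ``(trials, truth)`` where ``truth`` has one row per subject x film
    with the latent engagement/valence/arousal draws, the planted per-stream
    parameters and the integer rating. For large cohorts prefer
    :func:`iter_cohort` plus :func:`cohort_plan`.
    """
    return list(iter_cohort(config)), cohort_plan(config)["truth"]


def _make_trial(
    config: CohortConfig, master: int, si: int, fi: int, film: FilmSpec, sid: str,
    rating: int, z_e: float, z_v: float, z_a_res: float,
    subj_rr: float, emg_scale: np.ndarray, genre_delta: np.ndarray,
    streams: tuple,
) -> TrialRecording:
    fs = config.sfreq_raw
    signals: dict = {}
    rest: dict = {}
    sfreqs: dict = {}

    if "eeg" in streams or "eog" in streams:
        scale = _channel_band_scale(config, z_e, z_v, z_a_res)
        eeg, eog = synth_eeg(
            film.duration, fs, config.band_weights, config.pink_noise_level,
            config.blink_rate, _rng(master, si, fi, "eeg"), channel_band_scale=scale,
        )
        r_eeg, r_eog = synth_eeg(
            config.rest_duration, fs, config.band_weights, config.pink_noise_level,
            config.blink_rate, _rng(master, si, fi, "eeg", rest=True),
        )
        signals["eeg"], signals["eog"] = eeg, eog
        rest["eeg"], rest["eog"] = r_eeg, r_eog
        sfreqs["eeg"] = sfreqs["eog"] = fs

    if "ppg" in streams:
        _, _, ppg = synth_cardiac(
            film.duration, subj_rr, config.sdnn_ms, config.ar_phi,
            _rng(master, si, fi, "ppg"), sfreq=fs, noise_sd=0.02,
        )
        _, _, r_ppg = synth_cardiac(
            config.rest_duration, subj_rr, config.sdnn_ms, config.ar_phi,
            _rng(master, si, fi, "ppg", rest=True), sfreq=fs, noise_sd=0.02,
        )
        signals["ppg"], rest["ppg"] = ppg, r_ppg
        sfreqs["ppg"] = fs

    for mi, (stream, muscle_pref_genre) in enumerate(
        [("emg_zyg", "comedy"), ("emg_corr", "drama")]
    ):
        if stream not in streams:
            continue
        g = 1.0 if film.genre == muscle_pref_genre else -1.0
        tone = max(emg_scale[mi] + 0.5 * g * genre_delta[mi], 0.05)
        signals[stream] = synth_emg(
            film.duration, fs, config.emg_burst_rate,
            config.emg_base_amplitude * tone,
            _rng(master, si, fi, stream), baseline_level=tone,
        )
        rest[stream] = synth_emg(
            config.rest_duration, fs, config.emg_burst_rate * 0.5,
            config.emg_base_amplitude * emg_scale[mi] * 0.5,
            _rng(master, si, fi, stream, rest=True), baseline_level=emg_scale[mi],
        )
        sfreqs[stream] = fs

    if "eda" in streams:
        eda, _ = synth_eda(
            film.duration, fs, config.scr_rate_per_min, config.scr_amplitude,
            config.tonic_drift, _rng(master, si, fi, "eda"), tonic_level=config.tonic_level,
        )
        r_eda, _ = synth_eda(
            config.rest_duration, fs, config.scr_rate_per_min * 0.7, config.scr_amplitude,
            config.tonic_drift, _rng(master, si, fi, "eda", rest=True),
            tonic_level=config.tonic_level,
        )
        signals["eda"], rest["eda"] = eda, r_eda
        sfreqs["eda"] = fs

    return TrialRecording(
        subject_id=sid, film_id=film.film_id, genre=film.genre, rating=rating,
        signals=signals, rest=rest, sfreq=sfreqs,
        duration=film.duration, rest_duration=config.rest_duration,
    )


def _channel_band_scale(config: CohortConfig, z_e: float, z_v: float, z_a_res: float) -> np.ndarray:
    """Per-channel (theta, alpha, beta) power multipliers planting the latent
    engagement (global beta), valence (frontal alpha asymmetry: F4 up / F3
    down for positive valence) and residual arousal (frontal beta) effects."""
    scale = np.ones((len(EEG_CHANNELS), 3))
    scale[:, 2] *= np.exp(config.eeg_engagement_gain * z_e)
    i_f3 = EEG_CHANNELS.index("F3")
    i_f4 = EEG_CHANNELS.index("F4")
    scale[i_f4, 1] *= np.exp(+config.eeg_valence_gain * z_v / 2.0)
    scale[i_f3, 1] *= np.exp(-config.eeg_valence_gain * z_v / 2.0)
    for ch in ("F7", "F3", "Fz", "F4", "F8"):
        scale[EEG_CHANNELS.index(ch), 2] *= np.exp(config.eeg_arousal_gain * z_a_res)
    return scale


def null_config(**overrides) -> CohortConfig:
    """A cohort configuration with every planted effect switched off."""
    cfg = CohortConfig(
        genre_emg_d=0.0, rating_engagement_r=0.0, rating_valence_r=0.0,
        eeg_engagement_gain=0.0, eeg_valence_gain=0.0, eeg_arousal_gain=0.0,
    )
    return replace(cfg, **overrides)
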