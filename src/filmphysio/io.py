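"""Trial serialization: delimited long format and 16-bit EDF.

Delimited format: one CSV per trial with columns ``time_s, stream, channel,
value``; rest-segment samples carry negative times (the film starts at 0).
Round-trips exactly (full float precision).

EDF: a minimal EDF-conformant writer (1-s data records, 16-bit samples,
per-signal physical scaling). Each trial file holds the rest segment followed
by the film period; the rest duration is recorded in the cohort manifest.
Round-trips within the format's 16-bit quantization. ``read_trial_edf`` parses
the same subset; files are also readable by any standard EDF reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import EEG_CHANNELS, TrialRecording

_SIGNAL_ORDER = ("eeg", "eog", "ppg", "emg_zyg", "emg_corr", "eda")
_UNITS = {"eeg": "uV", "eog": "uV", "ppg": "au", "emg_zyg": "uV", "emg_corr": "uV", "eda": "uS"}


# ---------------------------------------------------------------------------
# delimited long format
# ---------------------------------------------------------------------------

def write_trial_delimited(rec: TrialRecording, path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for stream in _SIGNAL_ORDER:
        if stream not in rec.signals:
            continue
        fs = rec.sfreq[stream]
        for segment, sign in (("rest", -1.0), ("film", 1.0)):
            data = rec.rest[stream] if segment == "rest" else rec.signals[stream]
            if stream == "eeg":
                n = data.shape[1]
                t = _segment_times(n, fs, segment)
                for ci, ch in enumerate(EEG_CHANNELS):
                    frames.append(pd.DataFrame(
                        {"time_s": t, "stream": stream, "channel": ch, "value": data[ci]}
                    ))
            else:
                n = len(data)
                t = _segment_times(n, fs, segment)
                frames.append(pd.DataFrame(
                    {"time_s": t, "stream": stream, "channel": stream, "value": data}
                ))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _segment_times(n: int, fs: float, segment: str) -> np.ndarray:
    if segment == "rest":
        return (np.arange(n) - n) / fs
    return np.arange(n) / fs


def read_trial_delimited(
    path: str | Path,
    subject_id: str = "",
    film_id: str = "",
    genre: str = "",
    rating: int = 0,
) -> TrialRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "stream", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"malformed delimited trial: missing {sorted(required - set(df.columns))}")
    signals: dict = {}
    rest: dict = {}
    sfreq: dict = {}
    duration = 0.0
    rest_duration = 0.0
    for stream, g in df.groupby("stream", sort=False):
        film = g[g["time_s"] >= 0]
        rst = g[g["time_s"] < 0]
        if stream == "eeg":
            sig = np.stack([
                film.loc[film["channel"] == ch, "value"].to_numpy() for ch in EEG_CHANNELS
            ])
            rsig = np.stack([
                rst.loc[rst["channel"] == ch, "value"].to_numpy() for ch in EEG_CHANNELS
            ])
            t = film.loc[film["channel"] == EEG_CHANNELS[0], "time_s"].to_numpy()
        else:
            sig = film["value"].to_numpy()
            rsig = rst["value"].to_numpy()
            t = film["time_s"].to_numpy()
        fs = round(1.0 / np.median(np.diff(t)), 6) if len(t) > 1 else 1.0
        signals[stream], rest[stream], sfreq[stream] = sig, rsig, fs
        n_film = sig.shape[-1]
        duration = max(duration, n_film / fs)
        rest_duration = max(rest_duration, rsig.shape[-1] / fs)
    return TrialRecording(
        subject_id=subject_id, film_id=film_id, genre=genre, rating=rating,
        signals=signals, rest=rest, sfreq=sfreq,
        duration=duration, rest_duration=rest_duration,
    )


# ---------------------------------------------------------------------------
# minimal EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_trial_edf(rec: TrialRecording, path: str | Path) -> Path:
    """Write rest + film as one continuous multi-signal EDF file."""
    path = Path(path)
    labels, data, rates, units = [], [], [], []
    for stream in _SIGNAL_ORDER:
        if stream not in rec.signals:
            continue
        full = (
            np.concatenate([rec.rest[stream], rec.signals[stream]], axis=-1)
            if stream != "eeg"
            else np.concatenate([rec.rest[stream], rec.signals[stream]], axis=1)
        )
        fs = rec.sfreq[stream]
        if stream == "eeg":
            for ci, ch in enumerate(EEG_CHANNELS):
                labels.append(f"EEG {ch}")
                data.append(full[ci])
                rates.append(fs)
                units.append(_UNITS[stream])
        else:
            labels.append(stream.upper().replace("_", " "))
            data.append(full)
            rates.append(fs)
            units.append(_UNITS[stream])
    ns = len(labels)
    n_records = int(np.ceil(max(len(d) / r for d, r in zip(data, rates))))
    header_bytes = 256 + ns * 256
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field(f"subject {rec.subject_id}", 80))
        f.write(_edf_field(f"trial {rec.film_id}", 80))
        f.write(_edf_field("01.01.20", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(header_bytes, 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(n_records, 8))
        f.write(_edf_field(1, 8))  # record duration, s
        f.write(_edf_field(ns, 4))
        phys_min, phys_max, scaled = [], [], []
        for d in data:
            lo, hi = float(np.min(d)), float(np.max(d))
            if hi <= lo:
                hi = lo + 1.0
            span = hi - lo
            lo -= 0.001 * span
            hi += 0.001 * span
            # encode with exactly the (8-char, truncated) values the header
            # stores, so writer and reader use identical scaling
            lo = float(f"{lo:.6g}"[:8])
            hi = float(f"{hi:.6g}"[:8])
            phys_min.append(lo)
            phys_max.append(hi)
            dig = np.round((d - lo) / (hi - lo) * (32767 - (-32768)) + (-32768))
            scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))
        for lab in labels:
            f.write(_edf_field(lab, 16))
        for _ in labels:
            f.write(_edf_field("", 80))
        for u in units:
            f.write(_edf_field(u, 8))
        for v in phys_min:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            f.write(_edf_field(f"{v:.6g}"[:8], 8))
        for _ in labels:
            f.write(_edf_field(-32768, 8))
        for _ in labels:
            f.write(_edf_field(32767, 8))
        for _ in labels:
            f.write(_edf_field("", 80))
        for r in rates:
            f.write(_edf_field(int(round(r)), 8))
        for _ in labels:
            f.write(_edf_field("", 32))
        for rec_i in range(n_records):
            for d, r in zip(scaled, rates):
                spr = int(round(r))
                seg = d[rec_i * spr : (rec_i + 1) * spr]
                if len(seg) < spr:  # pad final record with the last sample
                    pad = np.full(spr - len(seg), seg[-1] if len(seg) else 0, dtype="<i2")
                    seg = np.concatenate([seg, pad])
                f.write(seg.tobytes())
    return path


def read_trial_edf(
    path: str | Path,
    rest_duration: float,
    subject_id: str = "",
    film_id: str = "",
    genre: str = "",
    rating: int = 0,
) -> TrialRecording:
    path = Path(path)
    with open(path, "rb") as f:
        header = f.read(256)
        ns = int(header[252:256].decode().strip())
        n_records = int(header[236:244].decode().strip())
        sig_hdr = f.read(ns * 256)
        labels = [sig_hdr[i * 16 : (i + 1) * 16].decode().strip() for i in range(ns)]
        off = ns * 16 + ns * 80 + ns * 8

        def fields(offset, width):
            base = offset
            return [sig_hdr[base + i * width : base + (i + 1) * width].decode().strip() for i in range(ns)]

        phys_min = [float(v) for v in fields(off, 8)]
        phys_max = [float(v) for v in fields(off + ns * 8, 8)]
        dig_min = [float(v) for v in fields(off + ns * 16, 8)]
        dig_max = [float(v) for v in fields(off + ns * 24, 8)]
        spr = [int(v) for v in fields(off + ns * 32 + ns * 80, 8)]
        raw = np.frombuffer(f.read(), dtype="<i2")
    per_record = sum(spr)
    raw = raw[: n_records * per_record].reshape(n_records, per_record)
    pos = 0
    chans: list[tuple[str, np.ndarray, float]] = []
    for i in range(ns):
        d = raw[:, pos : pos + spr[i]].reshape(-1).astype(float)
        pos += spr[i]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        chans.append((labels[i], phys_min[i] + (d - dig_min[i]) * gain, float(spr[i])))
    eeg_chs = {lab.replace("EEG ", ""): (x, fs) for lab, x, fs in chans if lab.startswith("EEG ")}
    signals: dict = {}
    rest: dict = {}
    sfreq: dict = {}
    if eeg_chs:
        missing = [ch for ch in EEG_CHANNELS if ch not in eeg_chs]
        if missing:
            raise ValueError(f"EDF missing EEG channels: {missing}")
        fs = eeg_chs[EEG_CHANNELS[0]][1]
        full = np.stack([eeg_chs[ch][0] for ch in EEG_CHANNELS])
        nr = int(round(rest_duration * fs))
        rest["eeg"], signals["eeg"], sfreq["eeg"] = full[:, :nr], full[:, nr:], fs
    for lab, x, fs in chans:
        if lab.startswith("EEG "):
            continue
        stream = lab.lower().replace(" ", "_")
        nr = int(round(rest_duration * fs))
        rest[stream], signals[stream], sfreq[stream] = x[:nr], x[nr:], fs
    return TrialRecording(
        subject_id=subject_id, film_id=film_id, genre=genre, rating=rating,
        signals=signals, rest=rest, sfreq=sfreq,
        duration=(len(chans[0][1]) / chans[0][2]) - rest_duration,
        rest_duration=rest_duration,
    )


def read_trial(path: str | Path, fmt: str = "delimited", **meta) -> TrialRecording:
    """Read one trial; ``fmt`` is ``delimited`` or ``edf``.

    For EDF, pass ``rest_duration`` (from the cohort manifest) in ``meta``.
    ``meta`` may also carry subject_id/film_id/genre/rating. Missing declared
    streams raise ``ValueError`` naming the stream.
    """
    expect = meta.pop("expect_streams", None)
    if fmt == "delimited":
        rec = read_trial_delimited(path, **meta)
    elif fmt == "edf":
        rec = read_trial_edf(path, **meta)
    else:
        raise ValueError(f"unknown trial format {fmt!r}")
    if expect:
        missing = [s for s in expect if s not in rec.signals]
        if missing:
            raise ValueError(f"trial file missing streams: {missing}")
    return rec


def write_cohort(
    trials: list[TrialRecording], out_dir: str | Path, fmt: str = "delimited"
) -> Path:
    """Write all trial files plus the cohort manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in trials:
        ext = "csv" if fmt == "delimited" else "edf"
        fname = f"{rec.subject_id}_{rec.film_id}.{ext}"
        fpath = out_dir / fname
        if fmt == "delimited":
            write_trial_delimited(rec, fpath)
        elif fmt == "edf":
            write_trial_edf(rec, fpath)
        else:
            raise ValueError(f"unknown trial format {fmt!r}")
        rows.append({
            "subject_id": rec.subject_id, "film_id": rec.film_id, "genre": rec.genre,
            "duration_s": rec.duration, "rest_duration_s": rec.rest_duration,
            "rating": rec.rating, "path": fname, "format": fmt,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
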