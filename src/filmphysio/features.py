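"""Per-trial feature extraction and feature-matrix assembly.

Every trial contributes one row of baseline-corrected (``_blc``) features:

* per EEG channel: theta/alpha/beta median Welch power, the three pairwise
  band ratios, both engagement indices, and the eleven complexity measures;
* scalars: frontal arousal and valence indices;
* cardiac: the ten HRV statistics from the Hampel-cleaned RR series;
* facial EMG: rectified means for zygomaticus and corrugator;
* electrodermal: SCR amplitude sum per second.

A stream that is absent from a trial (or fails its preconditions) yields NaN
cells for its features; the row is retained and the cells are later handled by
the outlier-masking + imputation stage of the prediction pipeline.
"""

from __future__ import annotations

import pandas as pd

from . import cardiac, complexity, eeg, emg_eda
from .synth import EEG_CHANNELS, TrialRecording

ID_COLUMNS = ("subject_id", "film_id", "genre", "rating")


def eeg_trial_features(rec: TrialRecording) -> dict:
    out: dict = {}
    fs = rec.sfreq["eeg"]
    pre_t = eeg.preprocess_eeg(rec.signals["eeg"], rec.signals["eog"], sfreq=fs)
    pre_r = eeg.preprocess_eeg(rec.rest["eeg"], rec.rest["eog"], sfreq=fs)
    pow_t = eeg.welch_band_powers(pre_t.data, pre_t.mask, sfreq=pre_t.sfreq)
    pow_r = eeg.welch_band_powers(pre_r.data, pre_r.mask, sfreq=pre_r.sfreq)
    for ch in EEG_CHANNELS:
        for band in ("theta", "alpha", "beta"):
            out[f"eeg_{ch}_{band}_blc"] = pow_t[ch][band] - pow_r[ch][band]
    idx = eeg.compute_indices(pow_t, pow_r)
    for name, val in idx["corrected"].items():
        key = f"{name}_blc" if name in ("arousal", "valence") else f"eeg_{name}_blc"
        out[key] = val
    for ci, ch in enumerate(EEG_CHANNELS):
        ct = complexity.compute_complexity(pre_t.data[ci], sfreq=pre_t.sfreq).as_dict()
        cr = complexity.compute_complexity(pre_r.data[ci], sfreq=pre_r.sfreq).as_dict()
        for k in ct:
            out[f"eeg_{ch}_{k}_blc"] = ct[k] - cr[k]
    return out


def cardiac_trial_features(rec: TrialRecording) -> dict:
    fs = rec.sfreq["ppg"]
    rr_t = cardiac.hampel_clean(cardiac.detect_beats(rec.signals["ppg"], fs))
    rr_r = cardiac.hampel_clean(
        cardiac.detect_beats(rec.rest["ppg"], fs, min_duration=10.0)
    )
    hrv = cardiac.hrv_features(rr_t, rr_r)
    return {f"hrv_{k}_blc": v for k, v in hrv.baseline_corrected.items()}


def emg_eda_trial_features(rec: TrialRecording) -> dict:
    out: dict = {}
    for stream, muscle in (("emg_zyg", "zygomaticus"), ("emg_corr", "corrugator")):
        if stream in rec.signals:
            feat = emg_eda.emg_trial_mean(
                rec.signals[stream], rec.rest[stream], rec.sfreq[stream], muscle=muscle
            )
            out[f"emg_{muscle}_blc"] = feat.baseline_corrected
    if "eda" in rec.signals:
        scr = emg_eda.eda_scr_statistic(rec.signals["eda"], rec.rest["eda"], rec.sfreq["eda"])
        out["eda_scr_sum_per_s_blc"] = scr.baseline_corrected
    return out


def extract_trial_features(rec: TrialRecording) -> dict:
    """One feature row (dict) for a trial; missing streams give no keys."""
    row = {
        "subject_id": rec.subject_id,
        "film_id": rec.film_id,
        "genre": rec.genre,
        "rating": rec.rating,
    }
    if "eeg" in rec.signals:
        row.update(eeg_trial_features(rec))
    if "ppg" in rec.signals:
        try:
            row.update(cardiac_trial_features(rec))
        except ValueError:
            pass  # undetectable pulsatility -> NaN cells via assembly
    row.update(emg_eda_trial_features(rec))
    return row


def assemble_matrix(rows: list[dict]) -> pd.DataFrame:
    """Stack per-trial feature dicts into the (trials x features) matrix."""
    df = pd.DataFrame(rows)
    if df.duplicated(subset=["subject_id", "film_id"]).any():
        raise ValueError("duplicated subject x film rows")
    id_cols = [c for c in ID_COLUMNS if c in df.columns]
    feat_cols = sorted(c for c in df.columns if c not in id_cols)
    return df[id_cols + feat_cols]


def extract_cohort_features(trials: list[TrialRecording]) -> pd.DataFrame:
    return assemble_matrix([extract_trial_features(t) for t in trials])


def feature_channel_map(matrix: pd.DataFrame) -> dict:
    """Map feature columns -> EEG channel (None for peripheral/scalar),
    defining the per-channel families for BH adjustment."""
    mapping = {}
    for col in matrix.columns:
        if col in ID_COLUMNS:
            continue
        ch = None
        if col.startswith("eeg_"):
            parts = col.split("_")
            if parts[1] in EEG_CHANNELS:
                ch = parts[1]
        mapping[col] = ch
    return mapping
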