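"""Synthetic cohort generator: determinism, planted-effect calibration, and
per-stream construction properties."""

import numpy as np
import pytest
from scipy import signal

from filmphysio import (
    CohortConfig,
    FilmSpec,
    generate_cohort,
    null_config,
    synth_cardiac,
    synth_eda,
    synth_eeg,
    synth_emg,
)
from filmphysio.synth import bateman_kernel_max, solve_rating_betas
from filmphysio.eeg import welch_band_powers, indices_from_powers

from conftest import SHORT_FILMS, small_config


class TestCohort:
    def test_default_design_yields_168_trials(self):
        cfg = CohortConfig(streams=())
        trials, truth = generate_cohort(cfg)
        assert len(trials) == 21 * 8 == 168
        assert len(truth) == 168
        assert set(truth["genre"]) == {"comedy", "drama"}
        assert truth["rating"].between(1, 10).all()

    def test_determinism_bitwise(self):
        cfg = small_config(n_subjects=2, films=(SHORT_FILMS[0], SHORT_FILMS[2]))
        t1, truth1 = generate_cohort(cfg)
        t2, truth2 = generate_cohort(cfg)
        assert truth1.equals(truth2)
        for a, b in zip(t1, t2):
            for stream in a.signals:
                np.testing.assert_array_equal(a.signals[stream], b.signals[stream])
                np.testing.assert_array_equal(a.rest[stream], b.rest[stream])

    def test_stream_lengths_match_design(self):
        cfg = small_config(n_subjects=2, films=(SHORT_FILMS[0], SHORT_FILMS[2]))
        trials, _ = generate_cohort(cfg)
        rec = trials[0]
        film = SHORT_FILMS[0]
        for stream, sig in rec.signals.items():
            n = sig.shape[-1]
            assert abs(n - film.duration * rec.sfreq[stream]) <= 1
            assert abs(rec.rest[stream].shape[-1] - cfg.rest_duration * rec.sfreq[stream]) <= 1
        assert rec.signals["eeg"].shape[0] == 18

    def test_null_config_latents_independent_of_ratings(self):
        cfg = null_config(streams=(), seed=5)
        _, truth = generate_cohort(cfg)
        for latent in ("engagement", "valence"):
            r = np.corrcoef(truth[latent], truth["rating"])[0, 1]
            # n=168 null correlation: |r| < 3/sqrt(n)
            assert abs(r) < 3 / np.sqrt(len(truth))

    def test_engagement_rating_correlation_near_target(self):
        cfg = CohortConfig(streams=(), rating_engagement_r=0.4, seed=7)
        _, truth = generate_cohort(cfg)
        r = np.corrcoef(truth["engagement"], truth["rating"])[0, 1]
        assert abs(r - 0.4) < 0.15

    def test_rating_beta_solution_hits_targets_at_large_n(self):
        cfg = CohortConfig(streams=(), n_subjects=600, rating_engagement_r=0.4,
                           rating_valence_r=0.2, seed=3)
        b_e, b_v, s = solve_rating_betas(cfg)
        _, truth = generate_cohort(cfg)
        r_e = np.corrcoef(truth["engagement"], truth["rating"])[0, 1]
        assert abs(r_e - 0.4) < 0.05  # rounding/clipping attenuation is small
        assert b_e > 0 and b_v > 0 and s > 0

    def test_invalid_configs_name_the_field(self):
        with pytest.raises(ValueError, match="n_subjects"):
            generate_cohort(small_config(n_subjects=1))
        with pytest.raises(ValueError, match="must be < 1"):
            small_config(rating_engagement_r=0.9, rating_valence_r=0.9).validate()
        with pytest.raises(ValueError, match="streams"):
            small_config(streams=("eeg", "bogus")).validate()
        with pytest.raises(ValueError, match="genre"):
            CohortConfig(films=(FilmSpec("a", 30, "comedy"), FilmSpec("b", 30, "comedy"))).validate()


class TestSynthEEG:
    def test_alpha_only_weights_concentrate_power(self):
        eeg, _ = synth_eeg(30, 1000.0, {"theta": 0, "alpha": 1, "beta": 0},
                           pink_noise_level=0.0, seed=2)
        f, p = signal.welch(eeg[0], fs=1000, nperseg=4096)
        band = p[(f >= 4) & (f < 30)].sum()
        alpha = p[(f >= 8) & (f < 12)].sum()
        assert alpha / band >= 0.8

    def test_zero_blink_rate_gives_noise_only_eog(self):
        _, eog = synth_eeg(20, 1000.0, {"theta": 1, "alpha": 1, "beta": 1},
                           blink_rate=0.0, seed=2, eog_noise=2.0)
        assert np.abs(eog).max() < 2.0 * 6  # pure measurement noise, no 150 uV blinks

    def test_doubling_beta_weight_increases_extracted_beta_alpha_index(self):
        idx = {}
        for label, beta_w in (("lo", 0.5), ("hi", 1.0)):
            eeg, _ = synth_eeg(60, 1000.0, {"theta": 1, "alpha": 1, "beta": beta_w},
                               pink_noise_level=0.2, seed=4)
            from filmphysio._filters import decimate_fir
            x = decimate_fir(eeg, 8, 1000.0, axis=-1)
            powers = welch_band_powers(x, sfreq=125.0)
            idx[label] = indices_from_powers(powers)
        for ch in ("F3", "Cz", "O2"):
            assert idx["hi"][f"{ch}_engagement_ba"] > idx["lo"][f"{ch}_engagement_ba"]

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            synth_eeg(-5, 1000.0, {"theta": 1, "alpha": 1, "beta": 1})
        with pytest.raises(ValueError):
            synth_eeg(10, 1000.0, {"theta": -1, "alpha": 1, "beta": 1})


class TestSynthCardiac:
    def test_zero_sdnn_is_perfectly_periodic(self):
        rr, beats, _ = synth_cardiac(60, 800.0, 0.0, seed=0)
        assert np.allclose(rr, 800.0)
        assert np.allclose(np.diff(beats), 0.8)

    def test_beat_count_matches_mean_rr(self):
        rr, beats, _ = synth_cardiac(400, 800.0, 0.0, seed=0)
        assert abs(len(beats) - 500) <= 1

    def test_ar1_stationary_sd_matches_target(self):
        rr, _, _ = synth_cardiac(10000 * 0.8, 800.0, 50.0, phi=0.3, seed=9)
        assert len(rr) > 9000
        assert abs(rr.std() - 50.0) < 3.0

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            synth_cardiac(60, -100, 50)
        with pytest.raises(ValueError):
            synth_cardiac(60, 800, 50, phi=1.2)


class TestSynthEMG:
    def test_no_bursts_rectified_mean_matches_closed_form(self):
        x = synth_emg(120, 1000.0, burst_rate=0.0, burst_amplitude=0.0, seed=3,
                      baseline_level=2.0)
        from filmphysio.emg_eda import rectified_mean
        observed = rectified_mean(x, 1000.0)
        # envelope constant 2.0 x unit-RMS Gaussian carrier: E|x| = 2 sqrt(2/pi)
        expected = 2.0 * np.sqrt(2 / np.pi)
        assert abs(observed - expected) / expected < 0.05

    def test_amplitude_monotonicity(self):
        from filmphysio.emg_eda import rectified_mean
        means = [
            rectified_mean(synth_emg(60, 1000.0, 0.3, amp, seed=5), 1000.0)
            for amp in (1.0, 2.0)
        ]
        assert means[1] > means[0]

    def test_seeds_differ_but_statistics_agree(self):
        a = synth_emg(60, 1000.0, 0.2, 1.0, seed=1)
        b = synth_emg(60, 1000.0, 0.2, 1.0, seed=2)
        assert not np.allclose(a, b)
        assert abs(np.abs(a).mean() - np.abs(b).mean()) / np.abs(a).mean() < 0.15

    def test_low_sfreq_rejected(self):
        with pytest.raises(ValueError):
            synth_emg(10, 500.0, 0.2, 1.0)


class TestSynthEDA:
    def test_analytic_kernel_max_matches_sampled_kernel(self):
        from filmphysio.synth import bateman_kernel
        t = np.arange(0, 30, 1e-4)
        for tau_r, tau_d in ((0.75, 3.0), (0.5, 6.0)):
            sampled = bateman_kernel(t, tau_r, tau_d).max()
            assert abs(bateman_kernel_max(tau_r, tau_d) - sampled) < 1e-6

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            bateman_kernel_max(3.0, 0.75)

    def test_zero_rate_has_no_phasic_activity(self):
        x, events = synth_eda(60, 100.0, scr_rate=0.0, scr_amplitude=0.5, seed=1)
        assert len(events) == 0
        assert np.ptp(x) < 0.5  # tonic drift only

    def test_planted_events_recovered_by_detector(self):
        from filmphysio.emg_eda import _scr_sum_per_s
        x, events = synth_eda(300, 100.0, scr_rate=4.0, scr_amplitude=0.5,
                              tonic_drift=0.05, seed=21)
        _, _, peak_times = _scr_sum_per_s(x, 100.0, tonic_window_s=30.0, min_amplitude=0.01)
        hits = sum(
            np.any((peak_times >= onset) & (peak_times <= onset + 3.0))
            for onset in events["onset_s"]
        )
        assert hits >= 0.8 * len(events)
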