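# Methods

This note documents the models, parameters, numerical choices and known
limitations of `filmphysio`. It is the package's own account of its science;
every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## The design being emulated

A within-subject film-viewing experiment: 21 subjects each watch 8 short
films (4 comedies, 4 dramas; durations 261–445 s), with a 60-s seated rest
before each film, and rate each film 1–10. Recorded at 1,000 Hz: 18-channel
EEG (F7, F3, Fz, F4, F8, T7, C3, Cz, C4, T8, P8, P4, Pz, P3, P7, O1, Oz, O2),
one vertical EOG channel, a finger photoplethysmogram, surface EMG over
*zygomaticus major* and *corrugator supercilii*, and skin conductance. The
default `CohortConfig` reproduces exactly this design (168 trials).

## Synthetic cohort generator

### Latent structure and ratings

Each trial draws latent standard-normal engagement `z_e`, valence `z_v`, and
an arousal variable `z_a = 0.6 z_e + 0.8 z_res` (so engagement and arousal are
correlated by construction, as engagement-type EEG indices empirically are).
Ratings are

    rating = round(clip(mu_subject + b_e*z_e + b_v*z_v + eps, 1, 10))

with `mu_subject ~ N(6.2, 0.8)` and `eps ~ N(0, 1.5)`. The coefficients are
solved in closed form, `b = r_target * s` with
`s^2 = (0.8^2 + 1.5^2) / (1 - r_e^2 - r_v^2)`, so that on the continuous scale
`corr(z_e, rating) = rating_engagement_r` (default 0.4) and
`corr(z_v, rating) = rating_valence_r` (default 0.2). Rounding and clipping
attenuate the realized correlation by a few hundredths at these noise levels —
well inside the ±0.15 recovery band the acceptance suite checks at n = 168.
The rating noise SD is a free parameter of the design (only means of the
rating distribution are published for the emulated study); 1.5 plus the
subject spread reproduces a plausible between-trial SD ≈ 2.3 on a 1–10 scale.

### EEG

Each channel is a sum of narrowband processes — ideal band-filtered white
noise in theta (4–8), alpha (8–12) and beta (12–30 Hz), synthesized in the
frequency domain so that the in-band power equals the configured band weight
(defaults θ:α:β = 1.0:1.5:0.8, resting-style alpha dominance; overall scale
10 µV RMS) — plus a 1/f background. Planted effects are multiplicative on
band power: engagement scales beta globally by `exp(0.4 z_e)`; valence tilts
frontal alpha (`F4: exp(+0.15 z_v)`, `F3: exp(−0.15 z_v)`), so the
hemispheric-asymmetry valence index increases with `z_v`; the residual
arousal component scales frontal beta by `exp(0.2 z_res)`. With these gains
the extracted mean engagement index correlates ≈ 0.95 with the latent, so the
planted engagement→rating correlation survives extraction nearly unattenuated
(measured: latent r = 0.40, extracted r = 0.38 at n = 168).

Blinks are a fixed 400-ms biphasic template at Poisson times (default
0.1/s — subjects are asked to limit blinking), projected on the scalp with a
fixed front-to-back gain profile and copied at double amplitude into the EOG
channel, enabling regression-based correction.

EEG is generated at 1,000 Hz and pushed through the same decimation path as
real data, so the preprocessing chain is genuinely exercised.

### Cardiac, EMG, EDA

* RR intervals follow an AR(1), `RR_i = mu + phi(RR_{i-1} - mu) + eps`, with
  `eps` scaled so the stationary SD equals `sdnn_ms` (default 50 ms,
  phi = 0.3, subject means ~ N(800, 60) ms). The PPG places a fixed
  two-bump pulse template at the cumulative beat times; the template peaks
  `PULSE_PEAK_OFFSET = 0.15 s` after each beat.
* EMG is a 10–350 Hz unit-RMS noise carrier multiplied by an envelope: a
  tonic level plus smooth 0.5-s Gaussian bursts (default 0.1/s). The genre
  effect is planted **additively on the tonic envelope**: subject i's
  comedy-minus-drama contrast is `delta_i ~ N(d * 0.2, 0.2)` (in tonic
  units), applied ±delta/2 by genre, so the population paired Cohen's d of
  the contrast equals `genre_emg_d` exactly. (A multiplicative plant scaled
  by the log-normal subject amplitude inflates the contrast's between-subject
  SD and attenuates the realized d to ~0.65 — measured, and the reason for
  the additive choice.)
* EDA is a slowly drifting tonic level plus Poisson SCR events (default
  3/min), each a Bateman kernel `A(exp(-t/3.0) - exp(-t/0.75))` with
  log-normal amplitude jitter around 0.4 µS; event times and amplitudes are
  returned as ground truth.

### Determinism

Every stream of every trial is seeded by
`SeedSequence(master, spawn_key=(subject_idx, film_idx, stream_code))`
(rest segments: code + 16; cohort-level draws: spawn key `(999999,)`), so a
single trial can be regenerated in isolation and identical configurations are
bit-identical. `iter_cohort` yields trials lazily: a full-length multimodal
trial holds ~70 MB of samples, and the full cohort is never materialised at
once.

## Feature extraction

**EEG preprocessing order**: gross-artifact clamp → decimate ×8 (zero-phase
FIR, cutoff 0.8× the new Nyquist, implemented by polyphase resampling) →
band-pass 0.05–30 Hz (2nd-order zero-phase Butterworth high-pass + 257-tap
zero-phase FIR low-pass) → deterministic bad-channel repair (total power
>10× or <0.1× the montage median → mean of fixed-adjacency neighbours) → EOG
regression (per-channel least squares on the identically filtered EOG) →
|z| > 10 masking, dilated ±0.5 s. The gross clamp (samples beyond 30 robust
SDs set to the channel median, neighbourhood flagged into the mask) exists
because a filter smears an extreme spike over seconds; without it the |z|>10
mask cannot protect the PSD. Welch band powers use 125-sample (1-s) Hann
windows at 50% overlap; windows touching masked samples are dropped; the per
band statistic is the **median over windows** of the mean density inside the
band (band edges are half-open: [4,8), [8,12), [12,30) Hz at the 1-Hz window
resolution). Note the median of a k-bin average of exponential periodogram
values sits at `median(Gamma(k))/k` of the true density, so the wide beta
band carries a slightly different small-sample factor than the 4-bin theta
and alpha bands; the test suite checks band flatness against this closed
form, not against naive equality.

**Baseline correction** subtracts the rest segment's value of each derived
index (`index_trial − index_rest`), not the underlying band powers: the
indices are the variables carried forward. The alternative ordering is one
code path away (`compute_indices` takes any two power tables).

**Complexity** (order-3, delay-1 embeddings; population variance; ordinal
ties broken by stable argsort; ⌈√N⌉ histogram bins; 256-point Welch segments
for spectral entropy): formulas are in the module docstring. Constant series
return fractal dimensions of 1 by convention and NaN for variance-based
measures.

**Cardiac**: beats = local maxima of the 0.5–8 Hz band-passed pulse wave over
a rolling mean + 0.2·SD threshold (3-s window), 300-ms refractory. Hampel
window is 3 points per side including the centre (the standard definition);
outliers beyond 3·1.4826·MAD are replaced by the window median and flagged.
HRV uses population variance so `sd1 = rmssd/√2` (up to the vanishing mean of
the differences) and `sd1² + sd2² = 2·sdnn²` hold to 1e-6. pNN thresholds are
strict (>20, >50 ms). Rest baselines relax the minimum-length preconditions
(10 s of PPG, 10 RR intervals) since 60-s rests are short.

**EDA** is analysed at 20 Hz. The tonic component is a **30-s** moving
median: the window must be long relative to the SCR kernel, otherwise the
median is pulled up by the response itself and the recovered amplitude of an
isolated SCR is roughly halved (measured: ratio 0.51 with an 8-s window vs
0.99 with 30 s). SCR amplitude = peak − preceding local minimum, minimum
0.01 µS; the trial statistic is Σ amplitudes / duration.

## Statistics

Paired Cohen's d is mean(Δ)/SD(Δ) = t/√n — the only convention consistent
with t(20) = 3.25 ↔ d = 0.71 at n = 21. Correlation p-values use the exact
t transform with n−2 df; the suite checks them against a 10,000-draw
permutation oracle. BH runs within each channel's family of indices
(peripheral scalars are their own one-element families); a global variant is
available. The median split ranks each subject's films and labels the lower
half "low"; boundary ties are broken by a seeded jitter draw (integer ratings
are never flipped by it), with a warning when all ratings tie.

## Prediction protocol

Within each leave-one-film-out fold: outlier statistics (mean ± 3 SD per
column) are computed on the training films only and applied to both splits;
the training matrix is imputed by chained equations (median initialisation,
10 sweeps, per-sweep seeded column order, each incomplete column regressed on
all others by minimum-norm least squares — exact for duplicated-column
structure and deterministic); held-out rows are filled with training medians
(missingness after ±3 SD masking is ~0.3%, so the cheaper fill is
inconsequential and keeps the fold boundary obvious); the top 15 features by
random-forest impurity (Gini) importance (100 trees, seeded) are selected on
training rows; models are fit on those features (inputs standardised for the
scale-sensitive models). Each fold's training statistics are hashed into a
fingerprint, and a test asserts the fingerprint is invariant to arbitrary
corruption of the held-out film — leakage is excluded by construction and by
test. Binary labels come from the within-subject median split over **all**
films, replicating the emulated protocol (the held-out film's rating
participates in its own label; the fully-out-of-sample variant is available
by passing labels explicitly). A `paper_faithful_selection` flag reproduces
the ambiguous pre-CV global feature selection variant; fold-wise selection is
the default. AUC uses decision-function scores oriented to the "high" class;
folds with a single test class yield NaN and are excluded from means.

MAPE uses the observed rating as denominator (ratings are 1–10, so it is
always defined). The boosted-tree slots use scikit-learn's gradient boosting
with default depth/learning rate; SVR/SVC use RBF kernels; KNN uses k = 5;
hyperparameters are fixed, not searched.

## Problem sizes in the test suite

The suite must run in minutes, so tests choose the smallest scale at which
the checked property is scale-free or its scale dependence is modelled:

* unit tests use 4-subject × 4-film cohorts with 32–40-s films and 15-s
  rests;
* plant-and-recover uses the full 21 × 8 design with 120-s films — long
  enough that trial-level measurement noise is negligible and the detection
  rate across 50 seeds (41/50) matches the latent-level rate for the same
  seeds, i.e. the exact paired-t power at d = 0.7, n = 21 (0.862);
* the permuted-label chance-level test uses peripheral streams only, 35-s
  films and 60 permutations (Monte-Carlo SE ≈ 0.01 on the mean AUC, so the
  ±0.03 band is a 3σ check);
* `scripts/acceptance.py` runs the full default design (168 full-length
  multimodal trials, ~500 features, 100 permutations).

## What passing tests do and do not show

The generator produces stationary, artifact-light, unit-consistent signals
with planted monotone effects. Passing plant-and-recover tests shows the
pipeline is correct and calibrated **for data of this kind**; it does not
show that real film-viewing physiology carries effects of these sizes, nor
does it validate the preprocessing against real artifact morphologies
(movement, electrode drift, non-stationary alpha). Known limitations, by
construction: no biophysical EEG forward model (channels are independent up
to the planted structure — no volume conduction); PPG morphology is a fixed
template (beat detectability, not waveform realism); no respiration or its
coupling into HRV; frequency-domain HRV is out of scope; EMG left/right
hemiface asymmetry is not modelled (single-side recording); gamma-band
features are deliberately excluded (scalp gamma is not separable from muscle
activity); the printed p-values of an analysis of this design are exactly
reproducible only when the effective n after outlier removal is known.
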