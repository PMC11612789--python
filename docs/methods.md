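# Methods

This note documents the models, algorithms, defaults and design choices in
`shrewvoc`, and what the synthetic-data tests do and do not demonstrate.

## Synthetic call model

The generator emulates the four call types of the Etruscan shrew repertoire
at the acquisition conditions of ultrasound field recorders (mono PCM
16-bit, 200 kHz default, 192 kHz supported):

* **Screams** — long, weakly modulated tonal calls. Adult preset: 0.16 s,
  F0 23.5 → 25 kHz (mean ≈ 24.5 kHz); pup preset longer (0.24 s) with
  higher F0 (≈ 29.5 kHz). Three harmonics at −6 dB per harmonic give a
  harmonic structure sufficient for HNR/entropy contrast without modelling
  the real vocal tract.
* **Screeches** — solely non-tonal: Butterworth band-pass noise
  (8–45 kHz) amplitude-modulated at the tremolo rate. No numeric tremolo
  rate is published for this species, so the default (80 Hz adult, 50 Hz
  pup, log-normal scatter) is a free parameter chosen to give the pulsed
  structure its character; pup screeches are set slower, consistent with
  the slower modulation visible in pup sonograms.
* **Screech-screams** — a screech-like and a scream-like part concatenated
  (noisy part first by default, order randomized per call), RMS-matched at
  the junction. The tonal fraction is the gradation control; the campaign
  generator draws it uniformly from (0.15, 0.85).
* **Chirps** — short (0.03 s adult), ascending 14 → 24 kHz; pup chirps are
  longer (0.05 s) with a reversed-U (parabolic) contour and optional
  silent gaps < 50 ms.

Two noise sources are deliberate: a white recording floor at SNR 30 dB
(keeps segmentation non-trivial) and band-limited "turbulence" noise inside
tonal parts at 18 dB below the harmonics. The latter keeps measured HNR in
a realistic range (≈ 18 dB rather than the near-infinite HNR of a clean
oscillator) and, because the turbulence occupies the same band as the
screech noise, makes HNR and Wiener entropy grade smoothly with the tonal
fraction of mixed calls.

Campaign scale: the default `ExperimentConfig` emits 600 calls
(200/200/100/100 across the four types, with a pup share concentrated in
chirps and screams) over 12 dyad confrontation recordings (10 s closed-door,
60 s open-door) plus pup-isolation recordings. This compresses the original
experimental scale (tens of 30-minute sessions) to desk scale; call rates
and context shares are invariant to that compression because both are
normalized by phase duration or call counts. Calls are placed inside
behaviour events — chirps exclusively in caravanning, the socio-negative
types in socio-negative-interaction or avoidance events (4:1) — so the
context analysis has a known answer.

## Feature extraction

Frames are 2 ms with a 0.5 ms hop (≥ 40 periods of a 20 kHz fundamental per
window; the original tool settings are not published, so these are package
defaults, configurable).

**Pitch tracking.** Per frame, the Hann-windowed autocorrelation is computed
via the power spectrum and divided by the window autocorrelation
(Boersma-style normalization), then sinc-upsampled 4× in lag. Every local
maximum in the 5–100 kHz search range is parabolically interpolated; among
candidates within 0.02 of the (1-capped) best height, the shortest lag wins,
which resolves the period-multiple ambiguity of periodic signals. A frame is
voiced when the winning peak height (periodicity strength) ≥ 0.45 — the
published analysis defined voiced frames semi-automatically by visual F0
clarity, which this automates — and voiced runs shorter than 3 frames are
pruned as spurious. Two consequences matter downstream: band-limited
screech noise measures exactly 0 % voiced, and the upsampling keeps pure-tone
F0 errors ≈ 0.3 %.

**Tonality.** Voiced percentage = 100 × voiced/total frames. HNR is
`10·log10(r/(1−r))` per frame (r clipped to [0.01, 0.9999]), averaged over
*all* frames and then linearized as `10^(dB/10)`; averaging over all frames
(not just voiced ones) is what makes HNR grade with the tonal fraction of
mixed calls. Wiener entropy is spectral flatness — geometric/arithmetic mean
of a Welch-averaged power spectrum — reported in dB (≤ 0) and linear; Welch
averaging keeps white-noise flatness near 1 instead of the e^{−γ} ≈ 0.56 of
a raw periodogram. Linear-scale HNR and entropy feed all statistics.

**Spectral moments** use the full-call Hann periodogram (better frequency
resolution than the Welch spectrum used for flatness): centre of gravity,
spectral SD, skewness and *excess* kurtosis as power-weighted moments.

**Formants** (non-tonal and mixed calls only): the signal is resampled to
twice the ceiling, pre-emphasized (0.97), Hann-windowed, and fitted with
order-10 autocorrelation LPC via Levinson/Toeplitz solve; pole angles give
frequencies, pole radii bandwidths. The ceiling derives from the vocal
tract length by uniform-tube scaling (5500 Hz × 17.5 / VTL; 1.2 cm →
≈ 80.2 kHz). Candidates must lie in (1 kHz, ceiling) with bandwidth
< 30 % of the ceiling; fewer than three resonances leaves entries NaN.
Whether the original analysis used exactly this ceiling scaling is
unverifiable; it is configurable.

**Quality.** Clipped calls (any |sample| ≥ 0.999) and calls flagged low
quality are excluded from the feature table with a logged reason. Overlap
flagging is delegated to ground truth (synthetic mode) or an annotation
column (recordings mode); no automatic overlap detector is attempted.

## Clustering and gradation

The nine all-call parameters are z-scored (population-SD convention) and
embedded in 2-D with UMAP (n_neighbors 15, min_dist 0.1, fixed seed —
unpublished hyperparameters, so documented as non-reproducing defaults).
Fuzzy c-means (c = 3, μ = 2, ≤ 100 iterations, tol 1e-6 on the largest
membership change, centroids initialized on seed-sampled distinct points) is
written from scratch; a coincident point/centroid receives membership 1.

**Cluster input space.** By default FCM consumes the standardized
9-parameter matrix, not the embedding. Both paths are implemented; the
embedding path was demoted after testing showed that UMAP at this sample
size produces compact islands whose mutual distances are arbitrary, so a
3-centroid fit on the embedding can merge acoustically distant types (e.g.
screams with chirps) depending on island layout. In the feature space the
graded calls lie geometrically between the scream and screech centroids,
which is the structure the typicality analysis measures.

Cluster roles are inferred automatically (lowest mean voiced % → noisy;
of the rest, shortest mean duration → short-tonal; remainder →
long-tonal), overridable by config. Typicality = largest − second-largest
membership; thresholds default to the empirical lower/upper terciles of the
coefficient distribution (the original threshold construction is not
reprinted in the source material, so the tercile rule is a documented
stand-in with a fixed-constant escape hatch). A coefficient exactly at a
threshold is "neither" (the categories are defined by strict inequalities).
Final call types: long-tonal cluster with voiced ≥ 95 % → scream, below →
screech-scream; noisy cluster with voiced = 0 % → screech, above →
screech-scream; short-tonal cluster → chirp at any voiced percentage.

## Context and statistics

Calls are aligned to ethogram events by onset time (configurable to
midpoint); when several events contain a call, actual interactions outrank
position events with the explicit priority socio-negative > combination >
caravanning > avoidance > box > wire-mesh > none. Proximity shares report
three exclusive buckets (inside / within 1 s / outside) and additionally
the inside-plus-buffer tally, since whether the ±1 s buffer counts as
proximity is ambiguous. Call rates are N/min per call type per experiment;
closed-door calls are counted but not behaviour-coded.

Mixed models are ML fits (statsmodels `MixedLM`): a single random intercept
per individual for acoustic comparisons, and crossed random intercepts for
the two dyad members (variance components) for call rates. Per-term tests
rescale the ML Wald χ² into an F with *effective* residual degrees of
freedom n − k − edf, where edf is the sum of per-level shrinkage factors
n_l·v/(n_l·v + σ²) of the random effects. The naive Wald F (df = n − k)
was measured at 12–15 % type-I error per interaction block on null
call-rate simulations at the study scale (~48 experiments); the corrected
test measures ≈ 2–2.5 %, slightly conservative. Tukey-adjusted
least-squares means use model predictions averaged over the observed data
with the factor forced to each level, and the studentized-range
distribution with the same effective df. Backward elimination drops, at
each step, the interaction with the highest non-significant (α = 0.05)
p-value, refits, and stops when only main terms remain or every remaining
interaction is significant; the nested-model Wald comparison equals the
block test of the dropped coefficients.

The rate simulator draws each individual into ~3 experiments *within the
same dyad role*; with one appearance per level the individual variance
components are unidentifiable and ML degenerates (residual variance → 0),
which is a property of the design, not of the data.

## What the synthetic tests do and do not show

Passing tests demonstrate that the implementation is internally correct
(closed-form membership agreement, oracle-checked features, calibrated
tests) and that the pipeline recovers a repertoire whose structure mirrors
the target system: three discrete classes recovered essentially perfectly
(ARI ≈ 0.98–0.99 on discrete calls), graded calls the least typical, chirps
exclusive to caravanning, κ ≈ 0.9 against ground truth. They do **not**
show performance on real recordings: synthetic calls lack reverberation,
overlapping callers, microphone directionality, amplitude variation with
distance, and real vocal-tract spectra, and the graded calls here are exact
concatenations rather than physiological intermediates. Graded calls are
also genuinely ambiguous to the clustering — a screech-scream with tonal
fraction near 0.5 has no "correct" discrete cluster — so coarse-recovery
metrics are defined over discrete calls only.

## Numerical details and degenerate inputs

* Times are seconds from recording start, intervals half-open; feature
  tables store kHz, internals Hz.
* Segments shorter than one analysis window yield a single degenerate
  frame, flagged. Zero-energy segments raise explicit errors for tonality,
  spectral and formant features. Fewer than two voiced frames mask all F0
  features.
* Membership ties in hard assignment break toward the lowest cluster index
  and are logged; constant feature columns abort z-scoring with the column
  named.
* FCM's objective trace is checked non-increasing in tests; the stop rule
  is max |ΔU| < 1e-6.
* All randomness flows from explicit integer seeds; a pipeline re-run with
  the same config and seed reproduces its tables bit-identically.
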