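# Methods

This note documents the models, parameter choices, and numerical
conventions behind the package, and what the synthetic-data tests do and do
not establish about real recordings.

## Signal model of the synthetic generator

Each electrode's voltage trace is

    x(t) = n(t) + A0 · exp(ℓ(t) + g(t)) · c(t) [+ mains sinusoid]

* **Background** `n(t)`: Gaussian noise with power-spectral slope
  `−noise_exponent` (default 2.0, a typical intracranial 1/f² decay),
  25 µV RMS, flattened below 0.1 Hz.
* **Carrier** `c(t)`: a bank of 24 random-phase sinusoids uniform in
  60–160 Hz, unit RMS. A sinusoid bank (rather than filtered noise) gives
  an analytic envelope the 20 Hz band filters can recover, while still
  producing realistic Rayleigh-type envelope fluctuations per band.
* **Log-envelope** `ℓ(t)`: stationary Gaussian AR(1) in log-amplitude with
  s.d. `envelope_sigma` (default 0.2 ≈ 0.87 dB) and autocorrelation time
  1 s. HFB amplitude is known to be approximately log-normal; its temporal
  structure is not reported, and AR(1) is the minimal process producing
  realistic ultra-slow fluctuations. The rest-normalized dB trace is then
  Gaussian AR(1) with s.d. 10·σ/ln 10.
* **Task gains** `g(t)` (log-amplitude; a dB value d enters as d·ln10/10):
  viewing responses rise ~50 ms after the per-group latency and hold to
  stimulus offset; sustained recall-block gains equal `baseline_shift_db`
  for the block's target category (default 0.3 dB for category-selective
  electrodes — between the representative single-electrode values of ~0.5 dB
  and the ~0.05 dB group mean); recall-onset transients are cosine-ramped
  plateaus spanning −1.5..+2 s with peak `transient_db` (default 0.17 dB,
  positive for the preferred category, negative otherwise, laggable for
  frontal/parietal electrodes); the sustained gain collapses from 2 s before
  each intrusion error until its offset and dips around experimenter
  prompts, recovering after prompt offset — emulating the boundary-setting
  dynamics the analyses are designed to detect. Optional components add
  sporadic dB bursts, an ultra-slow sinusoidal recall modulation (default
  0.5 dB at 0.15 Hz for selective electrodes), and a low-frequency (<10 Hz)
  noise-power reduction during overt recollection (−0.95 dB default).

Task structure: per run, 200 s rest; 14 pictures (7 faces, 7 places, fresh
set per run) × 4 repetitions, 1500 ms on / 750 ms ISI, shuffled cycles with
no immediate repeats; 40 s distraction; two 150-s recall blocks (faces
first in run 1, places first in run 2). Recall onsets follow an
inhomogeneous Poisson process whose rate (0.10 Hz peak) halves every 75 s —
recall is more frequent early — with durations U(2, 6) s, a 1 s minimum
inter-onset gap, and intrusion probability 0.115. Inter-recall interval
distributions are not reported per patient; these defaults are plausible
rather than fitted. Prompts occupy recollection-free gaps ≥ 14 s.

All times are seconds; intervals are half-open `[start, end)`; sample index
= floor(t·rate), 0-based. Viewing epochs are the one deliberate exception:
−500..+1750 ms with both endpoints included (1126 samples at 500 Hz).

## Numerical conventions and edge cases

* Zero-phase filtering is forward–backward (`filtfilt`), so the effective
  attenuation is the square of the single-pass design; the band-pass order
  (138) refers to the single-pass FIR.
* Band means in HFB steps 3/5 are taken over the whole recording excluding
  artifact-masked samples.
* dB means 10·log10 of an *amplitude* ratio throughout (the field's HFB
  convention), so an amplitude factor is 10^(dB/10).
* Artifact masking keeps the time base intact: masked samples are excluded
  from statistics but never cut out, preserving event alignment. The
  per-channel SD for the 5-SD rule is computed over the whole recording in
  a single pass (no iteration). Note that with montages of ten channels or
  fewer, a single channel's excursions already satisfy the ≥10%-of-
  electrodes coincidence rule; the rule is meant for large clinical
  montages.
* The bad-channel criterion uses |voltage| (the conservative reading of a
  sign-ambiguous threshold).
* Medians are invariant under the monotone dB transform, so median-of-dB
  equals dB-of-median; medians are computed in dB for uniformity.
* Percentile-gain bins are 10 equal-probability bins of each trace's own
  distribution (`np.array_split` of the sorted samples, so bin sizes differ
  by at most one sample); ties and bin edges therefore need no special
  handling, and a constant offset reproduces itself exactly in every bin.
* Burst injection places rectangular pulses of height `burst_db` and width
  `window_s` (3 s) at random non-overlapping slots covering the requested
  occupancy, then convolves the added component with a **unit-area**
  Gaussian (s.d. = window_s/6). Unit area preserves the mean added dB
  (occupancy × burst_db, the quantity the oracle tests) and keeps the
  per-burst peak near `burst_db`; the convolution is applied to the added
  component only.
* Shift coverage < 1 is applied to a random sample subset — equivalent in
  distribution to any placement for a percentile statistic and simpler.
* The dynamics decision rule is: baseline-shift-like iff signed-rank on the
  per-electrode overall gain is significant at α = 0.05 *and* the
  Kruskal–Wallis test across percentile bins is not; burst-like iff
  Kruskal–Wallis is significant with a positive bin-gain trend (Spearman);
  otherwise indeterminate. The Kruskal–Wallis input treats electrodes as
  independent samples per bin; within-electrode correlation across bins
  makes the test conservative, which only strengthens a non-significance
  claim.
* Cluster statistic: sum of |t| over a maximal supra-threshold run
  (cluster mass); the paired null flips condition labels within electrode
  (sign flips — the sum of squares is flip-invariant, so only the means
  are recomputed), the unpaired null permutes group membership. Corrected
  p = fraction of permutation maximum masses ≥ the observed mass.
  Triangular smoothing (1000 ms) biases step-onset estimates by up to half
  the kernel width; cluster onsets are reported as measured and interpreted
  with that caveat.
* Multitaper: NW = (K+1)/2 (the standard K = 2NW−1 relation; the source
  procedure states K and a "resolution" but not NW). For the LFP
  configuration (T = 5 s, K = 7) this arithmetic gives W = 0.8 Hz, not the
  stated 1 Hz — documented here as a rounding in the source description.
  One-sided density scaling; only dB gains between conditions are reported,
  so the convention cancels. Segments are demeaned and zero-padded to 2^12
  (LFP) / 2^14 (HFB). 25-s HFB epochs touching the artifact mask are
  dropped whole (interpolation would distort ultra-slow power).
* Mixed model: statsmodels MixedLM, REML, random intercepts for patient and
  electrode-within-patient (variance components), sum-to-zero coding, Wald
  F per fixed term. Kenward–Roger degrees of freedom are not available in
  statsmodels; the contract therefore targets direction and significance of
  effects, not exact F replication. Random slopes are omitted (they
  over-parameterize designs of this size). An `aggregate` fallback
  (per-electrode condition means + crossed OLS ANOVA) is provided and
  agrees with the full model on accept/reject decisions in testing.
* Signed-rank uses exact enumeration for n ≤ 25 without ties, otherwise the
  normal approximation with tie correction; zero differences are dropped.

## Problem sizes

Analyses are exercised at deliberately compact sizes chosen to keep the
statistical guarantees meaningful: the discrimination experiment uses 50
repetitions of 30-electrode cohorts on 150-s traces at 500 Hz (matching the
block length the method targets); envelope-level recovery tests run at
100 Hz (the analyses are rate-agnostic above the envelope bandwidth);
cluster-permutation calibration uses 200 null repetitions × 500
permutations on a 601-point grid; the end-to-end pipeline default is a
19-electrode, two-run cohort (~22 minutes of simulated recording), and the
integration tests use a 12-electrode variant with shorter rest and viewing
phases.

## What the synthetic tests do and do not show

Passing parameter recovery on this generator shows the estimators are
unbiased and correctly calibrated *under the stated signal model*:
log-normal amplitude with AR(1) temporal structure, stationary background,
additive-in-log task gains, and exactly known event times. Real recordings
violate all of these to some degree — envelope spectra are not AR(1),
artifacts are not all captured by threshold rules, speech-onset times carry
extraction error (the 1000 ms smoothing exists precisely for that), and
electrode labels carry localization error. The tests therefore validate the
*machinery* (filters, normalizations, exclusion rules, permutation
calibration, decision rules), not the empirical claims about cortex; the
package makes no attempt to reproduce patient-level statistics, which
depend on data that are not publicly deposited.

## Known limitations

* No EDF export (the recording interchange format is TSV + JSON sidecar,
  with an optional EDF-style 16-bit quantization mode); EDF reading is out
  of scope.
* Electrode localization, atlas projection and speech-onset extraction are
  inputs, not computations.
* The prompt analysis assumes prompt durations are recorded; recovery is
  tested post-offset.
* `classify_dynamics` requires ≥ 10 electrodes with a preferred category;
  smaller cohorts report the analysis as skipped.
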