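# Methods

This note documents the models, conventions, and design choices behind
`alphaffr`: what each stage assumes, which constants are fixed by the
paradigm and which are this package's own decisions, and what the
synthetic cohort does and does not emulate.

## The analysis model

The pipeline treats the scalp EEG during an oddball speech task as a
superposition of (i) a brainstem/midbrain frequency-following response
phase-locked at the stimulus fundamental (F0 = 150 Hz, above the
cortical phase-locking limit, hence subcortically dominated), (ii)
posterior cortical alpha (8–12 Hz) whose power waxes and wanes with
arousal, and (iii) broadband noise.  The hypothesis the machinery
quantifies is cortico-subcortical coupling: the FFR's F0 amplitude
differs between trials of high versus low concurrent alpha power.  The
estimator is the F0 ratio

    F0 ratio = F0 amplitude (high-alpha average) / F0 amplitude (low-alpha average)

computed within participant and condition, so overall gain differences
between listeners cancel.

## Sampling rates and filters

Acquisition is emulated at 20 kHz; all analysis runs at 5 kHz after
anti-aliased polyphase resampling.  The 5 kHz analysis rate is forced by
internal consistency of the filter constants: a 100–1,000 Hz band-pass
of 661 taps spans 0.132 s, and an 8–12 Hz band-pass of 8,251 taps spans
1.65 s, only at 5 kHz.  The generator can fuse synthesis and decimation
per channel (`output_fs=`), which is numerically identical to
synthesizing at 20 kHz and resampling afterwards but keeps the peak
memory footprint of a full 32-channel condition modest.

Band-pass filters are Hamming-window sinc designs.  The automatic rule:
transition bandwidth at each edge is `min(max(0.25·edge, 2 Hz), margin)`
where the margin is the distance to DC or Nyquist; the length is
`ceil(3.3 / min_transition × fs)` forced odd (3.3 is the Hamming
window's normalized transition width); −6 dB cutoffs sit half a
transition width outside the band edges.  This single rule reproduces
all three printed constants (661 taps; 8,251 taps; cutoffs 7 / 13.5 Hz)
and is asserted in tests, as are the window's nominal 0.02 dB passband
ripple and 53 dB stopband attenuation (checked two transition widths
outside the band; they are design properties, not tight bounds at
arbitrary frequencies).  Filtering is applied as delay-compensated
linear-phase convolution (the `(n_taps−1)/2`-sample group delay is
removed) so FFR latencies are undistorted.

Referencing is stream-specific: common average for the brainstem band
(a requirement of the source inversion), linked mastoids (TP9/TP10) for
the cortical index streams.

## Epoching and the alpha index

Trials span [−50, +145) ms around each frequent-token onset — 195 ms,
975 samples at 5 kHz under the half-open convention we fix (the
inclusivity of the window endpoints is otherwise arbitrary; any
consistent convention shifts nothing downstream).  The window covers the
whole evoked FFR with no spillover between neighboring tokens (token
100 ms + ISI ≥ 95 ms).  Rare /ta/ trials are excluded everywhere.
Trials whose window exceeds the recording are dropped, never padded
(padding would bias RMS).

Alpha RMS per trial is computed at the POz proxy over the full epoch,
normalized to each run's median (making the index robust to slow
impedance and gain drifts), then pooled per participant × condition for
percentile categorization: low ≤ 35th percentile, high ≥ 65th.
Quantiles are linearly interpolated.  Tie rule (ours): boundary-equal
values join the extreme category; if ties push a category past the
count a distinct-valued sample would have, earliest trials are kept.
Low is assigned before high, so fully degenerate input still yields
disjoint 35% / 35% splits.  The same machinery runs unchanged on the
POz beta band (18–22 Hz) and on Fz alpha, the two control arms that
check the coupling is specific to posterior alpha.

## Source montage

The brainstem regional source has three orthogonal orientations; the
leadfield `L` (channels × 3) maps unit source currents to scalp
amplitudes.  We take the printed montage dimensions to be channels × 3
(the text's 3 × 64 / 64 × N pairing is inconsistent with a 32-channel
montage) and define the spatial filter as the Moore–Penrose
pseudo-inverse of the common-average-referenced leadfield; whether the
original montage normalized columns before inversion is unstated, so we
use the plain pseudo-inverse.  Only the z (vertical) orientation is
analyzed.  The synthetic leadfield is built from radial electrode
geometry around a deep, slightly posterior midline source, which makes
the z column dominate along the vertex line; it is a supplied input
(CSV), not a fitted head model.

## Spectra and the F0 ratio

The steady-state segment is [10, 100) ms post onset — 450 samples,
fixed by the printed 226 one-sided spectral points (450/2 + 1) and
11.1 Hz resolution (5000/450); consequently no zero padding.  The
segment is Blackman-tapered; amplitudes are normalized by the taper's
coherent gain so a unit sinusoid at a bin center reads ≈ 1.

The "11 Hz bin centered on 150 Hz" F0 search is implemented with
interval-overlap semantics: a grid bin qualifies when its spectral
extent (center ± half the 11.1 Hz spacing) overlaps 150 ± 5.5 Hz.  This
matters because the 11.1 Hz grid has no bin *center* inside that
interval — 150 Hz falls exactly between the bins at 144.4 and
155.6 Hz — so a centers-only reading selects nothing.  Overlap
semantics select exactly those two flanking bins and the maximum is
taken.

Response SNR is `20·log10(F0 amplitude / noise floor)` with the floor
defined (our choice; the original is unstated) as the mean amplitude
over bins whose centers lie 22–55 Hz from 150 Hz on either side —
symmetric flanks clear of F0 leakage.  Averages below 3 dB are flagged,
not dropped.  Alternating-polarity trials are averaged together
(envelope-emphasis convention); in the generator the evoked F0 response
is envelope-driven and does not flip with stimulus polarity, so pooling
is lossless.

## Statistics

Standard test internals are delegated to scipy/statsmodels.  Owned
here: the model structure, the log transform of F0 amplitudes before
ANOVA, Bonferroni bookkeeping (`p_adj = min(1, m·p)`, m logged), and
the slope-contrast algebra.  Two pieces are implemented in-repo because
no installed package provides them:

* **2 × 2 × 2 split-plot ANOVA** (two within factors, one between).
  Each 2-level within effect reduces to a per-subject contrast score;
  OLS of the scores on effects-coded group yields the within effect as
  the intercept test and its group interaction as the slope test, with
  the correct stratum error term.  This is the exact classical
  decomposition; with unequal group sizes the main effects are
  Type-III-style (unweighted group means), the convention of standard
  mixed-ANOVA software.  The implementation is validated against R's
  `aov(y ~ A*B*C + Error(subject/(B*C)))` term by term on balanced
  designs (where Type I and III coincide) in the test suite.
* **Conover–Iman pairwise rank test** with tie correction and
  Bonferroni adjustment, validated on a hand-computed example.

The Goldfeld–Quandt heteroscedasticity check splits at the median of X
with the middle 20% omitted (unstated in the original; fixed here for
determinism).  All tests are two-sided.  Regression slopes: with group
coded 0 (NH) / 1 (HL), β₁ is the NH slope, β₁+β₃ the HL slope (its SE
from the coefficient covariance), β₃ the difference; single-group input
is refused because the interaction column would be collinear.

## Classification

Features are the raw 226-point amplitude spectra (no standardization —
the procedure specifies none, and gamma = 'scale' adapts the kernel
width to feature variance).  Each iteration redraws the stratified
four-fold assignment and the minority-class oversampling (sampling with
replacement to balance, strictly inside training folds; the held-out
fold is never resampled).  The null re-shuffles each participant's 226
features independently *every* iteration (the more conservative reading
of the procedure; a single fixed shuffle would understate null
variance).  Note what the shuffle destroys: the spectral *pattern*, not
row-level statistics — a class difference in overall amplitude would
survive the null by construction.  "Exceeds" in `p = (a+1)/(n+1)` is
strict.

## The synthetic cohort

The generator's defaults are the study conditions: 3,000 + 3,000
frequent and 210 rare tokens per condition over three blocks, ISIs
uniform on {95, …, 155} ms in 5 ms steps with ≥ 2 frequent tokens
before every rare one, alternating polarity, 32-channel 10–20 montage,
13 NH + 19 HL listeners aged 52–75, NH PTAs in 8.3–20.83 dB HL and HL
in 15.8–45 dB HL.

Choices not fixed by the paradigm (ours, with rationale):

* **Coupling rule.** FFR source amplitude on trial *t* is
  `ffr_gain · (1 + coupling_g · (alpha_state_t − 1))`, where
  `alpha_state_t` is the alpha Hilbert envelope averaged over the
  trial's epoch window and normalized to the session median — mirroring
  the analysis-side normalized RMS so `coupling_g` maps interpretably
  onto the F0 ratio.  The paradigm's own account contains no generative
  alpha→FFR model (the coupling is the finding), so no external value
  constrains the scale; group defaults are 0.35 (NH) and 0.10 (HL).
* **Evoked template.** F0 + two harmonics (relative amplitudes 1 / 0.4
  / 0.2) over 10–100 ms with 5 ms raised-cosine ramps.  No acoustic
  speech is synthesized — the pipeline never touches audio — and
  formant-band coloring is omitted as nothing downstream reads it.
* **Alpha source.** 8–12 Hz Gaussian noise, amplitude-modulated by
  low-passed (0.1 Hz) noise at depth 0.3, projected with a Gaussian
  posterior topography peaking near Oz (Fz weight ≈ 0.02, which is what
  makes the Fz control arm uninformative).  NH mean posterior alpha
  4.5 µV RMS vs 3.5 µV for HL, SD 0.5 — the programmed group contrast.
* **Noise.** 5 µV per channel, split evenly between white and 1/f
  (3-pole IIR approximation).  At these levels a 2,100-trial category
  average clears the 3 dB response-SNR criterion by ~20 dB.
* **Babble condition.** Band-limited (100–1,000 Hz) Gaussian masker
  added to the evoked source drive at −10 dB relative amplitude, plus a
  0.8 gain scale — a degraded-response regime, not realistic babble.
* **Behavior links.** Hit probability is logistic in `ffr_gain`
  (clear-condition mean ≈ 0.88; the noise condition subtracts 1.2
  logits); single-trial RTs are lognormal around a mean that decreases
  with hit probability, giving the negative accuracy–RT association in
  the clear condition only.  QuickSiN keyword tallies are binomial(5)
  draws from a logistic psychometric whose SNR-50 tracks PTA
  (`1.6 + 0.1·PTA` dB plus listener noise, SD 0.7 dB NH / 2.0 dB HL —
  the HL group is programmed to be more variable).  FFR gain declines
  with PTA at −1.4%/dB in NH and −0.3%/dB in HL with 6% lognormal
  inter-listener jitter; the slopes were set once so the programmed
  NH-negative / HL-attenuated pattern is recoverable with high
  probability at the cohort's size, then frozen.
* **QuickSiN scoring.** Spearman–Kärber: SNR-50 = 27.5 − total keywords
  correct per list; SNR-loss subtracts the 2 dB normal-hearing
  reference; listener score averages four lists.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: eye/muscle artifacts and bad channels
(there is no artifact rejection stage by design), realistic head-model
leadfields (the montage inversion is exact by construction here;
real-montage accuracy depends on the supplied leadfield), cortical
sources other than the single alpha generator, non-stationary noise,
and any acoustic detail of the tokens.

## Problem sizes and numerical choices

Sessions serialize as FIF (MNE's native format) with a sidecar CSV
event table; EDF recordings are read through the same entry point.
Heavy validation runs use scaled conditions, chosen so Monte-Carlo
error is small against the asserted bands and stated in each test: the
categorization/spectral end-to-end checks run one full condition
(6,210 tokens, 20 kHz synthesis); the coupling-recovery grid uses
0.15-scaled sessions (5 couplings × 20 seeds); the no-coupling null
uses 0.3-scaled sessions × 50 seeds (the F0 ratio of a finite-trial
average is noisy, and its mean over seeds has MC error ≈ 0.009 at this
size, against a ±0.02 band); classifier calibration uses 200
replications of 200 iterations.  All stochastic stages consume
explicitly seeded `numpy` generators; pipeline stages draw from
independent spawned streams so cached re-runs reproduce later stages
bit-exactly.

Known limitations: the split-plot ANOVA covers the 2-level factorial
design only; the leadfield is supplied, not fitted; x/y source
orientations are discarded by design; and the F0-ratio estimator is
slightly biased upward at small trial counts (ratio of noisy
amplitudes), which is why null-band checks average over many seeds at
adequate trial counts.
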