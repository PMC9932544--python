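# alphaffr

Cortical state shapes subcortical sound encoding: speech-evoked
frequency-following responses (FFRs) recorded from the human brainstem
are not static, but co-vary trial-to-trial with posterior cortical alpha
(8–12 Hz) power — a running index of arousal.  `alphaffr` is a tested,
reusable pipeline for quantifying this cortico-subcortical interplay in
oddball speech-EEG experiments (frequent /ba/ and /pa/ tokens, rare /ta/
targets, F0 = 150 Hz), aimed at auditory-neuroscience labs studying
pitch encoding, aging, and hearing loss.

## What it computes

1. **Trial-wise alpha indexing** — single-trial alpha RMS at a POz proxy
   (mean of Pz and Oz, mastoid reference), normalized to each run's
   median, categorized per participant × condition into *low* (0–35th
   percentile) and *high* (65–100th percentile) alpha states.
2. **Brainstem source FFRs** — 100–1,000 Hz sensor data (common-average
   reference) projected through the pseudo-inverse of a brainstem
   regional-source leadfield, `SWF = L⁺ × FFR`; only the z (vertical)
   orientation is analyzed.
3. **F0 ratio** — per alpha category the steady-state FFR segment
   (10–100 ms; 450 samples at 5 kHz) is Blackman-tapered and Fourier
   transformed (226 points, 11.1 Hz resolution); F0 amplitude is the
   peak within an 11 Hz bin around 150 Hz, and

       F0 ratio = F0 amplitude (high alpha) / F0 amplitude (low alpha)

   so ratios above 1 mean stronger brainstem responses during high
   cortical alpha.
4. **Statistics** — one-sample t of ratios against 1, Mann-Whitney /
   Wilcoxon / Conover group comparisons, a 2 × 2 × 2 (SNR × alpha ×
   hearing group) split-plot mixed ANOVA on log F0 amplitudes with
   partial eta squared, Spearman brain–behavior correlations, and the
   dummy-coded slope-contrast regressions
   `Y = β₀ + β₁·X + β₂·group + β₃·X·group (+ β₄·age)` with residual
   diagnostics (Shapiro-Wilk, Breusch-Pagan, Goldfeld-Quandt), where
   β₁ is the NH slope, β₁+β₃ the HL slope, β₃ the slope difference.
5. **Decoding** — poor vs. good perceptual performers (30th/70th
   percentile of /ta/ detection) classified from their 226-point FFR
   spectra with an RBF SVM (C = 1,000, gamma = scale), stratified
   four-fold CV with training-fold-only minority oversampling, 5,000
   re-randomized iterations, a within-participant feature-shuffle null,
   and the empirical p-value `p = (a + 1)/(n + 1)`.

Because no public recordings accompany this paradigm, the `synth`
module generates complete cohorts with known ground truth: a brainstem
source phase-locked at 150 Hz projected through a known leadfield,
posterior alpha with slow amplitude modulation, and a programmable
coupling `coupling_g` between alpha state and FFR amplitude — the
quantity the F0 ratio estimates.

## Worked example

```python
import numpy as np
from alphaffr import synth, pipeline
from alphaffr.montage import make_leadfield

spec = synth.StimulusSpec().scaled(0.2)      # 600 + 600 + 42 tokens
leadfield = make_leadfield()
rng = np.random.default_rng(5)
listener = synth.draw_participant("NH", 0, rng, coupling=0.3)
schedule = synth.make_event_schedule(spec, 11)
session = synth.simulate_session(listener, leadfield, schedule,
                                 "clear", 12, spec=spec, fs=5000.0)
result = pipeline.analyze_session(session)
low, high = result["spectra"]["low"], result["spectra"]["high"]
print(f"trials: {low.n_trials} low / {high.n_trials} high alpha")
print(f"response SNR: {low.response_snr_db:.1f} / {high.response_snr_db:.1f} dB")
print(f"F0 ratio: {result['f0_ratio']:.3f}")
```

prints

```
trials: 420 low / 420 high alpha
response SNR: 15.8 / 14.5 dB
F0 ratio: 1.204
```

420 trials are the 35% tails of the 1,200 frequent-token trials; both
category averages clear the 3 dB response-SNR criterion by a wide
margin; and with a programmed coupling of 0.3 the high-alpha FFR carries
about 20% more F0 energy than the low-alpha FFR — the ratio the
statistics stage then tests against 1.

A full cohort run (13 NH + 19 HL listeners, both conditions, statistics
and classification) is one call:

```bash
alphaffr all --seed 7 --fraction 0.1 --iterations 200 --out runs/demo
alphaffr report runs/demo
```

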