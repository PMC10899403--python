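# Methods

`eegmdd` re-implements, as a tested pipeline over synthetic cohorts, a
resting-state EEG analysis for recognising major depressive disorder
(MDD): spectral band power over scalp regions, hemispheric asymmetry,
FDR-corrected group contrasts, and a cross-validated logistic diagnostic
model.  This note records the model, the conventions, and the design
choices where the design was genuinely open.

## Synthetic cohort model

Each subject contributes one eyes-open (EO) and one eyes-closed (EC)
19-channel 10–20 recording.  Every channel is a zero-mean Gaussian
process whose PSD is the sum of

* a `1/f^χ` background (default χ = 1, RMS 3.5 µV within 1–40 Hz,
  support 0.5 Hz to Nyquist), and
* six band-limited oscillations, one per analysis band, each with the
  squared-magnitude response of a 4th-order Butterworth band-pass as its
  spectral shape, normalized so a configured µV RMS amplitude sets its
  in-band power.

Signals are synthesized in the frequency domain (complex Gaussian draws
scaled by the target amplitude spectrum, inverse rFFT).  Because a sum of
independent Gaussian processes is Gaussian with the summed PSD, this is
statistically identical to adding zero-phase band-pass-filtered white
noise per band, at a fraction of the cost — the repeated-cohort
calibration studies run hundreds of recordings per minute.

Structure enters through the amplitude matrix (channel × band):

* **Topography** — posterior alpha gain 1.6 (the resting rhythm is
  parieto-occipital), and ×2 posterior alpha for EC (`alpha_reactivity`,
  alpha blocking on eye opening).
* **Group effects** — multiplicative factors on (group, eye state,
  channel set, band) cells.  Defaults mirror the reported MDD contrasts:
  EO frontal beta2 ×1.38 (central ×1.12), EO occipital beta3 reduction
  (O1/O2 ×0.84; Pz, shared with the parietal region, gets the mean of
  its regions' multipliers, ×0.92), EC right-medial-frontal beta2 ×1.28
  with a weaker left companion ×1.18, EC right-temporal alpha ×1.08, EC
  right-medial-occipital beta3 ×0.85.
* **Asymmetry shifts** — signed fractional amplitude shifts applied with
  opposite signs to homologous right/left temporal channel sets (right
  ×(1+s), left ×(1−s)); a fractional shift is scale-free across bands,
  which is why it is preferred over an absolute µV offset.  Group-specific
  defaults reproduce the reported signs: MDD right-shifted in EO
  alpha/beta1 and EC alpha, HC right-shifted in EO beta2/beta3 and EC
  theta.
* **Between-subject variability** — log-normal per-band subject factors
  (σ = 0.25) shared across channels and eye states, plus log-normal
  per-(channel, band) jitter (σ = 0.15).  The jitter must vary by band:
  a gain shared across a channel's bands cancels exactly in relative
  power, which would leave asymmetry scores artificially noise-free.

Default effect magnitudes were fixed by one large-cohort calibration run
(150/group): the asymmetry cells land on the reported d ≈ 0.3–0.55
scale with the printed signs, and the EO frontal beta2 contrast — for
which no effect size is printed — is the dominant power contrast
(relative-power d ≈ 0.9 at large n), the regime in which the planted
effect reliably heads the FDR ranking at 40 subjects per group.

**Clinical scores.** MDD subjects get
`HDRS-17 = 17 + max(0, round(6.6 + 1.8·z + ε))`, where `z` is the
subject's standardized beta2 latent and `ε ~ N(0, 4.9²)`; calibrated so
the MDD group lands near 24.1 ± 4.8 with the ≥ 17 inclusion floor, and
the cohort-level Pearson correlation between HDRS-17 and EO prefrontal
beta2 relative power sits near 0.23.  HAMA is uncoupled noise
(≈ 20 ± 7).  Sex ratios and age distributions follow the reference
cohort's demographics.

**Artifacts** (off by default; rates are parameters): blinks are 0.3–1 s
smooth positive transients, 100–300 µV at Fp1/Fp2, decaying posteriorly
by a fixed gain map; excursions are 0.15–0.4 s signed bursts of
250–450 µV on one random channel.  Ground truth records, for each
excursion, the span where the injected waveform alone exceeds 150 µV —
exactly what an amplitude-rejection stage should flag.

**Determinism.** The cohort is a pure function of its simulation spec.  Per-subject
seeds derive from the cohort seed; the subject profile (latents, jitter)
depends only on the subject seed, so both eye states share it, while the
noise draw also keys on the eye state.

## Preprocessing

Fixed order: band-pass → notch → downsample → ocular ICA → 2-s epoching
→ amplitude rejection → average re-reference.  Rejection runs on the
original reference; re-referencing comes last.

* **Band-pass 1–40 Hz**: zero-phase (forward–backward) Butterworth.  The
  contract is a two-pass passband gain within ±0.5 dB over 2–35 Hz; a
  4th-order design misses it by ~2 dB at 35 Hz, so the default order is
  12 (−0.25 dB at 35 Hz).  **Notch 49–51 Hz**: 2nd-order zero-phase
  band-stop (≥ 20 dB at 50 Hz, < 3 dB at 45 Hz).  **Downsample** to
  500 Hz by polyphase resampling; skipped with a provenance note when the
  recording is already at or below the target (the desk-scale preset
  simulates at 250 Hz).
* **Ocular ICA**: seeded FastICA; a component is ocular if its time
  course correlates with the Fp1/Fp2 mean beyond |r| > 0.7 or its mixing
  weights are frontally dominated (mean |weight| at Fp1/Fp2 > 3× the
  channel median).  FastICA's formal convergence test routinely fails on
  near-Gaussian sources (the unmixing rotation is non-identifiable in
  the Gaussian subspace) while the ocular components it isolates are
  stable and reconstruction is exact; the decomposition is therefore
  used regardless, with the convergence flag recorded, and only a hard
  failure falls back to pass-through with a logged warning.
* **Epoching**: consecutive, non-overlapping 2-s epochs; trailing
  partial epoch discarded.  **Rejection**: an epoch is dropped when any
  sample on any channel is strictly beyond ±150 µV (a peak of exactly
  150 µV is retained); sample values are never modified, and the log
  names the offending channel and peak.  **Average reference**:
  per-timepoint channel mean subtracted; idempotent.

Every stage appends parameters to the recording's provenance, so an
epoch set's history is reconstructible.

## Spectral features

Per retained epoch: one-sided Hann-tapered periodogram (2-s epochs give
a 0.5 Hz grid; the PSD integrates to the tapered variance).  Band power
sums the bins whose centre lies in the band's half-open range — delta
[1,4), theta [4,8), alpha [8,12), beta1 [12,16), beta2 [16,24), beta3
[24,40] with the final edge closed — so shared edges count once.  On the
0.5 Hz grid the six bandwidths are 3, 4, 4, 4, 8, 16.5 Hz; white noise
splits its relative power in those proportions (the package's spectral
calibration check).  A second estimator (zero-phase band-pass + Hilbert
analytic signal, half the mean squared magnitude) is provided and agrees
with PSD integration within ~10% on band-limited signals.

Relative power divides each band by the six-band total per channel and
epoch; relative powers are averaged across epochs (per-epoch
normalization first), then averaged over each region's channels and
renormalized (a no-op up to rounding).  Asymmetry is the right-ROI
fraction minus the homologous left-ROI fraction per band, delta
excluded.  Log-ratio alpha asymmetry is deliberately not used — the
reference quantities are raw relative-power differences.

## Group statistics

Welch's t-test by default (pooled available); two zero-variance samples
with equal means return (t = 0, p = 1) by convention.  Cohen's d uses
the n−1-weighted pooled SD and the **HC − MDD** difference, the only
convention reproducing the printed −0.547 for the EO temporal beta1
asymmetry row.  Benjamini–Hochberg adjustment runs within four families:
power and asymmetry features separately per eye state (the narrowest
reading of the reported per-condition corrections).  Demographic 2×2
tables use Pearson chi-square without continuity correction, df = 1.
Clinical correlations are Pearson r within the MDD group.

## Diagnostic model

Unpenalized binary logistic regression on raw (unstandardized) features
— relative-power fractions, hence coefficients of order tens — fit by
IRLS to 1e−8 log-likelihood tolerance; SEs from the inverse observed
information, two-sided Wald p.  Diverging standardized slopes
(|B|·sd > 12) signal separation; the model is then refit with a small
ridge (λ = 1e−4) and flagged.  The default feature set is declarative:
the 18 band-power and asymmetry features reported significant per
condition.

Performance: stratified 10-fold CV with a fixed seed; fold AUC is the
trapezoidal area under the ROC (equal to the Mann–Whitney U statistic
over n₊n₋; `score ≥ threshold ⇒ positive`); fold sensitivity/specificity
are measured at the Youden cut-off (max sens + spec − 1, ties broken
toward the lowest threshold, favouring sensitivity) derived from the
*training* scores — deriving it on the test fold would leak.  Metrics at
a fixed 0.5 cut-off are also reported.  The 95% CI is a percentile
bootstrap (2000 draws, stratified by class) of the AUC of the pooled
out-of-fold scores; it describes the pooled cross-validated
discrimination and need not bracket the fold-mean AUC.

## Problem sizes

The desk-scale preset — 60 s per eye state at 250 Hz, 40 subjects per
group — keeps a full cohort analysis under ten seconds and the
repeated-cohort studies (25 effect cohorts, 50 null cohorts) around ten
minutes on one core, while preserving 30 epochs per recording and the
reported group-effect structure.  The clinical protocol (600 s at
1000 Hz, downsampled to 500 Hz) is available by configuration and is
used in the EDF and epoch-count tests.

## What the simulation does and does not establish

Passing tests show the pipeline recovers exactly the structure the
generator plants: effect signs and approximate magnitudes, artifact
ground truth, chance-level behaviour under the null, and nominal type-I
error.  The generator is deliberately not a biophysical model: no head
model or volume conduction (channels are independent up to shared
amplitude factors, so spatial correlation of real EEG is absent), no
non-Gaussian ongoing activity, no nonstationarity within a recording, no
medication, comorbidity, or vigilance effects.  Consequently the
cross-validated AUC on synthetic cohorts characterizes the pipeline, not
the clinical problem, and the original study's fitted coefficients and
AUC are not reproduction targets — the raw cohort is not deposited.
The few published statistics recomputable from printed tables (the
demographic chi-squares and one asymmetry effect size) are recomputed
exactly.

Known limitations: the ROI scheme's shared electrodes (Fz, Pz) make
neighbouring regions correlated by construction; boosting one band's
amplitude leaks a little true power into adjacent bands through the
oscillation's spectral skirts, so zero-sum monotonicity holds for the
non-adjacent bands and the five-band total, not strictly per neighbour;
and at 30 epochs per recording the per-band Monte-Carlo error of
periodogram averaging is ~10%, which bounds how tightly single-subject
features can be pinned.
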