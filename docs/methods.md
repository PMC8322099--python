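# Methods

This note documents the models, conventions, numerical choices and
limitations behind each module. Parameter defaults are stated with units;
everything here is configurable unless noted.

## Vocal harmonic analysis

**Syllable detection.** The baseline-noise SD is estimated from a
configurable leading segment (default: first 50 ms); constant audio raises
an explicit no-baseline error. A candidate region is a contiguous run with
|amplitude| above `bound_k` (default 5) × SD; it becomes a syllable iff it
contains a sample above `detect_k` (default 10) × SD. Margins of 15 ms are
added and regions whose margin-extended intervals overlap are merged — the
merge rule is our choice, made so that closely spaced bursts are treated as
one syllable rather than double-counted.

**Contour extraction.** Spectrograms use a Hann short-time Fourier
transform whose hop equals the requested time resolution (0.5 or 1 ms
depending on strain conventions) and whose window is twice the hop. Per
time bin, broadband structure is removed by subtracting a moving average
along the frequency axis (4 kHz window); a 3×3 median filter and the Frangi
vesselness filter (σ = 1–3 px, standard constants, bypassable) enhance
ridge continuity. Pixels above 5% of the processed image's maximum are
kept, gated on positive detrended power — the ridge filter rings around
bright lines, and the gate removes the resulting ghost contours at
frequencies that carry no energy. Flood-fill (8-connected) components
shorter than 7 ms are rejected. For each contour and time bin the
representative frequency is refined by log-parabolic interpolation of the
raw magnitude around the brightest contour pixel, giving sub-bin (≪ one
500 Hz bin) accuracy; without this refinement the bin-center quantization
propagates into a percent-level F0 bias.

**Template matching.** For each candidate F0 on a grid (default 1–10 kHz
in 50 Hz steps, spanning the vocal range at resolution finer than its
width) each observed component frequency receives the harmonic order
`f = round(F_real/F0)`, clipped to ≥ 1. Because each component's term of
the evaluation function is independent, this per-component rounding *is*
the exhaustive minimum over order assignments, which the tests verify
against a brute-force oracle. The sum runs over observed components only
(missing harmonics are not penalized), and two components may legitimately
map to the same order. Exact EF ties occur at in-grid subharmonics of the
true fundamental; ties resolve to the highest tied candidate so F0/2 never
wins over F0. A segment is harmonic when EF < 0.5. Segments are 1.4 ms
wide; each contour contributes its mean ridge frequency within the segment.

## Stimulus construction

Component frequencies of harmonic stacks are exact integer multiples of
F0. Δonset shifts set the designated group's onset to the signed delta
(negative = the group leads); the unshifted group defines time zero.
"Lower half" of an n-component stack means the ⌊n/2⌋ lowest components,
which extends the even-stack protocol to odd n. Spectral jitter draws one
uniform perturbation per component; a draw that would produce a
non-positive frequency is redrawn (logged) so the component count is
preserved for downstream analyses. Waveforms sum sine-phase components
with 5 ms linear rise/fall ramps at 192 kHz; per-component amplitudes are
equal in linear amplitude (a dB-equal option is a caller-side choice of
levels) and scaled so the coherent peak sum equals the linear amplitude of
the nominal level relative to a configurable full-scale reference —
absolute SPL is not reproducible in software, so level labels are relative.
Presentation schedules randomize all stimuli once per block with an
independent seeded permutation per block.

## Synthetic data

The generators define the study conditions under which the analyses are
validated.

**Imaging populations.** Default conditions: five fundamentals (2, 2.8, 4,
5.7, 8 kHz), seven Δonsets (−45…45 ms, 15 ms steps), five randomized
blocks (five trials per stimulus), 30 Hz frame rate, 4 s trial spacing.
Response archetypes mirror the three empirical profile clusters:
negative-shift (full weight at negative Δonsets), positive-shift
(mirrored), coincidence (weight 1 at Δonset 0, 0.1 at ±15 ms), and
nonresponsive. Per trial the amplitude is
`a = w·peak·(1 + ε) + λ` with multiplicative trial noise ε (SD 0.2) and a
latent λ shared by all members of a same-F0 coincidence subnetwork on that
trial. The closed form `r = σ_λ²/(σ_λ² + σ_n²)` with σ_n the RMS over
stimuli of the per-trial amplitude noise calibrates the latent SD to a
target noise correlation. Amplitudes drive a difference-of-exponentials
calcium kernel (rise 50 ms, decay 1 s, GCaMP6s-like), normalized to unit
trapezoidal area over the 1 s response window — planted amplitudes are
therefore in ΔF/F·s and the analysis chain returns them exactly in the
noiseless limit. The kernel is truncated before the next trial's baseline
window so that exactness is not spoiled by tail bleed-through. Fluorescence
is written as `F = B + (B + offset)·ΔF/F` (B = 200 a.u., offset = 20 a.u.),
deliberately inverting the analysis normalization, and contaminated with
an independent background trace (100 a.u., SD 2) at the neuropil
coefficient so the correction step is exercised. Same-F0 coincidence cells
are placed in 2-D Gaussian clusters (σ = 50 µm) in a 620 × 620 µm field;
other cells are uniform. What the generator does *not* emulate: spiking
dynamics, nonlinear indicator saturation, correlated neuropil
contamination, motion artifacts, and cells responsive to several
fundamentals — passing tests demonstrate correctness of the analysis
algebra and estimator calibration, not robustness to those real-data
effects.

**Vocal audio.** Harmonic syllables (default 60 ms, three equal-amplitude
harmonics, 5 ms ramps) at listed fundamentals, separated by 80 ms silent
gaps, in white noise whose RMS sits a stated SNR below the syllable RMS.

**Spikes.** Inhomogeneous Poisson thinning on a 0.1 ms grid; light trials
multiply the rate by `floor + (1 − floor)·exp(−(t − latency)/τ)` after the
suppression latency.

**Behavior.** Lick probability follows a logistic in
`log10(1 + |Δonset|)` with a planted midpoint (ms) and slope; light trials
(default 30%, randomly interleaved) use a shifted midpoint. Δonset grid:
0 to −75 ms in 15 ms steps, matching the negative-shift testing protocol.

## Imaging analysis conventions

The per-trial baseline window is the 1 s before sound onset (length is our
choice; only "baseline" is inherited). ΔF/F adds the 20 a.u. offset to the
denominator only, as a guard against dim baselines; a flag to add it to
the numerator as well is available. Significance requires both the
single-trial and the trial-mean criterion with ≥ 0.5 s consecutive
suprathreshold frames; it is monotone in the threshold multiple. ROC
calibration picks, among candidate cutoffs with true-positive rate ≥ 0.9
on labeled tone responses, the one with minimal false-positive rate
(breaking ties toward higher TPR and returning the midpoint of the
resulting score gap) — for separable classes this yields the gap midpoint
at TPR 1, for overlapping classes the 90% quantile boundary of the
positive class. CI/LI clip negative amplitudes to zero first; 0/0 cases
return NaN sentinels that pooled statistics drop (counts retrievable).
CI pooling uses the ±15 and ±30 ms comparisons and excludes ±45 ms; the
whole-cell LI convention averages over the same four shifts before
comparison. BW70 averages the bin-inclusive span of significant
frequencies (outermost significant tones plus one grid step, compensating
the half-step discretization bias on each side) with the span where a
least-squares Gaussian over log2(frequency) exceeds half its peak.

## Ensemble and network analysis

Population matrices zero non-significant amplitudes before per-pair max
normalization; pairs without a significant condition, or with a zero
normalizer, are excluded. Euclidean distances divide by √(number of
pairs), making geometry invariant to duplicating the population. NMF uses
multiplicative updates with random non-negative initialization, a master
seed spawning per-restart seeds (so more restarts can only lower the best
reconstruction error), and the lowest-error restart wins. Templates are
named by the Δonset at which they peak; a peak set containing 0 resolves
to "coincidence". The matrix orientation is conditions × pairs
(factorizing pair profiles); a transposed analysis is a caller-side
transpose. The coincidence fraction's denominator includes "others" by
default. The overlap permutation test redraws each membership set
uniformly over the universe preserving its size and reports the add-one
corrected p, which is discrete (integer statistic) and therefore slightly
conservative — exact uniformity holds only in the fine-grained limit.
Noise correlations subtract per-stimulus trial means and concatenate
residuals across stimuli and trials; zero-variance residuals yield NaN
pairs. Distance matching uses a ±10% fractional tolerance, doubling up to
twice before giving up (or raising, under the strict flag); SD/SNR
matching takes the two closest-statistic ROIs per member and all four
cross combinations.

## Electrophysiology and behavior

PSTH bins are half-open `[lo, hi)`; the optional three-bin moving average
is for display and excluded from quantification. The suppression fit
models the normalized rate as 1 before the latency and an exponential
decay to a floor after it, least-squares over a small latency
initialization grid; non-decaying inputs (late mean ≥ 0.95) return a
failure sentinel rather than a fit. d′ uses the equal-variance Gaussian
convention `z(hit) − z(fa)` with rates clipped (conventionally at 1/(2N));
the source protocol does not state its formula, so this standard choice is
ours. Psychometric fits maximize the binomial likelihood of a logistic in
the signed log-modulus coordinate via Nelder-Mead from several slope
initializations; degenerate all-lick/no-lick conditions return a failure
sentinel. The half-max Δonset back-transforms the fitted midpoint. Session
trimming removes leading/trailing runs of ≥ 10 consecutive misses and an
optional first-250-trials cap. Broadening is reported two ways — the mean
of per-session fractional widenings and the widening of the group-mean
thresholds — because the two differ under between-session heterogeneity
(the per-session mean of ratios is inflated by noisy session thresholds);
neither is privileged.

## Problem sizes in the test and acceptance runs

The suite validates at desk scale: ~30 planted syllables (~10³ analysis
segments) for vocal recovery; populations of 60–180 ROI-F0 pairs for NMF
(20 noise seeds at archetype SNR 3); 200+ same-subnetwork pairs across
three seeds for noise-correlation calibration; 200 simulations × 1000
permutations for null calibration; 50 seeds × 250 trials for psychometric
recovery; 500 Poisson trials for suppression kinetics. These sizes were
chosen as the smallest at which the estimators' sampling error is clearly
inside the asserted tolerances.

## Known limitations

- The F0 grid search is linear in grid size; very fine grids over wide
  ranges are quadratic in (grid × components) per segment.
- Harmonic-order assignment assumes components below ~1.5 × F0 are the
  fundamental (order ≥ 1 clipping); strongly inharmonic inputs are
  meaningfully matched only through the EF threshold.
- The significance test pools baseline SD across trials; slow baseline
  drift inflates it and makes the test conservative.
- NMF cluster identity relies on template peaks over Δonset; with k other
  than 3 the label set no longer maps onto the three archetype names.
- Matched-control construction is per field of view and does not model
  across-session registration.
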