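# Methods

somnadapt implements the analysis chain of a sleep/face-adaptation
experiment: observers adapt to a strongly extended distortion of a familiar
face, sleep (or stay awake) for an interval, and then judge every level of
a 13-step compressed-to-extended continuum as "compressed" or "extended"
(2AFC). The behavioural readout is the fitted mean rating (FMR); the
physiological readout is polysomnography summarized as stage durations,
spindle densities and spectral band power, correlated with FMR across
subjects.

## Stimulus continuum

The continuum maps integer levels k ∈ [−6, +6] to warped versions of one
source face; k = 0 is the untouched original. The warp is radial about the
face midpoint with Gaussian falloff: a source pixel at radius r maps to

    r' = r · (1 + s·k·exp(−r² / (2f²)))

with gain s (default 0.02 per level) and falloff f (default 30 % of the
image's smaller dimension). Positive k pushes inner features outward
("extended"), negative k compresses; the border is essentially fixed, so
the face outline is preserved while the internal configuration changes —
the qualitative manipulation of configural face distortion. Rendering
inverts the radial map numerically on a dense monotone radius table and
samples the source by bilinear interpolation (inverse mapping; no holes;
border clamp). The map is monotone, hence invertible, whenever s·|k| is
well below 1; the constructor rejects parameters that break this. Colour
images are warped identically per channel. The exact functional form of
the original stimulus-generation algorithm is not recoverable; this warp
is a documented stand-in with the same interface and semantics, and the
mean absolute displacement — linear in |k| for fixed s, f — is the tested
monotonicity invariant.

## Trial schedules

Adaptation: four durations (0.5/2/4/6 s) × three sizes form 12 trials per
cycle, shuffled independently per cycle; four cycles per block, six
blocks, 288 trials, 900 s cumulative exposure. Randomizing within cycles
(not globally) is what preserves the counterbalancing, and the duration
multiset makes total exposure seed-invariant. Stimulus positions are
uniform over placements that keep the image fully on a 1024 × 768 canvas;
30-s inter-block breaks enter trial onsets as metadata but are not
simulated time. Test: each repetition is an independent random permutation
of the 13 levels (4 or 12 repetitions in the two experiment designs), 2 s
per stimulus.

## Psychometric fitting and FMR

P(extended | k) is modelled as the two-parameter logistic
1/(1 + exp(−β(k − α))): α is the point of ambiguity, β > 0 the slope. We
fit by Bernoulli maximum likelihood (no lapse/guess parameters, matching
the printed two-parameter form) with L-BFGS-B, bounds α ∈ [−12, 12],
β ∈ (0, 10], likelihood tolerance 1e-8, and three starts (a logit-linear
moment estimate plus two fixed starts) against local optima. FMR is the
fitted curve at k = 0; 0.5 means no bias, values below 0.5 the expected
after-effect toward "compressed" following adaptation to an extended
face. If a subject answers identically everywhere the likelihood has no
interior optimum: the fit is flagged non-converged and the empirical mean
is reported with a warning. All test repetitions are pooled into one fit
per subject. Outlier exclusion is a single pass: subjects whose FMR
deviates more than 2.5 group s.d. from the group mean (mean and s.d. over
the full group, applied within group cells) are flagged.

## Sleep EEG

Preprocessing resamples to 256 Hz (polyphase, built-in anti-alias) and
applies zero-phase 4th-order Butterworth bandpasses per modality: EEG
0.3–35 Hz, EOG 0.1–35 Hz, EMG 40–120 Hz. Filter family and order are our
choice (only the bands are given by the design); zero-phase filtering
preserves event timing for the detectors downstream. Resampling precedes
filtering — cheaper and equivalent within the passband.

Hypnograms are inputs (30-s epochs, labels W, S1–S4, REM, MT); manual
scoring is not re-implemented. Total sleep time (TST) is epochs minus wake
epochs; movement time stays inside TST but belongs to no stage, so stage
percentages over S1–REM can sum below 100 %. SWS is S3 + S4 collapsed.
Scorer concordance is percent epoch-wise agreement.

## Spindle detection

Per channel (Fz, Cz, Pz) and band (slow 9–12 Hz, fast 12–15 Hz): bandpass
(zero-phase Butterworth order 4), restrict to S2–S4 epochs, moving RMS in
a 0.2-s centered window (edges truncate), threshold at `threshold_sd`
(default 1.5, allowed 1.5–2.5) times the s.d. of the band-filtered signal
computed over the included epochs only — a whole-night baseline would be
deflated by wake. Supra-threshold runs closer than 0.1 s are merged
(threshold chatter; configurable), then events lasting 0.5–3 s are kept.
Restricting detection to eligible samples truncates events at boundaries
into non-S2–S4 epochs. Density is events per minute of S2–S4 sleep, per
channel and pooled (mean over channels); the per-minute denominator is the
field convention, as density is otherwise undefined here.

A caveat the tests respect: a 0.2-s RMS window plus narrowband filter
ringing lengthen the supra-threshold run of a very strong (≈10× noise)
burst by roughly 0.3–0.45 s, so a strong burst slightly shorter than the
0.5-s gate can still yield an in-gate detection. The duration gate
operates, as defined, on the detected run, and the short-side gate test
uses a weak short burst whose run genuinely stays below 0.5 s.

## Spectral analysis

Signals are bandpassed to 0.15–48 Hz; W and MT epochs are dropped; each
remaining 30-s epoch is cut into four 10-s windows with starts spread
uniformly (offsets 0, 20/3, 40/3, 20 s — samples 0, 1707, 3413, 5120 at
256 Hz), giving 0.1-Hz bins. FFT magnitudes (|FFT|/N; magnitude, not
squared power) of all windows of all eligible epochs are averaged per
channel and bin, and the natural log of that mean is the spectrum; the
normalization and log base are recorded in the output metadata. No taper
is applied by default (plain FFT of the windows); a Hann option exists.
Band power is the mean of per-bin log values over [lo, hi), with delta
defined as < 2 Hz and theta as 3–7 Hz.

## Group statistics

Group FMRs are tested against the theoretical point of ambiguity 0.5 with
one-tailed one-sample t-tests (lower tail, the a-priori direction) and
Cohen's d = |mean − 0.5|/s.d. Between-subjects factorial ANOVAs use
Type-III sums of squares under sum-to-zero (effect) coding, computed by
explicit design-matrix model comparison (drop each term's columns from the
full model); this handles the unbalanced and degenerate designs that arise
after subject exclusion, defines F = 0 when an effect's SS is zero, drops
interactions (with a warning) when design cells are empty, and reports
partial eta squared SS_effect/(SS_effect + SS_error). Bonferroni post hocs
are pairwise t-tests with p multiplied by the number of comparisons.
Sleep–behaviour relations are uncorrected bivariate Pearson correlations
with two-tailed t-transform p-values (two-tailed as the conservative
default even for directional claims); parameters with fewer than three
complete pairs or no variance are skipped with a warning. A two-factor
mixed ANOVA (one within, one between) for repeated ratings such as
sleepiness delegates to pingouin.

## Synthetic data

`simulate_night` builds a 256-Hz three-channel recording: 1/f background
noise (exponent 1 — realistic enough for threshold statistics without
modelling full EEG microstructure), a 0.5–2 Hz oscillation at 3× noise
s.d. in S3/S4, low-amplitude 4–7 Hz activity in REM, and Hann-enveloped
spindle bursts at the band centers (11/13.5 Hz — fixed for unambiguous
band attribution) with durations uniform in [0.5, 2] s, placed wholly
inside S2–S4 epochs at Poisson rates (defaults 2/min slow, 3/min fast per
channel) and peak amplitude 10× the background s.d. Ground-truth onsets
are returned. The default 180-epoch nap template totals 27 W, 35 S1,
60 S2, 13 S3, 32 S4, 11 REM, 2 MT — the realistic nap architecture the
stage summaries target.

`simulate_cohort` plants a population correlation r* between a sleep
parameter and FMR via FMR = a + b·param + ε with b = r*·σ_F/σ_P and
ε ∼ N(0, σ_F²(1 − r*²)); FMRs are clipped to [0, 1] with the clip rate
reported. Defaults are the nap-group study conditions (FMR 0.20 ± 0.19,
REM epochs 11.4 ± 14.2), at which clipping truncates a nontrivial share
of the FMR distribution and attenuates the realized correlation — a real
feature of bounded outcome measures. The correlation-recovery tests
therefore exercise the planting machinery at FMR mean 0.5, s.d. 0.15,
where clipping probability is negligible by construction, so they measure
the generator, not the truncation. At n = 12 the sample Pearson r is
biased low by ≈(1 − r²)/(2n) (≈0.018 at r = 0.7), well inside the test
band.

`simulate_experiment` assembles a full cohort: sleep-group subjects get
simulated nights, their true FMR tied to the night's REM epoch count
(slope −0.012 per epoch around mean 0.20, mirroring the studied REM ↔
adaptation association), responses drawn from the implied logistic
observer (β = 0.8); wake and immediate groups draw FMRs around 0.43 and
0.20 (s.d. 0.15). All generators are bit-reproducible given their seed.

What the synthetic data do not emulate: real EEG microstructure
(K-complexes, slow-oscillation coupling, topography), scorer disagreement,
lapses and response biases in 2AFC behaviour, and circadian structure of
full nights. Passing tests therefore demonstrate correctness of the
computations under the stated generative model, not detector or fit
performance on human recordings.

## Problem sizes and numerical choices

Test-suite simulations use 10–20-minute nights (20–40 epochs) for detector
performance (10 seeds), 200 responses/level for parameter recovery
(3 settings × 10 seeds, each fit cross-checked against a grid-search ML
oracle; recovery asserted on the per-setting mean over seeds, since
per-fit extremes at this sample size are dominated by MLE sampling noise),
500 replicate cohorts of n = 12 for correlation recovery, and a
3 + 3 + 3-subject, 20-epoch cohort for the end-to-end determinism check —
sizes chosen so the full suite runs in well under a minute while keeping
every assertion statistically comfortable. Degenerate inputs (all-wake
hypnograms, constant responses, zero eligible minutes, zero-variance
samples) are flagged or raised rather than silently propagated, as
documented per function.

## Known limitations

- EDF is read (via mne) but not written; the canonical on-disk raw format
  is a documented columnar TSV (~7 significant digits, finer than 16-bit
  quantization).
- The warp is a stand-in for the original (unavailable) stimulus
  algorithm; identity at k = 0, compress/extend semantics and displacement
  monotonicity are guaranteed, pixel-level equality to the original
  stimuli is not.
- Spindle detection duration reflects the supra-threshold run, which for
  very strong bursts exceeds the underlying burst duration (see above).
- Correlation p-values are uncorrected by design; interpretation across
  the parameter family is the user's responsibility.
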