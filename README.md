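# somnadapt

Analysis pipeline for studying how **sleep affects long-term visual face
adaptation**, written for researchers in sleep neurophysiology and visual
psychophysics. Observers adapt to a strongly extended distortion of a
familiar face, then — after a full night, a 90-min nap, a wake interval,
or immediately — judge every level of a 13-step compressed-to-extended
face continuum as "compressed" or "extended" (2AFC). The package covers
the entire chain:

- **Stimuli** — a radial Gaussian-falloff warp generates the distortion
  continuum k ∈ [−6, +6] (k = 0 is the untouched face).
- **Schedules** — counterbalanced adaptation trials (4 durations × 3
  sizes × 4 cycles × 6 blocks = 288 trials, 900 s exposure) and
  randomized 13-level test blocks.
- **Psychometrics** — per-subject maximum-likelihood fits of the logistic
  P(extended | k) = 1/(1 + exp(−β(k − α))), where α is the point of
  ambiguity and β the slope. The adaptation statistic is the **fitted
  mean rating (FMR)**: the fitted curve at k = 0. FMR = 0.5 means no
  bias; lower values mean a stronger after-effect toward "compressed".
  Subjects beyond 2.5 group s.d. are excluded.
- **Sleep EEG** — resampling to 256 Hz, modality-specific zero-phase
  bandpasses (EEG 0.3–35, EOG 0.1–35, EMG 40–120 Hz), hypnogram stage
  summaries (absolute epochs and % of total sleep time, SWS = S3 + S4),
  scorer concordance.
- **Spindles** — slow (9–12 Hz) and fast (12–15 Hz) spindle detection on
  Fz/Cz/Pz by moving-RMS (0.2 s) thresholding at 1.5–2.5 s.d. of the
  band-filtered signal over S2–S4 epochs, with a 0.5–3 s duration gate;
  densities in events per minute of S2–S4 sleep.
- **Spectra** — per-epoch FFT over four overlapping 10-s windows,
  log mean |FFT| per 0.1-Hz bin, delta (< 2 Hz) and theta (3–7 Hz) band
  power.
- **Statistics** — one-tailed one-sample t-tests of group FMRs against
  0.5 with Cohen's d, Type-III factorial ANOVAs with Bonferroni post
  hocs, mixed ANOVA for repeated ratings, and uncorrected Pearson
  correlations of sleep parameters with FMR.
- **Synthetic data** — seeded generators for stage-structured EEG with
  ground-truth spindle bursts, logistic 2AFC observers, and cohorts with
  planted sleep–behaviour correlations, so the full pipeline runs and is
  testable without any recordings.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Run the end-to-end pipeline on a simulated nap cohort (6 sleep, 6 wake,
6 immediate subjects; 30-min nights; 12 test repetitions):

```
somnadapt run --out demo --seed 1 --n-sleep 6 --n-wake 6 --n-immediate 6 \
              --epochs 60 --repetitions 12
```

which prints (abridged):

```
group FMRs (fitted probability of judging k=0 'extended'; 0.5 = no adaptation)
  immediate  n=  6  M=0.217 (SD 0.105)  t(5)=-6.58  p(one-tailed)=0.0006  d=2.69
  sleep      n=  6  M=0.288 (SD 0.045)  t(5)=-11.61  p(one-tailed)=0.0000  d=4.74
  wake       n=  6  M=0.387 (SD 0.190)  t(5)=-1.46  p(one-tailed)=0.1026  d=0.59

factorial ANOVA on FMR (Type III):
  group                F(2,12)=2.434  p=0.1297  np2=0.289
  ...
sleep parameter correlations with FMR (Pearson, uncorrected):
  abs_S4                   r=-0.883  p=0.0197  n=6
  abs_SWS                  r=-0.816  p=0.0476  n=6
  abs_REM                  r=-0.186  p=0.7244  n=6
  ...
```

Reading it: the simulated sleep and immediate groups show FMRs well below
0.5 (strong after-effects, large d), the wake group sits nearer 0.5
(decayed after-effect), and the correlation table relates each subject's
sleep architecture and spindle/band-power measures to their FMR. Tidy
CSVs (`fits.csv`, `sleep_summary.csv`, `spindle_events.csv`,
`spindle_density.csv`, `band_power.csv`, `correlations.csv`, `anova.csv`)
plus `report.txt` and a seed/config manifest land in the output
directory; identical configurations reproduce byte-identical outputs.

The other subcommands (`simulate`, `continuum`, `psychfit`, `spindles`,
`spectra`, `sleepstats`, `correlate`, `report`) expose each stage on its
own; `somnadapt <cmd> --help` lists the parameters.

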