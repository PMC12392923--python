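# Methods

`neurocardiac` implements a response-locked neurocardiac analysis of a
mental-arithmetic stress paradigm: heart-rate (HR) dip/rebound dynamics
around the behavioral response, EEG relative band-power features, and
channel-wise random-intercept mixed-model t-maps, driven end to end by a
synthetic cohort generator with known ground truth. This note documents
the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic validation does and does not show.

## The paradigm being emulated

A cohort of 25 participants (13 female, 12 male; sex coded 1 = female,
2 = male) performs mental arithmetic in three sequential phases — control,
stress 1, stress 2 (coded 1/2/3) — of 5 runs x 15 trials each, i.e. 225
trials per participant, with a 10-s fixation baseline before each phase.
In the stress phases the allotted response time is 90% of that
participant's mean control-phase response time; timeouts are coded as
errors with the maximum time assigned as the response time. Mood is
assessed by the 16-item BMIS before and after the session (score =
positive-adjective sum minus negative-adjective sum, range -24..24) and
stress appraisal by the 16-item PASA after each phase (four 4-item
subscales; five reverse-scored items answered as 7 - x; global index =
primary minus secondary appraisal). Subscales are aggregated by item
*means* so all appraisal scores share the 1-6 item scale (sum-based
scoring is available via `aggregate="sum"`); the instrument's original
description does not fix this choice.

## Synthetic cohort generator (`synth`)

The generator is first-class, tested code: every downstream stage is
validated by recovering its planted parameters.

**Behavior.** Response times are truncated-lognormal: moment-matched
lognormal draws at the phase mean/SD — (7.0 ± 2.5, 3.7 ± 1.1,
5.1 ± 1.6) s — scaled by a per-participant lognormal factor (σ = 0.12),
with draws beyond the allotted time becoming timeouts. A positive,
right-skewed law is the standard choice for response times; only means
and SDs are constrained by the emulated study. Phase error rates
(3.1 / 14.8 / 37.8%) are *total* error probabilities: the wrong-answer
Bernoulli rate is discounted by the analytic timeout probability so the
realized totals match the targets (in stress 2 roughly half the errors
are timeouts). A learning trend (default -0.8 and -1.0 percentage points
per run in control and stress 1, centered on run 3) reproduces
practice-related improvement. The realized stress-2 mean response time
(~4.9 s) sits slightly below the nominal 5.1 s because truncation at the
allotted time removes the upper tail; this is a property of the emulated
censoring, not a calibration error.

**Questionnaires.** PASA items are generated from a latent global index
(base 0.5, phase shifts 0 / +1.0 / +1.5, participant SD 0.5, item SD
0.7) by splitting the index symmetrically into primary/secondary subscale
targets. With item noise disabled the four items of a subscale are
constructed to hit the target mean exactly (to 0.25-point resolution),
which keeps the noiseless scoring oracle exact; with noise, items are
rounded and clipped to 1-6. BMIS items shift by ±0.5 scale points
pre/post, emulating the observed mood decline.

**Heart rate.** The instantaneous HR profile is

    base(sex) + participant intercept + phase offset(t) + Σ templates + HRV noise

with female/male bases 78/70 bpm (females higher, as typically observed),
intercept SD 2.5 bpm, task-phase offsets (0, -3, -5) bpm applied inside
the task span with 4-s cubic ramps and released during inter-phase rest
(so baseline correction against the pre-phase rest recovers the offsets),
and HRV noise = white noise low-passed at 0.4 Hz, SD 1 bpm. Each response
adds a dip/rebound template: a piecewise cubic-smoothed excursion
parameterized directly by the extracted features — onset, dip magnitude
and duration, rebound magnitude and duration — with a fixed 2.5-s return
to baseline after the rebound peak. Defaults: female onset -1.2 s,
dip 4.0 bpm over 2.8 s, rebound 5.0 bpm over 3.0 s; male onset -1.6 s,
dip 3.5 bpm over 3.0 s, rebound 4.3 bpm over 3.2 s (males earlier and
longer, females larger — the sex-strategy contrast the analysis is meant
to detect). Two deliberate constraints shape these numbers:

1. *Rebound overshoot.* The rebound magnitude exceeds the dip magnitude,
   so the rebound peak lies above baseline and the subsequent return to
   baseline makes it a genuine local maximum. A template that returned to
   baseline from a below-baseline peak would have no local maximum for
   the extractor to find, leaving "rebound" ill-defined.
2. *Beat-sampling physics.* HR is observable only once per beat
   (~0.8-1 s). A reconstruction from R-R intervals (midpoint assignment +
   linear interpolation) sags below a curved profile by ≈ f''T²/6 for
   interval length T; keeping template transitions ≥ 2.8 s bounds this
   below 0.5 bpm at the simulated heart rates. Faster templates are
   representable in the profile but not in any beat-derived HR series.

Covariate effects on template parameters (`hr_feature_effects`) plant the
study's reported associations: dip magnitude grows with the centered PASA
index (+0.3 bpm/unit, both sexes) and the male dip onset advances with
PASA (-0.3 s/unit by default; the interaction-recovery experiments plant
-0.5 s/unit, the effect size they are specified to detect). R-peak times
come from integrating the profile (beat-count crossings of integers); the
ECG waveform is a stereotyped 1-mV P-QRS-T template at each R time plus
0.25-Hz baseline wander and Gaussian noise — only R timing matters
downstream, so no morphological realism is attempted.

**EEG.** Each channel of the 32-electrode 10-20 montage is a sum of
band-limited Gaussian noise over the five analysis bands with
variance shares following a base profile (D/T/A/B/G =
0.30/0.22/0.25/0.15/0.08), a per-participant random intercept (SD 0.02 on
the share scale), and planted linear effects of the centered predictors
(phase code, PASA index, run error rate). The default plant mirrors the
qualitative female stress signature — negative frontal theta slopes
(F3/Fz/F4), positive right-parietal beta slopes (P4/P8) versus phase —
plus an opposite-signed alpha modulation on P3/P4 driving the laterality
index. Pre-response analysis windows are synthesized per trial (with
0.1-s crossfades into the background so filtering sees no steps);
amplitude is calibrated to 15 µV rms, and artifact trials (default rate
0.01, matching the ~1% rejection reported for the emulated study) receive
a 180-µV slow bump so the ±100 µV rejection removes exactly the planted
trials. Determinism: one global seed; per-participant, per-modality
substreams via fixed `SeedSequence` spawn keys.

The generator does *not* emulate: EEG forward/volume conduction,
eye-blink or EMG artifact physics, ECG morphology variation, 1/f
spectral slopes beyond the five-band composition, or hormonal covariates.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under the stated statistical structure, not robustness to every
physiological confound of real recordings.

## ECG processing (`ecg`)

Zero-phase 4th-order Butterworth band-pass 0.5-60 Hz and 2nd-order 50-Hz
band-stop (forward-backward, so effective magnitude is the squared
single-pass response). QRS detection is classic Pan-Tompkins: 5-15 Hz
band-pass, five-point derivative, squaring, 150-ms moving-window
integration, adaptive dual thresholds with search-back and a 200-ms
refractory period, fiducials refined to the local maximum of the
band-passed ECG. One guard was added: a global floor of 2% of the
integrated signal's maximum, because on silent stretches the purely
adaptive threshold collapses to zero and accepts filter ringing.

R-R cleaning is two-stage: (1) intervals whose relative change versus the
previous kept interval exceeds 30% (configurable; "physiologically
implausible" is not quantified by convention) are flagged; (2) a
two-sided generalized extreme studentized deviate (GESD) test at
α = 0.05 with max outliers = 10% of beats runs on the survivors. Flagged
values are replaced by linear interpolation over interval midpoint time.
Manual inspection is replaced by flag counts in the returned series
(automation substitutes for the interactive step; counts are auditable).
HR = 60/RR is assigned at interval midpoints and linearly interpolated
directly onto the uniform 256-Hz grid — the midpoint series is piecewise
linear, so interpolating straight onto the final grid is exact for it,
and a separate native-rate grid plus anti-aliased resampling would only
add FIR edge transients. Baseline correction subtracts the mean HR of the
10-s rest preceding each phase; the per-phase correction regions
partition the whole recording (each extends to the next phase's baseline)
so trailing-gap samples inside the last trials' epochs are corrected too.

## HR dynamics (`hr_dynamics`)

Epochs span -4..+6 s around response onset; features are computed on
participant x phase *average* traces. The extractor: velocity is the
gradient of a moving-average-smoothed trace (250 ms); the dip is the
global minimum inside a -2..+2 s search window and must be a genuine
local minimum; the onset is found by walking back from the steepest
descent point through the contiguous negative-velocity run and taking the
first crossing below -0.2 bpm/s; the rebound is the first post-dip local
maximum with ≥ 0.25 bpm prominence (falling back to the first occurrence
of the post-dip maximum). Three numerical choices deserve note:

- "Near-zero change" before the onset is |v| < 1 bpm/s sustained 250 ms
  (no convention exists; both are config keys, and a missing plateau is
  noted rather than fatal).
- The onset uses a small velocity *crossing* (-0.2 bpm/s) rather than the
  raw sign change: centered smoothing spreads the descent backward by
  half the smoothing window, so a sign test is systematically ~0.13 s
  early, while the crossing is late by only ε/(peak acceleration)
  ≈ 0.02-0.09 s for the default templates.
- Segmentation (run-walk) uses a doubly-smoothed velocity and starts at
  the steepest point because beat-interval sampling leaves ~1-Hz ripple
  on averaged traces that flips velocity signs near the flat dip bottom.

At 256 Hz on exact template traces the seven features are recovered
within 0.06 s and 0.02 bpm; with per-trial HRV noise (SD 1 bpm, 75-trial
averages) the dip-magnitude bias stays well under 0.5 bpm over 50
replicates. Through the full waveform chain the additional beat-sampling
ripple bounds recovery at roughly ±0.3 s / ±0.4 bpm for 12-trial
averages — a measurement-physics limit, not an extractor artifact, which
is why the extractor's accuracy is certified on traces and the waveform
chain separately on profile reconstruction (≤ 0.5 bpm). Pointwise phase
comparisons use a paired two-sided Wilcoxon signed-rank test per
timepoint with Benjamini-Hochberg (BH) adjustment across timepoints; the
emulated study does not name its pointwise test, and the signed-rank
choice follows its stated within-group convention.

## EEG features (`eeg_features`)

Epochs span -3..-0.5 s before the response (pre-response window, clear of
stimulus-evoked components); trials with any |sample| > 100 µV are
rejected whole. Band power uses a full-epoch Hann-windowed periodogram
(0.4 Hz resolution on the 2.5-s window) with rectangular integration;
bands are half-open [low, high) on the discrete grid and the broad
denominator is [0.5, 60] Hz on the same estimate, so the five shares sum
to ≤ 1. A Welch scheme with 1-s segments was considered and rejected: its
1-Hz resolution cannot resolve the 0.5-Hz band edges (e.g. delta's
3.5-Hz upper edge), and a 2.5-s epoch admits only one 2-s segment anyway.
No EEG baseline correction is applied — relative power normalizes each
trial, and the 10-s pre-phase rests are too short to be a stable spectral
reference. Ratios are T/B and G/T on relative powers (zero denominators
flagged missing). Alpha laterality is ln(L) - ln(R) per homologous pair,
sign-flipped for right-side channels, zero on the midline (Fz/Cz/Pz/Oz);
relative power makes the index invariant to global gain. Run-level means
(the mixed models' dependent variable) are arithmetic means over a run's
surviving trials. ICA-based cleaning is out of scope: component selection
is a human-judgment step; the amplitude threshold plus a pluggable
pre-filter hook stand in its place.

## Statistics (`stats`)

The channel-wise model is `y ~ x + (1 | participant)` fitted by maximum
likelihood. The fitter profiles the variance ratio ρ = σ_u²/σ_e²: for a
single grouping factor the GLS normal equations reduce to within-group
sums, β and σ_e² solve in closed form given ρ, and only ρ is optimized
(bounded 1-D search on log ρ, with the ρ = 0 / OLS boundary checked
explicitly). Agreement with statsmodels `MixedLM(reml=False)` is verified
in the tests to ≤ 1e-4 on estimates, standard errors and log-likelihood;
the dedicated fitter runs a full 32-channel map in ~0.25 s, which keeps
the 200-replicate null calibration tractable. Degrees of freedom use the
residual method (n_obs - n_fixed_params; e.g. 125 observations and 2
fixed parameters give df = 123) and two-sided p-values come from the
t-distribution. Effect sizes: r = sign(t)·√(t²/(t²+df)) for model terms,
r = Z/√N for rank tests (N = total observations for two samples, number
of non-zero pair differences for paired tests — the "total observations"
convention is ambiguous for paired data; the choice is recorded here and
in the docstring). BH adjustment families are: all channels within one
t-map, all timepoints within one pointwise comparison, and all
feature x predictor x term cells within the HR interaction grid — family
boundaries follow the figure a table mirrors, since no finer convention
is stated. Phase enters the models as the numeric 1/2/3 code: although
described as categorical, a single per-predictor column in the emulated
heatmaps implies one slope, and the numeric coding is what a single
column can represent. HR-feature models are OLS `y ~ sex * x` per
feature x predictor (sex 1/2, so the interaction coefficient is the
male-minus-female slope difference). Rank tests use exact p-values up to
n = 25 without ties and the normal approximation with continuity and tie
corrections beyond; all-tied input returns p = 1 by convention.

## Validation experiments and problem sizes

`neurocardiac.validation` packages the recovery experiments the
acceptance suite runs:

- **ECG round trip** — a noiseless 2-participant cohort with fixed,
  widely spaced responses (14-s RTs), so successive templates do not
  overlap; overlapping dips would steepen the profile beyond what
  beat-interval sampling can represent, which is a property of cardiac
  measurement rather than of the detector. R-peak sensitivity/precision
  at ±10 ms and the max HR reconstruction error are reported.
- **Dip recovery** — extractor accuracy on exact template traces (zero
  noise) and bias over 50 noisy replicates of 75-trial averages.
- **t-map calibration/detection** — 200 null maps and 100 planted-channel
  maps at the run-feature level (25 participants x 15 runs x 32 channels,
  intercept SD 0.02, run-level noise SD 0.01 — the run-mean standard
  error observed from the waveform pipeline; planted slope 0.018 per
  phase step, the measured relative-power displacement of the generator's
  0.02 weight slope). Feature-level simulation is used because these are
  hypotheses about the statistical engine; the waveform chain contributes
  nothing to them and is certified separately.
- **Sex-interaction recovery** — 100 cohorts of template-derived features
  (extraction noise 0.15 s / 0.8 bpm / 0.2 s for timings, magnitudes,
  durations) with the -0.5 s/PASA-unit male onset plant; detection means
  the sex x PASA term on dip onset is BH-significant with the planted
  sign within the full 7 x 4 grid.
- **EEG sign recovery** — the full waveform chain (synthesis → filtering
  → epoching → rejection → periodogram → run aggregation → LME) on 20
  small cohorts (1 F + 1 M, 3 runs x 5 trials, shortened responses),
  checking the sign of the planted frontal-theta slope.

The default test suite runs in ~2 minutes and the acceptance script in
~2 minutes on one CPU; simulation sizes above were chosen to make each
experiment's Monte-Carlo error small relative to its acceptance margin at
those budgets.

## Known limitations

- The synthetic EEG has band-flat spectra within bands and no 1/f slope,
  alpha peaks, or inter-channel correlation; topographies are therefore
  meaningful only through the planted effects.
- Beat-interval sampling fundamentally limits HR feature recovery through
  the waveform chain (see above); studies needing sub-0.1-s onset
  precision from real ECG would need longer averaging or beat-domain
  modeling rather than a finer grid.
- The GESD stage assumes approximate normality of the R-R series within
  the cleaned segment; heavy-tailed rhythm disturbances (ectopy runs
  longer than the max-outlier budget) would partially survive.
- Pipeline inputs are the simulated session format (TSV + JSON); EDF
  ingestion is not provided, as no EDF writer is available to produce
  test data, and the container types make external readers easy to adapt.
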