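# Methods

`seegbench` evaluates how automated re-referencing ("data cleaning") of
stereo-EEG (SEEG) recordings affects gesture decoding, end to end, on
synthetic data whose generative structure is fully known. This note
documents the models, the defaults and why they were chosen, the numerical
choices, and what passing tests do and do not establish.

## The experiment being emulated

A cued three-gesture task (scissor / fist / thumb): each 10-s trial is 4 s
rest, a 1-s cue, then 5 s of repeated movement; 20 trials per gesture (60
per subject). SEEG is recorded from depth electrodes (shafts of contacts at
3.5-mm spacing) at 1000 or 2000 Hz together with a surface-EMG pair, whose
burst marks the actual movement onset, on average 0.72 s (SD 0.38 s) after
the gesture picture. Signals are aligned to that onset; analysis windows
are baseline = [-4, -2) s and task = [0, 4) s around it (half-open, time 0
at the onset sample).

## Synthetic subject model

Each channel is a sum of layered components, all band-limited to
0.5–400 Hz:

* **private activity** — per-channel pink (1/f-amplitude) noise,
  SD `sd_channel` = 5 µV: the local population signal;
* **global common mode** — one pink series shared by all channels,
  SD `sd_common` = 50 µV: reference/amplifier noise;
* **within-shaft field** — per-shaft pink series correlated AR(1)-style
  along the contacts (neighbor correlation `shaft_spatial_rho` = 0.95),
  SD `sd_shaft` = 15 µV: locally shared fields that decay with distance
  along the shaft;
* **line noise** — 50 Hz plus 3 harmonics (base amplitude 4 µV, clean
  channels jittered in [0.8, 0.95] of it); planted "bad" channels carry
  exactly `line_noise_bad_multiplier` (30) times the base amplitude, so
  their 50-Hz RMS always exceeds the multiplier times the median channel's;
* **EMG pair** — unit Gaussian noise plus a 55–145 Hz burst (amplitude 8)
  from the true onset to the end of the task stage, coupled with opposite
  sign into the two electrodes.

**Electrode coupling.** The shared components are multiplied per channel by
`alpha_c(t) = 1 + static_c + drift_c(t)`: a static profile (shaft offset
SD 0.2, a linear gradient of span 0.3 along each shaft, channel jitter
SD 0.03) plus a slow drift interpolated between knots every 2.5 s
(shaft-level SD 0.15, channel-level SD 0.05). This models heterogeneous
contact impedance and its drift. It is what makes re-referencing matter
*for decoding*: if shared noise were identically coupled everywhere, a
linear classifier on band-power features cancels it across channels by
itself and raw signals decode as well as cleaned ones. With spatially
smooth, slowly drifting coupling, amplitude-domain local references
(Laplacian, bipolar) still remove the shared field almost exactly (their
residual is quadratic in the local coupling differences), while a classifier
operating on powers cannot track the drift.

**Task effect.** On a sparse set of informative channels (default 3, chosen
never adjacent so each carries its own modulation), the *private* in-band
component is scaled during [onset, end of task) so that its band power is
multiplied by a class-specific effect size, with 50-ms cosine ramps. Bands:
delta (1–4 Hz) and high gamma (70–150 Hz). The effect deliberately touches
only the private component — task modulation is a local population effect,
not a modulation of shared noise. Defaults (free parameters; nothing in the
emulated protocol pins them): delta gains {1.6, 2.5, 4.0} and high-gamma
gains {2.0, 3.2, 5.0} for the three gestures. These were set once, at
design time, to place the best cleaning methods around 70% window-level
accuracy and raw around 40% on the default cohort — far from both chance
and ceiling, so the ranking is resolvable.

The recording is the concatenation of the 60 trials in randomized class
order, plus a 2-s tail so the [-4, 4) s window of a late onset always fits.
Everything is driven by one `numpy` generator seeded from `SimConfig.seed`.

**Calibration caveat (delta).** The planted effect size is verified as the
task/rest in-band power ratio. For high gamma this recovers the configured
gain per class to within 15% at 20 trials. A 1–4 Hz band measured on ~3-s
windows has only ~5 effective degrees of freedom per trial, so per-class
delta ratios scatter ±20% under any estimator; the test pools the three
classes. A consistent ≈ −9% bias remains from gating sidebands and the
measurement filter's edge response; it is far below the factor-2+ spacing
of the class gains and does not affect the comparisons.

## Preprocessing

* Resampling to 1000 Hz by polyphase filtering (`scipy.signal.resample_poly`);
  only downsampling is supported.
* **Line-noise channel rejection**: each channel through a second-order peak
  filter at 50 Hz (−3 dB bandwidth 2 Hz); metric = mean |filtered|;
  threshold = median + 10 × mean absolute deviation of the pooled absolute
  filtered samples of all channels (a `per_channel` pooling mode over the
  channel summaries is selectable — the default is the literal reading of
  "concatenate, then median and MAD"). Channels strictly above threshold are
  excluded downstream. Note the pooled MAD is inflated when the montage is
  tiny; the detector is calibrated for realistic channel counts (tests use
  40 channels).
* **Comb notch**: cascaded second-order IIR notches at 50 k Hz, k = 1..8,
  with Q scaled by the harmonic so every notch has the same 50/70 ≈ 0.7 Hz
  absolute bandwidth. A fixed-Q cascade makes the 400-Hz notch 11 Hz wide
  and loses several percent of broadband power per pass. Even so, perfect
  stop-band idempotence is unattainable with IIR notches: a second pass
  always shaves skirt power; the achieved figure is <1% RMS change on white
  noise (≈0.1% on 1/f signals).
* **Band-pass**: 0.5–400 Hz, fourth-order Butterworth. All filters are
  applied forward–backward (zero phase) so onset timing is not shifted.
* **EMG onset**: difference of the two 55–145 Hz (sixth-order Butterworth)
  filtered channels. Candidate A = first post-cue crossing of the smoothed
  Hilbert envelope above rest-mean + 3·SD (rest window [−4, −1] s before
  the cue; 100-ms *trailing* moving average — a centered one biases onsets
  half a window early); candidate B = first crossing of |EMG| above 1.5 ×
  its task-stage mean; onset = the earlier. Trials without a crossing are
  flagged and dropped.
* **Epoching**: [−4, 4) s around each detected onset; windows crossing the
  recording edge are dropped, never padded.

## Re-referencing operators

All six schemes are fixed linear maps in channel space, built as matrices
(`reref_matrix`) and applied to epochs or continuous data — linearity and
exact common-mode annulment are structural. Conventions:

* contact 1 is the deepest; bipolar is deep minus superficial, the most
  superficial contact of each shaft yields no output channel, and the
  derived channel records the pair and inherits the deep contact's
  position;
* Laplacian interior contacts subtract the mean of their two shaft
  neighbors; end contacts are referenced to their single neighbor by
  default (`drop_ends` is selectable); a two-contact shaft degrades to
  mutual bipolar;
* excluded (bad) channels are removed before any averaging and break
  adjacency — contacts across a gap are never paired;
* gray/white-matter reference (GWR) averages gray and white channels
  separately; `unknown`-tissue contacts are excluded from the class
  averages and referenced to the global labeled average, with a warning;
* single-contact shafts cannot be shaft-referenced (ESR) and are excluded
  with a warning.

## Decoding

Task windows of 500 ms, hopped by 250 ms: 15 per trial (7 in the baseline).
Each window is fit with an AR(40) model (Burg) and the power spectral
density is evaluated on an fs/4096 grid; the feature per band is the mean
PSD inside each of the nine sub-bands (1–4, 4–8, 8–13, 13–30, 60–75, 75–95,
105–125, 125–145, 155–195 Hz). Features are z-scored per channel × band
against the mean and SD of all baseline windows of all trials (features
with zero baseline variance carry no information and are zeroed with a
warning).

The Burg recursion is vectorized across windows and runs in float32 by
default (5× faster; coefficient differences ~1e-7 against the float64
single-signal reference, far below estimation noise). A window of 500
samples supports order 40 comfortably; at much shorter windows the fit
overfits and inflates the lowest bands — the white-noise flatness test
documents the supported regime.

Forward channel selection is greedy: starting empty, each step adds the
channel maximizing the trial-based 10-fold cross-validated accuracy of the
growing set (ties broken by lowest channel index); the search stops when the
running peak has not been exceeded for three consecutive additions and the
peak set is returned. The classifier is a linear-kernel SVM (`LinearSVC`,
C = 1, no tuning; liblinear is ~35× faster than libsvm here and the choice
is immaterial for accuracy comparisons). Cross-validation is stratified at
the trial level (60 trials → 10 folds of 6, two per gesture; all windows of
a trial share a fold) and every feature dimension is re-normalized using
training-fold statistics only. Decoding accuracy (DA) is window-level
accuracy averaged over folds; a trial-level majority vote is available.
Baseline z-scoring uses baseline statistics of all trials, and channel
selection runs on all trials before the final CV — this mirrors the usual
offline procedure; whether that constitutes leakage cannot be settled here,
so both behaviors are implemented: a fully nested mode
(``decode_DA_nested``, ``--nested`` on the CLI) repeats the selection inside
each outer training fold so neither selection nor renormalization ever sees
the test trials, and the shuffled-label null under nested selection decodes
at chance (the no-leakage guarantee the tests enforce).

Single-band decoding accuracy (SDA) repeats the final classification with
one band's features only, on the channel set selected for the full-band DA;
the high-gamma band keeps its five sub-bins as separate features.

## Comparison statistics

* **TFD (time–frequency difference)**: per channel, a Hanning-tapered
  short-time FFT (500-ms window, 50-ms hop, 0.5-Hz zero-padded grid,
  0–195 Hz) per trial; each trial's log spectrogram is referenced to its own
  baseline-period mean per frequency (otherwise any reference change shifts
  absolute power everywhere and the map saturates in the baseline too);
  then a trial-wise paired t-test per (time, frequency) cell between the two
  methods, Bonferroni correction by the number of channels in the union of
  the two methods' selected sets (correction over the time–frequency grid
  is selectable), and −log10(p) averaged over those channels. Significance
  threshold −log10(0.05) ≈ 1.301. Zero-variance cells get p = 1. Bipolar
  channels are matched to other schemes' channels through their deep
  contact.
* **Task relevance**: per channel and band, sixth-order Butterworth
  band-pass → squared Hilbert magnitude → mean per trial over baseline and
  task windows → Spearman correlation of the 2n power values against their
  0/1 labels → 1000 label permutations. The default p is parametric from a
  Gaussian fit to the surrogate r's, one-sided (task > baseline), which
  avoids the 1/1001 floor; the empirical percentile is selectable.
  Bonferroni by the number of channels tested.
* **Relation between the two**: ordinary least squares of band-averaged
  task-period TFD on task relevance across channels, with the F-test
  (F = MSR/MSE, df (1, n−2)) and R². Zero x-variance flags the fit invalid
  rather than raising.
* **Group comparisons**: two-sided paired t-tests across subjects, optional
  Bonferroni over the five bands; identical vectors return p = 1 by
  convention.

## The default experiment and problem sizes

`default_cohort(seed)` builds 8 subjects (three at 1000 Hz, five at
2000 Hz), 60 trials each, with one planted extreme line-noise channel and
3 informative channels per subject, on a 2-shaft × 6-contact montage. The
montage is deliberately much smaller than clinical implants (~10 shafts of
8–16 contacts): it keeps the full 6-scheme × 8-subject comparison, with
forward selection and the AR spectra, at desk scale, and none of the
compared quantities depend on montage size beyond the number of candidate
channels. The generator accepts clinical-scale montages unchanged.

At design time this configuration ranked the schemes
raw ≪ CAR ≈ GWR < ESR < bipolar ≈ Laplacian, i.e. every cleaning method
above raw with Laplacian (and bipolar) on top — the qualitative structure
the pipeline is built to detect and the acceptance tests assert.

## What the synthetic tests do and do not show

Passing tests establish that every stage does what it claims on data whose
ground truth is known, that the detectors are calibrated (type-I error at
nominal level, sensitivity 1 at the planted contrast), and that the
pipeline ranks referencing schemes correctly *under this noise model*. They
do not establish clinical performance: real SEEG has non-stationary
artifacts, epileptiform transients, behaviorally variable EMG, correlated
task effects across neighboring contacts, and tissue labels with errors —
none of which are modeled. Absolute accuracies on synthetic data are
meaningless except relative to each other.

## Known limitations

* The coupling model (smooth static profile + slow drift) is the simplest
  structure that makes re-referencing consequential; real impedance drift
  is not Gaussian-interpolated.
* Laplacian/bipolar superiority depends on the within-shaft noise
  correlation decaying along the shaft (`shaft_spatial_rho` < 1); with
  perfectly uniform shaft noise, mean-removal references match them.
* EDF export quantizes to 16 bits against a per-channel physical range and
  zero-pads to whole-second records.
* The permutation p-value's Gaussian approximation is accurate in the bulk
  but not in the extreme tail (< 1e-6); empirical mode is available where
  exactness matters more than resolution.
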