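# Methods

`apneagram` screens for sleep apnea–hypopnea syndrome from a single
nocturnal ECG lead (DII by convention). This note documents the model each
stage implements, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices a maintainer would want spelled out.

## Processing model

The pipeline is a chain of seven stages; each consumes the previous
stage's output and a shared `RunConfig`.

**1. Denoising.** The record is resampled to 250 Hz (polyphase), a running
median of 0.2 s is subtracted as the baseline estimate (an optional second
0.6 s stage exists for strong wander, off by default), and mains
interference is removed with a zero-phase second-order IIR notch
(50 Hz default, Q = 30). The 0.2 s median leaves QRS complexes intact —
the window is short enough that the median inside it tracks the isoline —
while baseline wander (≈ 0.3 Hz) is followed and removed.

**2. Quality masking.** Sliding 5 s windows (1 s stride) are scored by
Pearson (non-excess) sample kurtosis. A window fails when kurtosis < 3.5
(statistically indistinguishable from Gaussian noise: at 5 s × 250 Hz the
99th percentile of Gaussian kurtosis is ≈ 3.4) or > 80 (impulsive
artifact), when its amplitude range is < 0.05 mV (flat line), or when it
contains a ≥ 0.5 s run pinned at one value (saturated or unhooked
electrode). A sample is low-quality when *any* covering window fails;
sliding windows with sample-level OR keep the detected zones aligned with
artifact boundaries regardless of phase, which a non-overlapping tiling
cannot do. Both kurtosis bounds are configurable: published kurtosis-based
ECG quality indices disagree on whether low or high kurtosis marks noise,
so a two-sided band covers both readings.

**3. Beat detection and rhythm screening.** QRS complexes are located by
greedy matching pursuit over a dictionary of unit-norm atoms (Gaussian,
first-derivative and Mexican-hat shapes; widths 0.04–0.30 s). Pursuit runs
on a 5–30 Hz band-passed copy of the denoised signal: in that band P and T
waves are strongly attenuated, so a 10×-reduced R wave inside a deep apnea
still outscores them. The pursuit is correlation-domain: initial
correlations are FFT-batched per 10 s window, each selection updates the
correlation surface through a precomputed atom-pair Gram table, and the
residual energy shrinks by the squared coefficient — no residual waveform
is formed. Stopping: residual below 0.5 % of window energy, 30 atoms per
10 s, or coefficient under 3 robust sigmas of the correlation surface
(1.4826 × median absolute correlation). Selections closer than the 0.2 s
refractory keep the stronger coefficient; wide-atom selections
(> 0.16 s) must additionally reach half the median narrow-selection
coefficient, which rejects smooth P/T residues while keeping tall, wide
ectopic beats. R times and amplitudes are then refined on the broadband
denoised waveform (extremum within ±40 ms); onset/offset come from the
selected atom's support.

Ectopic beats are flagged by three criteria, OR-combined: (a) QRS width
> 200 ms, (b) RR interval outside 0.6–1.2 s, (c) height above 1.5× the
mean of the ten previous complexes (a literal "higher than the mean"
reading would flag roughly half of all beats, so a configurable multiplier
is used; ties at the boundary are compliant). Time is excised (±5 s
guard) only around beats flagged for *width* — a morphological aberration
of the beat itself. Beats flagged for rhythm or relative height are
dropped from the EDR stream but do not excise time: in single-lead
screening those flags fire densely inside deep respiratory events, where
amplitude collapse and missed beats mimic ectopy, and excising them would
blind the event detector to precisely the epochs it must examine.

A record must retain ≥ 4 cumulative hours of good-quality, regular-rhythm
signal (closed boundary: exactly 4.0 h passes); otherwise the report
carries no AHI and a grey reliability label with the reason.

QRS morphology is classified per record: for each normal beat the largest
positive (P) and deepest negative (N) deflections inside the QRS support
give ρ = min/max; the record is *biphasic* when median ρ ≥ 0.5, else
*monophasic* (≥ 50 non-flagged beats required, otherwise unknown).

**4. EDR extraction.** Three ECG-derived-respiration series are built from
non-flagged beats inside analyzable segments and resampled to a uniform
4 Hz grid: the instantaneous heart period (RR tachogram), the R-wave
amplitude, and the signed QRS area as a morphology surrogate. Cubic
splines (natural boundary) interpolate within a segment, falling back to
linear interpolation when a segment holds fewer than four beats; nothing
is extrapolated beyond a segment's first/last beat, and a shared gap mask
marks every undefined sample.

**5. Abnormal-breathing detection.** Sliding 60 s windows (10 s step,
windows > 25 % masked are discarded) are summarized by seven features:
RWA mean-reduction ratio against the record median, RWA variance, mean and
range of the heart-period series, its 0.01–0.04 Hz (cyclic-variation) band
power, the morphology-series reduction ratio, and the lag-0 HRV–RWA
correlation. The two reduction ratios count masked samples as zero
amplitude — inside a deep event the R wave is undetectable, and that
dropout *is* the reduction. Features are z-scored over the record and
clustered (Ward linkage, k = 2); a silhouette below 0.1 declares the
record event-free. The cluster with the deeper amplitude reduction is the
abnormal one. Because window abnormality is a continuum (event overlap ×
depth) whose extreme tail is what Ward isolates, the abnormal label is
then expanded to every window lying more than 3 robust SDs (per-feature
MAD of the normal members, floored at 0.05) from the normal-cluster
centroid. Runs of abnormal windows, dilated by 240 s, become candidate
regions — deliberately generous region proposals, because the next stage
carries the precision.

**6. Confirmation and typing.** For each candidate, a reference amplitude
B is the larger of the 60 s-flank median and the 80th percentile over the
candidate plus flanks (flank medians alone are dragged down when
neighbouring events crowd the flanks). The smoothed RWA series (2.25 s
running median) gives a depth series 1 − RWA/B. Masked runs of 5–90 s are
scored as full depth when a defined neighbour on at least one side already
shows depth ≥ 0.1 — the onset decline is gradual while the arousal
recovery is abrupt, so only one informative edge can be expected; masked
runs bordered by normal amplitude on both sides (electrode artifacts amid
normal breathing) stay undefined. Every maximal run of depth > 0.3
lasting ≥ 10 s becomes one event (masked gaps ≤ 10 s inside a run are
bridged); its median depth decides the class — apnea at depth ≥ 0.9,
hypopnea at 0.3–0.9 — mirroring the ≥ 90 %/≥ 30 % airflow-reduction rules
of manual scoring on the amplitude surrogate, with the apnea boundary
closed. Confirmed apneas are typed by respiratory effort: if 0.15–0.5 Hz
RWA oscillation power inside the event is ≥ 25 % of the flank power the
apnea is obstructive (effort persists against the closed airway), else
central; hypopneas are never typed. Events ≥ 50 % inside confirmed wake
epochs are discarded; unscored epochs — typically the dropout inside deep
events — do not disqualify an event.

**7. Staging, AHI and reliability.** 30 s epochs of the EDR grid are
summarized (mean heart rate, heart-period SD, RWA variance and mean) and
classified wake/sleep by a logistic regression trained on synthetic
labeled studies; an MLP head is available as a nonlinear variant. The
stager is a training harness, not frozen clinical weights. Epochs > 50 %
masked are unscored; predictions are median-smoothed over 5 epochs;
TST = 30 s × (number of sleep epochs). AHI = (apneas + hypopneas)/TST.
Severity uses left-closed classes (none < 5 ≤ mild < 15 ≤ moderate < 30 ≤
severe); for AHI ≥ 15 the syndrome is central when central apneas exceed
half of all events, obstructive otherwise (ratio exactly 0.5 is
obstructive). The reliability index combines (i) the percentage of
estimated sleep time inside analyzable segments and (ii) a relevance
score: each event's confidence is 1/(1+d), d being the standardized
Euclidean distance of its windows to the abnormal-cluster centroid divided
by the feature count (scaled so a window matching the cluster within ~1 SD
per feature maps to ≈ 0.7); relevance is 100 × the mean confidence, or the
normal-cluster tightness for event-free records. The traffic light is
grey when either axis is below 50 %, green when relevance ≥ 70 % with at
least half the sleep analyzed, orange between — the minimal monotone
mapping consistent with the two-axis table; the formula is intentionally
simple and strictly decreases with injected noise.

## Agreement statistics

For paired AHI lists (reference minus estimate): bias b = mean difference,
σ = sample SD (N−1 denominator, standard Bland–Altman practice), limits of
agreement b ± 1.96 σ. Threshold classification at 15 /h (left-closed on
both axes) yields Se, Sp, PPV, NPV, Acc and F1 = 2·PPV·Se/(PPV+Se); a
metric with a vanishing denominator is reported as undefined, never as
zero.

## The synthetic generator

`synth.generate_study` emulates, with exact ground truth: sinus rhythm at
70 bpm with ±4 % respiratory sinus arrhythmia (0.22 Hz) and per-beat
jitter; a wake/sleep architecture on 30 s epochs (15 min initial and
10 min final wake, two awakenings, wake = +15 bpm with doubled
variability); apnea/hypopnea events placed only in sleep, ≥ 20 s apart,
15–45 s long, with the cyclic-variation pattern (linear RR lengthening to
+20 % across the event, −10 % for 5 s after it) and an R-amplitude
reduction of 0.90–0.98 (apneas) or 0.35–0.85 (hypopneas) with 2 s edge
ramps; persisting (×1.3) versus suppressed (×0.1) respiratory-band
amplitude oscillation for obstructive versus central apneas; wide
(0.24 s), tall (1.6× the local mean), premature ectopic beats; and
channel artifacts — Gaussian noise at a configured SNR (15 dB default),
50 Hz mains (0.05 mV), 0.3 Hz wander (0.15 mV), two saturation/detachment
segments and one 60 s matched-variance noise burst per night. Waveforms
are sums of Gaussian PQRST atoms (QRS constants calibrated so the 5 %
threshold-crossing width matches the configured width within ~5 ms),
rendered at 400 Hz so the resampling stage is always exercised.

At the generator's apnea depths the R wave drops to ≈ 0.02–0.1 mV, below
the 15 dB noise floor: roughly half the in-event beats are undetectable
*by construction*. Beat-level sensitivity targets (≥ 0.98) therefore hold
on event-free signal; inside deep events the pipeline reads the dropout
itself as evidence, as described above.

Not emulated: real QRS morphology variability between subjects,
atrial/ventricular arrhythmia other than isolated ectopy, desaturation or
arousal physiology (no SpO₂/EEG), position or movement effects, and the
correlation structure of real electrode noise. Passing the synthetic
suites therefore demonstrates the pipeline's mechanics — masking,
detection, typing, staging, scoring, agreement — under the stated signal
model, not clinical performance.

## Validation harness and problem sizes

`validate.run_cohort` screens generated cohorts end to end. The standard
cohort is 20 six-hour studies at 15 dB SNR, obstructive-apnea-dominant
(20 % hypopneas, 10 % of apneas central), truth AHI evenly spanning
2.5–47.5 /h — a screening-clinic-like severity spread; artifact-rejection
checks use ten half-hour records with 12 ectopics/h. The wake/sleep
harness trains on two 3 h synthetic studies built directly from the truth
beat stream.

## Known limitations

* Severity boundaries make AHI errors near 15 or 30 /h flip the class even
  when the AHI error is small.
* TST is systematically slightly underestimated at high AHI because
  unscored (gap-dominated) epochs inside dense event clusters are excluded
  from TST; this mirrors the underestimation the clinical comparison
  reports and partially offsets event undercounting in the AHI.
* Shallow hypopneas (true depth ≈ 0.35) sit at the 0.3 detection boundary
  and are missed more often than apneas — the same difficulty ordering the
  clinical study describes.
* The relevance scale is meaningful relatively (noise-monotone), not as a
  calibrated probability.
* EDF files are read (via `mne`) but not written; WFDB support is a
  minimal single-channel format-16 codec.
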