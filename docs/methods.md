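# Methods

This note records the models, parameter choices and numerical
conventions behind each stage, the design decisions that were
genuinely open, and what the synthetic-data studies do and do not
establish about real recordings.

## Study design assumed throughout

Two groups of cross-sex dyads — long-married elderly couples (default
17) and unacquainted controls (default 18) — perform a competitive
button-pressing task: rest (30 s), block 1 (20 trials), rest (30 s),
block 2 (20 trials), rest (30 s).  Each trial is a cue of uniform
0.6–1.5 s, a go signal with a 1.5 s response window, 4 s of feedback
and a 2 s blank; a block therefore lasts ≈160–170 s and a session
≈430 s.  Each participant wears 23 channels (1–4 left TPJ probe with
channel 3 over the left middle temporal cortex, 5–8 right TPJ probe
with channel 6 over the right TPJ, 9–23 prefrontal), recorded at
760/830 nm, 7.81 Hz, 3 cm source–detector separation.  Ages are drawn
from truncated normals: couples 67.44 ± 5.15 in [62, 78], controls
65.94 ± 5.05 in [58, 80] years.

## Synthetic data generator

The generator is the package's ground truth; every statistical stage
is validated against it.

**Behavior.** Member 1's RT is N(450, 80²) ms, floored at 150 ms.  The
member difference on each trial is a random-sign half-normal whose
expected magnitude equals the dyad's DRT target; targets default to
87.02/96.90 ms (couple, blocks 1/2) and 73.21/103.26 ms (control),
jittered multiplicatively per dyad (sd 25 %, shared across blocks).  A
small fraction (0.8 %) of RTs is replaced by uniform 1550–2500 ms
outliers.  These settings give a group × block interaction detection
rate of ≈0.65–0.7 at n = 17/18 and a clearly significant control
simple effect, with the couples' 9.9 ms shift usually non-significant.
The within-dyad trial-level spread implied by the half-normal model is
the dominant noise source; block-level means then have sd ≈ 16 ms, so
between-dyad SDs of DRT come out somewhat below those of real elderly
samples — a deliberate trade so the default cohort has usable power at
these sample sizes.

**Hemodynamics.** HbO (µM) per channel is the sum of: a per-participant
global systemic process (stochastic narrow-band oscillators — Mayer
≈0.10 Hz, amplitude 0.08; respiration 0.25 Hz, 0.05; cardiac 1.2 Hz,
0.04; fractional bandwidth 0.5 — plus low-pass drift, 0.10) mixed into
every channel with gain U(0.6, 1.4); independent white noise
(sd 0.03) and per-channel drift (0.02); an event-locked double-gamma
response (peak 6 s, undershoot 16 s) at the go onsets with amplitude
0.02 × U(0.5, 1.5); and Poisson motion artifacts (0.5 events/min per
channel, half single-sample spikes of ±0.5, half baseline steps of
sd 0.2).  HbR is −0.33·HbO plus small noise.  The oscillators are
*stochastic* (band-passed noise), not sinusoids: two independent pure
tones at the same frequency are indistinguishable from phase-locked
ones over any finite smoothing window, so sinusoidal physiology would
fabricate inter-brain coherence.

**Inter-brain coupling.** A single unit-variance Gaussian process
band-limited to 0.11–0.14 Hz (4th-order Butterworth, forward-backward)
is added to male channel 3 and female channel 6 during task blocks,
scaled per (group, block): couple 0.025/0.045 µM, control
0.040/0.018 µM.  These amplitudes were calibrated once against the
generator→WTC loop so that the group × block interaction at the
coupled pair is reliably detectable at n = 17/18 and the band-z means
reproduce the published ordering (couples rise across blocks, controls
fall); the absolute z level is higher than published values because z
here is arctanh(√R²) (see below).  A per-block lag may be configured:
lag > 0 delays the female component (male leads).

**Forward model.** HbO/HbR are projected to dual-wavelength intensity
via OD_λ = (ε_HbO,λ·HbO + ε_HbR,λ·HbR)·10⁻⁶·d·DPF_λ and
I = I₀·exp(−OD), with the standard compiled extinction coefficients
(760 nm: 1486.59/3843.71; 830 nm: 2321.40/1791.73 cm⁻¹ M⁻¹), d = 3 cm,
DPF = 6.0 at both wavelengths, and random per-channel I₀.  The
preprocessing module inverts exactly this relation, closing a
machine-precision test loop.  A fast path emits HbO directly at the
1 Hz analysis rate for simulation studies.

**What the generator does not emulate.** Optode-position variability,
wavelength-dependent DPF error, serially correlated motion (artifacts
are i.i.d. events), spatial correlation structure beyond one global
component, non-stationary physiology, and any real neurovascular
response model.  Passing tests establish that the *estimators* recover
the construction; they cannot certify performance on real data with
richer noise.

## Preprocessing

Order fixed as: channel CV screening → optical density → wavelet
motion correction → PCA global filtering → downsample → Beer–Lambert.
The PCA filter runs on optical density, before concentration
conversion.

* **CV screening.** CV = 100·sd/mean per channel and wavelength on raw
  intensity; a channel is bad if CV > 7.5 % (strict) at either
  wavelength; a participant fails if the bad fraction exceeds 30 %
  (strict); a dyad is dropped if either member fails.  Whether CV
  should pool wavelengths is unspecified in the underlying method;
  worst-wavelength is the conservative choice.
* **Motion correction.** db5 discrete wavelet decomposition, 4 levels,
  symmetric extension; detail coefficients outside median ± 1.5·IQR per
  level are zeroed.  Boundary coefficients (one filter length at each
  end of every level) are exempt: symmetric-extension kinks otherwise
  get flagged and their removal distorts the series ends by several
  percent.  Family, level count and fence are configurable; the cited
  method fixes none of them.
* **PCA.** Per participant and wavelength, the time-demeaned
  channels × time matrix loses its smallest leading set of principal
  components with cumulative explained variance ≥ 0.80.  With few
  channels this removes part of any single-channel signal as well —
  simulation studies on reduced montages accept that attenuation.
* **Downsampling.** Zero-phase 8th-order Butterworth at 0.45 × target
  rate, then interpolation onto the uniform 1 Hz grid of length
  round(n·f_out/f_in).
* **Beer–Lambert.** Exact 2 × 2 solve per channel and sample, using the
  same constants table as the forward model (config-overridable).

## Wavelet coherence and the IBS statistics

Analytic Morlet, ω₀ = 6, 12 voices per octave, scales covering
0.01–0.5 Hz (the analysis rate is 1 Hz, so the upper edge is the
Nyquist frequency; scanning above it is undefined).  Near the Nyquist
the wavelet's spectral window is truncated, which makes the implied
time kernel padding-sensitive at the 10⁻² level; this affects nothing
the pipeline averages but restricts exact cross-implementation
comparisons to frequencies below ≈0.22 Hz.

Smoothing: per scale, a unit-sum Gaussian in time with σ = s seconds;
across scales, a boxcar of ⌊0.6/(2·dj)⌋ voices each side.  With these
choices the null (independent inputs, 300 samples) in-band mean
coherence is ≈0.34 over the COI-valid region.  The cone of influence
uses the e-folding time √2·s; COI-contaminated points are excluded
from every segment average — without this the 30 s rest baselines are
dominated by edge artifacts at low frequencies.

Fisher z = arctanh(√R̄²) of the time-averaged squared coherence
(switchable to arctanh(R̄²)).  Segment "rest" pools all three rest
periods (≈90 s), "task" both blocks.

**Band selection.** Per frequency and pair, a paired t of z(task) −
z(rest) across dyads; BH-FDR at q = 0.005 over all frequency × pair
tests; the selected band is the contiguous run of frequencies with at
least one significant pair (ties between runs broken by total
significant-test count), reported rounded to 2 decimals.  Frequencies
where any dyad's segment is fully COI-excluded are skipped.  Whether
the original procedure tested each scale independently or pooled bands
is not documented; the per-scale scan is the finer-grained choice.

**Interaction scan.** The mixed ANCOVA (below) of band-z per
dyad × block at each pair; BH-FDR at q = 0.05 across pairs; the
pre-correction hit list (p < 0.005) feeds classification.

**Permutation test.** Males and females are re-paired uniformly at
random *within group* (preserving group sizes and one-male-one-female
composition); the band z per block and the interaction F are
recomputed per iteration; p = (1 + #{F_null ≥ F_obs})/(n + 1).
Cross-member coherence for arbitrary pairings is cached per
(male, female) combination, so 1000 iterations cost little more than
the ≈600 distinct combinations.  Recordings differ by a few samples
(random cue durations), so all series are truncated to the cohort
minimum before recombination — this clips only the tail of the final
rest.  One genuine subtlety: shared trial timing induces task-locked
inter-brain coherence in real pairings that recombined pairings lack
(the trial period ≈8.5 s sits at ≈0.117 Hz, inside the band), so the
recombination null is conservative in a task-evoked-response-rich
cohort; calibration studies that require exact uniformity therefore
switch the event-locked response off along with the coupling.

**Time-lag scan.** The male series is shifted by ±2…10 s (positive =
male series advanced, i.e. male leads; the generator's lag > 0 — female
delayed — is compensated at negative scan lags); the non-overlapping
ends are truncated and the interaction F recomputed per lag.  For
narrow-band coupling the coherence magnitude is insensitive to phase,
so the interaction F localizes lag poorly; the scan additionally
reports the mean band z per block, which decays with |lag| through
envelope decorrelation and is the informative lag diagnostic.

## Statistics engine

The mixed two-level-within ANCOVA uses the exact difference-score GLM:
with covariates mean-centred and the group effect-coded ±1, the within
main effect is the intercept test and the group × block interaction
the group test in the OLS of (block2 − block1); the between effect is
the group test in the OLS of the dyad means.  On balanced
covariate-free designs this reproduces classical mixed-ANOVA F ratios
exactly (verified against an independent sums-of-squares oracle and
pingouin).  Partial η² = SS_effect/(SS_effect + SS_error).  Degenerate
inputs follow fixed conventions: zero variance with zero effect gives
F = 0 (t = 0, p = 1); zero variance with a nonzero effect gives an
infinite statistic flagged as degenerate with p → 0.  Collinearity is
rejected at design condition number 10¹⁰.  The fully-within 2 × 2
repeated-measures ANOVA is computed from per-unit contrast scores
(F(1, n−1) = t²).  BH-FDR is the step-up procedure with ≤ thresholds
and monotone adjusted p.

## Granger causality

Least-squares VAR with intercept; BIC = n·ln det(Σ̂) + k·ln n with
k = dim²·order + dim, evaluated on a common effective sample
(observations from max_order on), ties to the smaller order; the
cohort-level order is the modal per-dyad-per-block BIC choice.
gc = ln(σ²_restricted/σ²_full) with maximum-likelihood variances; with
two series the pairwise *conditional* measure reduces to ordinary
bivariate GC — no conditioning set exists and none is invented.  GC
runs per block on the broadband preprocessed HbO (not band-filtered):
the anti-alias filtering at 1 Hz leaves strongly autocorrelated
series, so the empirical BIC order on generator output is typically
5–7 even though order-2 recovery on true VAR(2) data is ≥ 90 %; the
published choice of order 2 reflects their data, not a property of the
selector.

## Classification

Euclidean KNN with leave-one-out CV; features standardized with
training-fold statistics only (the held-out dyad never contributes its
mean/sd); distance ties break toward the smaller dyad index; vote ties
cannot occur (odd k, binary labels).  The headline number is the mean
LOO accuracy over odd k = 1…31, with the fraction of k values
individually above the majority-class rate reported alongside.  The
label-permutation null shuffles labels (class counts preserved) and
reuses the label-independent neighbour orders, so 10,000 iterations
are cheap; p uses the add-one convention.  Feature selection (the
pre-correction hit list) is computed on the full cohort before CV —
the optimistic bias this implies is inherited from the procedure being
reimplemented and is documented rather than silently fixed.

## Problem sizes in the test suite

Simulation suites run at reduced scale, chosen as the smallest designs
that make each property statistically decisive: band-recovery uses
3-channel montages with direct-HbO generation at 1 Hz, 30-dyad cohorts
and 50 seeds, with a strong uniform coupling amplitude (0.08 µM) as
the detectable ground truth (the default group × block amplitudes are
sized for the interaction contrast, not for single-seed band detection
on a tiny montage); permutation calibration uses 16-dyad cohorts, 200
iterations and 200 seeds; the end-to-end orchestration test runs 6 + 6
dyads on the full montage with reduced iteration counts.  The
acceptance script is the full-scale run (17 + 18 dyads, 23 channels,
raw-intensity path, 1000 permutation and 10,000 classification-null
iterations).

## Known limitations

* The CSV bundle and SNIRF layouts are this package's conventions; no
  vendor raw formats are read.
* With ≤ 3 channels the PCA global filter redistributes a
  single-channel signal across the montage, so reduced-montage
  simulations lose spatial specificity (full-montage runs do not).
* The band-selection FDR at q = 0.005 needs ≥ ~15 dyads per group to
  be reliable under realistic coupling strengths; small smoke cohorts
  legitimately return an empty band, which the pipeline reports as a
  hard stop.
* Coherence-based lag estimation is intrinsically coarse for
  narrow-band signals (phase-blind magnitude, slow envelopes).
* HbR is carried through preprocessing but not analysed, matching the
  HbO-only design of the procedure implemented.
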