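# Methods

This note documents the models, defaults and numerical choices behind
`wormmate`, and what the synthetic-data validation does and does not
demonstrate about real recordings.

## Generative model of a dual-channel recording

A recording is an `(n_frames, height, width, 2)` float stack at a frame
rate of ~30 frames/s. For frame time *t*:

* green cell pixel = `baseline_green · (1 + transient(t)) ·
  e^(−green_bleach_rate·t) · artifact(t) + background + noise`
* red cell pixel = `(plateau + span·e^(−rate·t)) · artifact(t) +
  background + noise`
* background pixel = `background + noise`

Cells are filled discs (default radius 4 px); their shape is irrelevant
to mean-pixel-intensity analysis. Noise is additive Gaussian, truncated
at zero. All randomness flows from one seeded generator per call;
identical seed and configuration reproduce the stack bit for bit.

**Transients** are multiplicative on the green baseline: a linear rise
over the first quarter of the event duration, then an exponential fall
with time constant duration/4, zero outside the event. A multiplicative
transient makes %ΔF/F₀ scale-free — the ground-truth percent series is
exactly `100·transient(t)` regardless of baseline, magnification or ROI
dilution — which is what makes parameter-recovery tests well defined.
The waveform truncates at the event end with a residual of e⁻³ ≈ 5% of
the peak; event durations of ~1.5 s make this invisible at the default
noise level.

**The shared artifact series** multiplies the fluorophore signal (not
the background) on both channels identically. The default model is
frame-scale illumination flicker — white multiplicative noise with SD
4%, whose extremes reach roughly the ±20% apparent-ΔF/F₀ band that
focusing/motion artifacts produce in hyperpolarized-neuron control
recordings — plus brief focusing/movement excursions modeled as a
mean-reverting (Ornstein–Uhlenbeck-style) walk with stationary SD 0.5%
and a correlation time of ~5 frames, the whole series clipped to a
configurable band (default [0.7, 1.3]). Mean reversion is essential, not
cosmetic: the experimenter actively refocuses and recenters, so
excursions are transient. A drifting artifact (e.g. a plain random walk)
is mathematically indistinguishable from photobleaching in a
red-referenced correction — any monotone artifact trend is absorbed into
the fitted decay and biases %ΔF/F₀ by roughly `(1 + ΔF/F₀) ×` the
relative shape error. That identifiability limit is a property of the
correction method itself and is stated under Limitations.

**Red bleaching** defaults to `(plateau, span, rate) = (120 AU, 30 AU,
0.15 /s)` on a 150 AU baseline: about a 15% signal loss over a 10 s
bout, noticeably faster than the (default zero) green bleaching, which
is the situation the one-phase-decay reference exists for.

## Ratiometric correction

The reference fit supports three modes. `mean` returns the flat trace
mean. `one_phase_decay` performs bounded least squares (plateau, span,
rate ≥ 0) with `scipy.optimize.curve_fit`, initialised at
`(min(red), max(red) − min(red), 1/duration)`; an all-constant trace
degenerates to the mean-equivalent fit. `auto` (the default in the
protocols) fits the decay and keeps it only when it converges, has a
positive rate, and reduces the sum of squared errors by at least 5%
relative to the mean line — recordings without appreciable red bleaching
fall back to the simple average reference. A fitted reference that is
not strictly positive at every frame is an error: the correction value
would be undefined.

%ΔF/F₀ is computed against the first frame (`F0 = G_corr(0)`). The
correction divides by `c(t)`, which is numerically identical to
multiplying by the inverse correction value.

Event calling thresholds the %ΔF/F₀ trace at the artifact band (default
20%): contiguous supra-band runs are events, runs separated by fewer
than 3 sub-band frames are merged, and events shorter than 2 frames are
dropped as single-frame noise blips. Band, gap and minimum duration are
configurable; the 20% default is taken from the hyperpolarized-neuron
control band and is not re-estimated from data.

## Thrust analysis

The per-frame population SD of pixel intensity inside the spicule ROI is
normalized as percent deviation from the bout median; the median is used
as the baseline because it resists contamination by the deflection peaks
themselves. Deflections are local maxima of the normalized trace above
the amplitude criterion (default 5%, peak-to-baseline), with maxima
closer than a 30 ms refractory window collapsed onto the larger one.
Bout frequency is `(n − 1)/(t_last − t_first)`; the inter-thrust
interval SD (population SD) is the rhythmicity measure — arrhythmic
thrusting raises the interval SD more than it moves the mean frequency.

The synthetic thrust waveform is a train of brief trapezoidal
deflections: full amplitude within ±15 ms of each cycle centre, falling
to baseline at ±20 ms. Two considerations fix this shape. First, a
thrust is fast relative to the dwell between thrusts, so the trace
spends most of each cycle near baseline and the median is a clean
baseline even at 11 Hz. Second, the 30 ms flat top guarantees that at
~35 samples/s at least one sample per cycle sits at full amplitude, so
the 5% criterion sees every cycle; a sinusoidal (50% duty) waveform at
11 Hz would both contaminate the median and alias peak heights at this
sampling rate. Cycle centres carry optional Gaussian timing jitter and
per-cycle dropouts.

## Behavioral scoring

Timelines are ordered, non-overlapping labeled intervals over
{`off`, `scanning`, `vulva_prodding`, `insertion`}, with at most one
terminal `insertion` whose start is the penetration time, and an
observation cap of 120 s. In the E_SI score the penalty denominator is
clamped at 1 s: a maximally diligent male has zero non-productive
contact, where the unclamped formula is undefined, and the clamp is the
minimal rule that reproduces the canonical score of
1.99 = 1 × 1 × (1 + 119/120). Durations are truncated at the cap (and at
the penetration time) before any ratio; the bonus uses the 120 s cap.
Only `vulva_prodding` counts as attempting insertion — prodding away
from the vulva is non-productive contact, which is exactly the behavior
the score is meant to penalize. The timeline generator accordingly emits
ectopic prodding bouts under the `scanning` label: the label vocabulary
describes productivity, not posture.

The timeline generator alternates exponential scanning and prodding
bouts (defaults: mean 10 s and 8 s; the first bout type is a fair draw),
marks each prodding bout ectopic with probability `p_ectopic` (default
0.2; an ectopic-regime male uses 0.8), and ends each on-vulva prodding
bout with penetration with probability 0.25. These defaults produce
wild-type-like timelines in which most insertion attempts are at the
vulva; raising `p_ectopic` reproduces the directional effect of
dopamine-deficient males (lower median E_SI).

## Statistics

Fisher's exact test is two-sided by the probability-mass rule (sum the
probabilities of all margin-consistent tables no more probable than the
observed one) — the convention of the graphing packages standard in this
field; doubling conventions give different p-values and are not used. A
zero margin returns p = 1 flagged as degenerate. Mann-Whitney switches
from the exact enumeration to the tie-corrected normal approximation
with continuity correction when the combined sample exceeds 20 or ties
are present. The implementations are thin layers over `scipy.stats`;
their correctness is established in the test suite against hand-written
enumeration oracles (full hypergeometric enumeration; all-permutations
U distributions). No multiple-testing correction is applied beyond Tukey
within an ANOVA family.

## Validation protocols and problem sizes

The frozen synthetic protocols used by the tests and the reproduction
script: imaging replicates are 64×64 px, 300 frames at 30 frames/s, one
neuron, two transients (onsets 2 s and 6 s, duration 1.5 s, peak
amplitudes uniform in 30–80%), artifact band ±20%, pixel noise 2% of the
green baseline, 20 replicates; thrust replicates are 10 s bouts at 35
samples/s, amplitudes 10%, timing jitter 10 ms, 100 replicates per
frequency at 7, 9 and 11 Hz; behavioral regimes use 100 timelines each;
the Fisher null calibration uses 5,000 replicates of equal binomials
(p = 0.5, n = 30 per arm). These sizes were chosen so the full suite
validates every stage in seconds while keeping Monte-Carlo error well
below the decision margins.

Under these conditions the pipeline calls the correct event count in all
replicates and recovers peak %ΔF/F₀ within ±5 percentage points in 19 of
20; the residual peak error is dominated by the variance of the
one-phase-decay fit under multiplicative flicker (the three decay
parameters are nearly collinear over a window of ~1.5 time constants),
not by the correction itself, which cancels the shared per-frame
artifact exactly.

A note on the Fisher null calibration: the exact size of the two-sided
probability-mass Fisher test at n = 30/30 and α = 0.05 is at most
0.0274 (attained at p = 0.5; computed by exact enumeration over the
31×31 outcome grid for all nuisance p). The test is therefore more
conservative than a nominal 3–6% rejection band implies; the observed
simulated rate of ≈ 0.025–0.03 is the correct behavior of the exact
test, not an implementation artifact.

## What the synthetic validation does not show

The generator emulates the statistical structure the analysis assumes,
not microscopy: no optics or point-spread function, no magnification
dependence (the source recordings mix 10× and 20× objectives), no
cell movement requiring ROI tracking (per-frame ROI positions are an
input, mirroring manual repositioning), no green-channel bleed-through
or cross-talk, and no spike inference — events are threshold crossings,
not deconvolved spikes. Passing the recovery tests shows the analysis
chain is correct and well calibrated under its own assumptions; it does
not certify performance on recordings whose artifacts drift slowly or
trend monotonically, where the red-referenced correction is
fundamentally unable to separate artifact from bleaching (see above).
ICL% is computed from supplied length measurements; body-outline
extraction from images is out of scope.
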