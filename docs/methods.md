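# Methods

`dendroca` analyzes two-photon Ca2+ imaging of cerebellar Purkinje cell (PC)
dendrites during a cued-licking task, with a synthetic-session generator that
reproduces the statistical structure of such recordings so every stage can be
validated against ground truth. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
benchmarks do and do not establish about real data.

## The generative model

A session is a cued-licking behavioral log plus one fluorescence trace (or a
pixel movie) per region of interest (ROI).

**Behavior.** Trials repeat every `trial_interval` (10 s): a 6-kHz-like tone
cue of 0.5 s, water at tone offset, then a lick bout starting a short
exponential reaction time (~0.2 s) later and lasting `bout_duration` (3 s)
with inter-lick intervals jittered around `lick_period` (0.13 s, ~7.7 Hz; the
within-bout period is not constrained by published numbers, so this is a free
parameter set to a typical mouse licking rate). No licking occurs between
trials.

**Events.** Climbing-fiber-evoked Ca2+ events form an inhomogeneous Poisson
train with rate `base_rate` (1.5 Hz) outside licking epochs and
`base_rate * lick_boost` (5x) inside them, matching the resting event rate of
~1.5 Hz and the roughly five-fold rate increase during licking that the
pipeline is designed around. A dead time of 2 frames (67 ms at 30 Hz) is
enforced because a 30 Hz detector cannot resolve closer events; the driving
intensity is compensated (`lambda' = r / (1 - r * dead)`) so the realized
rate matches the configured rate to within a few percent. The realized
in-epoch/out-of-epoch rate ratio sits slightly below the nominal boost
(~4.6 rather than 5) because refractoriness clips proportionally more of the
high-rate epochs — the same saturation a real recording would show.

**Amplitudes.** Event amplitudes are lognormal with mean `mean_amp`
(dF/F = 0.223) and coefficient of variation `amp_cv` (0.2): positive and
right-skewed, as observed amplitude distributions are. In the
`disinhibited` condition (chemogenetic suppression of molecular layer
interneurons, modeled purely as a flag) amplitudes of events falling in
movement (licking) epochs are multiplied by `cno_gain_move`; nothing else
changes. With equal seeds the control and disinhibited sessions share
behavior, event times, base amplitudes, and noise — an idealized paired
design.

**Traces.** Fluorescence follows the multiplicative model
`F(t) = F0 * (1 + sum_i a_i * k(t - t_i)) + noise`, with the indicator kernel
`k(t) = exp(-t/tau_decay) - exp(-t/tau_rise)` normalized to unit peak
(`tau_decay` = 150 ms for GCaMP6f in this preparation, `tau_rise` = 10 ms).
The multiplicative form makes dF/F recovery exact and scale-invariant. Noise
is i.i.d. Gaussian per frame with SD `noise_sigma * F0` (default 0.0446 =
`mean_amp` / 5, the benchmark signal-to-noise regime); Poisson noise is
available as an option but off by default, since shot-noise-dominated
two-photon data at this SNR is well approximated by the Gaussian.

**Movies.** Dendrites are disjoint vertical bands (parasagittal geometry),
blurred by a Gaussian point-spread function of 0.7 px before rendering;
pixels are `background + sum_k mask_k * trace_k + noise`. Optional rigid
drift is a smoothed Gaussian random walk with configurable SD, applied per
frame with bilinear interpolation and recorded in the ground truth.

**Branch pairs.** Two segments of one dendrite share event times; each
branch observes each event through an independent unit-mean lognormal jitter
with log-scale SD `branch_jitter_sd` (0.2). In the disinhibited condition
the jitter SD of movement-epoch events is multiplied by
`jitter_shrink_move` (default 1.0), modeling the drop in inter-branch
variability under disinhibition.

**Ex vivo trials.** Conjunctive stimulation experiments are simulated as
trial-averaged 500 Hz line-scan traces: a parallel-fiber transient, a
climbing-fiber (indicator-kernel) transient 150 ms later, and a conjunctive
trace equal to `gain` times their pointwise sum, each averaged over ~10
noisy trials.

All randomness in a session flows from one seeded generator; identical
config and seed give bit-identical output.

## Analysis pipeline

**Registration.** Each frame is aligned to a fixed template (mean of the
temporally middle 100 frames; robust to onset artifacts) by minimizing the
per-pixel mean squared intensity difference over the overlap across integer
translations within +-10 px (computed via FFT correlation identities),
refined to subpixel precision with a separable 3-point quadratic fit of the
error surface. When the error at the best integer node is numerically zero
the refinement is skipped, so exact integer shifts are returned exactly.
Aligned frames are resampled bilinearly; pixels entering from outside the
frame are NaN and excluded downstream. The same shift series applies
unchanged to a second simultaneously acquired channel.

**Segmentation.** The movie is reduced by PCA (components weighted by their
singular values), and the leading components — selected by a noise-floor
rule (explained variance above twice the median of the computed spectrum) —
are rotated by fixed-point ICA maximizing a third-moment (skewness) contrast
of the concatenation `[mu * spatial; (1 - mu) * temporal]`, `mu` = 0.5 by
default. A genuinely odd contrast matters here: even contrasts (kurtosis)
are blind to sign structure and can return +/- mixtures of one-sided
sources. Components are sign-corrected to positive spatial skewness, and
components whose time course has skewness below 0.15 are discarded
(residual-motion and noise components are roughly symmetric in time, real
Ca2+ sources are spiky). Spatial filters are thresholded at 3 robust
(MAD-based) SDs — robust because a source covering a sizable fraction of the
field would inflate a plain SD — connected components under 20 px dropped,
and each surviving component trimmed to its half-maximum footprint so PSF
skirts do not inflate masks. Near-duplicate ROIs (IoU > 0.5) are merged.
Traces are mask means. Hand-drawn ROIs (somata, boutons) bypass ICA via
labeled mask images. Cross-session ROI matching is greedy
centroid-nearest-neighbor with a distance cap, and is explicitly a
heuristic.

**Event inference.** Traces are converted to dF/F (session F0 = mean of the
lowest 5% of samples; a single minimum would be noise-dominated) and
deconvolved against the indicator kernel by L1-penalized nonnegative least
squares over a per-frame spike vector (FISTA, 300 iterations, with a jointly
fitted DC offset — without the offset the elevated session mean biases all
amplitudes down). The penalty is 1.5 x a MAD-derived noise scale of the
AR(1) innovation `f_t - g f_{t-1}`; local maxima of the spike vector are
then refit jointly without the penalty (debiasing NNLS with a free offset),
and candidates whose debiased amplitude exceeds 3.5 x the amplitude noise
scale (re-estimated from the fit residual, which unlike the raw innovation
MAD is not inflated by the events themselves) become events. Sub-refractory
splits are merged onto the larger amplitude. The joint fit lets events on
the decay of earlier events be detected down to the 2-frame refractory
spacing. On the benchmark sessions this achieves precision and recall above
0.95 at noise SD = mean amplitude / 5, and sub-frame timing noiselessly.

**Per-event dF/F.** F0 is the mean over the 200 ms immediately preceding the
event; for overlapping events that window sits on the predecessor's decay,
uncorrected. The default peak estimate ("fit") is the least-squares
amplitude of a unit-peak kernel with the onset scanned over one frame at
subframe resolution; the fit window reaches back through the baseline and
carries a constant plus a decaying exponential as nuisance regressors, which
absorb the predecessor tail that would otherwise bias isolated-event
amplitudes a few percent low. A raw-max variant ("max", maximum within one
decay constant) is available; a raw maximum is upward-biased by noise and
frame discretization, which is why the fitted peak is the default. Both are
invariant to multiplicative rescaling of the trace.

**Isolation classes.** Isolated = no neighbor within 0.5 s (a gap of exactly
0.5 s still counts as isolated); pair = exactly two events within 0.5 s of
each other and at least 0.5 s from all others; triplet = three events
spanning at most 1 s and at least 0.5 s from any other event; everything
else is "other". Rules apply in that order. Overlapping-pair selection keeps
consecutive events with gaps in [0.15, 0.20] s, inclusive at both ends;
boundary comparisons use a 1e-9 s tolerance. Under homogeneous-Poisson
trains, isolated events form the majority only at rates below ~0.7 Hz
(P(no neighbor within 0.5 s) = exp(-2 * rate * 0.5)); real trains are
clustered, so the generator reproduces the isolated-majority regime at
rest-like rates rather than inside licking bouts.

**Behavioral epochs.** A time is "licking" when a lick lies within 0.25 s
(symmetric look-back/look-ahead; the causal direction is ambiguous in the
task description, and the symmetric rule is exposed as parameters),
"non-licking" when no lick lies within 0.75 s (strict: a lick at exactly
0.75 s leaves the time unclassified), otherwise "unclassified". Events in
the unclassified gap enter neither epoch-conditioned average. Events carry
their onset-time label. Lick rate is the inverse of the mean inter-lick
interval; tone response time is the interval from cue offset to the first
later lick, absent (NaN) if none occurs before the next cue.

## The disinhibition statistics

**MDM ratio.** `(dF/F_CNO / dF/F_Ctrl)_movement / (dF/F_CNO /
dF/F_Ctrl)_rest`; 1 means no movement-specific effect of disinhibition. It
is invariant to any common rescaling of its four inputs. `mdm_map` applies
it per ROI or per pixel and reports the fraction above 1.

**Paired-session recovery.** For paired control/disinhibited sessions the
per-ROI MDM is computed by detecting events in both traces, pooling the
onset sets, and re-quantifying *both* traces by joint NNLS on the pooled
onsets (`events.quantify_at_times`). Quantifying the two conditions on the
same onset set makes the amplitude estimator linear and identical across
conditions, so detection-selection bias (larger disinhibited events are
easier to detect, pulling the naive mean down) and overlap-redistribution
differences cancel exactly in the CNO/control ratios. With separate
per-condition detection these biases reach -0.05 to -0.09 on a true gain of
1.3; the pooled-onset estimator recovers gains in {1.0 ... 1.3} to within a
few hundredths, and recovers the rest-epoch null essentially exactly in the
paired design.

**ROC effect fraction.** The empirical ROC over all thresholds of the pooled
pixel values, computed rank-based (Mann-Whitney; ties share ranks); the
percent of pixels showing an effect is `100 * max(0, 2*AUC - 1)` — the
standard "fraction separable beyond chance" reading of the area under the
curve, exposed as a pluggable mapping.

**Inter-branch variability.** `2 |A1 - A2| / (A1 + A2)` per simultaneous
event (amplitudes on the two branches matched within one frame); symmetric,
scale-invariant, bounded in [0, 2].

**Ex vivo supralinearity.** The peak of a stimulus-evoked transient is the
amplitude of a single exponential `a * exp(-(t - t_stim)/tau) + c` fitted by
least squares to the post-stimulus decay (from the post-stimulus maximum
on), minus the pre-stimulus baseline. Anchoring the amplitude at the
stimulus time lets the fit extrapolate across a blanked stimulus-artifact
window, so blanked and unblanked conditions are measured on the same
footing. Initialization: tau = 0.15 s, a = max - last sample; bounded
Levenberg-Marquardt, tolerance 1e-8; non-convergence is flagged and falls
back to the raw maximum. Supralinearity is 100 x the fitted peak of the
conjunctive trial average over the fitted peak of the *pointwise sum* of the
two single-input trial averages (summing traces before fitting, not fitted
peaks); normalization happens after trial averaging. The estimator is
unbiased at the null (mean 100% over seeds, symmetric) because numerator and
denominator share every systematic of the fit.

**Neuropil correction.** Bouton dF/F minus the adjacent-neuropil dF/F,
per sample.

## Problem sizes and tolerances

The test suite and the acceptance script run everything at desk scale,
chosen so each stage still has the statistics it needs: detection and
amplitude benchmarks use 120-200 s single-ROI sessions at 30 Hz;
segmentation benchmarks use 60 s movies of 32x32 or 64x64 px with 1-8
dendrites at noise = 20% of the mean amplitude; the paired MDM recovery uses
200 s, 32x32 px, 2-dendrite movies with 0.5 px drift SD; ROC recovery uses
10^4 pixel values; supralinearity uses 10 trials per condition and tens of
seeds. Coordinate conventions: times are float seconds, frames 0-based,
pixels 0-based row-major.

## What the synthetic benchmarks do not show

The generator's events are (refractory) Poisson, amplitudes lognormal, noise
Gaussian and white, motion purely translational and slow, and dendrites
disjoint bands with a common kernel. Passing the recovery benchmarks
therefore demonstrates correctness of the implementations under the stated
model, not robustness to real-data pathologies: overlapping or
co-fluctuating sources, indicator nonlinearity, slow baseline drift,
non-rigid motion, clustered (non-Poisson) event trains, or kernel mismatch.
Cross-session ROI matching is heuristic; under drift the ICA can split or
merge ROIs even when the extracted traces remain faithful, which is why the
paired MDM recovery matches ROIs by centroid and tolerates imperfect masks.

## Known limitations

- The epoch-conditioned analyses assume lick detection itself is noiseless.
- The ICA uses a single fixed-point run; with heavy residual motion the
  skewness objective can prefer mixtures (restarts do not fix this — the
  objective itself is at fault there), so masks under drift are best treated
  as approximate.
- The "adjusted lick rate" of related work is deliberately not implemented
  (its formula is defined elsewhere); plain inverse-mean-interval lick rate
  is.
- Event inference assumes the exponential kernel's time constants; they are
  arguments everywhere but are not estimated from data.
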