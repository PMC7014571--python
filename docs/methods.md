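# Methods

`wormnest` implements the analysis stack for studying how *C. elegans*
behaviors on three timescales nest inside one another: an ~0.05 Hz
forward/reverse command cycle, ~0.5 Hz propagated body bends (the crawling
gait), and ~1 Hz head-casts that initiate only within a restricted phase
window of the gait cycle. This note documents the models, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Posture model and conventions

A kymogram is a T x 24 matrix of signed bend angles. A worm midline of 25
equally spaced segments (26 points) yields 24 turning angles between
adjacent segment vectors; angle #1 is anterior. Ventral bends are positive,
dorsal negative (`ventral_positive=True`); the source data never fix a sign
convention, so this one is enforced everywhere. Time is 0-based frames;
intervals are half-open `[start, end)`.

Propagated-bend phase maps dorsal - ventral - dorsal onto 0 - pi - 2*pi rad:
phase 0 sits at a dorsal angle-#2 maximum (a minimum in signed angle,
because dorsal is negative).

## Propagation tracing

Angle columns are reduced to alternating extrema with the amplitude-
threshold (delta) detector: a maximum must be flanked on both sides by
values at least `delta` lower, and symmetrically for minima, so maxima and
minima strictly alternate and extrema need not straddle zero. Missing
samples break detection runs; series endpoints are never extrema.

Peaks in angle #2 seed head-bend events (angle #1 is noisier). Events are
processed in temporal order and every extremum is assigned to at most one
event — contested posterior bends therefore go to the earliest possible
head-bend. After an optional anterior attachment (the nearest previous
same-sign unassigned peak in angle #1 within 1 s), propagation iterates
posteriorly: the next same-sign unassigned peak in the next angle is
attached, with up to two angle columns skippable per event when no
correct-sign peak was detected. Assigned peaks may trail the previous one
by 0.1 s freely, and by up to 1 s once per event; the tracer tries the free
window first and spends the 1 s budget only as a rescue, because searching
the full backward window up-front would surface the previous opposite-sign
bend. The anterior attachment is inherently backward and does not consume
the budget.

Propagation terminates on: an opposite-sign next peak; a next peak more
than 10 s after the previous one; at least two unassigned peaks in the
anterior angle before (or within 0.1 s of) the candidate — the rule that
stops a head-cast from hijacking the next wave's posterior peaks; or a
reversal/missing-data boundary. Final segment <= #13 classifies the bend a
head-cast, >= #14 a propagated-bend; termination by reversal, missing data,
or the end of the recording before #14 leaves it unclassified (it might
have propagated further), as are isolated single-segment bends. Reverse
bouts are analyzed on the left/right-flipped kymogram so tail-to-head waves
mirror the forward analysis.

Cycle periods double inter-bend intervals: between two consecutive
head-casts (head-cast cycle), between two consecutive propagated-bends
with no intervening cast (strict), or between successive propagated-bends
regardless of cast interruption (full). Head-bend amplitude sums peak
|angle| over segments #2-#6.

Defaults chosen where the sources are silent: 0.3 s boxcar smoothing of
angle columns; missing runs strictly shorter than 1 s linearly bridged;
behavior detection threshold 0.3 rad (about 60% of a typical bend
amplitude) with the automatic per-column selection available via
`delta="auto"`.

## Automatic delta selection

The number of detected peaks as a function of delta falls steeply while
noise peaks disappear and is nearly flat once only real peaks remain. The
selector sweeps a delta range, scans every interior breakpoint of the
count curve, fits independent lines to both sides, and returns the split
with the smallest summed squared residual — the exact small-N criterion for
the point where mean and slope change most abruptly. Two numerical choices
matter:

- residuals are weighted relative to each segment's own level. The two
  regimes differ by orders of magnitude, and unweighted least squares lets
  the steep regime swamp misfit in the flat one, biasing the breakpoint
  liberal. A curve of two exact lines is still recovered exactly.
- the scan is repeated on the tail segment while it still starts well above
  its own plateau (1.3x the tail median) and a further split strongly
  improves the fit; convex transitions otherwise leave the breakpoint one
  knee-width early.

A constant count curve carries no changepoint; the caller falls back to a
range derived from the series standard deviation (max = sd, min = step =
sd/100) and ultimately to its upper bound. Four published sweep ranges ship
as presets (derivative, immobilized raw, 50 Hz raw, moving).

Operating envelope, measured on synthetic kernel traces at 3 Hz with a
1 s pre-smoothing boxcar: event-recovery F1 >= 0.95 at noise up to ~5% of
the transient amplitude, degrading to ~0.9 at 10% noise, where noise peaks
riding transient flanks clear the detected threshold and +-2-frame
localization starts to fail. Derivative-trace detection additionally drops
maxima below zero and, of two maxima whose intervening minimum stays above
zero, keeps only the first (slope changes within one calcium rise).

## Trace preprocessing

Single-channel traces: background-subtracted dF/F0 with F0 the trial mean.
Photobleaching is treated as multiplicative, so detrending divides (the
sources do not print the operation): step 1 divides out a pure exponential
`a*exp(-t/tau)` fitted to the whole trace; step 2 divides out an
exponential fitted only to detected peak values, flattening the transient
envelope. Fits are nonlinear least squares with log-linear initialization
and tau bounded positive. When step 2 inflates the variance by more than a
relative factor of 8 (the distortion cutoff), the step-1 version is
returned and flagged. Dual-channel traces: R = GCaMP/mCherry, R0 = mean of
the lowest 10% of ratio values, dR/R0 = (R - R0)/R0, optionally divided by
the recording's 95th percentile; non-positive mCherry frames are masked and
excluded from the R0 pool.

Derivatives use total-variation regularized differentiation: u minimizing
`0.5*||integral(u) - (f - f(0))||^2 + alpha*TV(u)`, solved by
lagged-diffusivity fixed-point iterations (epsilon = 1e-8 smoothing of
|du|) with conjugate-gradient inner solves, capped at 40 outer iterations.
The default alpha for command-state work is small (0.01-0.05 in dF/F0
units); the regularization level is exposed because no reference value is
printed.

## Command states

A command neuron's frames are labeled RISE (derivative above a positive
threshold), FALL (below a negative threshold), then HIGH/LOW by a level
threshold. Default thresholds: +-3 median absolute deviations of the
derivative and the trace midrange — exposed because none are printed.
RISE+HIGH map to the reversal command, FALL to the post-reversal turn, LOW
to forward; same-command frames merge into intervals and flicker shorter
than 2 s is absorbed into the preceding interval. Turn intervals stay
distinct from forward so forward-state statistics exclude the falling
phase. Forward states shorter than 50 s are excluded from frequency and
covariogram analyses (they rarely carry more than one fluctuation).

Boundary recovery, measured on synthetic command cycles with 0.5 s/1.5 s
rise/decay kinetics and 5% noise at 3 Hz: median error under 2 frames;
occasional short reverse states blur further because the trace barely
reaches its plateau.

## Population analysis

PCA runs on detrended traces and their time derivatives simultaneously
(two variables per neuron, each scaled to unit variance), centered, via
SVD; reconstruction from all components reproduces the input to numerical
precision and `scores @ loadings + mean` is the reconstruction contract.
Reconstruction quality per neuron group is the Pearson correlation between
each neuron's trace variable and its top-i reconstruction (the derivative
participates in the PCA, not in the correlation), averaged over the group —
insensitive to trace magnitude, unlike mean squared error. Mean activity
difference is the frame-weighted mean over all forward frames minus the
mean over all reverse frames. Peak frequencies are counted per retained
forward state and divided by state duration, keeping zero-peak states as
real zeros.

## Covariograms and event statistics

Raw cross-correlograms accumulate, for each reference peak, the lags of all
target peaks within the same forward state into 10 s bins spanning +-60 s,
and divide each bin by its available-frame count (frames in which a target
peak could have occurred, summed over reference peaks and states) — the
correction for unequal state durations. The shuffle corrector is the mean
of resampled correlograms in which the target's peak times are redrawn
uniformly at frame resolution, without replacement, within each state
(the redraw scheme matches the conditional law of a Bernoulli-per-frame
train given its per-state counts, so the null is exact). The covariogram is
raw minus corrector; its sign follows the larger of |max| and |min|, and
the p value is the fraction of resampled covariograms with an extremum at
least as large. The default 10^4 resamples give p resolution 10^-4
(a larger value is one config field away); pairs with under two events are
flagged low power with p = 1. A suppressive relationship can only win the
sign competition when reference peaks cover less than half of state time
(the deficit is bounded by chance level while the complementary surplus is
not), which constrains useful anti-correlation fixtures to sparse
references.

Multiple comparisons use Benjamini-Hochberg-Yekutieli step-up with
`c(m) = sum 1/k`, valid under arbitrary dependence. The inter-peak-interval
randomness test redraws per-state peak counts uniformly, pools IPIs over
states into 5 s bins, and scores the summed absolute bin-by-bin deviation
from the average random histogram; the p value is the fraction of
resampled IPI distributions deviating at least as much.

## Phase nesting

Interpolated phase runs 0 -> pi between an A anchor (dorsal propagated-bend
maximum, or the first SMDD peak following an SMDV peak) and the next B
anchor and pi -> 2*pi back, ignoring intervening same-type peaks, making
the phase independent of interleaved head-casts; frames outside the
anchored span are invalid, and events exactly at an anchor take the anchor
phase. Hilbert phase of the smoothed (1 s boxcar) head angle is computed
per locomotion bout with partial border cycles removed; the two methods
agree within 0.3 rad on clean oscillations.

The skewness test resamples, for each half-cycle that contributed a real
event-phase sample, one random phase from the time points where a peak
could have been detected (at least delta away from the previous detected
peak — the same delta that produced the peaks); histograms use 16 equal
bins over [0, 2*pi) for samples and null alike, and skewness is the summed
absolute difference from the all-phases distribution over those cycles.
The two-distribution test subsamples the larger distribution at the
smaller one's size with the same statistic. Both report plain resampling
fractions, as in the reference procedure.

## Synthetic data: what it emulates, and what not

`gen_kymogram` builds posture from a global alternating sequence of
discrete bends. Each bend is a smooth flexion bump traveling posteriorly
with a fixed per-segment delay (0.4 rad of wave phase per segment);
per-column signals are cosine chains through the bend peaks, which makes a
pure bend train an exact sinusoid and keeps every peak sharply detectable.
Angles relax to zero inside long inter-bend gaps (bout transitions).
Propagated bends reach segment 24; head-casts come as a pair of opposite
half-cycle bends (the typical half-cycle episode) restricted to segments
1-8 by default. Cast episodes initiate only when the body-wave phase lies
inside the configured gate *and* the half-cycle leaves room for the
episode between the flanking propagated bends (0.3 s separations plus the
0.5 s inter-cast interval); the per-half-cycle probability is
`1 - exp(-attempt_rate * usable_window)`. Slower waves therefore carry
more casts per unit time — the window-of-opportunity mechanism — while
initiation phases stay inside the same gate. A fixed per-cycle probability
override exists but removes that frequency dependence. Reversal bouts
arrive as a Poisson process; during them the wave travels tail to head and
casts are suppressed. Cycle periods jitter lognormally (CV 0.15), which is
what gives some half-cycles room for casts at the base frequency.

Two consequences of this construction matter for interpreting passing
tests. First, bends never straddle bout boundaries (the generator leaves a
0.4 s quiet margin), so tracer fidelity numbers exclude the genuinely
ambiguous boundary bends that real recordings contain — the tracer's
unclassified outcome covers those. Second, even with the gate fully open,
initiation phases are not uniform: the room constraint forbids casts too
close to either flanking bend, so an "ungated" recording still carries
weak phase structure and the skewness test correctly rejects it. Type-I
calibration therefore runs on the test's own null — one random detectable
phase per half-cycle — which is exactly the resampling scheme the test
assumes; measured rejection is 0.05 within Monte Carlo error.

`gen_traces` emulates immobilized recordings: a slow forward/reverse
command cycle (lognormal durations, means 100 s/25 s), neurons with
state-dependent event rates and double-exponential transients, optional
lagged coupling to a partner, multiplicative photobleaching
(`exp(-t/tau)`, default tau 900 s), and additive Gaussian noise. A
`command` mode neuron follows the reverse-state indicator with first-order
rise/decay kinetics (an AVA-like interneuron). An optional per-neuron
refractory interval reflects that rhythmic neurons have non-random IPIs;
without it, Poisson event pairs closer than the kernel width merge into a
single calcium peak that no detector can split. `gen_event_trains` draws
Bernoulli-per-frame trains inside forward states with excitatory (lagged
copies) or suppressive (deletion near lagged reference events) coupling.

Not emulated: biomechanics and proprioceptive coupling, image formation
and segmentation noise (missing data must be injected explicitly), neuron
identity inference, motion artifacts in moving recordings, and co-varying
event amplitudes across states.

## Benchmark problem sizes

The shipped benchmarks (also the acceptance script) use: 600 s behavior
recordings at 10 Hz for tracer fidelity; 1200 s for the 0.5 -> 0.25 Hz
window sweep; 1000 s at 0.25 Hz with attempt rate 2 /s (~200 cast episodes)
for nesting, with 10^4 skewness resamples and 500 null simulations at 10^3
resamples; 100 independent five-pair sets, 100 planted couplings (+15 s,
fraction 0.8) and 10 suppressive pairs at 10^4 covariogram resamples over
ten (thirty for suppressive) 100 s states; 500 Poisson neurons for IPI
calibration; three 6000 s kernel traces at 5% noise for event-recovery F1;
and three 1800 s command-cycle recordings for state boundaries. These sizes
give each rate estimate a standard error comfortably inside its tolerance.

## Known limitations

- The changepoint criterion for automatic delta selection is a documented
  stand-in (level-weighted two-segment least squares with tail refinement);
  no reference implementation is printed to compare against.
- Peak-recovery F1 and nesting power degrade with sampling rate and noise
  as described above; all quoted figures are for the stated regimes.
- The HIGH/LOW assignment rule for non-RISE/FALL frames is a plain level
  threshold; recordings whose baseline drifts across the midrange need
  explicit thresholds.
- `gen_kymogram` produces bends of constant amplitude; amplitude-dependent
  analyses (head-bend amplitude summaries) are exercised for correctness,
  not for realistic variance.
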