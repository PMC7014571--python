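# wormnest

Analysis tools for nested, multi-timescale dynamics in *C. elegans*
behavior and neural activity. The package is written for researchers who
quantify worm locomotion from posture kymograms and calcium imaging and
want to test whether fast actions are *phase-nested* inside slower
rhythms — the organizational signature of a behavioral hierarchy:

- an ~0.05 Hz forward/reverse **command cycle**, read out from a command
  interneuron's (AVA's) RISE/HIGH/FALL/LOW activity phases;
- ~0.5 Hz **propagated-bends**, head flexions that travel to the tail
  (segment #14 or beyond of 24 body-bend angles) and constitute the
  crawling gait;
- ~1 Hz **head-casts**, bends that terminate anterior to mid-body
  (segment #13 or earlier) and initiate only within a restricted phase
  window — the *window of opportunity* — of the propagated-bend cycle,
  with phase 0 - pi - 2*pi spanning dorsal - ventral - dorsal maxima.

The stack covers every stage between raw tabular recordings and the
hierarchy statistics:

| module | what it does |
| --- | --- |
| `wormnest.kymo` | bend angles from midlines, kymogram preprocessing, head-bend propagation tracing and head-cast/propagated classification, cycle periods, head-bend amplitude |
| `wormnest.peaks` | amplitude-threshold (delta) peak detection, automatic near-optimal delta from a piecewise-linear changepoint on the peaks-vs-delta sweep, derivative-trace peak rules |
| `wormnest.traces` | dF/F0, two-step exponential bleach correction with a variance-change fallback, dR/R0 for dual-channel recordings, total-variation regularized differentiation |
| `wormnest.states` | RISE/HIGH/FALL/LOW phase segmentation and forward/reverse/turn command states, 50 s forward-state exclusion |
| `wormnest.population` | PCA on traces + derivatives (equal-variance, two variables per neuron), per-group reconstruction quality, per-state mean-activity differences and peak frequencies |
| `wormnest.eventstats` | shuffle-corrected covariograms for sparse event trains with resampling significance, Benjamini-Hochberg-Yekutieli correction, inter-peak-interval randomness test |
| `wormnest.phase` | interpolated and Hilbert instantaneous phase, event-phase sampling, cycle peak fractions, polar skewness and two-distribution resampling tests |
| `wormnest.synthetic` | ground-truth generators: nested behavior kymograms, command-cycle calcium traces, coupled event trains |
| `wormnest.io_tables` | strict delimited-text readers/writers with metadata headers |
| `wormnest.pipeline` / `wormnest.cli` | end-to-end immobilized and moving pipelines, synthetic benchmark, `wormnest` command line |

The covariogram is the central statistic for immobilized recordings: for
every reference-neuron peak, the lags of target-neuron peaks within the
same forward command state accumulate into 10 s bins, each bin is
normalized by the number of frames a peak could have occupied, and the
mean of many state-wise resampled correlograms (the shuffle corrector) is
subtracted, so sparse trains cannot fake correlations. Phase nesting is
tested by resampling one detectable phase per half-cycle and comparing
histogram skewness against the all-phases distribution.

## Worked example

Simulate ten minutes of nested behavior (0.25 Hz wave, head-casts gated to
the dorsal-to-ventral half-cycle `[0, pi)`), trace every head bend, and
test the nesting:

```python
import numpy as np
from wormnest.synthetic import BehaviorSimConfig, gen_kymogram
from wormnest.pipeline import headcast_phase_analysis
from wormnest.kymo import cycle_periods

cfg = BehaviorSimConfig(duration_s=600.0, wave_freq_hz=0.25,
                        headcast_attempt_rate_hz=2.0,
                        reversal_rate_hz=0.0, seed=7)
kym, bouts, truth = gen_kymogram(cfg)
res = headcast_phase_analysis(kym, bouts, n_resamples=10_000,
                              rng=np.random.default_rng(7))
periods = cycle_periods(res["events"], "propagated_full", kym.frame_rate_hz)
phases = np.array([s.phase for s in res["samples"]])
print(f"propagated-bends: {res['n_propagated']}, head-casts: {res['n_head_casts']}")
print(f"median propagated-bend cycle: {np.median(periods):.2f} s")
print(f"initial head-casts sampled: {phases.size}; "
      f"{100 * np.mean(phases < np.pi):.1f}% inside the [0, pi) gate")
print(f"phase-nesting p = {res['p_value']:.4g}")
```

prints

```
propagated-bends: 298, head-casts: 238
median propagated-bend cycle: 4.00 s
initial head-casts sampled: 118; 97.5% inside the [0, pi) gate
phase-nesting p = 0
```

The tracer recovers the 0.25 Hz gait (full cycle 4 s) and classifies the
cast pairs; the first cast after each propagated bend is sampled at the
interpolated gait phase, nearly all samples fall inside the generating
gate (the remainder are detection noise), and the skewness test rejects
uniform placement at its resolution (p < 1e-4 at 10^4 resamples).

The same analyses run from the shell:

```bash
wormnest simulate --seed 7 --out sim/
wormnest kymo sim/kymogram.csv --bouts sim/reversals.csv --delta 0.3 --out out/
wormnest phase sim/kymogram.csv --seed 7 --out out/
wormnest run --pipeline synthetic-benchmark --seed 7 --out out/
```

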