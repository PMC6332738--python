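# Methods

This note documents the models, the numerical choices and the simulator
behind `dhmea`, and what the test suite does and does not establish.

## Data model

A recording is a table of threshold-crossing times per electrode
(unsorted multi-unit activity; no spike sorting anywhere in the package)
plus a stimulus-event log. The probe is a 16-channel linear array with
50 um pitch; channel 1 is the most superficial. Channels map onto laminar
regions as superficial (1-3), intermediate (4-9) and deep (10-16).
Channel indices, not nominal depths, are authoritative — the depth
annotation (200 um top, 50 um pitch) is informational only, since probe
geometry and histological depth cannot both be exact.

### Epoching and corrections

Epochs span 100 ms before to 1000 ms after each stimulus in 1 ms bins.
Bins are half-open `[lo, hi)`: a spike exactly at stimulus time falls in
the first post-stimulus bin, and a spike at exactly +3 ms belongs to the
Abeta band. An epsilon of 1e-9 bins in the binning arithmetic keeps these
decimal boundaries stable under floating-point subtraction. A spike may
belong to two overlapping epochs; each epoch is self-contained.

Corrections run in a fixed order enforced by a stage tag:

1. `raw` — integer counts;
2. artefact blanking — bins intersecting [0, 2) ms are zeroed (below the
   3 ms floor of the earliest band, so band sums are unaffected);
3. whole-channel baseline — each channel's mean pre-stimulus rate over a
   reference stimulus group (the subthreshold or saline block recorded
   first) is subtracted from every bin (`channel_corrected`);
4. optional per-stimulus baseline — each epoch's own pre-stimulus mean is
   subtracted from its bins (`stimulus_corrected`).

Negative corrected values are retained; they are meaningful (activity
below the ongoing rate). The per-stimulus step is forbidden for
frequency-series data: growth of ongoing activity across a 0.5 Hz train
is part of the wind-up phenomenon, and subtracting each epoch's own
baseline would delete it. `train_series` refuses `stimulus_corrected`
input outright.

The default pre-stimulus window is all available pre-stimulus bins
(100 ms). `pre_ms` is configurable (e.g. 300 ms) when inter-stimulus
spacing allows a longer epoch.

### Threshold-crossing detection

For synthetic wideband traces, the detector places each channel's
threshold a fraction (default 10 %) of the way from the baseline-window
mean toward the baseline-window minimum, negative-going. The baseline
window (default first 10 s) is a threshold-setting prelude: capture is
armed only after it ends, as in acquisition systems that estimate the
noise floor before arming the trigger. A refractory dead time (default
1 ms) suppresses retriggering. "10 % below baseline" admits several
readings (fraction of RMS, of full scale, of baseline depth); the
baseline-depth rule is one defensible choice and is configurable.

## Latency bands and laminar statistics

Default bands (ms post-stimulus, half-open): Abeta [3, 11), Adelta
[11, 90), C [90, 300), post-discharge [300, 800), combined C+PD
[90, 800), pre-stimulus [-100, 0). The four primary bands must be
mutually disjoint.

Regional aggregation uses **sum** across member channels for electrical
band analyses and **mean** for natural-stimulus region traces; the mode
is recorded in the result. Depth profiles report mean and sample SD
(ddof = 1) across a stimulus group per channel; a group of one yields
SD 0 with a warning. Heatmap matrices are the stimulus-group mean
time-course with 1 ms bins summed in non-overlapping blocks (10 ms by
default).

Z-score maps standardize each animal's *stimulus-group mean* time-course
(not single trials — the choice is documented here because the display
convention could be read either way) by the mean and sample SD of its
baseline-window bins, per electrode; cohort maps average animal maps.
Channels with zero baseline SD are flagged and excluded from the cohort
mean with a warning.

## Wind-up analysis

Per-stimulus band/region values are ordered by position in the train and
condensed to an AUC. The AUC is the plain (rectangular, unit-spacing)
sum over stimulus index: it is exact for constant and all-zero series,
linear in the values, and independent of any re-indexing convention;
trapezoidal integration is available as an option. Frequencies are
compared with a classical paired t test (two-sided; zero-variance
differences return a flagged degenerate result) or a sign-flip
permutation test on the mean paired difference, which enumerates all 2^n
sign patterns exactly when feasible and otherwise uses seeded Monte
Carlo with the add-one estimator. Animals are the replication unit.

## Pharmacology and natural stimuli

Drug studies summarize evoked activity per 600 s period anchored at the
application time (saline occupies negative times). Periods are
left-closed; boundary stimuli go to the later period; empty periods are
explicit NaN gaps, never interpolated. Normalization is a difference
from, or percentage of, the reference-period mean per region and band.

Mechanical and thermal responses are binned at 100 ms around stimulus
onset with a 1 s pre-onset baseline (the pre-onset window length is a
package choice); capsaicin at 10 s bins with a 30 s baseline.
Overlapping application windows are refused.

## LFP conditioning

The high-pass is a Butterworth designed from the 0.01 Hz stop band and
0.5 Hz pass band (3 dB pass ripple, 30 dB stop attenuation — the design
lands at a low order because the bands are two decades apart). The 50 Hz
notch (Q = 100) of nominal order 6 is realized as three cascaded
order-2 biquads; "order" for a Q-specified notch is ambiguous, so the
filter is asserted behaviourally: >= 20 dB steady-state attenuation at
50 Hz, passband gain within 5 % at 10 Hz, DC removed. Both filters are
applied forward-backward (`sosfiltfilt`), so evoked-potential latencies
are not shifted. Attenuation is measured on the interior of the trace
(excluding 1 s edges): the very narrow notch rings at the trace edges,
and the steady-state response is the meaningful figure. Averaged LFPs
subtract each channel's mean voltage over 300 ms before the first 20
stimuli (all available, with a warning, when fewer exist).

## The simulator

`dhmea.synth` emulates the statistical structure the analysis assumes.
It is a Poisson model, not a biophysical one.

**Recruitment.** Threshold follows the Weiss hyperbolic
strength-duration law `I_th(d) = rheobase * (1 + chronaxie/d)` — chosen
over the Lapicque exponential because it is simpler and gives the exact
defining property `I_th(chronaxie) = 2 * rheobase` used as a test. The
recruited fraction is a logistic in amplitude with class-specific slope,
clamped to 0 below 1 % and 1 above 99 %. Note the clamp makes the
duration response of the C class flat (zero) at the two shortest
durations of the standard series before rising strictly — "monotone
non-decreasing, strictly increasing once unclamped" is the invariant the
tests assert.

**Default fibre parameters** (per class: rheobase mA / chronaxie ms /
logistic slope mA / spikes per channel per stimulus at full
recruitment):

| class | rheobase | chronaxie | slope | mean evoked | depth profile |
|---|---|---|---|---|---|
| Abeta | 0.3 | 0.15 | 0.04 | 1.7 | uniform |
| Adelta | 0.8 | 0.4 | 0.1 | 2.4 | uniform |
| C | 3.0 | 1.5 | 0.5 | 5.0 | superficial + deep biased |
| PD | coupled | — | — | 1.5 | deep biased |

Rheobases sit strictly between adjacent tested amplitudes so the
discrete ascending series {0.1, 0.5, 1, 5, 10} mA shows detection
thresholds at 0.5 / 1 / 5 mA; the slopes are small enough that the 1 %
clamp silences every class at 0.1 mA. The per-channel mean evoked counts
were calibrated once, a priori, so that array-summed responses at the
standard amplitudes land in the few-tens-of-spikes range reported for
in-vivo recordings of this preparation (e.g. a C-band sum near 30 spikes
per 5 mA stimulus). C-fibre depth weights are 2.2 (superficial), 1/6
(intermediate), 1.2 (deep) per channel, normalized to sum to the channel
count; post-discharge weights are 0.8 / 0.6 / 10/7.

**Post-discharge** is its own Poisson process in [300, 800) ms whose
rate is coupled to the mean of the Adelta and C recruited fractions — it
reflects network excitability driven by both nociceptive inputs — and it
inherits the C class's drug sensitivity. The empirically reported
U-shaped amplitude response and inverse duration profile of
post-discharge have no mechanistic specification and are *not*
reproduced by defaults; this is a documented limitation.

**Wind-up** multiplies the evoked mean by `1 + beta * min(i, cap)` for
stimulus index `i` in trains at >= 0.5 Hz (beta: C 0.15, PD 0.2, cap
10); the gain is exactly 1 at 0.1 Hz and below. Ongoing background
(default 2 Hz per channel, homogeneous Poisson) grows analogously inside
0.5 Hz trains (beta 0.03), emulating the rise in pre-stimulus activity.

**Morphine** multiplies each class's evoked mean by
`1 - A * (1 - exp(-(t - delay)/tau))` per region: C is suppressed in all
regions (A 0.8, delay 5 min, tau 10 min), Adelta in superficial and deep
only (A 0.5, delay 10, tau 20), Abeta in deep only and weakly (A 0.15,
delay 60, tau 20). Background firing is unaffected.

**Natural stimuli** are region-level rate envelopes on a 10 ms grid:
von Frey contact/release transients in all regions scaling with the log
of the hair weight, sustained drive gated by region thresholds
(intermediate 2 g, deep 6 g, superficial 26 g) with after-discharge
lengthening with weight; thermal contact transients independent of
temperature plus, for >= 50 C, a late ramp in superficial and deep
regions; capsaicin as a ~30 s broad activation with a delayed deep
component near 2 min. These envelopes reproduce qualitative regional
selectivity, not quantitative firing rates.

**Determinism.** All randomness flows from a single master seed;
per-animal sub-seeds derive via `SeedSequence.spawn`, so cohorts are
bit-reproducible and animals are independent.

**What the simulator does not emulate**: electrode drift, spike-waveform
shape and overlap, refractoriness, correlated (non-Poisson) firing,
conduction-distance latency jitter, somatotopic variation. Passing tests
therefore demonstrate that the pipeline computes its statistics
correctly and recovers parameters from data with the assumed structure —
not that the assumed structure captures every property of real
recordings.

## Recruitment fitting

`RecruitmentModel` fits `R(I) = R_max * logistic((I - I_th)/s)` by least
squares to band sums over an amplitude series. With only five test
amplitudes the slope `s` is effectively unidentifiable, so it is fixed
at the known acquisition value by default (a free-slope fit is
available). The fitted `I_th` converts to rheobase through the Weiss law
given the chronaxie. Starting values come from the half-maximum crossing
of the observed series; bounds keep `I_th` within twice the largest
tested amplitude. Recovery precision differs by class: the Abeta
threshold (0.32 mA) sits between 0.1 and 0.5 mA where the series has a
single, nearly saturated transition point, so single-series estimates
are noisy; the acceptance-level check is the median over 20 simulated
series, which recovers all three rheobases within 20 %.

## Statistical calibration and test sizes

The paired t and permutation tests are verified to hold their nominal
5 % type-I error over 10,000 simulated null cohorts of 8 animals (the
permutation test runs exhaustively there, 256 sign patterns, so its
achievable p-values are multiples of 1/128). End-to-end checks use
4-animal cohorts of 20-stimulus trains — the study sizes the protocols
describe — and fixed seeds; simulation problem sizes throughout the
suite were chosen so the full run completes in well under a minute.
Where a check concerns an *expectation* of the simulator (the zero slope
of 0.1 Hz series), the test pools several seeds rather than judging one
4-animal draw against a 95 % interval whose failure rate on a true null
is 5 % by construction.

## Known limitations

- The detector's threshold rule is one reading of an under-specified
  convention; absolute-voltage or SD-multiple rules would need a one-line
  extension of `DetectionSpec`.
- Band edges must align with bin edges; non-integer alignments are
  rejected rather than prorated.
- The CLI covers the standard workflows; cohort-level statistics
  (paired tests across animals) are library calls, since they need
  multiple recordings in memory.
- Plotting is out of scope: matrices export as CSV for any plotting
  tool.
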