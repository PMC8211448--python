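# Methods

This note documents the model implemented by `dsgc_occlusion`: its
assumptions, the parameters that matter (with defaults and the reasoning
behind them), what the synthetic data do and do not emulate, and the
numerical choices made where the design was genuinely open.

## The population model

Two mosaics of On-Off direction-selective ganglion cells (DSGCs) tile a
patch of retina: a *with-motion* subtype whose preferred direction is the
bar-motion axis (0°) and an *against-motion* subtype preferring the opposite
direction (180°). Each subtype is an independent lattice in which successive
horizontal and vertical nearest-neighbor distances are N(39, 16²) µm draws
(non-positive draws rejected so ordering stays monotone); each row draws its
own horizontal offsets and each column its own vertical offsets, so both
axes' spacings are i.i.d. samples of the stated law. With 1000 cells per
subtype this yields an array of roughly 1.9 × 1.0 mm, centered on the
occluder position (1800, 800) µm so that the occluder sits approximately in
the middle of the array. Preferred directions get uniform jitter of ±14.1°
around the subtype axis. Receptive-field (RF) widths are 1.25 × N(88, 14.8²)
µm — the 1-SD radius of a Gaussian RF center profile.

**Label displacement.** The spiking RF of a DSGC is displaced toward its
*preferred side* — the side a preferred-direction stimulus enters first,
i.e. opposite the preferred-direction vector. Decoder position labels are
therefore `label = soma − f·rf_width·unit(preferred_direction)` with
`f = 0.5` by default (the displacement magnitude is a free parameter; half
an RF radius ≈ 55 µm). This sign convention is load-bearing: it is what
places the labels of the cells that fire at an occluder's exit right at the
exit itself.

## Single-cell responses

A cell's trial-mean response to the moving edge is a rectified sine:
amplitude = peak firing rate, half-period = response duration, phase set by
the onset time. Onset offsets (relative to the edge crossing the cell's
position label) follow a four-parameter beta law, default Beta(3, 3) scaled
to [−0.30, +0.30] s; durations follow the linear onset→duration relation
`d = 0.90 − 0.5·onset + N(0, 0.1²)` s floored at 0.05 s. At 330 µm/s the
typical response therefore lasts ~0.9 s — the time the edge needs to cross
an RF — and the *population* of active cells trails the edge by about half
a response, ~150 µm. That lag is the dominant full-field decoding error
(~5 µm per % of a degree; see below) and is a property of causal responses,
not a bug: a cell can only report where the edge was, weighted over its
response.

Direction tuning is a normalized Gaussian, `gain = exp(−Δ²/2w²)`, where `w`
is the angular deviation `sqrt(2·CV)` of a circular variance CV drawn from
N(0.25, 0.08²) truncated to (0, 1) — about 40° — applied multiplicatively to
the peak rate. Cells more than 90° from the motion direction are silent.
Peak rates are gamma stand-ins (shape 4; full-field mean 40 Hz,
occlusion-null mean 20 Hz), constrained only by positivity and the
preferred > null ordering.

**Speed scaling.** Onset scatter, latencies and durations are rescaled by
(330/speed): the response keeps a fixed spatial footprint, which is what the
duration power law `(speed/330)^−1` expresses. An additive onset-vs-speed
line is available in the config (`onset_slope_s_per_ums`) but defaults to
zero — travel time is already accounted geometrically, and a constant
additive shift would make cells at 2640 µm/s respond hundreds of µm before
the edge reaches them.

## The occluded run

The occluder is a 220 µm disc fixed at (1800, 800) µm. The edge is hidden
while it traverses [x_c − 110, x_c + 110] µm. The response logic is
one-dimensional along the motion axis (`occlusion_geometry="band"`; a strict
2-D footprint rule is available as `"disc"`):

* **Truncation at entry.** Responses still running when the edge disappears
  are cut off at that instant — the hidden edge no longer drives anyone, and
  a response outlasting its own RF sweep by the full occluder transit would
  contradict the duration ≈ RF-crossing relation above.
* **Emergence burst.** Cells of either subtype whose RF covers the exit
  point (|label_x − x_exit| ≤ rf_width) respond when the edge re-appears:
  with-motion cells with a preferred-direction transient, against-motion
  cells with the null-direction transient driven by partial activation of
  the preferred side of their displaced RF. Because labels are displaced
  toward the preferred side, both groups' labels center exactly on the exit:
  the coincident firing is a spatially localized mark of the interruption.
* **Kinetics.** Emergence-locked transients use their own onset→duration
  line (`d = 0.25 − 0.5·latency + N(0, 0.04²)` s, ≈ 0.22 s — the edge
  crosses the exposed RF remainder quickly) and a latency beta
  Beta(1.5, 2.5) scaled to [0, 0.15] s (mean ≈ 56 ms). The 125 ms
  coincidence-detection window is the model's event timescale: transients
  much slower than it would smear the coincidence it is designed to catch.
  With-motion cells whose natural onset was hidden are treated as *primed*
  (the edge had already crossed part of their RF): they relaunch with their
  residual onset scatter clipped at the emergence instant, so a fraction
  fires immediately. Cells whose hidden onset has no RF coverage of the exit
  missed the edge entirely and stay silent.

## Spike generation

Rates are discretized at 10 ms. Where a cell has evoked drive, the count per
bin is Gaussian with mean rate·dt and constant sub-Poisson variance 0.4,
clipped at zero and rounded. The constant-variance contract refers to the
pre-integerized draws at means well above the rectification floor;
rectification at small means emits occasional counts at the rising and
falling edges of a transient — a property of the stated law that the
simulation keeps. Baseline firing is a separate Poisson process
(`counts ~ Poisson(baseline·dt)`): integerizing a Gaussian around a
near-zero mean would produce ~0.2 counts/bin regardless of the configured
baseline, which would make the 0–0.1 Hz baseline regime meaningless.

## Decoding

The labeled-line (population-vector) estimate per 10 ms bin is

    x̂ = Σᵢ rᵢ x̃ᵢ / wᵢ²  ÷  Σᵢ rᵢ / wᵢ² ,   x̃ᵢ ~ N(xᵢ, wᵢ²),

with rᵢ the observed rate (counts/dt), xᵢ the position label (µm) or
preferred direction (deg) and wᵢ the RF width or tuning width. Label noise
is redrawn per bin by default (config: frozen per trial). Direction
estimates average unit vectors and read the angle from the resultant, which
behaves correctly when the 0° and 180° populations fire together. Bins with
no spikes have no estimate and are excluded from error statistics (the
exclusion count is logged on the trace).

Paired experiments share mosaics and parameter draws between full-field and
occluded runs. Errors are pooled across the trials of all blocks per time
bin; the windowed summary is the time average of per-bin RMSE over the
125 ms after the edge clears the exit. The percent decrease is
`100·(RMSE_ff − RMSE_occ)/RMSE_ff`; absolute decreases are also reported in
degrees of visual angle with a configurable retinal magnification (default
31 µm/°, an assumption — the conversion is not part of the model).

At 330 µm/s the mechanism yields a full-field windowed RMSE of ~150 µm
(the half-response lag) against an occluded windowed RMSE of ~35–40 µm
(burst localized at the exit), a ≈75% reduction; at 2640 µm/s the edge
leaves the burst behind within the window and the reduction falls to
≈40–47%. The residual occluded error has two floors: label-noise scatter in
the sparse first ~30 ms after emergence (latency means no information
arrives instantly) and the drift of the true edge away from the
exit-centered burst later in the window. Numbers in this paragraph are the
outputs of `scripts/acceptance.py` at the stated problem sizes.

## Coincidence detection

The monitored signal is the summed rate of against-motion cells within one
occluder diameter (220 µm) of its center. A difference-of-Gaussian (DoG)
temporal filter is fit by bounded least squares to the trial-averaged
occlusion transient on a time base referenced to the emergence instant.
The fit is DC-balanced by construction (equal center/surround areas, both
SDs bounded inside the ±0.5 s support): an unconstrained fit to a bump
degenerates to a pure Gaussian, and an unbalanced filter's output lacks the
negative lobes that let a 125 ms window isolate the event. Scoring is
matched filtering — the rate is correlated with the taps — so the output
peaks *at* the event (a delta input returns the time-reversed filter).

Detections are events: contiguous above-threshold runs of the score. On
occlusion trials an event overlapping the 125 ms window centered on the
emergence is the correct detection; events entirely outside it are false
alarms. On full-field trials every event is a false alarm. Sweeping the
threshold over the per-trial score extrema (plus pooled quantiles) yields
the ROC; AUC is trapezoidal; the reported accuracy is the occlusion-trial
hit rate at the threshold maximizing Youden's J (ties broken toward lower
false-alarm rates). At baselines ≤ 10 Hz the detector is essentially
perfect (accuracy 100%, AUC ≈ 1.0 at 100+100 trials per level); at 50 Hz
baseline the outside-window noise floor overwhelms it and the AUC collapses
— under this false-alarm convention a failed detector scores below 0.5
because the outside-window exposure is ~50× longer than the window.

## Spike/imaging metrics

PSTHs use 25 ms bins. Onset detection: first bin exceeding baseline + 4 SD
followed by a second such bin; offset: the same scan run backwards with a
2-of-3 rule. Baseline rate follows the recording convention (max rate in a
silent period per repetition, averaged); baseline SD is the per-bin SD over
the baseline interval pooled across trials — the SD estimator is not pinned
down by the source procedures, and this choice is exposed. The
rectified-sine fit is bounded least squares seeded from the detectors.
RSI = (Max − Opp)/(Max + Opp). Tuning statistics are resultant-vector based:
DSI = resultant length, circular variance = 1 − DSI, angular deviation =
sqrt(2·CV); the preferred angle is NaN-flagged when responses are uniform.
QI = Var_t[mean response] / mean[Var_t[response]] with the ≥ 0.45 quality
gate; ΔF/F0 uses a one- or two-term exponential baseline fit to intersweep
samples and a 4-sample sliding average.

## Synthetic data: what it does and does not emulate

The generators produce exactly the structures the analysis consumes —
rectified-sine spike trains with the stated count noise, Gaussian-tuned
direction responses, bleaching fluorescence with known transients — with
the ground truth embedded. The synthetic trial generator caps the count
variance at its Poisson ceiling at sub-variance means so that silent-edge
bins do not emit counts; real recordings additionally contain bursting,
adaptation, serial correlations and non-stationary baselines that none of
these generators attempt. Passing round-trip tests therefore demonstrates
the correctness of the analysis implementations, not their robustness to
every pathology of real data.

## Problem sizes and determinism

Default experiment scale is 100 blocks × 10 repetitions; the acceptance
script runs 20 × 10 for the single-speed comparisons, 10 × 10 per speed for
the speed sweep, and 100 + 100 trials per baseline level for the ROC —
sizes at which the reported quantities are stable to a percent-level across
seeds. All randomness flows through `numpy.random.SeedSequence` spawning
(master seed → block → trial), so every result is bit-reproducible for a
given seed and adding repetitions never perturbs earlier draws.

## Known limitations

* Only the On response to a bright leading edge is modeled; no Off-pathway,
  membrane-potential or conductance modeling.
* Motion is fixed along +x; the occlusion logic is one-dimensional along
  the motion axis by default.
* Several response-kinetics parameters (onset betas, duration lines, speed
  fits, peak-rate distributions) are stand-ins with documented defaults,
  all config-exposed; conclusions that hinge on their exact values should
  be re-checked under the user's own calibration.
* The full-field position decrease during the emergence window measures
  ~75% at the default calibration — the localized-burst mechanism is
  robust, but the exact percentage depends on the emergence-latency law.
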