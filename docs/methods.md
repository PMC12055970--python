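# Methods

`needlecav` quantifies cavitation activity around spring-loaded core-needle
biopsy (CNB) devices from two co-registered measurement streams: high-speed
shadowgraphy video of the needle tip and a calibrated hydrophone pressure
trace. This note describes the models, estimators, numerical choices and
known limitations; it is the companion to the API documentation in the
module docstrings.

## Measurement model and time axis

Both streams carry a trigger reference defining `t = 0` on a shared axis:
frame `k` maps to `(k − k_trigger)/frame_rate`, sample `j` to
`(j − j_trigger)/fs`. Defaults mirror the recording configuration the
package targets: 384×288 px frames at 100,000 frames/s with a 25 µm/pixel
optical scale and 0.357 µs exposure, and a 100 kHz hydrophone channel.
With this convention the firing events of interest (device-internal
collisions, the abrupt stop, bubble activity) appear at positive
trigger-aligned times of order 10–30 ms.

## Projected bubble area (optical side)

Shadowgraphy renders the needle and any vapour bubbles dark against a bright
backlight. The area estimator follows the classic binarise-and-subtract
chain:

1. each frame is binarised; dark pixels are those at or below a threshold
   computed once (Otsu on the first rest frame, or a fixed level) and then
   held fixed for the whole sequence, so the appearance of bubbles cannot
   shift it;
2. a needle-at-rest reference mask is the pixelwise majority vote of the
   binarised rest frames; its dark-pixel count `K_rest` is the reference;
3. the projected bubble area in frame `k` is
   `max(0, K_dark(k) − K_rest) · p²`, with `p = 0.025 mm` the pixel pitch
   (0.000625 mm² per pixel). Negative differences are clamped to zero and
   counted in a QC field.

The subtraction rule is deliberately literal: while the needle moves, pixels
of the *displaced* needle are counted as "bubble" area, which biases the
estimate upward (the bias is visible in the literal series of the example
reports). The package therefore also provides a needle-exclusion mode:
per frame, dark connected components touching the top frame edge are
classified as the needle (the shaft always enters from above) and removed;
the remaining dark pixels are bubbles. The exclusion mode is unbiased under
needle motion as long as bubbles do not touch the silhouette, and the
pipeline reports both series, using the exclusion mode for its headline
maximum. Bubbles overlapping the needle cannot be separated by either mode;
the synthetic generator refuses such scenes by default for that reason.

Event summaries report the maximum area, its time, and the duration — the
total time the area exceeds a configurable threshold, 0 mm² by default
(any nonzero area counts). Replicate ensembles (typically N = 9 from 3
devices × 3 technical replicates) are aggregated pointwise on a common time
grid as mean and sample standard deviation (denominator N−1).

### Rasterisation versus analytic truth

The synthetic generator records two ground truths per frame: the analytic
ellipse area `π·a·b` (reduced by the clipped fraction when an event crosses
the frame edge) and the rasterised truth, the count of pixels with more than
half their area covered, times `p²`. Pixel counting of a disk genuinely
differs from `πr²` by a lattice term (for an aligned 0.2 mm circle the
discrete count is 208 px vs `πr² = 201.1` px); this is a property of any
pixel-count estimator, not an implementation error. Accuracy tests
therefore compare the estimator against the rasterised truth (agreement
within 2 pixel-areas per event on noiseless scenes) while end-to-end
recovery is stated against the analytic truth at the percent level, where
the lattice term is negligible. Under the default intensity noise,
boundary-pixel flips add a per-frame fluctuation of a few pixel-areas whose
mean over an event lifetime is near zero.

## Needle-tip kinematics

Trackable features are ranked by the minimum eigenvalue of the local
gradient structure tensor (Shi–Tomasi cornerness, `skimage`), with a
deterministic ordering (score, then row, then column). Tracking is a
pyramidal Kanade–Lucas–Tomasi implementation: at each of 3 pyramid levels
(Gaussian smoothing, factor-2 decimation) the displacement of a 15×15
window is the iterative least-squares solution of the optical-flow normal
equations, refined coarse-to-fine (30 iterations, 0.01 px convergence).
A point is invalidated when the normal matrix is ill-conditioned, the
window's residual RMS exceeds a bound, or the point leaves the frame;
coarse levels whose window would leave the image are skipped rather than
failing the track. The tracker is fully deterministic. Against a
brute-force integer-shift SSD search it agrees within 0.5 px; on noiseless
rigid translations it is exact to better than 0.1 px/frame.

Displacement is converted to millimetres (y = +columns, z = −rows, i.e. up)
relative to the first tracked frame, with a positional uncertainty of about
one pixel (25 µm). Velocity and acceleration are central finite differences
(second-order one-sided at the series ends), applied after a 5-frame
moving average of the displacement by default: double-differencing 25 µm
quantised positions at 100 kHz amplifies pixel noise to ~10⁵ m/s² without
smoothing. The smoothing descriptor is recorded in every output. The
smoothing window passes 2 kHz flexural content essentially unattenuated
(<2%) but does clip the apparent peak velocity of motions with a velocity
*discontinuity* (an idealised instantaneous ring-down onset) by ~10%;
parameter-recovery experiments therefore use profiles with a short (0.3 ms)
differentiable onset.

Motion events: threshold crossings of per-axis |velocity| in both
directions, and a stop time defined as the instant of maximum deceleration
magnitude after the peak speed.

## Acoustics: calibrated SPL spectrograms

Hydrophone traces are kept in pascal end-to-end (WAV fixtures store 32-bit
float pascal, sensitivity 1, since no calibration chain is modelled).
`band_spl` is `20·log10(p_rms / 1 µPa)`; exact silence maps to a −20 dB
sentinel floor, below any physical level here.

The spectrogram is a short-time Fourier transform with a 2560-sample window
and 2500-sample overlap (Δf = 39.0625 Hz, hop 60 samples = 0.6 ms at
100 kHz), Hann window by default. Two scalings are offered:

* **band** (default): power-spectrum scaling with the window's coherent
  gain compensated, so a bin-centred pure tone's peak bin reads the tone's
  true band SPL (verified to 0.001 dB for a 56.23 Pa rms tone ↔ 155.0 dB);
* **density**: PSD scaling for energy accounting; summing bins times the
  bin width recovers the time-domain power within 1% (Parseval check).
  Levels differ from the band convention by `10·log10(ENBW)`.

Multiplying a trace by 10 raises every (nonzero-power) bin by exactly 20 dB,
and the trigger sample maps to the `t = 0` bin within half a hop.

### Broadband bursts

A burst is a time bin in which at least half of the frequency bins exceed
their per-frequency running median by 12 dB; adjacent qualifying bins merge
into one event timed at the peak of the median broadband excess. These
thresholds are artifact choices validated on synthetic fixtures — the events
this emulates are identified visually in practice. One resolution caveat
matters: the 25.6 ms display window smears millisecond bursts spaced 5 ms
apart into a single qualifying plateau with no interior maxima, so *burst
detection* runs on a dedicated short-window spectrogram (512 samples /
448 overlap, 5.12 ms, Δf ≈ 195 Hz). With that window the detector recovers
three side-cut-like and two front-cut-like injected bursts exactly, with
times within 0.3 ms, across all tested seeds. The calibrated 2560/2500
spectrogram remains the display and level reference.

### Ringing ridges

Persistent narrowband components (needle eigenfrequency ringing, typically
10–30 kHz, outliving the bubbles) are detected as frequency bins whose SPL
stays 10 dB above the per-time-bin median across frequency — a background
estimate robust to narrowband excess — for at least 20 ms; adjacent bins
with overlapping runs merge into one ridge reported at its strongest bin
with onset and persistence. White noise produces no 20 ms ridges at these
settings.

## Hydrodynamic characterisation

For a needle shaft (14 G, outer diameter L = 2.109 mm) moving laterally at
speed `u` through fluid at rest:

    Ca = (p − p_v) / (½ ρ u²),      Re = u L ρ / µ = u L / ν.

Low `Ca` favours cavitation inception (a cited wedge-bluff-body inception
value of 4.8 is kept as a comparison constant). Flow-regime classification
follows the bluff-body transition picture: laminar below Re = 49, Karman
vortex transition for 49 ≤ Re ≤ 190 (both boundaries implemented closed),
fully turbulent above. Default fluid constants are water at 20 °C
(ρ = 998 kg/m³, µ = 1.0 mPa·s, p_v = 2339 Pa, p = 101 325 Pa), all
overridable. For agarose phantoms only a kinematic viscosity of
5×10⁻⁶ m²/s is reported in the literature for a 0.9% w/v gel; the package
applies it to the 1.0% medium and uses an interpolated 2×10⁻⁶ m²/s for
0.3%, so the gel Reynolds numbers are indicative, not measured. The
pipeline evaluates Ca and Re at the measured peak lateral tip velocity of
each experiment with the medium's constants.

## The synthetic-data generator

The generator emulates the *structure* of the recordings, not bubble
physics (no Rayleigh–Plesset dynamics; events are prescribed, not
emergent):

* **Needle silhouettes** are filled polygons: a lancet-point stylet plus a
  bevelled outer cannula for the side-cut geometry, a Franseen (crown)
  cannula for the front-cut geometry. Rendering uses 4× supersampled
  coverage so edges carry sub-pixel information for the tracker.
* **Motion** is programmable; the default firing stroke is a smooth start,
  constant-speed travel and a hard stop, plus a damped lateral ring-down
  starting at the stop. Defaults: stop at t = 25 ms (side cut) / 26 ms
  (front cut), 2 mm longitudinal travel (scaled so the tip stays in the
  7.2 mm field of view; real strokes are an order of magnitude longer),
  ring-down of 0.6 mm at 2 kHz giving a ≈7.5 m/s peak lateral velocity for
  the side cut, within the 7–10 m/s band of interest, and a ≈0.05 mm
  ring-down (<1 mm lateral excursion) for the front cut.
* **Bubbles** are elliptical clouds with analytic areas: the side-cut
  ensemble peaks at ≈3.5 mm² and persists 0.84 ms after the stop, the
  front-cut pair at ≈0.5 mm² for 0.25 ms, and the "1.0% agarose" condition
  injects none. Bubble–needle overlap is rejected by default (see above).
* **Intensity model**: 8-bit, background ≈220, needle/bubbles ≈30,
  Gaussian noise SD 5 — the dark margin exceeds 5 noise SDs, so Otsu
  binarisation is unambiguous by construction.
* **Audio**: Gaussian noise floor (0.05 Pa rms), Hann-enveloped band-limited
  (1–45 kHz) noise bursts of 0.8 ms scaled to a prescribed in-window RMS at
  prescribed times (0.015/0.020/0.025 s side cut; 0.020/0.025 s front cut),
  and exponentially decaying ringing tones placed bin-centred in the
  10–30 kHz band starting at the stop.
* **Determinism**: one integer seed drives all draws through a single
  generator; identical seed ⇒ bit-identical frames and samples. Fixture
  bundles (multi-page TIFF, float WAV in Pa, ground-truth JSON) carry a
  SHA-256 manifest and round-trip exactly.

What passing tests on these fixtures does **not** show: robustness to real
shadowgraph artefacts (illumination gradients, motion blur at finite
exposure, out-of-plane bubbles, needle glint), to bubbles overlapping the
needle, or to hydrophone colouration; and the agarose media enter only
through fluid constants, not through mechanical bubble suppression.

## Problem sizes and runtime choices

The default end-to-end scene is 0.03 s at 100 kfps (3000 frames of 384×288)
with a 0.1 s audio trace — about a minute to render and ~15 s to analyse on
one core. Unit tests use sub-millisecond clips; the replicate-ensemble
analysis renders 9 firings per needle type. The acceptance script uses
closed-form inputs and a 10-frame scene, and runs in seconds.
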