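# Methods

This note documents the models, parameter choices, and numerical
conventions behind `hemoccl`, and what its synthetic tests do and do not
establish about real data.

## The occlusion model

A vessel of cross-section `A(t)` between (or near) the focal plane and
the objective attenuates measured fluorescence. We linearize the
underlying absorption (Beer–Lambert) in the relative cross-section
change:

    f(t) = clamp(1 − k · (A(t) − A₀)/A₀,  0.05, 20)

with `A₀` the resting cross-section and `k ≥ 0` a dimensionless gain.
Dilation (`A > A₀`) darkens the measured signal, constriction brightens
it. The measured soma fluorescence is `F_meas = F_true · f`. The clamp
bounds are a numerical guard, not a physiological claim; whether
occlusion saturates at large dilations is unknown, and the default
scenes never approach the clamp.

Vessel dynamics are kernel-driven: each event type (locomotion onset,
grating, mismatch, opto) has a signed kernel `a·(1−e^{−t/τ_r})e^{−t/τ_d}`
normalized so its discretized peak equals the amplitude `a` (fractional
cross-section change). Defaults — locomotion −10% (constriction, as in
frontal cortex), grating/opto +8% (dilation, as in visual cortex),
mismatch +4%, τ_r = 0.5 s, τ_d = 1.5–3 s — are chosen to produce a few
percent ΔF/F₀ at the default gain `k = 0.5`, the magnitude regime the
analysis is designed to detect. The kernels convolve an impulse train at
event onsets; `A(t)` is floored at 5% of `A₀` (with a logged count) if a
pathological configuration would drive it non-positive.

Geometry: light collected from a neuron at depth `d` through a cone of
half-angle θ passes a surface circle of diameter `2·d·tan θ` (1 mm at
500 µm and 45°, the regime where many surface vessels can contribute).
With a 60 Hz resonant scanner stepped over 4 piezo planes, each plane is
sampled at 15 Hz — the trace sampling rate used throughout.

## The synthetic scene

Behaviour is a two-state semi-Markov process: exponential dwell times
(means 20 s stationary, 15 s locomoting), per-bout target speeds
~N(10, 2.5²) cm/s, 0.5 s linear ramps, Gaussian smoothing (σ = 0.2 s)
and mild within-bout speed jitter. The running-speed statistics are this
package's choice; only the threshold semantics (0.25 cm/s) are
protocol-fixed. Visual flow equals running speed in closed loop (zeroed
during mismatch halts), is a half-session circular shift of it in open
loop, and is zero in darkness. Mismatches (1 s) are placed only where
speed stays ≥ 0.25 cm/s throughout the −0.5…+1 s validity window, so
generated events are valid by construction; gratings (2 s) recur every
~8 s with jittered gray gaps.

Rendering: a frame is neuropil background (30 photons/px) plus soma
disks (radius 7 µm, baseline ~120 photons/px with lognormal spread,
times the occlusion factor) and the vessel lumen, blurred by a Gaussian
PSF proxy (σ = 1 px), Poisson noise at a configurable photon scale, and
optional integer-pixel rigid jitter. The vessel is a filled ellipse of
fixed centre/orientation and time-varying area with (i) an analytic
antialiased edge and (ii) a radial darkening profile (dark core
brightening toward the wall, `1 − ρ⁴` weighting). Both matter: with a
hard binary edge, sub-pixel area changes alias into intensity
staircases, and the thresholded core collapses to degenerate
few-pixel blobs; the gradient makes the iso-intensity core scale with
the true cross-section, which is what makes the 0.5th-percentile
segmentation informative on noise-free scenes.

Ground truth (cross-section, per-soma attenuation and fluorescence,
injected shifts, geometry) is stored losslessly beside the stack; a
noise-free re-render from it reproduces the stack bit-identically.

What the generator does **not** emulate: slow drift of expression or
focus, z-motion, oxygenation-driven (volume-independent) absorption
changes, non-rigid deformation, multiple interacting vessels, realistic
PSF anisotropy, or genuine neuronal activity. Passing tests therefore
show that the analysis chain measures what the forward model injects —
they calibrate the machinery, not the biology.

## Processing conventions

- **Registration**: integer-pixel shift maximizing the overlap
  cross-correlation of mean-subtracted images within a ±5 px search
  radius; ties broken by smallest Euclidean shift, then
  lexicographically; vacated pixels filled with the frame median.
  Sub-pixel registration is out of scope for the synthetic contract.
- **Traces**: plain pixel means per ROI; no neuropil subtraction.
- **Drift**: 8th-percentile moving filter, 66 s window (62.5 s for the
  widefield variant), centred and truncated at the edges; the window is
  forced to an odd frame count so centring is exact. The baseline is
  subtracted and its mean re-added, so the absolute scale — and hence
  the median F₀ — remains meaningful; ΔF/F₀ = (F_c − F₀)/F₀. Whether
  the original protocol subtracted or divided the baseline is not
  specified; subtraction with scale restoration is this package's
  documented choice, and ΔF/F₀ is invariant to global gain either way.
- **Frame/time mapping**: frame `i` covers `[i/rate, (i+1)/rate)`;
  second-valued windows map to half-open frame ranges
  `[⌊t₀·rate⌋, ⌊t₁·rate⌋)`.
- **Onsets**: speed ≥ threshold at the onset frame and for the whole
  following 1 s, strictly below for the whole preceding 1 s. Boundary
  equality at the threshold counts as "above" (the protocol does not
  specify). The rule needs no extra refractory period. Note the often-
  assumed monotonicity — higher threshold ⇒ fewer onsets — holds for
  clean single-crossing bouts but not for arbitrary traces (a trace
  hovering just above a low threshold has no onsets, while a higher
  threshold can create a valid below-period first); the test suite pins
  the property on bout-structured traces only.
- **Responsiveness**: ≥ 3 complete trials; per-trial baselines −0.5…0 s
  (−1…−0.5 s for locomotion, avoiding preparatory activity); response
  windows +0.5…+1.5 s (locomotion/mismatch) and +0.5…+2.5 s (2 s
  gratings); a second profile (0…+2 s and +0.5…+3 s) reproduces the
  indicator-comparison windows. Two-sided one-sample t-test at
  α = 0.05, no multiple-testing correction (fractions are compared to
  the nominal 0.05 chance line). Zero-variance trials with nonzero mean
  are reported maximally significant.
- **Random triggers**: drawn uniformly without replacement from frames
  satisfying the mismatch validity rule, excluding ±1 s around true
  mismatches; the trigger count defaults to the session's valid
  mismatch count. The 95% band is the per-bin 2.5–97.5 percentile over
  ≥ 40 repetitions of the population average.
- **Hierarchical bootstrap**: sites drawn with replacement (observed
  count), then neurons within each drawn site (that site's own count —
  preserving per-site sample sizes; the alternative of a pooled count is
  not used). Two levels only; trials are averaged per neuron before
  resampling. N = 10,000 for tests, 1,000 for plotted curves. The SE
  band is the 15.8–84.2 percentile interval (≈ ±1 SD, 68% mass);
  condition comparisons use independent resampling per condition and
  per-bin two-sided sign-fraction p values `2·min(P(Δ≤0), P(Δ≥0))`,
  floored at 1/N, masked at p < 0.01 without across-bin correction.
  With a single site the scheme reduces exactly to the ordinary
  bootstrap, which is also the vectorized fast path.
- **Vessel area**: one global threshold — the 0.5th percentile of all
  pixel intensities of the cropped trial-averaged video — binarizes
  every frame (strictly below); 8-connected components; largest
  component; moment-matched ellipse with the 1/12 square-pixel moment
  correction (so tiny or collinear components keep a well-defined area
  ≈ their pixel count); area = πab. Components touching the crop edge
  are flagged as possibly truncated; frames with no below-threshold
  pixels get area 0 with a warning. Note a degenerate case the strict
  inequality implies: on a perfectly uniform dark plateau the threshold
  equals the plateau value and nothing is "below" it — real (noisy or
  gradient-bearing) videos do not hit this.
- **Variance explained**: both series smoothed with a centred 0.5 s
  boxcar (odd frame count, edge-truncated), then R² = squared Pearson
  correlation, on the −2…+6 s peri-event window of trial-averaged
  signals or over the entire recording. Zero variance ⇒ missing (NaN).
- **Outliers**: Tukey fences at quartiles ± 1.5·IQR, display-level
  omission only — never applied before statistics.
- **State correlations**: frames classified per-frame at 0.25 cm/s with
  no hysteresis and no peri-transition exclusion (unspecified in the
  protocol); sites need ≥ 150 frames (10 s at 15 Hz) per state, a guard
  added here against unstable estimates. Pearson correlation on
  state-restricted concatenated frames; per-ROI mean over same-site
  pairings; zero-variance traces yield missing pairings.

## Problem sizes and determinism

Default test scenes are 64×64 px at 2 µm/px, 2–10 minutes at 15 Hz, 8
somata and one vessel — small enough that the full suite runs in well
under a minute while every stage operates above its minimum-trials and
minimum-frames guards. The calibration harness uses 20 sites × 50 ROIs
× 12 events for the type-I rate and 1,000 repetitions × 1,000 replicates
for bootstrap-band coverage, matching the study-scale design of those
checks. One root seed fans out to per-stage children through
`numpy.random.SeedSequence`; identical configurations are bit-identical
end to end.

## Known limitations

- The attenuation is single-vessel and spatially uniform per soma; real
  occlusion superposes many vessels with distance-dependent weights.
- The cropped-video 0.5th-percentile rule captures a fixed *total*
  budget of dark pixels across the video, so per-frame core areas are a
  relative, not absolute, cross-section measure; the fitted area is
  validated against ground truth by correlation, not equality.
- The open-loop replay is a circular shift of the same session's
  running, not an independently recorded session.
- CLI subcommands operate on single-site bundles; multi-site nesting
  enters through the `NestedSamples` container rather than the CLI.
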