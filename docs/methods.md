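# Methods

This note documents the models behind each module, the parameters that
matter, the numerical conventions, and what the synthetic generators do
and do not emulate. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Spectral analysis

Tremor-monitor and EMG traces are treated as uniformly sampled voltages.
The analysis chain is: offset removal (subtract the sample mean), bin
alignment, Hanning-window FFT, band sums.

**Bin alignment.** Acquisition rates rarely make FFT bins land on round
frequencies, so traces are resampled (linear interpolation) to the largest
rate `fs' ≤ fs` with `fs' = r · 2^k` for the target resolution `r`
(0.25 or 0.5 Hz). At the default 5000 Hz this gives 4096 Hz with
nfft = 16384 (0.25 Hz bins) or 8192 (0.5 Hz bins). Linear interpolation is
used because the original acquisition software's kernel is unspecified;
at these oversampling ratios the difference is far below the noise floor.

**Scaling.** Spectra are one-sided, Welch-averaged over non-overlapping
segments, and Parseval-normalized: the sum of bin powers equals the
mean-square of the signal to within the Hanning leakage error (≈1%,
asserted by tests). Absolute V² from an uncalibrated accelerometer is
meaningful only relatively; every comparison in this package is a
within-pipeline ratio, and no conversion to m/s² is attempted.

**Bands.** Alpha+beta is 8–19.5 Hz — a single combined band so a
drug-induced tremor peak near 12.5 Hz is never split across analysis
bands — and gamma is 20–30 Hz. Band intervals are closed; the DC bin is
always excluded because the offset is removed upstream. Segment averaging
uses no overlap; analysis windows of 25–120 s are typical.

**Peak detection** is the argmax bin in a band, ties broken toward the
lower frequency. **Sonograms** are short-time FFT power in dB re 1 V²
(`10·log10 P`), columns every `hop` samples.

## Spike-train statistics

The per-cell quantities are firing rate = count/duration (robust to
bimodal ISI distributions, unlike 1/mean(ISI)), CV, CV2, mean pre- and
post-complex-spike pauses, and the simple:complex count ratio. Recordings
shorter than 30 s warn rather than fail.

Simple-spike ISIs that span a complex spike are excluded from simple-spike
CV/CV2: the pause structure around complex spikes is quantified separately
(pre/post pause), and double-counting those intervals would conflate local
burst irregularity with the complex-spike relationship. Whether the
original acquisition-software scripts made the same exclusion is unknown;
it is a documented convention here. Pauses are averaged complex-spike by
complex-spike within a cell; the per-cell mean is the statistical unit.
The count ratio equals the rate ratio whenever both species span the same
recording.

**Outlier screen.** A simplified univariate ROUT-style procedure: robust
centre (median) and scale (normal-consistent MAD), two-sided t(n−1) tail
probabilities of the studentized residuals, and a Benjamini–Hochberg FDR
step at Q = 0.1%. t rather than normal tails are used because the MAD
scale estimate is noisy at small n; with normal tails, simulation showed
~5% of clean 15-sample Gaussian datasets acquiring a false flag, versus
≤1% required and observed with t tails. The commercial implementation's
internals are proprietary, so this screen is validated by simulation, not
by output matching.

## Optogenetic stimulation

Pulse trains are "sinusoidal": each on-pulse ramps 0 → max power → 0 as a
half-sine over one half-period (`500/f` ms), with an equal off gap, and
the train is flanked by one half-period of darkness on each side. A
raised-cosine pulse shape is available behind a flag. The half-period
table (1 Hz = 500 ms … 20 Hz = 25 ms) follows from the equal on/off rule;
a printed value of 166.65 ms at 3 Hz is treated as rounding of
500/3 = 166.67 ms.

**Light propagation.** Irradiance below the fiber tip combines conical
divergence with Kubelka–Munk-style scattering loss:

    I(z) = I₀ · ρ² / ((S·z + 1)(z + ρ)²),  ρ = r·√((n/NA)² − 1),
    I₀ = P/(π r²)

Defaults: core radius r = 0.1 mm and NA = 0.39 (catalog values for the
200 µm multimode fiber used for cerebellar implants), tissue refractive
index n = 1.36 and scattering coefficient S = 11.2 mm⁻¹ (standard mouse
brain-tissue values). All four are configuration, not constants. The
effective stimulation depth solves I(z*) = threshold (default 1 mW/mm²)
by bracketed Brent root-finding to 10⁻⁴ mm; I is strictly decreasing so
the root is unique. With these defaults the model places the 1 mW/mm²
contour at ≈0.8 mm for 3.6 mW and ≈0.3 mm for 0.43 mW. Monte-Carlo photon
transport, opsin kinetics and heating are out of scope.

## Closed-loop DBS simulation

The controller is a discrete-time state machine on the sample grid
(default 5000 Hz, where all protocol durations are whole samples):

* **Detector.** Band power 0–25 Hz (DC excluded; configurable) from a
  single 8192-sample Hanning periodogram of the most recent samples —
  1.6384 s of history, 0.6104 Hz bins — Parseval-scaled like the offline
  spectra so thresholds are comparable across the package.
* **Threshold** = the maximum windowed band power over the individual's
  baseline recording (hop = control tick).
* **Idle cadence.** The protocol re-evaluates "as close to real time as
  possible"; here the idle re-evaluation tick defaults to 4 ms
  (configurable).
* **Pulse train.** On a crossing: first pulse 1 ms later, pulses every
  8 ms (125 Hz). The train runs in 36 ms blocks; at the start of each
  block's final 8 ms inter-pulse gap (i.e. at the block's last pulse) the
  detector is re-evaluated once — check-once, not continuously, an
  interpretation the protocol text leaves open. Flag still up → another
  36 ms block; down → stimulation halts until the next crossing.
* Pulse micro-structure (biphasic waveform, µs timing, current) is
  metadata; at 5000 Hz the unit event is the pulse time.

The scheduler is verified against an independently written brute-force
reference on random detector-flag sequences, injected through a
`power_fn` hook.

**The plant.** Real closed-loop suppression acts through the animal; for
testing, a synthetic plant scales the tremor oscillation amplitude by a
gain g(t) that relaxes exponentially toward `floor_fraction` with time
constant `suppression_tau_s` while stimulation is on, and back toward 1
with `recovery_tau_s` while off (defaults 0.2, 0.2 s, 1.0 s). With
stimulation permanently off the plant output is sample-identical to the
raw generator output. The plant is deliberately phenomenological: it makes
no claim about DBS mechanism, and suppression results on it are
property-level (orderings, monotonicity), never value-matched to animal
data.

`evaluate_suppression` runs three phases — baseline (physiological-tremor
configuration; also sets the threshold), tremor (drug-like configuration,
controller off), closed-loop (same plant, controller on) — and normalizes
each phase's band power to the maximum across phases. Default phase
length is 90 s, covering the 80 s analysis windows the protocol quantifies
while keeping the default suite fast; tests that only need orderings use
40 s. One regime subtlety: once `floor_fraction` is low enough that
suppressed tremor falls below threshold, the loop toggles and holds band
power near the threshold, so dose-response in `floor_fraction` is strictly
monotone only above that regulation point and saturates below it.

## Synthetic data generators

All generators draw from `numpy.random.default_rng(seed)` with one
explicit integer seed per call; identical config + seed gives
byte-identical output. They define the study conditions the tests run
under:

* **Tremor traces** = 1/f-power-shaped Gaussian noise (physiological
  tremor spectra decay with frequency) + an amplitude-modulated sinusoid.
  Default sampling 5000 Hz (implied exactly by the 8192-point/1.6384 s
  detector specification). Baseline mode: 11 Hz peak, amplitude 0.01 V
  over a 0.02 V noise floor (weak peak, broadband-dominated). Harmaline
  mode: 12.5 Hz peak, amplitude 0.1 V (strong narrowband peak, the
  control+drug condition). Entrained mode: peak at the commanded stimulus
  frequency. AM depth 0.3 at 1 Hz adds the waxing-waning envelope of real
  tremor bouts. Not emulated: movement artifacts, non-stationary drug
  onset/washout, accelerometer calibration — so passing tests demonstrate
  pipeline correctness, not robustness to those real-data features.
* **Spike trains.** Tonic mode: simple-spike ISIs from a gamma renewal
  process (CV = shape^(−1/2)); defaults are the control-baseline operating
  point, 77.63 Hz with shape 1/0.4902² (CV 0.4902), plus complex spikes as
  an independent gamma(2) renewal process at 1.289 Hz. Bursting
  (drug-state) mode: each burst period (rate 2.876 Hz) opens with a
  complex spike followed by a Poisson-sized (mean 17) burst of simple
  spikes at irregular intervals, the last pinned exactly `pre_cs_pause_s`
  (default 46.51 ms) before the next complex spike. The pinning makes the
  recovered pre-complex-spike pause exact; the irregular intra-burst
  timing and variable burst sizes are what elevate CV above the tonic
  value, as bursting does in recordings — evenly spaced bursts at the same
  rates would paradoxically *lower* CV once pause intervals are excluded.
* **EMG** = inhomogeneous Poisson motor-unit impulses (base rate 100 Hz,
  sinusoidal rate modulation depth 0.8 at the tremor frequency) convolved
  with a biphasic Gaussian-derivative kernel (width 2 ms). Band power
  scales as kernel amplitude squared.
* **Puncta images**: disks (default 50, radius 4 ± 15% px on a 256 px
  field at 0.5 µm/px) over Gaussian background noise, with rasterized
  per-punctum areas, the union foreground fraction, and any deliberately
  overlapping pairs (`clump_fraction`) recorded as ground truth.

## Puncta quantification

Threshold: Otsu by default, with a fixed-level override — an automatic,
reproducible stand-in for the operator-set threshold of the original
workflow; hand-thresholded absolute counts are therefore not reproduction
targets. Watershed: seeds are local maxima of the lightly smoothed
distance transform (σ ≈ 0.15 × blob radius, minimum peak separation
≈ 0.5 × radius). These values were set by construction tests: touching
pairs at 1.5 radii centre distance must always split in two and single
disks must never split, across radii 3–10 px; heavier smoothing (e.g.
σ = half the radius) merges large pairs. Blobs whose seeds are lost keep a
connected-component label, so the watershed never undercounts relative to
connected components. Particle analysis counts particles whose centroid
lies inside the ROI polygon (boundary inclusive) with area ≥ 4 µm²
(single-pixel noise rejection; configurable). Density = count/ROI area;
coverage = Σ particle areas / ROI area × 100.

## Numerical conventions and degenerate inputs

* CV of a perfectly constant ISI sequence returns exactly 0.
* `normalize_to_peak` rejects all-zero inputs; `band_power` rejects bands
  outside the spectrum; empty label classes raise instead of returning 0.
* `effective_depth` returns 0 with a warning when the threshold is at or
  above the fiber exit irradiance.
* An empty mask yields zero watershed labels; a constant image cannot be
  auto-thresholded.
* Controller timing parameters must be whole samples at the configured
  rate; the segment must cover the first-pulse delay plus four inter-pulse
  intervals.

## Known limitations

The plant is invented test scaffolding, not a physiological model; group
statistics (ANOVA families, regression) are intentionally delegated to
standard statistical software; spike sorting and complex-spike detection
from waveforms are out of scope (labels are taken as given); light
propagation ignores photon scattering anisotropy and absorption beyond the
single effective S; absolute tremor power is uncalibrated by design.
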