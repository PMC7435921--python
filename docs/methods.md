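# Methods

This note records the models, estimator conventions and design choices
behind `vfegm`, in the spirit of the methods documentation of mature
scientific packages: what is computed, under which assumptions, which knobs
matter, and what the synthetic experiments do and do not demonstrate.

## Signals and windows

An analysis unit is a pair of simultaneously sampled voltage traces from the
left (LV) and right (RV) ventricle, uniformly sampled at `fs` (default
200 Hz, the rate of the emulated recording platform) and at least 6 s long.
Amplitudes are treated as uncalibrated: device amplifier gain differs
between patients and channels, so every downstream quantity is either
amplitude-invariant by construction (OI, LK, MI) or computed after explicit
normalization (unit-area spectra; z-scored signals for entropies).

Two analysis windows are used, half-open in time: W1 = [0, 3) s and
W2 = [3, 6) s. At 200 Hz each holds exactly 600 samples and the two windows
partition the first six seconds with no shared sample. Sample indexing is
0-based throughout.

## Welch spectrum

The power spectral density is the averaged Welch periodogram with
256-sample **rectangular** segments (maximum spectral resolution at the cost
of −13 dB sidelobes), 50% overlap (hop 128) and a 4096-point transform
support; a 600-sample window yields exactly three segments. The recording
mean is removed once, globally, before segmentation (no per-segment
detrending), and the one-sided spectrum is normalized to unit area,
`Σ P̂ₙ(f)·Δf = 1`, so spectra are comparable across gains. Two resolution
scales matter and are carried on the spectrum object: the grid step
`fs/4096 ≈ 0.049 Hz` and the effective resolution (mainlobe width)
`fs/256 ≈ 0.78 Hz`. `scipy.signal.welch` performs the computation; the test
suite checks it against an explicit segment-loop, direct-DFT-sum
implementation to 1e-9 relative error.

## Spectral parameters

All band-limited quantities use the 2–30 Hz analysis band (configurable).

* **DF** — frequency of the global in-band maximum of P̂ₙ.
* **MF** — in-band spectral centroid `Σ f·P̂ₙ(f) / Σ P̂ₙ(f)`.
* **f0 and harmonics.** Candidate peaks are local maxima that are (i) at
  least one mainlobe width apart — closer peaks are unresolvable at this
  window length and the larger one is kept — and (ii) above 2% of the
  in-band maximum, which rejects the rectangular window's sidelobes (≤1.6%
  of their parent peak in power). Candidate comb spacings are integer
  fractions of observed peak frequencies within [2, 10] Hz, restricted to
  spacings with a detected peak in their own fundamental slot (rejecting
  subharmonic octave errors). Each candidate is scored by summing, over
  harmonic slots k = 0..5 at targets (k+1)·f0, the power of the nearest
  peak within ±0.5·f0, weighted triangularly by its distance from the
  target: a peak counts fully only on-target, fading to zero at the slot
  edge. Without the weighting, a wrong spacing can collect the true peaks
  far off-center in its slots and win on sidelobe crumbs. Ties go to the
  smallest spacing. Harmonic k is then reported at the nearest qualifying
  peak, falling back to the grid bin at the target (the local floor) when
  no peak lies in the slot. No sub-bin interpolation is applied to peak
  locations: frequencies are reported on the 4096-point grid.
* **BW (75% bandwidth)** — walk outward from the peak bin until P̂ₙ first
  drops below 75% of the peak value on each side, with linear interpolation
  of the crossing; walks that hit a spectrum edge are flagged one-sided.
* **OI** — fraction of in-band power inside bands around the harmonic
  peaks, overlapping bands merged, out-of-band harmonics dropped. The
  default band half-width is **one mainlobe width** (0.78 Hz at 200 Hz):
  a narrower band (e.g. the older ±0.5 Hz convention, still available via
  the `half_width` argument) cannot contain even a perfectly concentrated
  peak at this resolution, capping a pure sinusoid's OI around 0.88, which
  defeats OI's purpose as an organization measure. With resolution-matched
  bands a pure tone scores ≈0.92, broadband signals score near the
  band-length ratio.
* **LK** — maximum Pearson correlation with a sinusoid at the fundamental,
  phase-optimized. Computed in closed form as √R² of the regression of the
  mean-removed signal on the quadrature pair (sin, cos) at f0; optimizing
  the phase explicitly is never needed. When LK is computed downstream of
  spectral f0 detection, the correlation is additionally maximized over
  frequency within ±one grid step (bounded scalar search) to undo the grid
  quantization of f0 — a time-domain refinement, not spectral
  interpolation.

## Entropy and mutual information

Estimators are deliberately the simplest consistent ones — plug-in
histograms — because the short recordings make their bias/variance
behaviour the scientific point, not a nuisance:

* Marginal: bins `[k·Δb, (k+1)·Δb)` anchored at 0;
  `ĥ = −Σ p̂ᵢ log₂ p̂ᵢ + log₂ Δb`. The `+log₂ Δb` correction makes the value
  a differential-entropy estimate directly comparable to closed forms
  (0.5·log₂(2πe σ²) for a Gaussian). A constant sequence occupies one bin
  and degenerates to log₂ Δb, flagged as such.
* Joint: square Δb×Δb cells anchored at (0, 0), correction `+2·log₂ Δb`.
* MI: `I = ĥ(x) + ĥ(y) − ĥ(x, y)` with identical binning, so the
  corrections cancel exactly; the identity holds to machine precision and
  I ≥ 0 as for any plug-in estimate on shared bins. Bin counts are summed
  in sorted order so MI is bit-exactly symmetric in its arguments.

Cardiac signals are z-scored (zero mean, unit variance) before
histogramming so one shared Δb is meaningful across patients with different
gains; a raw-amplitude mode is available. The cohort default is
Δb = 0.4833, the middle of the candidate grid {0.6952, 0.4833, 0.3360,
0.2336} examined by the bin-width sweep — large enough to control the
small-N bias at N = 600–1200, small enough to retain sensitivity between
patients.

Known estimator facts the sweep reproduces: with N samples and Δb small
enough that all samples occupy distinct bins, the estimate saturates at
`log₂ N + log₂ Δb` regardless of the true entropy (at N = 100, Δb = 10⁻³ a
unit Gaussian reads ≈ −3.3 bits against a true 2.05); with N = 10⁶ the
estimate tracks the closed form for almost any Δb ≤ 1. One quantification
worth recording: the *quantization* component of the bias for a
unit-variance Gaussian, computable exactly from the Gaussian CDF, is
0.0006 bits at Δb = 0.1, 0.019 at Δb = 0.56, and 0.0577 at Δb = 1.0 — at
coarse bins the plateau is flat but sits visibly above the continuous
closed form, independent of N and of bin anchoring. The plateau criterion
used by the stability report is a relative change below 5% between adjacent
grid points (configurable).

## Synthetic data

*Bivariate Gaussian sets* use an eigendecomposition factor so that
rank-deficient covariances are exact: the "dependent" preset
[[1, 1], [1, 1]] yields elementwise-identical channels, the "correlated"
preset [[1, 0.5], [0.5, 1]] has MI −0.5·log₂(0.75) ≈ 0.2075 bits.

*VF-like pairs* are `Σₖ envₖ·sin((k+1)·θ(t) + φₖ) + noise` per channel,
where θ(t) integrates an instantaneous fundamental
`f0·(1 + jitter_sd·g(t))` (g a standardized 0.25 s moving-average Gaussian
process), keeping the harmonic ladder phase-locked; envelopes are truncated
below Nyquist. A single coupling parameter c ∈ [0, 1] blends shared and
channel-own realizations of the jitter, the initial phases (via unit-vector
mixing) and the broadband noise with weights √c and √(1−c): c = 0 gives
independent channels, c = 1 identical ones (given equal envelopes and noise
levels), and the estimated MI is monotone in c.

Cohort defaults are the study conditions being emulated: 22 patients, 6 s
at 200 Hz, per-patient fundamental ~N(4.74, 0.5²) Hz clipped to
[3.2, 6.5] Hz, coupling 0.5, jitter 3%, LV envelope (0.4, 0.7, 0.5, 0.8,
1.0, 0.3) peaking at harmonic index 4 with noise SD 0.35, RV envelope
(0.35, 1.0, 0.5, 0.4, 0.3, 0.2) peaking at index 1 with noise SD 0.2. These
produce the qualitative inter-ventricular pattern: DF(LV) ≫ DF(RV) with a
shared f0, and higher OI/LK in the less noisy RV. Patient i uses derived
seed `seed + i`, so cohorts are reproducible under subsetting.

What the generator does *not* model: rotor or reaction-diffusion
electrophysiology, electrode/lead-configuration transfer functions,
amplifier saturation, nonstationarity across the 6 s episode, or realistic
EGM waveshape (deflection morphology). Passing tests therefore demonstrate
estimator correctness and sensitivity to the controlled structure — not
that real VF recordings would show these effect sizes. In particular the
synthetic LK (~0.25) is far below values reported for real electrograms
(~0.85–0.9), because the generator spreads power across a wide harmonic
ladder, and synthetic cohort entropies (~1.9–2.0 bits on z-scored signals
at Δb = 0.4833) are near-Gaussian by construction.

## Population statistics

Per parameter and window, the cohort table reports mean ± SD per channel
and a two-sided paired Student t-test, `t = mean(d)/(sd(d)/√n)`, df = n−1
(`scipy.stats.ttest_rel`; verified against the closed form and a resampled
null in the tests). Zero-variance differences are a flagged degenerate
case. Patients missing one channel are dropped from the affected window
with a logged warning. Raw p-values are the primary report, with p ≥ 0.05
rendered "ns" in the text table; a Holm step-down column (per window) is
emitted additionally and labelled as such. Sidedness was a free choice:
two-sided tests are used since the comparisons are symmetric.

## Pipeline and determinism

`run_pipeline` composes load/simulate → windowing → spectral parameters →
entropy/MI (and optional bin-width sweep) → cohort summary, writing CSV
artifacts plus a JSON manifest echoing the configuration and library
versions. All randomness flows from the single config seed; reruns are
byte-identical. Stage failures abort with a message naming the stage and
patient.

## Problem sizes

Default problem sizes were chosen to keep any single validation run in
seconds while leaving the estimators in their scientifically relevant
regimes: Gaussian validation at N = 10⁵–10⁶ (where closed-form recovery is
meaningful), 13-point logarithmic Δb grids over [10⁻³, 1], cardiac windows
at their native 600–1200 samples, 22-patient cohorts, and 10–20 replicate
seeds for median-based ordering checks.
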