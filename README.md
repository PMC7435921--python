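# vfegm

Spectral and information-theoretic analysis of simultaneously recorded left-
and right-ventricular electrograms (EGMs) during ventricular fibrillation
(VF).

## The problem

During VF the two ventricles can behave differently: experimental work
suggests fast, relatively organized sources in the left ventricle (LV) with
the right ventricle (RV) as a slower, smoother bystander. Biventricular
defibrillator platforms (CRT-D) sense both chambers at once, yielding short
paired recordings — typically 6 s at 200 Hz — whose comparison requires
estimators that behave sensibly at a few hundred samples. `vfegm` provides
that toolchain for researchers in cardiac electrophysiology and biomedical
signal processing:

* **Welch spectral parameters.** The averaged Welch periodogram (256-sample
  rectangular segments, 50% overlap, 4096-point transform) is normalized to
  unit area, `Σ P̂ₙ(f)·Δf = 1`, and reduced to the standard VF descriptors in
  the 2–30 Hz band: fundamental frequency f0 (harmonic comb base), dominant
  frequency DF (global spectral maximum), mean frequency MF (spectral
  centroid), harmonic peak powers Pₙ(f0..f5), 75% peak bandwidths, the
  Organization Index

  `OI = ∫_harmonic bands P̂ₙ(f) df / ∫_2–30 Hz P̂ₙ(f) df`,

  and the Leakage LK, the maximum Pearson correlation between the signal and
  a phase-optimized sinusoid at the fundamental.

* **Histogram entropy and mutual information.** Differential entropy
  `h(x) ≈ −Σᵢ p̂ᵢ log₂ p̂ᵢ + log₂ Δb` with bins anchored at integer multiples
  of the bin width Δb, the joint analogue on Δb×Δb cells, and
  `I(x, y) = h(x) + h(y) − h(x, y)` with exact cancellation of the Δb
  corrections. Sweep utilities map the estimators' bias/variance over sample
  size N and bin width Δb — the key diagnostic before trusting entropy
  numbers computed from 600-sample windows.

* **Synthetic data with known ground truth.** A bivariate Gaussian generator
  for closed-form validation, and a VF-like EGM generator (harmonic ladder
  on a jittered ~4.7 Hz fundamental plus broadband noise, with a coupling
  knob controlling the information shared between channels) that emulates a
  22-patient cohort, including the inter-ventricular asymmetry: LV spectral
  envelope peaking at a high harmonic, RV more organized and low-pass.

* **Population statistics.** Mean ± SD per channel and two-sided paired
  Student t-tests per parameter and analysis window (0–3 s and 3–6 s), with
  an additional Holm-corrected column.

## Worked example

```python
from vfegm import VFSignalConfig, extract_spectral_params, generate_vf_pair

pair = generate_vf_pair(VFSignalConfig(seed=11))   # one synthetic patient
lv, rv = extract_spectral_params(pair, "W1")       # first 3 s
```

Running `python examples/02_spectral_parameters.py` prints

```
window W1  (0-3 s)
  LV: f0= 4.79 Hz  DF=24.02 Hz  MF=18.05 Hz  BW(f1)=0.47 Hz  OI=0.77  LK=0.24
  RV: f0= 4.79 Hz  DF= 9.62 Hz  MF=12.22 Hz  BW(f1)=0.48 Hz  OI=0.89  LK=0.26
```

Both channels share the fundamental (~4.8 Hz, the common VF rate), but the
LV's dominant frequency sits at its fifth harmonic (≈24 Hz) while the RV's
sits at its second (≈9.6 Hz), and the RV is the more organized channel
(higher OI) — the asymmetry the generator is built to emulate. The estimator
side is validated against closed forms
(`python examples/03_entropy_mutual_information.py`):

```
Gaussian entropy: 2.0504 bits   (closed form 2.0471)
Gaussian MI (rho=0.5): 0.2078 bits (closed form 0.2075)
coupling=0.0: H(LV)=2.020  H(RV)=1.932  H(LV,RV)=3.848  MI=0.103 bits
coupling=0.5: H(LV)=1.942  H(RV)=1.977  H(LV,RV)=3.643  MI=0.276 bits
coupling=1.0: H(LV)=1.958  H(RV)=1.872  H(LV,RV)=2.830  MI=1.000 bits
```

The remaining scripts in `examples/` cover cohort generation, the N×Δb
bias sweep, and the end-to-end population table. A thin CLI mirrors the
pipeline stages (`vfegm simulate | spectral | info | sweep | cohort |
pipeline`).

## Layout

```
src/vfegm/        io, synthetic, spectral, info, stats, pipeline, cli
tests/            unit, property and acceptance tests (pytest + hypothesis)
examples/         one narrative script per capability
docs/methods.md   models, estimator conventions, design choices, limitations
```
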