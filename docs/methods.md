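# Methods

This note documents the models behind `mpspec`, the defaults that matter,
what the synthetic data do and do not emulate, and the numerical choices
made where the design was open.

## Signal model

**Acquisition.** All signals share one drive/sampling contract: a
sinusoidal field B(t) = B_ex·sin(2π·f_ex·t) with f_ex = 25 kHz and
B_ex = 25 mT, sampled at an integer number of samples per period
(default 64) over an integer number of periods (default 16, i.e.
N = 1024 samples, 640 µs). Coherent sampling puts every harmonic on an
exact DFT bin, so a rectangular window is leak-free and no apodization or
zero padding is used. The acquisition length is a package choice — the
instrument's internal averaging is not published — and 64 samples/period
supports analysis up to harmonic 31, far beyond the n ≤ 9 range where
tracer signal exceeds the noise floor.

**Equilibrium magnetization.** A physical tracer preset is a lognormal
ensemble of spherical single-domain cores (median diameter `d_med`, shape
`sigma_d`) with core saturation magnetization `M_s`. The ensemble
equilibrium moment is the volume-weighted Langevin average,
m_eq(B) = m_sat·Σᵢ wᵢ·L(ξᵢ), with ξᵢ = M_s·(π/6)dᵢ³·B/(k_B·T). The
diameter integral uses 33-node Gauss–Legendre quadrature on ln d over
±4·sigma_d (deterministic, smooth integrand; a single node when
sigma_d = 0). The total core volume follows from the iron mass by
treating cores as magnetite (ρ = 5170 kg/m³, iron mass fraction 0.724);
this conversion only sets an overall moment scale and cancels from all
calibrated quantities. L(ξ) switches to the Taylor branch ξ/3 − ξ³/45
below |ξ| = 10⁻⁴.

**Dynamics.** Relaxation is a single effective Debye time constant per
preset: dm/dt = (m_eq(B(t)) − m)/τ. No Néel/Brown decomposition and no
field-dependent τ are attempted; the experimental literature the presets
emulate discusses relaxation mechanisms qualitatively, and one effective
τ reproduces the observable consequences (negative, order-increasing
phase lag). Because the equation is linear with periodic forcing, the
periodic steady state is computed exactly in the frequency domain: the
equilibrium waveform is evaluated on an 8× oversampled grid over one
period, each Fourier harmonic k is multiplied by 1/(1 + i·k·ω·τ), and the
result is resampled onto the acquisition grid. This is the state any
time-stepping integrator converges to after its transient; the test suite
verifies that against an independent fixed-step RK4 integrator at 100×
oversampling with explicit transient discard (agreement is at the 10⁻⁸
level, far inside the 0.5% / 0.5° tolerance asserted). τ longer than 100
excitation periods is rejected: such a sample has no meaningful steady
response within a realistic acquisition.

**Template presets.** Where only the spectral fingerprint matters, a
template preset pins relative odd-harmonic amplitudes (A3 ≡ 1) and
per-harmonic phases directly; synthesis places each component at
sin(nωt + θ_eq(n) + φₙ) so the analyzer recovers the template verbatim.
The packaged templates encode the published fingerprint coordinates of
the three tracer families (A5/A3 ≈ 10/20/30 %, φ3 ≈ −2/−10/−30°); orders
7 and 9 are filled in with a plausibly decaying continuation since only
the (A5/A3, φ3) coordinates are constrained by data.

**Contaminants.** Dietary ferromagnetic contamination is a smooth
rectangular hysteron: ascending branch m = m_c·tanh((B − B_c)/B_w),
descending branch m = m_c·tanh((B + B_c)/B_w), branch chosen by the sign
of dB/dt. The branches meet continuously at the field extrema; B_c > 0
opens a loop and produces a large negative φ3 together with a flat
harmonic spectrum — exactly the features that separate contamination from
a superparamagnetic tracer. Per-specimen jitter draws m_c log-uniformly
over ±0.5 decade around 10⁻⁹ A m², B_c uniformly in 5–20 mT and B_w in
1–5 mT, giving the broad fingerprint scatter seen in contaminated
specimens.

**Noise and blanks.** Instrument noise is additive white Gaussian noise
per sample. A noise-only harmonic bin amplitude is then Rayleigh
distributed, which pins the blank statistics: mean and SD of a
single-shot blank A3 cannot be set independently (their ratio is fixed at
√(4/π − 1)/√(π/4) ≈ 0.52). The default noise SD is therefore derived by
matching μ + 3σ of the Rayleigh law to the device detection limit of
2×10⁻¹¹ A m², giving ≈ 1.41×10⁻¹⁰ A m² per sample at the default
acquisition. The deterministic 20-blank worked example (ten values
1.4×10⁻¹¹ − δ, ten 1.4×10⁻¹¹ + δ, δ = 0.2×10⁻¹¹·√(19/20)) has sample
mean 1.4×10⁻¹¹ and sample SD 0.2×10⁻¹¹ exactly, hence LOD = 2×10⁻¹¹ by
construction.

## Harmonic analysis

Amplitudes are A_n = 2|c_k|/N at bin k = n·n_periods. The phase
convention needs a reference: the raw phase of harmonic n is measured
against sin(2πnf_ex·t) and then referenced to θ_eq(n), the phase (0° or
180°) of the n-th Fourier component of an ideal lag-free saturable
response. θ_eq is computed numerically once per order from
tanh(3·sin ωt); for a monotone saturable odd response all odd sine
coefficients come out positive, so the reference is 0° throughout — but
it is computed rather than assumed. With this referencing a τ = 0 sample
reads exactly 0° at every order and any relaxation delay reads negative,
matching the instrument's negative-lag sign convention. Voltage-mode
signals (u ∝ −dm/dt) are deconverted per harmonic (amplitude ÷ 2πnf_ex,
phase +90°). The fundamental is never analyzed (n ≥ 3 only), mirroring
the hardware's high-pass/gradiometric suppression as reporting-side
truncation.

Per-order noise floors are the median amplitude of the non-harmonic bins
within one harmonic spacing of the target bin; with a single acquired
period no such bins exist and the estimator falls back to a global median
with a warning. Spectra from repeated measurements are averaged as
complex phasors.

## Quantification and detection limit

The specific moment Â3 = A3/m(Fe) of a reference sample converts A3 to
iron mass. The LOD follows the IUPAC blank rule μ + 3σ with the sample SD
(n − 1 denominator; the blanks are a sample of the background process).
Readings below the LOD are censored and carry the upper bound
LOD/Â3 rather than a value. The same μ + 3σ rule applies per harmonic;
because the background is white, every harmonic bin shares the blank
distribution and the n = 5 LOD used for feature censoring equals the
n = 3 LOD. Dilution series are checked with a through-origin least-squares
fit of A3 on concentration (the blank response is zero by construction)
and an uncentered R², plus the largest deviations of A5/A3 (relative) and
φ3 (absolute) across points whose A5 exceeds its floor.

## Fingerprint classification

The discriminator is exactly the two-dimensional (A5/A3, φ3) plane; both
features are invariant under amplitude scaling, hence concentration
independent. The published acceptance region is a visual ellipse; here it
is formalized as a Gaussian region: centroid = mean and covariance =
sample covariance of ≥ 3 non-censored reference fingerprints, with a
squared-Mahalanobis threshold at the χ²₂ quantile of the requested
coverage (default 0.99). Censored ratios never enter the fit (their
upper-bound values would bias the covariance) but do participate in
classification, flagged. Classification precedence is LOD gate first,
then region test: below-LOD samples are never called contaminated.

Reference sets span the environmental variation a tracer shows in
practice (pH, ionic strength, cellular uptake): a common phase offset
N(0, 1.5°), a spectral-shape factor exp N(0, 0.08) on the ratio, and
amplitudes log-uniform over 10⁻⁹–10⁻⁸ A m² so that measurement noise is a
minor contributor to the fitted covariance. Two consequences are worth
knowing. First, with an estimated mean and covariance the χ² threshold
slightly undercovers (a Hotelling-type effect, ≈ 1–1.5% at 60 reference
points); empirical acceptance of fresh same-law replicates is ≈ 98.5% at
nominal 99%. Second, near the detection limit feature noise grows
(phase noise ≈ noise floor / A3), so acceptance of genuine tracer
degrades for samples within roughly a decade of the LOD — the region is a
distribution test, not a likelihood-ratio test with per-sample noise
models, which is a documented limitation.

## Synthetic study

The default design crosses treatments (vehicle PBS vs intravenous
tracer at 0.03 mmol Fe per kg body weight) with three disease models, an
organ panel of colon, kidney, small intestine, caecum, liver, spleen,
colonic and caecal feces, and the animal feed, 8 replicates per cell.
Body mass is N(20, 2) g; the injected iron (≈ 34 µg for a 20 g animal)
distributes with dominant hepatic (55%) and splenic (12%) clearance and
small (0.5–1.2%) renal/intestinal fractions, lognormally jittered (σ =
0.25) between animals. The tracer-specific moment is fixed at
20 A m²/kg(Fe), putting the LOD at 1 ng iron — the sensitivity range of
benchtop MPS. Contamination is Bernoulli per specimen with probabilities
mirroring the observed intestinal exclusion fractions (colon 0.5, caecum
and small intestine 0.3, feces and food 1.0, parenchymal organs 0);
contaminated specimens add a jittered hysteron to their tracer signal.
All randomness flows from one seed through named substreams, so studies
are bit-reproducible.

What the generator does **not** emulate: within-animal correlation across
organs (each record draws independently), tracer pharmacokinetics over
time, field-dependent or temperature-dependent relaxation, instrument
drift or 1/f noise, partial-volume/positioning effects, and any coupling
between inflammation model and biodistribution beyond the shared
fractions. Passing tests therefore demonstrate the correctness and
statistical behaviour of the analysis chain under its stated noise model,
not instrument-level fidelity.

## Numerical choices and degenerate inputs

- Collinear or duplicated reference fingerprints are rejected via an
  eigenvalue-ratio test (smallest/largest ≤ 10⁻¹²) rather than a raw
  determinant, which is scale-free.
- Quartiles use linear interpolation (type 7); group SDs use the sample
  convention (ddof = 1). Whisker conventions (5th/95th percentile,
  mean ± SD, 1.5·IQR) affect only whiskers and outlier counts, never the
  box statistics; the default is 5th/95th percentiles and the mode is
  recorded in every summary.
- Below-LOD values are excluded from group moments rather than imputed;
  counts always report how much censoring occurred.
- Signal files serialize samples with 17 significant digits so a
  write→read round trip is bit-exact; every structured output embeds the
  run-configuration hash, and re-running a pipeline into a directory
  whose report carries the same hash is a no-op.
- The τ = 0 limit, B_c = 0 hysteron, zero-noise blanks and empty groups
  are all exercised explicitly in the test suite.

## Problem sizes

Default runs are desk-scale by design: 1024-sample signals, 432-specimen
default study, 60-point reference sets, and a few hundred Monte-Carlo
replicates in the statistical tests — the full suite and the end-to-end
pipeline each complete in well under a minute on one CPU.
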