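# mpspec

Magnetic particle spectroscopy (MPS) analysis for nanoparticle
biodistribution studies: simulate the nonlinear magnetization response of
magnetic nanoparticle (MNP) tracers and ferromagnetic contaminants,
extract odd-harmonic amplitude/phase spectra, quantify tracer iron
against a reference calibration with an IUPAC detection limit, and use
the concentration-independent (A5/A3, φ3) fingerprint to exclude dietary
magnetic contamination before reporting organ-level results.

## Who this is for

MPS measures the dynamic magnetic moment of a sample driven by a
sinusoidal field B(t) = B_ex·sin(2π·f_ex·t) (here 25 mT at 25 kHz) and
reads out harmonics n = 3, 5, 7, … of the drive. Diamagnetic tissue and
paramagnetic blood iron respond linearly and vanish from the odd
harmonics, which makes MPS attractive for quantifying superparamagnetic
tracers (e.g. very small iron oxide particles, VSOP) in organ samples.
The catch: ferro-/ferrimagnetic contamination — most prominently from
animal feed passing through the gut — is also MPS-visible and can mimic
tracer signal in intestinal specimens. This package implements the full
desk-scale workflow a lab would use to study and correct for that effect,
with a synthetic-data generator standing in for the (non-public)
instrument data.

## The model in brief

- **Tracer forward model.** The equilibrium moment of a lognormal
  ensemble of cores is m_eq(B) = m_sat·⟨L(ξ(d))⟩ with the Langevin
  function L(ξ) = coth ξ − 1/ξ and ξ = M_s·(π/6)d³·B/(k_B·T); dynamics
  follow Debye relaxation dm/dt = (m_eq(B(t)) − m)/τ, whose periodic
  steady state attenuates harmonic n by 1/(1 + i·n·ω·τ) — the source of
  the negative phase lag of larger particles. Template presets instead
  pin the harmonic fingerprint directly and are exact under the analyzer.
- **Harmonic analysis.** Rectangular-window DFT over an integer number of
  periods; A_n = 2|c_n|/N, phases referenced so that a lag-free saturable
  response reads 0° and lag reads negative.
- **Quantification.** A3 is proportional to iron mass; dividing by the
  specific moment Â3 (A m²/kg Fe) of a reference sample of known iron
  content yields the sample's iron. LOD = μ + 3σ over 20 empty-holder
  blanks (IUPAC); readings below it are censored.
- **Contamination fingerprint.** (A5/A3, φ3) is concentration
  independent. A Gaussian acceptance ellipse (Mahalanobis distance,
  χ²₂ quantile, default coverage 0.99) is fit over reference
  measurements; above-LOD samples outside it are classified as
  contaminated and excluded from biodistribution statistics.
- **Hysteretic contaminants** are modeled as a smooth rectangular
  hysteron: m = m_c·tanh((B ∓ B_c)/B_w) on the ascending/descending
  branch, with per-specimen jitter of (m_c, B_c, B_w).

## Worked example

```python
import mpspec as m

cfg = m.ExcitationConfig()            # 25 kHz, 25 mT, 64 samples/period, 16 periods
lod = m.compute_lod(m.generate_blanks())
print(f"LOD = {lod.lod:.2e} A m^2")

# calibrate from a reference vial holding 1 ug iron
ref = m.synthesize_template(cfg, m.get_preset("vsop"), 2e-8, sample_id="ref")
cal = m.calibrate(m.extract_harmonics(ref), iron_mass=1e-9, lod=lod)
print(f"specific moment = {cal.specific_moment_A3:.1f} A m^2/kg(Fe)")

# fingerprint of a multicore tracer vs the VSOP acceptance region
refs = m.generate_reference_signals(cfg, m.get_preset("vsop"), n=60, seed=0)
region = m.fit_region(
    [m.extract_features(m.extract_harmonics(s), lod5=lod.lod) for s in refs]
)
mcp = m.extract_harmonics(m.synthesize_template(cfg, m.get_preset("mcp_resovist"), 1e-9))
print(m.extract_features(mcp), m.classify(mcp, region, lod).value)
```

prints

```
LOD = 2.00e-11 A m^2
specific moment = 20.0 A m^2/kg(Fe)
FingerprintFeatures(r53=0.3000000000000005, phi3=-30.000000000000682, r53_censored=False) contaminated
```

i.e. the blank set reproduces the device detection limit of 2×10⁻¹¹ A m²,
the reference vial calibrates to 20 A m² per kg iron, and a multicore
tracer at (A5/A3 = 0.30, φ3 = −30°) falls far outside the VSOP acceptance
region near (0.10, −2°) and is flagged as foreign magnetic material.

## Analysis scripts

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/`:

1. `01_tracer_fingerprints.py` — fingerprint coordinates of the three
   tracer families and their environmental scatter;
2. `02_calibration_and_lod.py` — detection limit, calibration, dilution
   linearity;
3. `03_synthetic_study.py` — the default 432-specimen organ-panel study;
4. `04_classify_and_quantify.py` — region fit, classification, corrected
   quantification with per-organ exclusion counts;
5. `05_report.py` — corrected group summaries and fingerprint plot data.

The same pipeline is available as a CLI (`mpspec run --seed 0 --out out/`,
plus `simulate`, `analyze`, `lod`, `calibrate`, `fit-region`, `classify`,
`quantify`, `report` subcommands).

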