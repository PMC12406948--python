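#!/usr/bin/env python
"""Detection limit and iron calibration.

Computes the IUPAC limit of detection (mu + 3 sigma) from the packaged
20-blank worked example and from freshly simulated empty-holder
measurements, calibrates the tracer-specific moment from a reference
sample of known iron mass, and verifies amplitude linearity plus
fingerprint stability over a 1, 1/2, 1/4, 1/8 dilution series.
Finding: the blank fixture reproduces the device LOD of 2e-11 A m^2,
random blanks land at the same level, and the dilution series is
through-origin linear (r^2 > 0.9999) with a stable spectral shape.
"""

import json
from pathlib import Path

from mpspec import (
    ExcitationConfig,
    calibrate,
    check_dilution_series,
    compute_lod,
    extract_harmonics,
    generate_blanks,
    get_preset,
    synthesize_template,
)
from mpspec.signal_model import DEFAULT_NOISE_SD

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    cfg = ExcitationConfig()
    vsop = get_preset("vsop")

    lod_fix = compute_lod(generate_blanks(mode="fixture"))
    lod_rand = compute_lod(
        generate_blanks(mode="random", n=20, noise_sd=DEFAULT_NOISE_SD,
                        seed=SEED, config=cfg)
    )
    print(f"LOD (packaged blanks):  {lod_fix.lod:.3e} A m^2 "
          f"(mu = {lod_fix.mu:.3e}, sigma = {lod_fix.sigma:.3e})")
    print(f"LOD (simulated blanks): {lod_rand.lod:.3e} A m^2")

    reference_fe = 1e-9  # kg iron in the reference vial
    ref = synthesize_template(cfg, vsop, 20.0 * reference_fe)
    cal = calibrate(extract_harmonics(ref), reference_fe, lod=lod_fix)
    print(f"specific moment: {cal.specific_moment_A3:.4g} A m^2 / kg(Fe)")

    conc = [1.0, 0.5, 0.25, 0.125]
    spectra = [
        extract_harmonics(synthesize_template(cfg, vsop, 4e-9 * c)) for c in conc
    ]
    rep = check_dilution_series(spectra, conc)
    print(
        f"dilution: r^2 = {rep.r_squared:.6f}, "
        f"max A5/A3 deviation = {rep.max_ratio_deviation:.2e}, "
        f"max phi3 deviation = {rep.max_phase_deviation:.2e} deg"
    )

    OUT.mkdir(exist_ok=True)
    doc = {
        "lod_fixture_am2": lod_fix.lod,
        "lod_random_am2": lod_rand.lod,
        "specific_moment_a3": cal.specific_moment_A3,
        "dilution_r_squared": rep.r_squared,
        "dilution_max_ratio_deviation": rep.max_ratio_deviation,
        "dilution_max_phase_deviation_deg": rep.max_phase_deviation,
    }
    (OUT / "calibration_lod.json").write_text(json.dumps(doc, indent=2) + "\n")
    print(f"wrote {OUT / 'calibration_lod.json'}")


if __name__ == "__main__":
    main()
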