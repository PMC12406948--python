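#!/usr/bin/env python
"""Generate and analyze the default synthetic biodistribution study.

Simulates the full organ panel (6 treatment x model groups, 9 specimen
types, 8 replicates each), extracts harmonic spectra, and writes the
study manifest and spectra tables.  Finding: tracer-injected liver and
spleen dominate raw A3; intestinal specimens, feces and food carry
contamination signals that are also present in vehicle-treated animals.
"""

from pathlib import Path

import pandas as pd

from mpspec import ExcitationConfig, StudyDesign, extract_harmonics, generate_study
from mpspec.io import spectra_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    cfg = ExcitationConfig()
    dataset = generate_study(StudyDesign(seed=SEED), config=cfg)
    spectra = []
    rows = []
    for rec in dataset.records:
        rec.spectrum = extract_harmonics(dataset.signals[rec.sample_id])
        spectra.append(rec.spectrum)
        rows.append(
            {
                "id": rec.sample_id,
                "treatment": rec.treatment,
                "organ": rec.organ,
                "a3_am2": rec.spectrum.amplitude(3),
            }
        )
    OUT.mkdir(exist_ok=True)
    dataset.manifest().to_csv(OUT / "study_manifest.tsv", sep="\t", index=False)
    spectra_table(spectra).to_csv(OUT / "study_spectra.tsv", sep="\t", index=False)
    frame = pd.DataFrame(rows)
    print(f"generated {len(frame)} specimens "
          f"({frame.treatment.nunique()} treatments)")
    print("\nraw mean A3 by organ (tracer-injected groups), A m^2:")
    eu = frame[frame.treatment == "EuVSOP"].groupby("organ").a3_am2.mean()
    print(eu.sort_values(ascending=False).to_string(float_format="{:.3e}".format))
    print(f"\nwrote {OUT / 'study_manifest.tsv'} and {OUT / 'study_spectra.tsv'}")


if __name__ == "__main__":
    main()
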