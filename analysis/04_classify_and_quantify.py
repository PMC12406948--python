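#!/usr/bin/env python
"""Fingerprint classification and corrected iron quantification.

Fits the tracer acceptance region from reference measurements, classifies
every study specimen (LOD gate, then Mahalanobis region test), excludes
contaminated samples, and quantifies tracer iron for the remainder.
Finding: all vehicle-group specimens end up below the LOD or excluded as
contaminated -- none is falsely quantified -- while intestinal exclusion
counts mirror the designed contamination rates.
"""

from pathlib import Path

from mpspec import (
    ExcitationConfig,
    StudyDesign,
    calibrate,
    compute_lod,
    correct_quantification,
    extract_features,
    extract_harmonics,
    fit_region,
    generate_blanks,
    generate_study,
    get_preset,
)
from mpspec.fingerprint import records_frame
from mpspec.signal_model import (
    DEFAULT_NOISE_SD,
    add_noise,
    generate_reference_signals,
    synthesize_template,
)
from mpspec._rng import substream

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    cfg = ExcitationConfig()
    vsop = get_preset("vsop")
    lod = compute_lod(generate_blanks())
    rng = substream(SEED, "calibration")
    ref = add_noise(synthesize_template(cfg, vsop, 20.0 * 1e-9), DEFAULT_NOISE_SD, rng)
    cal = calibrate(extract_harmonics(ref), 1e-9, lod=lod)
    refs = generate_reference_signals(cfg, vsop, n=60, seed=SEED)
    region = fit_region(
        [extract_features(extract_harmonics(s), lod5=lod.lod) for s in refs],
        quantile=0.99,
    )
    print(
        f"region: centroid (r53 = {region.centroid[0]:.3f}, "
        f"phi3 = {region.centroid[1]:.2f} deg), "
        f"md2 threshold = {region.md2_threshold:.3f} (q = {region.quantile})"
    )

    dataset = generate_study(StudyDesign(seed=SEED), config=cfg)
    for rec in dataset.records:
        rec.spectrum = extract_harmonics(dataset.signals[rec.sample_id])
    records, exclusions = correct_quantification(dataset.records, region, cal, lod)
    frame = records_frame(records)

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "records_classified.tsv", sep="\t", index=False)
    exclusions.to_csv(OUT / "exclusion_counts.tsv", sep="\t", index=False)

    print("\nlabel counts:", frame.label.value_counts().to_dict())
    pbs = frame[frame.treatment == "PBS"]
    print(f"vehicle-group specimens falsely quantified: "
          f"{(pbs.label == 'target_MNP').sum()} of {len(pbs)}")
    intestinal = exclusions[exclusions.organ.isin(["COL", "CAE", "SIT"])]
    print("\nintestinal exclusion counts (excluded / total):")
    for row in intestinal.itertuples():
        print(f"  {row.treatment:7s} {row.model:13s} {row.organ}: "
              f"{row.n_excluded} / {row.n_total}")
    print(f"\nwrote {OUT / 'records_classified.tsv'} and "
          f"{OUT / 'exclusion_counts.tsv'}")


if __name__ == "__main__":
    main()
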