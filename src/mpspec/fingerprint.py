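"""Contamination discrimination in the (A5/A3, phi3) fingerprint plane.

The spectral shape of a tracer is concentration independent: the harmonic
ratio A5/A3 and the third-harmonic phase phi3 together form a fingerprint
that separates tracer families from each other and from ferromagnetic
contaminants.  An acceptance region for the target tracer is fit as a
Gaussian Mahalanobis ellipse over reference measurements spanning the
expected environmental variation; above-LOD samples falling outside the
region are classified as contaminated and excluded from quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .calibration import CalibrationModel, LodEstimate, quantify_iron
from .harmonics import HarmonicSpectrum

__all__ = [
    "FingerprintFeatures",
    "FingerprintRegion",
    "ClassLabel",
    "SampleRecord",
    "extract_features",
    "fit_region",
    "classify",
    "correct_quantification",
    "records_frame",
]


class ClassLabel(str, Enum):
    below_LOD = "below_LOD"
    target_MNP = "target_MNP"
    contaminated = "contaminated"


@dataclass(frozen=True)
class FingerprintFeatures:
    """Concentration-independent fingerprint of one spectrum.

    ``r53`` is A5/A3 (dimensionless), ``phi3`` in degrees.  When A5 is
    below its floor, ``r53`` is the floor-based upper bound and
    ``r53_censored`` is set.
    """

    r53: float
    phi3: float
    r53_censored: bool = False

    def __post_init__(self) -> None:
        if self.r53 < 0:
            raise ValueError("r53 must be non-negative")
        if not (-180.0 < self.phi3 <= 180.0):
            raise ValueError("phi3 must lie in (-180, 180]")

    def as_array(self) -> np.ndarray:
        return np.array([self.r53, self.phi3])


@dataclass(frozen=True)
class FingerprintRegion:
    """Gaussian acceptance ellipse for a target tracer.

    ``md2_threshold`` is the chi-square(2 dof) quantile at the nominal
    coverage, applied to the squared Mahalanobis distance from the
    centroid under the reference covariance (mixed units: dimensionless
    ratio and degrees).
    """

    centroid: np.ndarray
    covariance: np.ndarray
    md2_threshold: float
    quantile: float
    n_reference: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, float))
        if self.centroid.shape != (2,) or self.covariance.shape != (2, 2):
            raise ValueError("centroid must be length 2, covariance 2x2")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.covariance) <= 0):
            raise ValueError("covariance must be positive definite")
        if self.md2_threshold <= 0:
            raise ValueError("md2_threshold must be positive")

    def md2(self, features: FingerprintFeatures) -> float:
        """Squared Mahalanobis distance of a feature point to the centroid."""
        d = features.as_array() - self.centroid
        return float(d @ np.linalg.solve(self.covariance, d))

    def contains(self, features: FingerprintFeatures) -> bool:
        return self.md2(features) <= self.md2_threshold

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """(n_points, 2) polyline of the ellipse at ``md2_threshold``."""
        theta = np.linspace(0.0, 2.0 * np.pi, n_points)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        l = np.linalg.cholesky(self.covariance)
        return (self.centroid[:, None] + np.sqrt(self.md2_threshold) * (l @ circle)).T


def extract_features(spectrum: HarmonicSpectrum, lod5: float = 0.0) -> FingerprintFeatures:
    """(A5/A3, phi3) of a spectrum, censoring A5 at its background level."""
    a3 = spectrum.amplitude(3)
    if a3 <= 0:
        raise ValueError("A3 must be positive to form the harmonic ratio")
    a5 = spectrum.amplitude(5)
    floor = max(lod5, spectrum.noise_floor(5))
    if a5 < floor:
        return FingerprintFeatures(r53=floor / a3, phi3=spectrum.phase(3),
                                   r53_censored=True)
    return FingerprintFeatures(r53=a5 / a3, phi3=spectrum.phase(3))


def fit_region(
    reference_features: list[FingerprintFeatures], quantile: float = 0.99
) -> FingerprintRegion:
    """Fit the acceptance ellipse from non-censored reference fingerprints.

    Centroid = sample mean, covariance = sample covariance, threshold =
    chi-square(2) quantile at the requested coverage.  Censored reference
    points are rejected: their upper-bound ratios would bias the
    covariance.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    pts = [f for f in reference_features if not f.r53_censored]
    if len(pts) < len(reference_features):
        warnings.warn(
            f"dropping {len(reference_features) - len(pts)} censored reference "
            "point(s): upper-bound ratios would bias the covariance",
            stacklevel=2,
        )
    if len(pts) < 3:
        raise ValueError("need at least 3 reference points")
    x = np.array([p.as_array() for p in pts])
    cov = np.cov(x, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], np.finfo(float).tiny):
        raise ValueError("reference points are collinear or duplicated "
                         "(singular covariance)")
    return FingerprintRegion(
        centroid=x.mean(axis=0),
        covariance=cov,
        md2_threshold=float(chi2.ppf(quantile, df=2)),
        quantile=quantile,
        n_reference=len(pts),
    )


def classify(
    spectrum: HarmonicSpectrum,
    region: FingerprintRegion,
    lod: LodEstimate,
    lod5: float | None = None,
) -> ClassLabel:
    """Three-way call: LOD gate first, then the fingerprint region test.

    ``lod5`` defaults to the A3 LOD (white background: every harmonic bin
    shares the blank distribution).
    """
    if spectrum.amplitude(3) < lod.lod:
        return ClassLabel.below_LOD
    features = extract_features(spectrum, lod5=lod.lod if lod5 is None else lod5)
    return (
        ClassLabel.target_MNP if region.contains(features) else ClassLabel.contaminated
    )


@dataclass
class SampleRecord:
    """One specimen: identity, measurement, classification and ground truth."""

    sample_id: str
    treatment: str = ""
    model: str = ""
    organ: str = ""
    tissue_mass_g: float = np.nan
    spectrum: HarmonicSpectrum | None = None
    features: FingerprintFeatures | None = None
    label: ClassLabel | None = None
    fe_mass_kg: float = np.nan
    fe_censored: bool = False
    fe_upper_bound_kg: float = np.nan
    fe_per_g: float = np.nan
    truth_fe_kg: float = np.nan
    truth_contaminated: bool = False
    signal_path: str = ""


def correct_quantification(
    records: list[SampleRecord],
    region: FingerprintRegion,
    cal: CalibrationModel,
    lod: LodEstimate,
    lod5: float | None = None,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Classify every record and quantify iron for target-tracer calls only.

    Contaminated records carry no iron estimate (they are excluded from
    biodistribution reporting); below-LOD records carry a censored upper
    bound.  Returns the updated records and a per-(treatment, model, organ)
    table of exclusion counts ``(n_excluded, n_total)``.
    """
    lod5_val = lod.lod if lod5 is None else lod5
    for rec in records:
        if rec.spectrum is None:
            raise ValueError(f"record {rec.sample_id!r} has no analyzed spectrum")
        rec.label = classify(rec.spectrum, region, lod, lod5=lod5_val)
        if rec.label is ClassLabel.below_LOD:
            rec.features = None
            q = quantify_iron(rec.spectrum, cal, lod)
            rec.fe_mass_kg = np.nan
            rec.fe_censored = True
            rec.fe_upper_bound_kg = q.upper_bound_kg
        else:
            rec.features = extract_features(rec.spectrum, lod5=lod5_val)
            if rec.label is ClassLabel.target_MNP:
                q = quantify_iron(rec.spectrum, cal, lod)
                rec.fe_mass_kg = q.value_or_nan()
                rec.fe_censored = False
                rec.fe_upper_bound_kg = np.nan
            else:  # contaminated: no iron estimate
                rec.fe_mass_kg = np.nan
                rec.fe_censored = False
                rec.fe_upper_bound_kg = np.nan
    rows = []
    frame = records_frame(records)
    for key, grp in frame.groupby(["treatment", "model", "organ"], sort=True):
        rows.append(
            {
                "treatment": key[0],
                "model": key[1],
                "organ": key[2],
                "n_excluded": int((grp["label"] == ClassLabel.contaminated.value).sum()),
                "n_total": int(len(grp)),
            }
        )
    return records, pd.DataFrame(rows)


def records_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Flat table view of classified records."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "treatment": r.treatment,
                "model": r.model,
                "organ": r.organ,
                "tissue_mass_g": r.tissue_mass_g,
                "a3_am2": r.spectrum.amplitude(3) if r.spectrum is not None else np.nan,
                "r53": r.features.r53 if r.features is not None else np.nan,
                "phi3_deg": r.features.phi3 if r.features is not None else np.nan,
                "r53_censored": bool(r.features.r53_censored) if r.features else False,
                "label": r.label.value if r.label is not None else "",
                "fe_mass_kg": r.fe_mass_kg,
                "fe_censored": r.fe_censored,
                "fe_upper_bound_kg": r.fe_upper_bound_kg,
                "fe_per_g": r.fe_per_g,
                "truth_fe_kg": r.truth_fe_kg,
                "truth_contaminated": r.truth_contaminated,
                "signal_path": r.signal_path,
            }
        )
    return pd.DataFrame(rows)
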