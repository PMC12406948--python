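"""Group-level descriptive statistics and plot-ready exports.

Mirrors the reporting style of biodistribution box plots: per
(treatment, model, organ) cells, quartiles with configurable whiskers,
per-tissue-mass normalization, and scatter + region-boundary tables for
the (A5/A3, phi3) fingerprint plane.  Below-LOD values are counted but
never imputed into moments; contaminated records are excluded from iron
statistics entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .fingerprint import ClassLabel, FingerprintRegion

__all__ = [
    "GroupSummary",
    "summarize",
    "summaries_frame",
    "normalize_per_tissue_mass",
    "export_fingerprint_plot_data",
    "WHISKER_MODES",
]

WHISKER_MODES = ("percentile_5_95", "sd", "iqr_1_5")


@dataclass
class GroupSummary:
    """Descriptive statistics of quantified records in one group cell."""

    treatment: str
    model: str
    organ: str
    n_total: int
    n_below_lod: int
    n_contaminated: int
    n_quantified: int
    a3_mean: float = np.nan
    a3_sd: float = np.nan
    a3_median: float = np.nan
    a3_q1: float = np.nan
    a3_q3: float = np.nan
    a3_whisker_low: float = np.nan
    a3_whisker_high: float = np.nan
    a3_n_outliers: int = 0
    fe_per_g_mean: float = np.nan
    fe_per_g_sd: float = np.nan
    fe_per_g_median: float = np.nan
    whisker_mode: str = "percentile_5_95"


def _whiskers(values: np.ndarray, q1: float, q3: float, mode: str):
    if mode == "percentile_5_95":
        return float(np.percentile(values, 5)), float(np.percentile(values, 95))
    if mode == "sd":
        m, s = float(np.mean(values)), float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        return m - s, m + s
    if mode == "iqr_1_5":
        iqr = q3 - q1
        return q1 - 1.5 * iqr, q3 + 1.5 * iqr
    raise ValueError(f"unknown whisker mode {mode!r}; choose from {WHISKER_MODES}")


def summarize(
    records: pd.DataFrame,
    grouping: tuple = ("treatment", "model", "organ"),
    whisker_mode: str = "percentile_5_95",
) -> list[GroupSummary]:
    """Per-group box statistics of A3 and iron per tissue mass.

    Quartiles use linear interpolation (inclusive, type-7).  Statistics are
    computed over quantified (target-tracer) records only; below-LOD and
    contaminated records appear in the counts.  Empty groups yield
    count-only summaries.
    """
    if whisker_mode not in WHISKER_MODES:
        raise ValueError(f"unknown whisker mode {whisker_mode!r}")
    out = []
    for key, grp in records.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        labels = dict(zip(grouping, key))
        n_total = len(grp)
        n_blod = int((grp["label"] == ClassLabel.below_LOD.value).sum())
        n_cont = int((grp["label"] == ClassLabel.contaminated.value).sum())
        quant = grp[grp["label"] == ClassLabel.target_MNP.value]
        summary = GroupSummary(
            treatment=labels.get("treatment", ""),
            model=labels.get("model", ""),
            organ=labels.get("organ", ""),
            n_total=n_total,
            n_below_lod=n_blod,
            n_contaminated=n_cont,
            n_quantified=len(quant),
            whisker_mode=whisker_mode,
        )
        if len(quant) > 0:
            a3 = quant["a3_am2"].to_numpy(float)
            summary.a3_mean = float(np.mean(a3))
            summary.a3_sd = float(np.std(a3, ddof=1)) if a3.size > 1 else 0.0
            summary.a3_q1 = float(np.percentile(a3, 25))
            summary.a3_median = float(np.percentile(a3, 50))
            summary.a3_q3 = float(np.percentile(a3, 75))
            lo, hi = _whiskers(a3, summary.a3_q1, summary.a3_q3, whisker_mode)
            summary.a3_whisker_low = lo
            summary.a3_whisker_high = hi
            summary.a3_n_outliers = int(np.sum((a3 < lo) | (a3 > hi)))
            if "fe_per_g" in quant and np.isfinite(quant["fe_per_g"]).any():
                fe = quant["fe_per_g"].to_numpy(float)
                fe = fe[np.isfinite(fe)]
                summary.fe_per_g_mean = float(np.mean(fe))
                summary.fe_per_g_sd = float(np.std(fe, ddof=1)) if fe.size > 1 else 0.0
                summary.fe_per_g_median = float(np.percentile(fe, 50))
        out.append(summary)
    return out


def summaries_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


def normalize_per_tissue_mass(records: pd.DataFrame) -> pd.DataFrame:
    """Add iron per gram of tissue (ug/g); censored bounds are normalized too.

    ``fe_per_g`` holds the quantified iron mass divided by the specimen
    mass; for censored (below-LOD) records ``fe_per_g_upper`` carries the
    normalized upper bound and the censored flag is preserved.
    """
    mass = records["tissue_mass_g"].to_numpy(float)
    if np.any(~np.isfinite(mass)) or np.any(mass <= 0):
        raise ValueError("tissue masses must be positive and finite")
    out = records.copy()
    out["fe_per_g"] = records["fe_mass_kg"].to_numpy(float) * 1e9 / mass  # ug/g
    out["fe_per_g_upper"] = (
        records["fe_upper_bound_kg"].to_numpy(float) * 1e9 / mass
    )
    return out


def export_fingerprint_plot_data(
    records: pd.DataFrame,
    regions: list[FingerprintRegion],
    n_boundary_points: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Scatter and region-boundary tables for the (A5/A3, phi3) plane.

    Returns ``(scatter, boundaries, legend)``: one scatter row per record
    with features (below-LOD records have none and are only counted in the
    legend), one boundary polyline per region sampled on the ellipse at
    its Mahalanobis threshold, and a legend table of per-label counts.
    """
    has_features = records["r53"].notna() & (
        records["label"] != ClassLabel.below_LOD.value
    )
    scatter = records.loc[
        has_features,
        ["sample_id", "treatment", "model", "organ", "r53", "phi3_deg", "label"],
    ].reset_index(drop=True)
    rows = []
    for idx, region in enumerate(regions):
        for r53, phi3 in region.boundary(n_boundary_points):
            rows.append(
                {"region": idx, "r53": r53, "phi3_deg": phi3,
                 "md2_threshold": region.md2_threshold}
            )
    boundaries = pd.DataFrame(rows)
    legend = (
        records.groupby("label").size().rename("n").reset_index()
    )
    return scatter, boundaries, legend
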