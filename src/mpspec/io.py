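"""File formats: signals, spectra tables, calibration/region/LOD configs.

Delimited text is the interchange default (one sample per line, ``#
key=value`` headers); an HDF5 container is available for signal batches.
Every structured export carries the pipeline configuration hash so runs
are traceable and idempotent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel, LodEstimate
from .excitation import ExcitationConfig, TimeSignal
from .fingerprint import FingerprintRegion
from .harmonics import HarmonicSpectrum

__all__ = [
    "write_time_signal",
    "read_time_signal",
    "write_signal_batch",
    "read_signal_batch",
    "spectra_table",
    "spectra_table_wide",
    "write_calibration",
    "read_calibration",
    "write_region",
    "read_region",
    "config_hash",
]

_HEADER_KEYS = (
    "sample_id",
    "f_ex",
    "b_ex",
    "sample_rate",
    "n_periods",
    "temperature",
    "voltage_mode",
)


def write_time_signal(signal: TimeSignal, path: str | Path) -> None:
    """Serialize one signal: header lines then one sample per line.

    Samples are written with 17 significant digits, so a write-read round
    trip is bit-exact for doubles.
    """
    cfg = signal.config
    header = {
        "sample_id": signal.sample_id,
        "f_ex": repr(cfg.f_ex),
        "b_ex": repr(cfg.B_ex),
        "sample_rate": repr(cfg.sample_rate),
        "n_periods": cfg.n_periods,
        "temperature": repr(cfg.temperature),
        "voltage_mode": int(signal.voltage_mode),
    }
    lines = [f"# {k}={header[k]}" for k in _HEADER_KEYS]
    lines += [f"{x:.17g}" for x in signal.samples]
    Path(path).write_text("\n".join(lines) + "\n")


def read_time_signal(path: str | Path) -> TimeSignal:
    """Parse a signal file, validating header completeness and length."""
    header: dict[str, str] = {}
    samples: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            header[key.strip()] = value.strip()
        else:
            samples.append(float(line))
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"signal file {path} missing header key(s): {missing}")
    cfg = ExcitationConfig(
        f_ex=float(header["f_ex"]),
        B_ex=float(header["b_ex"]),
        sample_rate=float(header["sample_rate"]),
        n_periods=int(header["n_periods"]),
        temperature=float(header["temperature"]),
    )
    if len(samples) != cfg.n_samples:
        raise ValueError(
            f"signal file {path} holds {len(samples)} samples but the header "
            f"implies n_periods*sample_rate/f_ex = {cfg.n_samples}"
        )
    return TimeSignal(
        np.array(samples),
        cfg,
        sample_id=header["sample_id"],
        voltage_mode=bool(int(header["voltage_mode"])),
    )


def write_signal_batch(signals: list[TimeSignal], path: str | Path) -> None:
    """HDF5 container: one group per sample mirroring the text header."""
    with h5py.File(path, "w") as fh:
        for sig in signals:
            grp = fh.create_group(sig.sample_id)
            grp.create_dataset("samples", data=sig.samples)
            cfg = sig.config
            grp.attrs.update(
                {
                    "f_ex": cfg.f_ex,
                    "b_ex": cfg.B_ex,
                    "sample_rate": cfg.sample_rate,
                    "n_periods": cfg.n_periods,
                    "temperature": cfg.temperature,
                    "voltage_mode": int(sig.voltage_mode),
                }
            )


def read_signal_batch(path: str | Path) -> list[TimeSignal]:
    out = []
    with h5py.File(path, "r") as fh:
        for sid in fh:
            grp = fh[sid]
            cfg = ExcitationConfig(
                f_ex=float(grp.attrs["f_ex"]),
                B_ex=float(grp.attrs["b_ex"]),
                sample_rate=float(grp.attrs["sample_rate"]),
                n_periods=int(grp.attrs["n_periods"]),
                temperature=float(grp.attrs["temperature"]),
            )
            out.append(
                TimeSignal(
                    grp["samples"][:],
                    cfg,
                    sample_id=sid,
                    voltage_mode=bool(int(grp.attrs["voltage_mode"])),
                )
            )
    return out


def spectra_table(spectra: list[HarmonicSpectrum]) -> pd.DataFrame:
    """Long-format spectra table: one row per (sample, harmonic)."""
    rows = []
    for s in spectra:
        for n, a, phi, floor in zip(s.orders, s.A_n, s.phi_n, s.noise_floor_n):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "n": int(n),
                    "A_n": a,
                    "phi_n_deg": phi,
                    "noise_floor_n": floor,
                }
            )
    return pd.DataFrame(rows)


def spectra_table_wide(spectra: list[HarmonicSpectrum]) -> pd.DataFrame:
    """Wide export: A3..A{n_max}, phi3..phi{n_max} columns per sample."""
    rows = []
    for s in spectra:
        row = {"sample_id": s.sample_id}
        for n, a, phi in zip(s.orders, s.A_n, s.phi_n):
            row[f"A{n}"] = a
            row[f"phi{n}"] = phi
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_calibration(
    cal: CalibrationModel, lod: LodEstimate, path: str | Path,
    provenance_hash: str = "",
) -> None:
    doc = {
        "specific_moment_A3": float(cal.specific_moment_A3),
        "reference_iron_mass_kg": float(cal.reference_iron_mass),
        "reference_id": cal.reference_id,
        "lod": float(lod.lod),
        "mu": float(lod.mu),
        "sigma": float(lod.sigma),
        "n_blanks": int(lod.n_blanks),
        "config_hash": provenance_hash,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_calibration(path: str | Path) -> tuple[CalibrationModel, LodEstimate]:
    doc = yaml.safe_load(Path(path).read_text())
    cal = CalibrationModel(
        specific_moment_A3=doc["specific_moment_A3"],
        reference_iron_mass=doc["reference_iron_mass_kg"],
        reference_id=doc.get("reference_id", ""),
    )
    lod = LodEstimate(
        mu=doc["mu"], sigma=doc["sigma"], lod=doc["lod"], n_blanks=doc["n_blanks"]
    )
    return cal, lod


def write_region(region: FingerprintRegion, path: str | Path,
                 provenance_hash: str = "") -> None:
    doc = {
        "centroid_r53": float(region.centroid[0]),
        "centroid_phi3_deg": float(region.centroid[1]),
        "cov_rr": float(region.covariance[0, 0]),
        "cov_rp": float(region.covariance[0, 1]),
        "cov_pp": float(region.covariance[1, 1]),
        "md2_threshold": float(region.md2_threshold),
        "quantile": float(region.quantile),
        "n_reference": int(region.n_reference),
        "config_hash": provenance_hash,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_region(path: str | Path) -> FingerprintRegion:
    doc = yaml.safe_load(Path(path).read_text())
    cov = np.array(
        [[doc["cov_rr"], doc["cov_rp"]], [doc["cov_rp"], doc["cov_pp"]]]
    )
    return FingerprintRegion(
        centroid=np.array([doc["centroid_r53"], doc["centroid_phi3_deg"]]),
        covariance=cov,
        md2_threshold=doc["md2_threshold"],
        quantile=doc["quantile"],
        n_reference=doc["n_reference"],
    )
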