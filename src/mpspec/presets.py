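"""Particle and contaminant presets and the packaged preset registry.

Two kinds of tracer presets exist.  *Template* presets specify the harmonic
fingerprint directly (relative amplitudes, A3 = 1, and phases) and are exact
by construction when passed through the analyzer; they encode the published
fingerprint coordinates of the tracer families.  *Physical* presets
parameterize the Langevin equilibrium model with a lognormal core-size law
and a Debye relaxation time, and are used where actual magnetization
dynamics matter (phase-vs-relaxation behaviour, oracle checks).

Ferromagnetic dietary contaminants are modeled as a smooth rectangular
hysteron with per-specimen jitter of its parameters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ParticlePreset",
    "ContaminantPreset",
    "load_registry",
    "get_preset",
]


@dataclass(frozen=True)
class ParticlePreset:
    """A named magnetic-nanoparticle model.

    Exactly one of the two modes is active:

    - ``physical``: ``d_med`` (median core diameter, m), ``sigma_d``
      (lognormal shape), ``M_s`` (core saturation magnetization, A/m) and
      ``tau`` (effective Debye relaxation time, s).
    - ``template``: ``template_amps`` maps odd harmonic order to relative
      amplitude (A3 = 1), ``template_phases`` maps order to phase in degrees
      under the negative-lag convention.
    """

    name: str
    mode: str  # "physical" | "template"
    d_med: float = 0.0
    sigma_d: float = 0.0
    M_s: float = 0.0
    tau: float = 0.0
    template_amps: Mapping[int, float] = field(default_factory=dict)
    template_phases: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode == "physical":
            if self.d_med <= 0:
                raise ValueError("physical preset requires d_med > 0")
            if self.sigma_d < 0 or self.M_s <= 0 or self.tau < 0:
                raise ValueError("invalid physical preset parameters")
        elif self.mode == "template":
            amps = dict(self.template_amps)
            if not amps:
                raise ValueError("template preset requires template_amps")
            if any(n % 2 == 0 for n in amps):
                raise ValueError("template orders must be odd")
            if amps.get(3) != 1:
                raise ValueError("template_amps[3] must be 1 (A3 reference)")
            orders = sorted(amps)
            vals = [amps[n] for n in orders]
            if any(v <= 0 or v > 1 for v in vals):
                raise ValueError("relative amplitudes must lie in (0, 1]")
            if any(b > a for a, b in zip(vals, vals[1:])):
                raise ValueError("relative amplitudes must be non-increasing in n")
        else:
            raise ValueError(f"unknown preset mode {self.mode!r}")

    @property
    def orders(self) -> list[int]:
        if self.mode != "template":
            raise ValueError("orders defined for template presets only")
        return sorted(self.template_amps)

    def perturbed(self, phase_shift_deg: float, r53_factor: float) -> "ParticlePreset":
        """Template preset with an environmental perturbation applied.

        ``phase_shift_deg`` shifts every harmonic phase (a common extra lag);
        ``r53_factor`` scales the relative amplitude of every order above 3,
        emulating spectral-shape variation from pH, ionic strength or
        cellular uptake while keeping A3 = 1.
        """
        if self.mode != "template":
            raise ValueError("perturbed() applies to template presets")
        amps = {
            n: (a if n == 3 else min(1.0, a * r53_factor))
            for n, a in self.template_amps.items()
        }
        phases = {n: p + phase_shift_deg for n, p in self.template_phases.items()}
        return replace(self, template_amps=amps, template_phases=phases)


@dataclass(frozen=True)
class ContaminantPreset:
    """Smooth rectangular hysteron model of a ferromagnetic contaminant.

    ``m_c`` saturation moment (A m^2), ``B_c`` coercivity (T), ``B_w``
    switching smoothness (T).  ``jitter`` gives per-specimen randomization
    widths: ``m_c_decades`` (log10 half-width of a log-uniform draw of m_c)
    and uniform half-widths for ``B_c`` and ``B_w``.
    """

    m_c: float
    B_c: float
    B_w: float
    jitter: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m_c <= 0:
            raise ValueError("m_c must be positive")
        if self.B_c < 0:
            raise ValueError("B_c must be non-negative")
        if self.B_w <= 0:
            raise ValueError("B_w must be positive")

    def sample(self, rng: np.random.Generator) -> "ContaminantPreset":
        """Draw a jittered copy (one specimen's contaminant).

        Consumes the same number of random variates regardless of jitter
        widths so that jitter = 0 is exactly reproducible across seeds.
        """
        u = rng.uniform(-1.0, 1.0, size=3)
        dec = float(self.jitter.get("m_c_decades", 0.0))
        m_c = self.m_c * 10.0 ** (u[0] * dec)
        B_c = self.B_c + u[1] * float(self.jitter.get("B_c", 0.0))
        B_w = self.B_w + u[2] * float(self.jitter.get("B_w", 0.0))
        return ContaminantPreset(m_c, max(B_c, 0.0), max(B_w, 1e-5), jitter={})


def _parse_entry(name: str, entry: Mapping) -> ParticlePreset | ContaminantPreset:
    mode = entry.get("mode")
    if mode == "contaminant":
        return ContaminantPreset(
            m_c=float(entry["m_c"]),
            B_c=float(entry["B_c"]),
            B_w=float(entry["B_w"]),
            jitter={k: float(v) for k, v in entry.get("jitter", {}).items()},
        )
    if mode == "template":
        return ParticlePreset(
            name=name,
            mode="template",
            template_amps={int(k): float(v) for k, v in entry["template_amps"].items()},
            template_phases={
                int(k): float(v) for k, v in entry["template_phases"].items()
            },
        )
    if mode == "physical":
        return ParticlePreset(
            name=name,
            mode="physical",
            d_med=float(entry["d_med"]),
            sigma_d=float(entry["sigma_d"]),
            M_s=float(entry["M_s"]),
            tau=float(entry["tau"]),
        )
    raise ValueError(f"preset {name!r}: unknown mode {mode!r}")


def load_registry(path: str | None = None) -> dict:
    """Load a preset registry; with no path, the packaged registry."""
    if path is None:
        text = (
            importlib.resources.files("mpspec.data")
            .joinpath("presets.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: _parse_entry(name, entry) for name, entry in raw.items()}


_REGISTRY_CACHE: dict | None = None


def get_preset(name: str) -> ParticlePreset | ContaminantPreset:
    """Look up a preset from the packaged registry (cached)."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        _REGISTRY_CACHE = load_registry()
    try:
        return _REGISTRY_CACHE[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_REGISTRY_CACHE)}"
        ) from None
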