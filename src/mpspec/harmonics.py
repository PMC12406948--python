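"""Harmonic amplitude/phase spectra of time-domain MPS signals.

The analyzer reports, for each odd harmonic order ``n`` of the drive
frequency, an amplitude ``A_n`` in A m^2 and a phase ``phi_n`` in degrees.
Phases follow the negative-lag convention: the response of an ideal,
lag-free saturable magnetization reads exactly 0 deg at every order, and
any relaxation-induced delay appears as a negative phase.

Because a saturable odd nonlinearity produces harmonics with alternating
sign (+, -, +, ... for n = 1, 3, 5, ...), the raw phase of harmonic ``n``
measured against the drive reference ``sin(2*pi*n*f_ex*t)`` is referenced
to 0 deg or 180 deg depending on ``n mod 4`` before reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .excitation import ExcitationConfig, TimeSignal

__all__ = [
    "HarmonicSpectrum",
    "equilibrium_phase_deg",
    "extract_harmonics",
    "average_spectra",
    "estimate_noise_floor",
]


_EQ_PHASE_CACHE: dict[int, float] = {}


def equilibrium_phase_deg(n: int) -> float:
    """Raw phase reference of harmonic ``n``: 0 or 180 deg.

    Computed once per order as the sign of the Fourier sine coefficient of
    an ideal lag-free saturable response ``tanh(3*sin(wt))`` against the
    drive reference ``sin(n*w*t)``.  Referencing reported phases to this
    makes a relaxation-free sample read exactly 0 deg and any delay read
    negative.  (For a monotone saturable odd response all odd sine
    coefficients turn out positive, so the reference is 0 deg throughout;
    it is still computed rather than assumed.)
    """
    if n % 2 == 0:
        raise ValueError("equilibrium reference defined for odd harmonics")
    if n not in _EQ_PHASE_CACHE:
        theta = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
        b_n = 2.0 * np.mean(np.tanh(3.0 * np.sin(theta)) * np.sin(n * theta))
        _EQ_PHASE_CACHE[n] = 0.0 if b_n >= 0.0 else 180.0
    return _EQ_PHASE_CACHE[n]


def wrap_phase_deg(phi):
    """Wrap angles (degrees) into (-180, 180]."""
    w = (np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return w if w.ndim else float(w)


@dataclass
class HarmonicSpectrum:
    """Odd-harmonic spectrum of one measurement.

    ``A_n`` are moment amplitudes in A m^2; ``phi_n`` are phases in degrees
    (negative = lag); ``noise_floor_n`` is the per-order background
    amplitude estimated from off-harmonic bins.
    """

    orders: np.ndarray
    A_n: np.ndarray
    phi_n: np.ndarray
    noise_floor_n: np.ndarray
    config: ExcitationConfig
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.orders = np.asarray(self.orders, dtype=int)
        self.A_n = np.asarray(self.A_n, dtype=float)
        self.phi_n = np.asarray(self.phi_n, dtype=float)
        self.noise_floor_n = np.asarray(self.noise_floor_n, dtype=float)
        if not (self.orders.size and np.all(np.diff(self.orders) > 0)):
            raise ValueError("orders must be non-empty, strictly increasing")
        if np.any(self.orders % 2 == 0):
            raise ValueError("orders must be odd")
        if np.any(self.A_n < 0):
            raise ValueError("amplitudes must be non-negative")

    def _index(self, n: int) -> int:
        idx = np.nonzero(self.orders == n)[0]
        if idx.size == 0:
            raise KeyError(f"harmonic {n} not present (orders {list(self.orders)})")
        return int(idx[0])

    def amplitude(self, n: int) -> float:
        return float(self.A_n[self._index(n)])

    def phase(self, n: int) -> float:
        return float(self.phi_n[self._index(n)])

    def noise_floor(self, n: int) -> float:
        return float(self.noise_floor_n[self._index(n)])

    def scaled(self, k: float) -> "HarmonicSpectrum":
        """Spectrum with every amplitude (and floor) scaled by ``k``."""
        return replace(
            self, A_n=self.A_n * k, noise_floor_n=self.noise_floor_n * k
        )


def _bin_amplitudes(signal: TimeSignal) -> np.ndarray:
    """Two-sided-corrected DFT bin amplitudes ``2|X_k|/N`` (k = 0..N/2)."""
    x = np.fft.rfft(signal.samples)
    return 2.0 * np.abs(x) / signal.samples.size


def estimate_noise_floor(signal: TimeSignal, n_max: int = 9) -> np.ndarray:
    """Per-order background amplitude from off-harmonic bins.

    For each odd order ``n`` the floor is the median amplitude of the
    non-harmonic DFT bins within one harmonic spacing of bin
    ``n*n_periods``, in the same units as ``A_n``.  With a single acquired
    period there are no off-harmonic bins and the estimate falls back to a
    global median with a warning.
    """
    if n_max % 2 == 0:
        raise ValueError("n_max must be odd")
    cfg = signal.config
    n_p = cfg.n_periods
    amps = _bin_amplitudes(signal)
    n_bins = amps.size
    orders = np.arange(3, n_max + 1, 2)
    harmonic_bins = set(range(0, n_bins, n_p)) if n_p > 1 else set()
    floors = np.empty(orders.size)
    for i, n in enumerate(orders):
        center = n * n_p
        lo, hi = max(1, center - n_p + 1), min(n_bins - 1, center + n_p - 1)
        window = [k for k in range(lo, hi + 1) if k not in harmonic_bins]
        if n_p > 1 and window:
            floors[i] = np.median(amps[window])
        else:
            warnings.warn(
                "no off-harmonic bins near harmonic; using global median",
                stacklevel=2,
            )
            rest = [k for k in range(1, n_bins) if k != center]
            floors[i] = np.median(amps[rest])
    return floors


def extract_harmonics(signal: TimeSignal, n_max: int = 9) -> HarmonicSpectrum:
    """Fourier analysis of one acquisition into ``A_n``/``phi_n``.

    Amplitudes are ``2|c_k|/N`` at the exact harmonic bins (rectangular
    window over an integer number of periods; no leakage).  Voltage-mode
    signals are deconverted to moment units per harmonic (divide by
    ``2*pi*n*f_ex``, rotate the phase by +90 deg).
    """
    if n_max % 2 == 0:
        raise ValueError("n_max must be odd")
    cfg = signal.config
    if n_max > cfg.max_harmonic():
        raise ValueError(
            f"n_max = {n_max} exceeds Nyquist-supported harmonic "
            f"{cfg.max_harmonic()} at {cfg.samples_per_period} samples/period"
        )
    n = signal.samples.size
    spec = np.fft.rfft(signal.samples)
    orders = np.arange(3, n_max + 1, 2)
    bins = orders * cfg.n_periods
    phasors = 2.0 * spec[bins] / n
    A = np.abs(phasors)
    # raw phase theta such that the component is A*sin(n*w*t + theta)
    theta = np.degrees(np.angle(phasors)) + 90.0
    if signal.voltage_mode:
        A = A / (2.0 * np.pi * orders * cfg.f_ex)
        theta = theta + 90.0
    ref = np.array([equilibrium_phase_deg(int(k)) for k in orders])
    phi = wrap_phase_deg(theta - ref)
    floors = estimate_noise_floor(signal, n_max=n_max)
    if signal.voltage_mode:
        floors = floors / (2.0 * np.pi * orders * cfg.f_ex)
    return HarmonicSpectrum(
        orders=orders,
        A_n=A,
        phi_n=phi,
        noise_floor_n=floors,
        config=cfg,
        sample_id=signal.sample_id,
    )


def average_spectra(spectra: list[HarmonicSpectrum]) -> HarmonicSpectrum:
    """Complex (phasor) average of repeated measurements.

    Identical spectra average to themselves; incoherent noise is attenuated
    by sqrt(K), which is reflected in the averaged noise floors.
    """
    if not spectra:
        raise ValueError("cannot average an empty list of spectra")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.orders, first.orders):
            raise ValueError("spectra have mismatched harmonic orders")
        if s.config != first.config:
            raise ValueError("spectra have mismatched acquisition configs")
    k = len(spectra)
    z = np.mean(
        [s.A_n * np.exp(1j * np.radians(s.phi_n)) for s in spectra], axis=0
    )
    floors = np.mean([s.noise_floor_n for s in spectra], axis=0) / np.sqrt(k)
    return HarmonicSpectrum(
        orders=first.orders.copy(),
        A_n=np.abs(z),
        phi_n=wrap_phase_deg(np.degrees(np.angle(z))),
        noise_floor_n=floors,
        config=first.config,
        sample_id=f"avg[{k}]:{first.sample_id}",
    )
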