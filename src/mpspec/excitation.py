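"""Acquisition configuration and time-domain signal container.

An MPS measurement drives the sample with a sinusoidal field
``B(t) = B_ex * sin(2*pi*f_ex*t)`` and records the dynamic magnetic moment
(or, on a real spectrometer, the induction voltage, which is proportional
to ``-dm/dt``).  Signals are always an integer number of excitation periods
with an integer number of samples per period, so that every harmonic falls
on an exact DFT bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExcitationConfig", "TimeSignal", "DEFAULT_EXCITATION"]


@dataclass(frozen=True)
class ExcitationConfig:
    """Sinusoidal drive and sampling parameters of one acquisition.

    Parameters
    ----------
    f_ex
        Excitation frequency in Hz.
    B_ex
        Excitation field amplitude in T.
    sample_rate
        Sampling rate in Hz.  Must be an integer multiple of ``f_ex``.
    n_periods
        Number of excitation periods acquired.
    temperature
        Sample temperature in K (enters the Langevin argument).
    """

    f_ex: float = 25e3
    B_ex: float = 25e-3
    sample_rate: float = 64 * 25e3
    n_periods: int = 16
    temperature: float = 296.0

    def __post_init__(self) -> None:
        if self.f_ex <= 0:
            raise ValueError("f_ex must be positive")
        if self.B_ex <= 0:
            raise ValueError("B_ex must be positive")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        ratio = self.sample_rate / self.f_ex
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 2:
            raise ValueError(
                "sample_rate must be an integer multiple of f_ex "
                f"(got sample_rate/f_ex = {ratio})"
            )

    @property
    def samples_per_period(self) -> int:
        return round(self.sample_rate / self.f_ex)

    @property
    def n_samples(self) -> int:
        return self.samples_per_period * self.n_periods

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def time(self) -> np.ndarray:
        """Sample times in s."""
        return np.arange(self.n_samples) * self.dt

    def field(self, t: np.ndarray | None = None) -> np.ndarray:
        """Drive field B(t) in T at the sample times (or at given times)."""
        if t is None:
            t = self.time()
        return self.B_ex * np.sin(2 * np.pi * self.f_ex * np.asarray(t))

    def max_harmonic(self) -> int:
        """Largest odd harmonic strictly below Nyquist."""
        n = int(self.samples_per_period // 2) - 1
        return n if n % 2 == 1 else n - 1


DEFAULT_EXCITATION = ExcitationConfig()


@dataclass
class TimeSignal:
    """One sampled measurement.

    ``samples`` holds the magnetic moment in A m^2, or the moment rate in
    A m^2/s when ``voltage_mode`` is set (the induction-voltage picture,
    ``u(t) ~ -dm/dt``).
    """

    samples: np.ndarray
    config: ExcitationConfig
    sample_id: str = ""
    voltage_mode: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size != self.config.n_samples:
            raise ValueError(
                f"signal length {self.samples.size} does not match "
                f"n_periods*sample_rate/f_ex = {self.config.n_samples}"
            )

    @property
    def dt(self) -> float:
        return self.config.dt

    def with_samples(self, samples: np.ndarray) -> "TimeSignal":
        return TimeSignal(samples, self.config, self.sample_id, self.voltage_mode)

    def to_voltage_mode(self) -> "TimeSignal":
        """Spectral derivative: return ``-dm/dt`` as a voltage-mode signal."""
        if self.voltage_mode:
            return self
        n = self.samples.size
        freqs = np.fft.rfftfreq(n, d=self.dt)
        spec = np.fft.rfft(self.samples)
        dspec = spec * (2j * np.pi * freqs)
        samples = -np.fft.irfft(dspec, n=n)
        return TimeSignal(samples, self.config, self.sample_id, voltage_mode=True)

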