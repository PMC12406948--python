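"""Independent numerical oracles used only by the test suite.

These deliberately avoid the code paths they check: the Debye dynamics
oracle is a fixed-step RK4 time integrator with explicit transient decay
(the implementation solves the periodic steady state spectrally), and the
hysteron oracle projects a densely sampled branch waveform onto the
harmonic basis by quadrature (the implementation goes through the sampled
DFT).
"""

import numpy as np

from mpspec import ExcitationConfig, equilibrium_moment
from mpspec.harmonics import equilibrium_phase_deg, wrap_phase_deg


def rk4_debye_moment(config: ExcitationConfig, preset, iron_mass: float,
                     oversample: int = 100) -> np.ndarray:
    """Steady-state moment samples via brute-force RK4 at fine steps.

    Integrates dm/dt = (m_eq(B(t)) - m)/tau from m(0) = m_eq(B(0)) with a
    fixed step of dt/oversample, discards a transient of
    max(10 periods, 10 tau), and returns the following n_periods sampled
    on the acquisition grid.
    """
    tau = preset.tau
    spp = config.samples_per_period
    n_transient = max(10, int(np.ceil(10.0 * tau * config.f_ex)))
    total_periods = n_transient + config.n_periods
    n_steps = total_periods * spp * oversample
    h = config.dt / oversample
    t_half = np.arange(2 * n_steps + 1) * (h / 2.0)
    m_eq = equilibrium_moment(config.field(t_half), preset, iron_mass, config)
    if tau == 0.0:
        m_all = m_eq[::2]
    else:
        m_all = np.empty(n_steps + 1)
        m = m_eq[0]
        m_all[0] = m
        for i in range(n_steps):
            e0, e1, e2 = m_eq[2 * i], m_eq[2 * i + 1], m_eq[2 * i + 2]
            k1 = (e0 - m) / tau
            k2 = (e1 - (m + 0.5 * h * k1)) / tau
            k3 = (e1 - (m + 0.5 * h * k2)) / tau
            k4 = (e2 - (m + h * k3)) / tau
            m = m + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            m_all[i + 1] = m
    start = n_transient * spp * oversample
    return m_all[start::oversample][: config.n_samples]


def hysteron_harmonic(config: ExcitationConfig, m_c: float, B_c: float,
                      B_w: float, n: int, n_grid: int = 200_000):
    """(A_n, phi_n) of the hysteron branch waveform by dense quadrature.

    Builds the two-branch loop over one drive period on a dense phase grid
    and projects onto sin/cos(n*theta) with the trapezoidal rule, then
    applies the same equilibrium phase reference the analyzer uses.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    B = config.B_ex * np.sin(theta)
    ascending = np.cos(theta) >= 0.0
    m = np.where(
        ascending,
        m_c * np.tanh((B - B_c) / B_w),
        m_c * np.tanh((B + B_c) / B_w),
    )
    b = 2.0 * np.mean(m * np.sin(n * theta))
    a = 2.0 * np.mean(m * np.cos(n * theta))
    amplitude = float(np.hypot(a, b))
    theta_raw = np.degrees(np.arctan2(a, b))  # m ~ A*sin(n th + theta_raw)
    phi = float(wrap_phase_deg(theta_raw - equilibrium_phase_deg(n)))
    return amplitude, phi
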