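import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpspec import (
    ContaminantPreset,
    ExcitationConfig,
    ParticlePreset,
    equilibrium_moment,
    extract_harmonics,
    generate_blanks,
    langevin,
    mix_signals,
    saturation_moment,
    simulate_contaminant,
    simulate_physical,
    synthesize_template,
)
from mpspec.constants import K_B

from _oracles import hysteron_harmonic


class TestLangevin:
    def test_fixed_values(self):
        assert langevin(0.0) == 0.0
        assert langevin(1.0) == pytest.approx(0.3130352855, abs=1e-9)
        assert langevin(-1.0) == pytest.approx(-0.3130352855, abs=1e-9)

    @given(st.floats(-500, 500, allow_nan=False))
    @settings(deadline=None, max_examples=200)
    def test_odd_and_bounded(self, x):
        y = langevin(x)
        assert -1.0 < y < 1.0 or x == 0
        assert langevin(-x) == pytest.approx(-y, abs=1e-15)

    def test_series_branch_continuous(self):
        # values straddling the series/closed-form switch at |xi| = 1e-4
        xs = np.array([9.9e-5, 1.01e-4])
        ys = langevin(xs)
        assert np.all(np.abs(ys - xs / 3.0) < 1e-12)


class TestEquilibriumMoment:
    def single_size(self):
        return ParticlePreset("mono", "physical", d_med=5e-9, sigma_d=0.0,
                              M_s=3e5, tau=0.0)

    def test_single_size_matches_direct_langevin(self, cfg):
        # xi = M_s * (pi/6) d^3 * B / (k_B T) evaluated independently
        p = self.single_size()
        cfg300 = dataclasses.replace(cfg, temperature=300.0)
        m_p = p.M_s * np.pi / 6.0 * (5e-9) ** 3
        xi = m_p * 25e-3 / (K_B * 300.0)
        assert xi == pytest.approx(0.1185, abs=2e-4)
        m_sat = saturation_moment(1e-9, p.M_s)
        expected = m_sat * langevin(xi)
        got = equilibrium_moment(25e-3, p, 1e-9, cfg300)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got / m_sat == pytest.approx(0.0394, abs=3e-4)

    def test_odd_monotone_saturating(self, cfg):
        p = ParticlePreset("poly", "physical", d_med=12e-9, sigma_d=0.3,
                           M_s=3e5, tau=0.0)
        B = np.linspace(-0.2, 0.2, 41)
        m = equilibrium_moment(B, p, 1e-9, cfg)
        assert np.allclose(m, -m[::-1], rtol=1e-12)
        assert np.all(np.diff(m) > 0)
        m_sat = saturation_moment(1e-9, p.M_s)
        assert np.all(np.abs(m) <= m_sat)
        # Langevin limit: strong field reaches saturation within 2%
        d_big = np.exp(np.log(12e-9) + 4 * 0.3)
        m_small = p.M_s * np.pi / 6.0 * np.exp(np.log(12e-9) - 4 * 0.3) ** 3
        B_strong = 50 * K_B * cfg.temperature / m_small
        assert equilibrium_moment(B_strong, p, 1e-9, cfg) > 0.98 * m_sat

    def test_template_preset_rejected(self, cfg, vsop):
        with pytest.raises(ValueError):
            equilibrium_moment(0.01, vsop, 1e-9, cfg)


class TestSimulatePhysical:
    def test_tau_zero_equals_equilibrium_sampling(self, cfg):
        p = ParticlePreset("p", "physical", d_med=8e-9, sigma_d=0.2,
                           M_s=3e5, tau=0.0)
        sig = simulate_physical(cfg, p, 1e-9)
        expected = equilibrium_moment(cfg.field(), p, 1e-9, cfg)
        assert np.allclose(sig.samples, expected, rtol=1e-10)
        phases = extract_harmonics(sig).phi_n
        assert np.all(np.abs(phases) < 0.1)

    def test_linear_in_iron_mass(self, cfg):
        p = ParticlePreset("p", "physical", d_med=8e-9, sigma_d=0.2,
                           M_s=3e5, tau=5e-7)
        s1 = simulate_physical(cfg, p, 1e-9)
        s2 = simulate_physical(cfg, p, 2e-9)
        assert np.allclose(s2.samples, 2.0 * s1.samples, rtol=1e-12)

    def test_half_period_antisymmetry_kills_even_harmonics(self, cfg):
        p = ParticlePreset("p", "physical", d_med=10e-9, sigma_d=0.25,
                           M_s=3e5, tau=1e-6)
        sig = simulate_physical(cfg, p, 1e-9)
        half = cfg.samples_per_period // 2
        one = sig.samples[: cfg.samples_per_period]
        assert np.allclose(np.roll(one, half), -one, atol=1e-18 + 1e-9 * np.max(np.abs(one)))
        spec = np.abs(np.fft.rfft(sig.samples)) * 2 / sig.samples.size
        a3 = spec[3 * cfg.n_periods]
        even_bins = spec[2 * cfg.n_periods::2 * cfg.n_periods]
        assert np.all(even_bins < 1e-6 * a3)

    def test_phase_lag_monotone_in_tau(self, cfg):
        phis = []
        for tau in (0.0, 2e-7, 5e-7, 1e-6, 2e-6):
            p = ParticlePreset("p", "physical", d_med=10e-9, sigma_d=0.25,
                               M_s=3e5, tau=tau)
            phis.append(extract_harmonics(simulate_physical(cfg, p, 1e-9)).phase(3))
        assert phis[0] == pytest.approx(0.0, abs=0.1)
        assert np.all(np.diff(phis) < 0)  # increasingly negative lag

    def test_reproducible_under_seed(self, cfg):
        p = ParticlePreset("p", "physical", d_med=8e-9, sigma_d=0.2,
                           M_s=3e5, tau=0.0)
        a = simulate_physical(cfg, p, 1e-9, noise_sd=1e-11, seed=5)
        b = simulate_physical(cfg, p, 1e-9, noise_sd=1e-11, seed=5)
        c = simulate_physical(cfg, p, 1e-9, noise_sd=1e-11, seed=6)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_overlong_relaxation_rejected(self, cfg):
        p = ParticlePreset("p", "physical", d_med=8e-9, sigma_d=0.2,
                           M_s=3e5, tau=101.0 / cfg.f_ex)
        with pytest.raises(ValueError, match="100 excitation periods"):
            simulate_physical(cfg, p, 1e-9)


class TestSynthesizeTemplate:
    def test_single_tone_identity(self, cfg):
        p = ParticlePreset("tone", "template", template_amps={3: 1.0},
                           template_phases={3: 0.0})
        sp = extract_harmonics(synthesize_template(cfg, p, 1e-10))
        assert sp.amplitude(3) == pytest.approx(1e-10, rel=1e-12)
        assert sp.phase(3) == pytest.approx(0.0, abs=1e-9)
        assert sp.amplitude(5) < 1e-25
        assert sp.amplitude(7) < 1e-25

    def test_vsop_fingerprint_exact(self, cfg, vsop):
        sp = extract_harmonics(synthesize_template(cfg, vsop, 1e-10))
        assert sp.amplitude(5) / sp.amplitude(3) == pytest.approx(0.10, rel=1e-9)
        assert sp.phase(3) == pytest.approx(-2.0, abs=1e-9)

    def test_mcp_fingerprint_exact(self, cfg, mcp):
        sp = extract_harmonics(synthesize_template(cfg, mcp, 1e-10))
        assert sp.phase(3) == pytest.approx(-30.0, abs=1e-9)

    def test_even_orders_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ParticlePreset("bad", "template", template_amps={3: 1.0, 4: 0.5},
                           template_phases={})

    def test_physical_preset_rejected(self, cfg):
        p = ParticlePreset("p", "physical", d_med=8e-9, sigma_d=0.2,
                           M_s=3e5, tau=0.0)
        with pytest.raises(ValueError):
            synthesize_template(cfg, p, 1e-10)


class TestSimulateContaminant:
    def test_no_coercivity_reduces_to_anhysteretic(self, cfg):
        p = ContaminantPreset(m_c=1e-9, B_c=0.0, B_w=3e-3)
        sp = extract_harmonics(simulate_contaminant(cfg, p))
        assert np.all(np.abs(sp.phi_n) < 0.1)

    def test_loop_produces_large_phase_lag(self, cfg):
        p = ContaminantPreset(m_c=1e-9, B_c=10e-3, B_w=2e-3)
        sp = extract_harmonics(simulate_contaminant(cfg, p))
        assert abs(sp.phase(3)) > 10.0
        # cross-check amplitude and phase against the dense quadrature oracle
        a3_oracle, phi3_oracle = hysteron_harmonic(cfg, 1e-9, 10e-3, 2e-3, 3)
        assert sp.amplitude(3) == pytest.approx(a3_oracle, rel=0.02)
        assert sp.phase(3) == pytest.approx(phi3_oracle, abs=1.0)

    def test_deterministic_without_jitter(self, cfg):
        p = ContaminantPreset(m_c=1e-9, B_c=10e-3, B_w=2e-3, jitter={})
        a = simulate_contaminant(cfg, p, seed=1)
        b = simulate_contaminant(cfg, p, seed=2)
        assert np.array_equal(a.samples, b.samples)

    def test_jitter_spans_prior(self, cfg, contaminant):
        draws = [contaminant.sample(np.random.default_rng(i)) for i in range(200)]
        b_c = np.array([d.B_c for d in draws])
        b_w = np.array([d.B_w for d in draws])
        assert 5e-3 <= b_c.min() and b_c.max() <= 20e-3
        assert 1e-3 <= b_w.min() and b_w.max() <= 5e-3

    def test_excess_coercivity_rejected(self, cfg):
        p = ContaminantPreset(m_c=1e-9, B_c=30e-3, B_w=2e-3)
        with pytest.raises(ValueError, match="never traversed"):
            simulate_contaminant(cfg, p)


class TestBlanks:
    def test_fixture_statistics_exact(self):
        blanks = generate_blanks()
        assert np.mean(blanks.a3_values) == pytest.approx(1.4e-11, rel=1e-12)
        assert np.std(blanks.a3_values, ddof=1) == pytest.approx(0.2e-11, rel=1e-12)

    def test_random_mode_noise_free_is_zero(self, cfg):
        blanks = generate_blanks(mode="random", n=5, noise_sd=0.0, config=cfg)
        assert np.all(blanks.a3_values == 0.0)

    def test_too_few_blanks_rejected(self):
        with pytest.raises(ValueError):
            generate_blanks(mode="random", n=1)


class TestMixAndScale:
    def test_mixture_is_additive(self, cfg, vsop, contaminant):
        a = synthesize_template(cfg, vsop, 1e-9)
        b = simulate_contaminant(cfg, contaminant, seed=0)
        mixed = mix_signals(a, b)
        assert np.allclose(mixed.samples, a.samples + b.samples)

    def test_doubling_mass_doubles_amplitudes_not_shape(self, cfg, vsop):
        s1 = extract_harmonics(synthesize_template(cfg, vsop, 1e-10))
        s2 = extract_harmonics(synthesize_template(cfg, vsop, 2e-10))
        assert np.allclose(s2.A_n, 2.0 * s1.A_n, rtol=1e-12)
        assert np.allclose(s2.phi_n, s1.phi_n, atol=1e-9)
        r1 = s1.amplitude(5) / s1.amplitude(3)
        r2 = s2.amplitude(5) / s2.amplitude(3)
        assert r1 == pytest.approx(r2, rel=1e-12)
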