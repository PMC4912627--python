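"""Delayed-coupling oscillator chain: frequency profiles, collective
frequency, steady wave patterns, stability, synchrony."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from segclock.oscillator import (
    TWO_PI,
    OscillatorParams,
    SteadyPattern,
    characterize_pattern,
    collective_frequency,
    collective_frequency_roots,
    damascus_like_params,
    desync_resync,
    frequency_profile,
    order_parameter,
    phase_diagram,
    probe_stability,
    simulate,
    solve_preset_pattern,
    solve_steady_pattern,
    wt_like_params,
)

W0 = TWO_PI / 23.5


def _uniform_pair(eps, tau, **kw):
    return OscillatorParams(n_cells=2, omega0=W0, epsilon=eps, tau=tau,
                            advection_v=0.0, profile_shape="uniform", **kw)


# ---------------------------------------------------------------------------
# frequency profile


def test_profile_maximum_at_tailbud_and_arrest_at_front():
    p = OscillatorParams(profile_shape="linear")
    L = p.psm_length_L
    assert frequency_profile(0.0, p) == pytest.approx(p.omega0)
    assert frequency_profile(L, p) == pytest.approx(0.0, abs=1e-12)


def test_profile_exponential_closed_form():
    p = OscillatorParams(profile_shape="exponential",
                         profile_params=(("x0", 150.0),))
    assert frequency_profile(150.0, p) == pytest.approx(p.omega0 / math.e)


@pytest.mark.parametrize("shape", ["linear", "exponential", "sigmoid",
                                   "uniform"])
def test_profile_non_increasing(shape):
    p = OscillatorParams(profile_shape=shape)
    x = np.linspace(0.0, p.psm_length_L, 200)
    w = frequency_profile(x, p)
    assert np.all(np.diff(w) <= 1e-12)
    assert w[-1] >= -1e-12


def test_profile_domain_error():
    p = OscillatorParams()
    with pytest.raises(ValueError):
        frequency_profile(-5.0, p)
    with pytest.raises(ValueError):
        frequency_profile(p.psm_length_L + 5.0, p)


# ---------------------------------------------------------------------------
# parameter validation


def test_dt_must_resolve_delay():
    with pytest.raises(ValueError):
        OscillatorParams(tau=1.0, dt=2.0)


def test_cfl_bound():
    with pytest.raises(ValueError):
        OscillatorParams(advection_v=100.0, dt=1.0, spacing_a=10.0)


# ---------------------------------------------------------------------------
# collective frequency


def test_delay_free_collective_frequency_is_omega0():
    for eps in (0.0, 0.05, 0.2, 1.0):
        assert abs(collective_frequency(W0, eps, 0.0) - W0) < 1e-10


def test_collective_frequency_satisfies_self_consistency():
    Om = collective_frequency(W0, 0.1, 14.0)
    assert Om - W0 + 0.1 * math.sin(Om * 14.0) == pytest.approx(0.0,
                                                               abs=1e-12)
    assert any(abs(r - Om) < 1e-10
               for r in collective_frequency_roots(W0, 0.1, 14.0))


# ---------------------------------------------------------------------------
# simulate


def test_uncoupled_identical_oscillators_advance_linearly():
    p = OscillatorParams(n_cells=5, omega0=W0, epsilon=0.0, advection_v=0.0,
                         profile_shape="uniform", noise_sigma=0.0)
    traj = simulate(p, duration=3 * p.natural_period, initial="inphase")
    expected = W0 * traj.times[:, None]
    assert np.max(np.abs(traj.phases - expected)) < 1e-9


def test_simulate_reproducible_for_fixed_seed():
    p = OscillatorParams(n_cells=10, noise_sigma=0.05, advection_v=0.0,
                         profile_shape="uniform", seed=5)
    a = simulate(p, 20.0)
    b = simulate(p, 20.0)
    assert np.array_equal(a.phases, b.phases)


def test_delay_free_coupled_frequency_is_omega0_exactly():
    p = _uniform_pair(0.1, 0.0)
    T = TWO_PI / W0
    traj = simulate(p, 20 * T, initial="inphase")
    m = traj.times >= 10 * T
    slope = stats.linregress(traj.times[m], traj.phases[m, 0]).slope
    assert slope == pytest.approx(W0, abs=1e-10)


@pytest.mark.parametrize("eps_frac", [0.05, 0.1, 0.2])
@pytest.mark.parametrize("tau_frac", [0.1, 0.5, 1.0])
def test_two_site_frequency_matches_self_consistency_root(eps_frac,
                                                          tau_frac):
    """Long-run two-oscillator frequency equals the homotopy-continued root
    of Omega = omega0 - eps sin(Omega tau) (stable in-phase states only)."""
    eps = eps_frac * W0
    tau = tau_frac * TWO_PI / W0
    Om = collective_frequency(W0, eps, tau)
    if math.cos(Om * tau) <= 0.0:
        pytest.skip("in-phase state linearly unstable at this delay")
    p = _uniform_pair(eps, tau)
    T = TWO_PI / W0
    traj = simulate(p, 40 * T, initial="inphase")
    m = traj.times >= 20 * T
    slope = stats.linregress(traj.times[m], traj.phases[m, 0]).slope
    assert abs(slope - Om) < 1e-4


# ---------------------------------------------------------------------------
# steady patterns


def test_uncoupled_pattern_matches_closed_form(uncoupled_params):
    """eps=0: K = omega0 L / (4 pi v) and lambda_A = 2 pi v / omega0 for the
    linear profile, to 2% on a 200-site chain."""
    p = uncoupled_params
    pat = solve_steady_pattern(p)
    assert pat.converged and pat.residual < 1e-8
    K_exact = p.omega0 * p.psm_length_L / (4 * math.pi * p.advection_v)
    lam_exact = TWO_PI * p.advection_v / p.omega0
    assert pat.wave_count_K == pytest.approx(K_exact, rel=0.02)
    assert pat.anterior_wavelength == pytest.approx(lam_exact, rel=0.02)
    assert pat.collective_frequency_Omega == pytest.approx(p.omega0,
                                                           abs=1e-10)


def test_uncoupled_uniform_profile_is_flat():
    p = OscillatorParams(n_cells=50, epsilon=0.0, advection_v=3.0,
                         profile_shape="uniform")
    pat = solve_steady_pattern(p)
    assert np.max(np.abs(pat.psi)) < 1e-9
    assert pat.wave_count_K == pytest.approx(0.0, abs=1e-9)
    assert math.isnan(pat.anterior_wavelength)  # wavelength undefined


def test_wave_count_consistent_with_wavelength_integral(wt_pattern):
    lam = wt_pattern.local_wavelength
    K_int = np.trapezoid(1.0 / lam, wt_pattern.positions)
    assert wt_pattern.wave_count_K == pytest.approx(K_int, rel=0.02)


def test_characterize_uniform_gradient_pattern():
    lam0 = 50.0
    p = OscillatorParams(n_cells=40, spacing_a=5.0)
    psi = -TWO_PI * p.positions / lam0
    pat = SteadyPattern(
        collective_frequency_Omega=p.omega0, psi=psi, positions=p.positions,
        local_wavelength=np.full(40, np.nan), wave_count_K=np.nan,
        anterior_wavelength=np.nan, residual=0.0, converged=True, params=p)
    lam_A, K = characterize_pattern(pat)
    assert np.allclose(pat.local_wavelength, lam0)
    assert lam_A == pytest.approx(lam0)
    # the discrete chain spans (N-1) spacings
    assert K == pytest.approx(p.positions[-1] / lam0, rel=1e-9)


def test_solver_and_simulator_agree_on_the_pattern():
    """A simulation started on the solved pattern stays on it to better
    than 1e-3 rad over 10 collective periods."""
    params = wt_like_params()
    pat = solve_preset_pattern(params)
    assert pat.residual < 1e-8
    rep = probe_stability(params, pat, perturbation_amplitude=0.0, seed=0,
                          n_periods=10, transient_periods=0.0)
    assert rep.perturbation_norm_trace.max() < 1e-3


def test_lattice_omega_near_scalar_root():
    """The finite-lattice collective frequency sits within a tenth of a
    percent of the homogeneous-posterior self-consistency root."""
    params = wt_like_params()
    pat = solve_preset_pattern(params)
    Om_scalar = max(collective_frequency_roots(params.omega0, params.epsilon,
                                               params.tau))
    assert pat.collective_frequency_Omega == pytest.approx(Om_scalar,
                                                           rel=1e-3)


# ---------------------------------------------------------------------------
# stability


def test_uncoupled_pattern_is_stable(uncoupled_params):
    """With eps=0, advection flushes perturbations anteriorly and the
    zero-mean deviation decays."""
    pat = solve_steady_pattern(uncoupled_params)
    rep = probe_stability(uncoupled_params, pat, seed=1)
    assert rep.stable
    assert rep.growth_rate < 0


def test_two_site_inphase_stable_antiphase_unstable():
    """Two delay-free oscillators: linearizing the implemented coupling
    around the in-phase state gives decay at rate eps/2; around the
    anti-phase state, growth at eps/2."""
    eps = 0.1
    p = _uniform_pair(eps, 0.0)
    inphase = SteadyPattern(
        collective_frequency_Omega=W0, psi=np.array([0.0, 0.0]),
        positions=p.positions, local_wavelength=np.full(2, np.nan),
        wave_count_K=0.0, anterior_wavelength=np.nan, residual=0.0,
        converged=True, params=p)
    rep = probe_stability(p, inphase, seed=2)
    assert rep.stable
    assert rep.growth_rate == pytest.approx(-eps / 2, rel=0.2)

    antiphase = SteadyPattern(
        collective_frequency_Omega=W0, psi=np.array([0.0, math.pi]),
        positions=p.positions, local_wavelength=np.full(2, np.nan),
        wave_count_K=0.5, anterior_wavelength=np.nan, residual=0.0,
        converged=True, params=p)
    rep2 = probe_stability(p, antiphase, seed=2)
    assert not rep2.stable
    assert rep2.growth_rate > 0


def test_preset_patterns_are_stable(wt_pattern, damascus_pattern):
    for params, pat in ((wt_like_params(), wt_pattern),
                        (damascus_like_params(), damascus_pattern)):
        rep = probe_stability(params, pat, seed=4)
        assert rep.stable


# ---------------------------------------------------------------------------
# phase diagram


@pytest.fixture(scope="module")
def small_diagram():
    base = OscillatorParams(n_cells=50, spacing_a=10.0, omega0=W0,
                            profile_shape="linear", advection_v=3.0)
    return base, phase_diagram([0.0, 0.05, 0.10], [0.0, 14.0], base,
                               n_init=4, seed=0)


def test_diagram_eps_zero_column_matches_closed_form(small_diagram):
    base, cells = small_diagram
    K_exact = base.omega0 * base.psm_length_L / (4 * math.pi
                                                 * base.advection_v)
    for c in cells:
        if c.epsilon == 0.0:
            assert c.stable and c.n_solutions == 1
            # 50-site discretization bias ~1/N
            assert c.wave_count_K == pytest.approx(K_exact, rel=0.03)


def test_diagram_tau_zero_row_keeps_omega0(small_diagram):
    base, cells = small_diagram
    from dataclasses import replace
    for c in cells:
        if c.tau == 0.0 and c.stable and c.n_solutions == 1:
            p = replace(base, epsilon=c.epsilon, tau=0.0, dt=None)
            pat = solve_steady_pattern(p)
            # the exact lattice frequency deviates from omega0 by the
            # posterior boundary-gradient term, O(eps * a * omega0 / (v L))
            assert pat.collective_frequency_Omega == pytest.approx(
                base.omega0, rel=5e-3)


def test_diagram_has_damascus_direction_region(small_diagram):
    """At a fixed delay there is a stable-unique region where raising the
    coupling strength increases the wave count and shortens the anterior
    wavelength — the elevated-coupling signature."""
    _, cells = small_diagram
    row = sorted((c for c in cells if c.tau == 14.0 and c.stable
                  and c.n_solutions == 1), key=lambda c: c.epsilon)
    assert len(row) >= 2
    found = any(
        b.wave_count_K > a.wave_count_K
        and b.anterior_wavelength < a.anterior_wavelength
        for a, b in zip(row, row[1:])
    )
    assert found


def test_wt_vs_damascus_presets_reproduce_signature(wt_pattern,
                                                    damascus_pattern):
    assert damascus_pattern.wave_count_K > wt_pattern.wave_count_K
    assert (damascus_pattern.anterior_wavelength
            < wt_pattern.anterior_wavelength)
    ratio = (wt_pattern.anterior_wavelength
             / damascus_pattern.anterior_wavelength)
    assert ratio == pytest.approx(1.27, abs=0.02)


# ---------------------------------------------------------------------------
# order parameter and resynchronization


def test_order_parameter_basics():
    assert order_parameter(np.zeros(7)) == pytest.approx(1.0)
    for n in (2, 3, 5, 8):
        phases = TWO_PI * np.arange(n) / n
        assert order_parameter(phases) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        order_parameter(np.array([]))


def test_order_parameter_random_phases_small():
    n, hits = 1000, 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        z = order_parameter(rng.uniform(0, TWO_PI, n))
        hits += z <= 3.0 / math.sqrt(n)
    assert hits >= 38  # resultant length of n iid phasors ~ Rayleigh(1/sqrt n)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-100.0, 100.0), min_size=1, max_size=64))
def test_order_parameter_bounded(phases):
    z = order_parameter(np.array(phases))
    assert -1e-12 <= z <= 1.0 + 1e-12


def _resync_params(eps, seed):
    return OscillatorParams(n_cells=50, omega0=W0, epsilon=eps, tau=0.0,
                            noise_sigma=0.08, advection_v=0.0,
                            profile_shape="uniform", seed=seed)


def test_resync_no_block_trivial():
    p = _resync_params(0.1, 0)
    p = OscillatorParams(**{**p.__dict__, "noise_sigma": 0.0, "dt": p.dt})
    st_ = desync_resync(p, 0.0, 0.0, Zc=0.9, segment_period_T=23.5,
                        duration=100.0, seed=0, n_oscillators=30)
    assert np.allclose(st_.Z, 1.0, atol=1e-9)
    assert st_.t_recovery == pytest.approx(0.0, abs=1.0)
    assert st_.predicted_FRS >= 10


def test_resync_censored_without_coupling():
    p = _resync_params(0.0, 1)
    st_ = desync_resync(p, 0.0, 250.0, Zc=0.85, segment_period_T=23.5,
                        duration=600.0, seed=1, n_oscillators=100)
    assert st_.t_recovery is None and st_.predicted_FRS is None
    assert st_.Zmin < 0.85
    assert np.all((st_.Z >= 0.0) & (st_.Z <= 1.0))


def test_doubled_coupling_recovers_faster_on_matched_seeds():
    wins = 0
    n = 10
    for seed in range(n):
        lo = desync_resync(_resync_params(0.05, seed), 0.0, 250.0, 0.85,
                           23.5, duration=900.0, seed=seed,
                           n_oscillators=100)
        hi = desync_resync(_resync_params(0.10, seed), 0.0, 250.0, 0.85,
                           23.5, duration=900.0, seed=seed,
                           n_oscillators=100)
        assert hi.t_recovery is not None and lo.t_recovery is not None
        wins += hi.t_recovery < lo.t_recovery
    assert wins >= 9
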