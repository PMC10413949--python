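import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutflux.chemistry import KineticParams
from gutflux.digestion import DigestionParams
from gutflux.exchange import (
    GutSystem,
    SystemState,
    Trajectory,
    bioavailability_reduction,
    fold_increase,
    initialize_state,
    simulate,
    water_fraction,
)

NO_DIGESTION = DigestionParams(ffa_max=0.0, k_ffa=1.0, micelle0=5.7e-3, oil0=8.76e-2)


def make_system(**kw) -> GutSystem:
    return GutSystem(digestion=kw.pop("digestion", NO_DIGESTION), **kw)


def make_params(**kw) -> KineticParams:
    defaults = dict(k1=1e4, k2=0.5, k_micelle=1e5, k_oil=1e6, k_pom=1e5, f1=1.0)
    defaults.update(kw)
    return KineticParams(**defaults)


# --- water fraction -------------------------------------------------------


def test_water_fraction_is_one_without_sorbing_phases():
    kp = make_params(k_micelle=0.0, k_oil=0.0, k_pom=0.0)
    assert water_fraction(kp, 1.0, 1.0, 1.0) == 1.0
    kp = make_params()
    assert water_fraction(kp, 0.0, 0.0, 0.0) == 1.0


def test_water_fraction_hand_value():
    kp = make_params(k_micelle=1e5, k_oil=0.0, k_pom=0.0)
    assert water_fraction(kp, 5.7e-3, 0.0, 0.0) == pytest.approx(1 / 571.0, rel=1e-12)


@given(st.floats(0.1, 10))
def test_water_fraction_product_invariance(scale):
    kp = make_params()
    kp2 = make_params(k_micelle=kp.k_micelle * scale, k_oil=kp.k_oil * scale,
                      k_pom=kp.k_pom * scale)
    assert water_fraction(kp, 5.7e-3, 8.76e-2, 1.4e-3) == pytest.approx(
        water_fraction(kp2, 5.7e-3 / scale, 8.76e-2 / scale, 1.4e-3 / scale),
        rel=1e-12,
    )


# --- initial conditions ---------------------------------------------------


def test_total_anchor_symmetric_partitioning():
    """Equal K and equal phase concentrations split the load equally."""
    d = DigestionParams(ffa_max=0.0, k_ffa=1.0, micelle0=1.0, oil0=1.0)
    sys = make_system(digestion=d, ldpe_conc0=1.0, dilution_factor=1.0,
                      n_strips0=10, removal_times=())
    # K_micelle*[mic] = K_oil*[oil] = (k1/k2)/f1 = 1 each; water also 1 share
    kp = make_params(k_micelle=1.0, k_oil=1.0, k_pom=0.0, k1=1.0, k2=1.0, f1=1.0)
    s0 = initialize_state(sys, kp, c_total=100.0)
    m_total = 100.0 * sys.v_w
    assert s0.m_ldpe == pytest.approx(m_total / 4)
    assert s0.m_pool == pytest.approx(3 * m_total / 4)


def test_pom_anchor_direct_substitution():
    sys = make_system(dilution_factor=1.0, removal_times=())
    kp = make_params(k_pom=1e6)
    s0 = initialize_state(sys, kp, c_pom_star_day28=1e6, c_ldpe_star0=50.0)
    c_w = 1.0  # 1e6 / 1e6
    m_mic = kp.k_micelle * NO_DIGESTION.micelle0 * c_w * sys.v_w
    m_oil = kp.k_oil * NO_DIGESTION.oil0 * c_w * sys.v_w
    m_w = c_w * sys.v_w
    assert s0.m_pool == pytest.approx(m_w + m_mic + m_oil, rel=1e-12)
    assert s0.m_ldpe == pytest.approx(50.0 * sys.ldpe_conc0 * sys.v_w, rel=1e-12)


def test_fast_slow_split_follows_f1():
    sys = make_system(dilution_factor=1.0, removal_times=())
    s0 = initialize_state(sys, make_params(f1=1.0), c_total=10.0)
    assert s0.m_ldpe_slow == 0.0
    s0 = initialize_state(sys, make_params(f1=0.25), c_total=10.0)
    assert s0.m_ldpe_fast == pytest.approx(s0.m_ldpe_slow / 3)


def test_anchor_usage_errors():
    sys = make_system()
    kp = make_params()
    with pytest.raises(ValueError):
        initialize_state(sys, kp)
    with pytest.raises(ValueError):
        initialize_state(sys, kp, c_total=1.0, c_pom_star_day28=1.0)


# --- simulation -----------------------------------------------------------


def closed_form_fast(t, k1, k2, f_w, c_a, c0):
    """Analytic single-exponential relaxation of the linear two-pool system."""
    lam = k1 * f_w + k2
    c_eq = k1 * f_w * c_a / lam
    return c_eq + (c0 - c_eq) * np.exp(-lam * np.asarray(t))


def test_equilibrium_start_is_fixed_point():
    sys = make_system(removal_times=(), dilution_factor=1.0)
    kp = make_params()
    s0 = initialize_state(sys, kp, c_total=80.0)
    t = np.linspace(0, 72, 25)
    traj = simulate(sys, kp, s0, t)
    c = traj.c_ldpe_star
    assert np.max(np.abs(c / c[0] - 1)) < 1e-8


def test_simulation_matches_closed_form_oracle():
    """Constant compartments, no removals: single-exponential relaxation."""
    sys = make_system(removal_times=(), dilution_factor=1.0)
    kp = make_params(k1=2e4, k2=0.8)
    eq = initialize_state(sys, kp, c_total=60.0)
    s0 = replace(eq, m_ldpe_fast=0.1 * eq.m_ldpe_fast,
                 m_pool=eq.m_pool + 0.9 * eq.m_ldpe_fast)
    t = np.linspace(0, 24, 49)
    traj = simulate(sys, kp, s0, t)
    f_w = water_fraction(kp, NO_DIGESTION.micelle0, NO_DIGESTION.oil0, 0.0)
    c_a = (s0.m_ldpe_fast + s0.m_pool) / sys.v_w
    expected = closed_form_fast(t, kp.k1, kp.k2, f_w, c_a, s0.m_ldpe_fast / sys.v_w)
    got = np.array([s.m_ldpe_fast / sys.v_w for s in traj.states])
    assert np.max(np.abs(got - expected) / np.max(expected)) < 1e-6


def test_mass_conservation_with_removal_events():
    sys = make_system()  # full 9-event schedule
    kp = make_params(f1=0.5)
    s0 = initialize_state(sys, kp, c_total=80.0, )
    s0 = replace(s0, m_ldpe_fast=0.2 * s0.m_ldpe_fast,
                 m_pool=s0.m_pool + 0.8 * s0.m_ldpe_fast)
    t = np.unique(np.concatenate([np.linspace(0, 72, 37), np.array(sys.removal_times)]))
    traj = simulate(sys, kp, s0, t)
    assert traj.mass_balance_error() < 1e-6
    assert traj.states[-1].strips_remaining == sys.n_strips0 - len(sys.removal_times)
    assert traj.states[-1].m_removed > 0


def test_strip_removal_continuity_of_solid_basis():
    """C*_LDPE is continuous across an event; system-basis C drops by 1/n."""
    sys = make_system(removal_times=(24.0,), dilution_factor=1.0)
    kp = make_params()
    s0 = initialize_state(sys, kp, c_total=50.0)
    eps = 1e-7
    t = np.array([0.0, 24.0 - eps, 24.0, 72.0])
    traj = simulate(sys, kp, s0, t)
    before, after = traj.states[1], traj.states[2]
    n = before.strips_remaining
    assert after.strips_remaining == n - 1
    c_star_before = before.m_ldpe / (before.ldpe_conc * sys.v_w)
    c_star_after = after.m_ldpe / (after.ldpe_conc * sys.v_w)
    assert c_star_after == pytest.approx(c_star_before, rel=1e-6)
    assert after.m_ldpe == pytest.approx(before.m_ldpe * (n - 1) / n, rel=1e-6)


def test_grid_refinement_invariance():
    sys = make_system()
    kp = make_params()
    s0 = initialize_state(sys, kp, c_total=80.0)
    s0 = replace(s0, m_ldpe_fast=0.1 * s0.m_ldpe_fast,
                 m_pool=s0.m_pool + 0.9 * s0.m_ldpe_fast)
    coarse = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0, 48.0, 72.0])
    fine = np.unique(np.concatenate([coarse, np.linspace(0, 72, 289)]))
    tc = simulate(sys, kp, s0, coarse)
    tf = simulate(sys, kp, s0, fine)
    mask = np.isin(tf.times, coarse)
    assert np.allclose(tf.c_ldpe_star[mask], tc.c_ldpe_star, rtol=1e-6)


def test_c_ldpe_star_monotone_in_k1():
    sys = make_system(removal_times=())
    t = np.linspace(0, 48, 13)
    prev = None
    for k1 in (1e3, 1e4, 1e5):
        kp = make_params(k1=k1)
        s0 = initialize_state(sys, kp, c_total=50.0)
        s0 = replace(s0, m_ldpe_fast=0.05 * s0.m_ldpe_fast,
                     m_pool=s0.m_pool + 0.95 * s0.m_ldpe_fast)
        c = simulate(sys, kp, s0, t).c_ldpe_star
        if prev is not None:
            assert np.all(c[1:] >= prev[1:] - 1e-12)
        prev = c


def test_digestion_shifts_water_fraction_and_loading():
    """Lipolysis shrinks the oil pool, freeing chemical for the plastic."""
    strong = DigestionParams(ffa_max=5e4, k_ffa=0.1, micelle0=5.7e-3, oil0=8.76e-2)
    kp = make_params()
    base_sys = make_system(removal_times=(), dilution_factor=1.0)
    dig_sys = make_system(digestion=strong, removal_times=(), dilution_factor=1.0)
    s0 = initialize_state(base_sys, kp, c_total=60.0)
    t = np.linspace(0, 72, 25)
    flat = simulate(base_sys, kp, s0, t).c_ldpe_star
    rising = simulate(dig_sys, kp, s0, t).c_ldpe_star
    assert rising[-1] > flat[-1] * 1.001


# --- scenario metrics -----------------------------------------------------


def test_fold_increase_is_one_at_equilibrium():
    sys = make_system(removal_times=(), dilution_factor=1.0)
    kp = make_params()
    s0 = initialize_state(sys, kp, c_total=40.0)
    traj = simulate(sys, kp, s0, np.linspace(0, 72, 10))
    assert fold_increase(traj) == pytest.approx(1.0, abs=1e-8)


def test_fold_increase_approaches_equilibrium_ratio():
    """Starting the fast pool at 10% of equilibrium gives a factor near 10."""
    sys = make_system(removal_times=(), dilution_factor=1.0)
    kp = make_params()
    eq = initialize_state(sys, kp, c_total=40.0)
    s0 = replace(eq, m_ldpe_fast=0.1 * eq.m_ldpe_fast,
                 m_pool=eq.m_pool + 0.9 * eq.m_ldpe_fast)
    traj = simulate(sys, kp, s0, np.linspace(0, 400, 51))
    assert fold_increase(traj) == pytest.approx(10.0, rel=0.05)
    assert fold_increase(traj) >= 1.0


def test_bioavailability_reduction_zero_without_exchange():
    sys = make_system(removal_times=(), dilution_factor=1.0)
    kp = KineticParams(k1=0.0, k2=0.0, k_micelle=1e5, k_oil=1e6, k_pom=0.0, f1=1.0)
    s0 = SystemState(t=0.0, m_ldpe_fast=1.0, m_ldpe_slow=0.0, m_pool=10.0,
                     strips_remaining=10, ldpe_conc=sys.ldpe_conc0)
    traj = simulate(sys, kp, s0, np.linspace(0, 72, 10))
    assert bioavailability_reduction(traj) == pytest.approx(0.0, abs=1e-10)


def test_bioavailability_reduction_bounded_and_positive_when_loading():
    sys = make_system()
    kp = make_params(f1=0.5)
    s0 = initialize_state(sys, kp, c_total=80.0)
    s0 = replace(s0, m_ldpe_fast=0.1 * s0.m_ldpe_fast,
                 m_pool=s0.m_pool + 0.9 * s0.m_ldpe_fast)
    t = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0, 48.0, 72.0])
    traj = simulate(sys, kp, s0, t)
    red = bioavailability_reduction(traj)
    assert -100.0 <= red <= 100.0
    assert red > 0
    # excluding egested strips can only lower the sequestered share
    assert bioavailability_reduction(traj, include_removed=False) <= red


def test_trajectory_frame_decomposes_pool():
    sys = make_system(removal_times=(), dilution_factor=1.0)
    kp = make_params()
    s0 = initialize_state(sys, kp, c_total=50.0)
    traj = simulate(sys, kp, s0, np.linspace(0, 10, 5))
    df = traj.frame()
    for t_h, sub in df[df.basis == "system"].groupby("t_h"):
        assert sub.value.sum() == pytest.approx(50.0, rel=1e-8)
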