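"""Digestion-coupled chemical exchange between microplastic and gut fluid.

The gut system is a closed, well-mixed vessel holding water, mixed
micelles, olive oil, (optionally) a POM sampler, and LDPE strips.  Water,
micelles, oil and POM equilibrate instantaneously and are lumped into one
"pool"; exchange across the LDPE-water interface is the rate-determining
step and is biphasic: a fast surface/amorphous reservoir (fraction f1 of
plastic-bound chemical, rate constants k1 uptake / k2 desorption on the
system-volume basis) and a slow intrapolymer reservoir (k3), frozen by
default over digestion time scales.

The fast reservoir obeys

    dC_LDPE,fast/dt = k1 * C_w - k2 * C_LDPE,fast        (ug/L, h)

with the freely dissolved concentration recomputed each step from the
pool mass and the time-varying water fraction

    f_w(t) = 1 / (1 + K_micelle*[micelle]_t + K_oil*[oil]_t + K_POM*[POM])

where [micelle]_t grows and [oil]_t shrinks as lipolysis liberates fatty
acids.  Strip removals are discrete events that carry a proportional
share of the LDPE phase and its chemical load out of the system;
solid-phase (ug/kg) concentrations are continuous across an event while
system-basis concentrations drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chemistry import KineticParams
from .digestion import DigestionParams, compartments_at

__all__ = [
    "GutSystem",
    "SystemState",
    "Trajectory",
    "water_fraction",
    "initialize_state",
    "simulate",
    "fold_increase",
    "bioavailability_reduction",
    "DEFAULT_SCHEDULE",
]

#: strip sampling schedule of the digestion assay (hours)
DEFAULT_SCHEDULE = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0, 48.0, 72.0)


@dataclass(frozen=True)
class GutSystem:
    """Geometry and schedule of the simulated gut vessel.

    All concentrations are post-lipase-addition ("final") values.
    Defaults mirror a 69.9 mL gut-fluid vessel receiving 10 mL of lipase
    (volume 79.9 mL), 7 g olive oil, 10 LDPE strips of 0.7 g total, and a
    removal schedule taking one strip at each sampling time.  The POM
    sampler is collected before lipase addition, so [POM] defaults to 0
    during digestion.
    """

    digestion: DigestionParams
    v_w: float = 79.9e-3
    ldpe_conc0: float = 0.7e-3 / 79.9e-3
    n_strips0: int = 10
    removal_times: tuple[float, ...] = DEFAULT_SCHEDULE
    pom_conc: float = 0.0
    dilution_factor: float = 8.0 / 7.0

    def __post_init__(self) -> None:
        if self.v_w <= 0:
            raise ValueError("v_w must be > 0")
        if self.ldpe_conc0 < 0 or self.pom_conc < 0:
            raise ValueError("phase concentrations must be >= 0")
        if self.n_strips0 < len(self.removal_times):
            raise ValueError("more removals scheduled than strips available")
        if list(self.removal_times) != sorted(self.removal_times):
            raise ValueError("removal_times must be sorted")
        if self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class SystemState:
    """Chemical masses (ug) and plastic inventory at one instant.

    m_pool lumps water + micelle + oil + POM (instantaneous equilibrium);
    m_removed is the cumulative chemical mass carried out by sampled
    strips, kept so the closed-system mass balance stays checkable.
    """

    t: float
    m_ldpe_fast: float
    m_ldpe_slow: float
    m_pool: float
    strips_remaining: int
    ldpe_conc: float
    m_removed: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m_ldpe_fast", "m_ldpe_slow", "m_pool", "m_removed"):
            if getattr(self, name) < -1e-9:
                raise ValueError(f"{name} must be >= 0")
        if self.strips_remaining < 0:
            raise ValueError("strips_remaining must be >= 0")

    @property
    def m_ldpe(self) -> float:
        return self.m_ldpe_fast + self.m_ldpe_slow

    @property
    def total_mass(self) -> float:
        """In-system plus removed chemical mass (ug); conserved."""
        return self.m_ldpe_fast + self.m_ldpe_slow + self.m_pool + self.m_removed


def water_fraction(kp: KineticParams, micelle_conc: float, oil_conc: float,
                   pom_conc: float = 0.0) -> float:
    """Freely dissolved fraction of the instantaneously equilibrating pool.

    C_w = f_w * (pool mass / V_w) with
    f_w = 1/(1 + K_micelle*[micelle] + K_oil*[oil] + K_POM*[POM]).
    """
    if micelle_conc < 0 or oil_conc < 0 or pom_conc < 0:
        raise ValueError("phase concentrations must be >= 0")
    return 1.0 / (1.0 + kp.k_micelle * micelle_conc + kp.k_oil * oil_conc
                  + kp.k_pom * pom_conc)


def _ldpe_equilibrium_factor(kp: KineticParams) -> float:
    """K_p*[LDPE]: system-basis LDPE/water concentration ratio at equilibrium.

    At the fast-reservoir steady state C_fast = (k1/k2) C_w, and with the
    slow reservoir at its f1:(1-f1) share the whole-polymer ratio is
    (k1/k2)/f1, independent of the plastic concentration.
    """
    if kp.k2 <= 0:
        raise ValueError("k2 must be > 0 for an equilibrium initial condition")
    return (kp.k1 / kp.k2) / kp.f1


def initialize_state(sys: GutSystem, kp: KineticParams, *,
                     c_pom_star_day28: float | None = None,
                     c_total: float | None = None,
                     c_ldpe_star0: float | None = None) -> SystemState:
    """Equilibrium initial condition at the start of digestion (t = 0 h).

    Exactly one chemical anchor must be supplied:

    * ``c_pom_star_day28`` (ug/kg): the pre-incubation sampler reading.
      C_w = C*_POM/K_POM fixes the water concentration of the pre-dilution
      vessel; micelle and oil loads follow from their partition
      coefficients, and the LDPE load from ``c_ldpe_star0`` (a measured
      t = 0 strip concentration, ug/kg) or, if absent, from the k1/k2
      equilibrium.  Lipase addition then dilutes the vessel by
      ``sys.dilution_factor`` (masses conserved, volume scaled).
    * ``c_total`` (ug/L, post-dilution basis): full equilibrium
      partitioning of the total load across all phases.

    The plastic-bound mass is split f1:(1-f1) between fast and slow
    reservoirs (reservoirs in mutual equilibrium).
    """
    if (c_pom_star_day28 is None) == (c_total is None):
        raise ValueError("supply exactly one of c_pom_star_day28 or c_total")
    d = sys.digestion
    mic0, oil0 = d.micelle0, d.oil0
    m_ldpe_kg = sys.ldpe_conc0 * sys.v_w

    if c_pom_star_day28 is not None:
        # pre-dilution water concentration; phase masses K*conc_pre*C_w*V_pre
        # reduce to K*conc_post*C_w*V_post because conc_pre*V_pre = conc_post*V_post
        c_w = c_pom_star_day28 / kp.k_pom
        v_pre = sys.v_w / sys.dilution_factor
        m_w = c_w * v_pre
        m_mic = kp.k_micelle * mic0 * c_w * sys.v_w
        m_oil = kp.k_oil * oil0 * c_w * sys.v_w
        m_pom = kp.k_pom * sys.pom_conc * c_w * sys.v_w
        if c_ldpe_star0 is not None:
            m_ldpe = c_ldpe_star0 * m_ldpe_kg
        else:
            m_ldpe = _ldpe_equilibrium_factor(kp) * c_w * v_pre
        m_pool = m_w + m_mic + m_oil + m_pom
    else:
        if c_ldpe_star0 is not None:
            raise ValueError("c_ldpe_star0 only combines with the POM anchor")
        m_total = c_total * sys.v_w
        denom = (1.0 + kp.k_micelle * mic0 + kp.k_oil * oil0
                 + kp.k_pom * sys.pom_conc + _ldpe_equilibrium_factor(kp))
        c_w = c_total / denom
        m_ldpe = _ldpe_equilibrium_factor(kp) * c_w * sys.v_w
        m_pool = m_total - m_ldpe

    return SystemState(
        t=0.0,
        m_ldpe_fast=kp.f1 * m_ldpe,
        m_ldpe_slow=(1.0 - kp.f1) * m_ldpe,
        m_pool=m_pool,
        strips_remaining=sys.n_strips0,
        ldpe_conc=sys.ldpe_conc0,
    )


@dataclass
class Trajectory:
    """Simulated time course with per-phase concentration accessors."""

    sys: GutSystem
    kp: KineticParams
    states: list[SystemState]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def c_ldpe_star(self) -> np.ndarray:
        """LDPE chemical concentration on the solid basis (ug/kg)."""
        return np.array([
            s.m_ldpe / (s.ldpe_conc * self.sys.v_w) if s.ldpe_conc > 0 else np.nan
            for s in self.states
        ])

    def mass_balance_error(self) -> float:
        """Max relative deviation of in-system + removed mass from M_total."""
        totals = np.array([s.total_mass for s in self.states])
        return float(np.max(np.abs(totals - totals[0])) / totals[0])

    def frame(self) -> pd.DataFrame:
        """Tidy per-time concentrations on both bases.

        Columns: t_h, phase, basis ('system' ug/L or 'solid' ug/kg), value.
        The pool is decomposed through the instantaneous-equilibrium
        relations C_phase = K_phase*[phase]_t*C_w.
        """
        rows = []
        v = self.sys.v_w
        for s in self.states:
            mic_t, oil_t = compartments_at(s.t, self.sys.digestion)
            f_w = water_fraction(self.kp, float(mic_t), float(oil_t), self.sys.pom_conc)
            c_pool = s.m_pool / v
            c_w = f_w * c_pool
            sysbasis = {
                "water": c_w,
                "micelle": self.kp.k_micelle * float(mic_t) * c_w,
                "oil": self.kp.k_oil * float(oil_t) * c_w,
                "pom": self.kp.k_pom * self.sys.pom_conc * c_w,
                "ldpe": s.m_ldpe / v,
            }
            solid_conc = {"micelle": float(mic_t), "oil": float(oil_t),
                          "pom": self.sys.pom_conc, "ldpe": s.ldpe_conc}
            for phase, val in sysbasis.items():
                rows.append((s.t, phase, "system", val))
                if phase in solid_conc and solid_conc[phase] > 0:
                    rows.append((s.t, phase, "solid", val / solid_conc[phase]))
        return pd.DataFrame(rows, columns=["t_h", "phase", "basis", "value"])

    def removal_log(self) -> pd.DataFrame:
        """Removal events reconstructed from stored states."""
        rows = []
        prev = self.states[0]
        for s in self.states[1:]:
            if s.strips_remaining < prev.strips_remaining:
                rows.append((s.t, prev.strips_remaining - s.strips_remaining,
                             s.m_removed - prev.m_removed))
            prev = s
        return pd.DataFrame(rows, columns=["t_h", "strips_removed", "mass_removed_ug"])


def _remove_strips(state: SystemState, n: int = 1) -> SystemState:
    """Discrete sampling event: n strips leave with their proportional load."""
    if state.strips_remaining < n:
        raise ValueError("no strips left to remove")
    keep = (state.strips_remaining - n) / state.strips_remaining
    lost = (1.0 - keep) * (state.m_ldpe_fast + state.m_ldpe_slow)
    return replace(
        state,
        m_ldpe_fast=state.m_ldpe_fast * keep,
        m_ldpe_slow=state.m_ldpe_slow * keep,
        strips_remaining=state.strips_remaining - n,
        ldpe_conc=state.ldpe_conc * keep,
        m_removed=state.m_removed + lost,
    )


def simulate(sys: GutSystem, kp: KineticParams, s0: SystemState,
             t_grid: Sequence[float], *, apply_removals: bool = True,
             slow_reservoir: bool = False, rtol: float = 1e-8) -> Trajectory:
    """Integrate the exchange ODE over ``t_grid`` with strip-removal events.

    Between events the fast-reservoir mass obeys (masses, ug)

        dm_fast/dt = k1 * f_w(t) * m_pool - k2 * m_fast

    with m_pool = m_avail - m_fast (- m_slow when the slow reservoir is
    enabled) and f_w recomputed from the lipolysis-driven compartments.
    Removal times are forced onto the solver mesh as segment boundaries;
    a state stored exactly at a removal time is the post-event state.
    ``apply_removals=False`` simulates the plastic-retained (no-sampling)
    exposure scenario on the same system.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if t_grid[0] != s0.t:
        raise ValueError("t_grid must start at the initial state's time")
    t_end = float(t_grid[-1])

    events = []
    if apply_removals:
        events = sorted(t for t in sys.removal_times if s0.t <= t <= t_end)

    state = s0
    if events and events[0] == s0.t:
        state = _remove_strips(state)
        events = events[1:]

    d = sys.digestion
    k1, k2, k3, f1 = kp.k1, kp.k2, kp.k3, kp.f1
    pom = sys.pom_conc

    def rhs(t, y, m_avail):
        m_fast, m_slow = y
        mic_t, oil_t = compartments_at(t, d)
        f_w = water_fraction(kp, float(mic_t), float(oil_t), pom)
        m_pool = m_avail - m_fast - m_slow
        dfast = k1 * f_w * m_pool - k2 * m_fast
        dslow = k3 * ((1.0 - f1) / f1 * m_fast - m_slow) if slow_reservoir else 0.0
        return (dfast, dslow)

    boundaries = [float(s0.t)] + [t for t in events if t > s0.t] + [t_end]
    boundaries = sorted(set(boundaries))
    atol = max(state.total_mass, 1.0) * 1e-14

    states: list[SystemState] = []
    if t_grid[0] == state.t:
        states.append(state)

    for left, right in zip(boundaries[:-1], boundaries[1:]):
        m_avail = state.m_ldpe_fast + state.m_ldpe_slow + state.m_pool
        interior = t_grid[(t_grid > left) & (t_grid < right)]
        t_eval = np.unique(np.concatenate([interior, [right]]))
        sol = solve_ivp(
            rhs, (left, right), (state.m_ldpe_fast, state.m_ldpe_slow),
            t_eval=t_eval, args=(m_avail,), method="LSODA",
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed on [{left}, {right}] h: {sol.message}")
        for ti, mf, ms in zip(sol.t, sol.y[0], sol.y[1]):
            st = replace(state, t=float(ti), m_ldpe_fast=float(mf),
                         m_ldpe_slow=float(ms),
                         m_pool=m_avail - float(mf) - float(ms))
            if ti == right and right in events:
                st = _remove_strips(st)
            state = st
            if ti in t_grid:
                states.append(state)
        # ensure segment-end state carried forward even if not on the grid
        if state.t != right:
            raise RuntimeError("integrator did not reach the segment boundary")

    return Trajectory(sys=sys, kp=kp, states=states)


def fold_increase(traj: Trajectory) -> float:
    """Solid-basis LDPE concentration ratio C*_LDPE(t_end)/C*_LDPE(0)."""
    c = traj.c_ldpe_star
    if len(c) == 0 or not np.isfinite(c[0]) or c[0] <= 0:
        raise ValueError("initial LDPE concentration must be positive")
    return float(c[-1] / c[0])


def bioavailability_reduction(traj: Trajectory, *, include_removed: bool = True) -> float:
    """Percent of total gut chemical newly sequestered by plastic.

    100 * (chemical mass in LDPE at t_end - at t_0) / M_total.  With
    ``include_removed`` the load carried out by sampled strips counts as
    sequestered (it left the gut with the plastic); without, only the
    plastic still in the system counts.
    """
    first, last = traj.states[0], traj.states[-1]
    m_total = first.total_mass
    seq_end = last.m_ldpe + (last.m_removed if include_removed else 0.0)
    seq_start = first.m_ldpe + (first.m_removed if include_removed else 0.0)
    return 100.0 * (seq_end - seq_start) / m_total
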