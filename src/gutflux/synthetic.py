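"""Synthetic gut-fluid experiments with known ground truth.

Generates the three data products the estimation stages consume —
congener tables, equilibrium partition vials, and digestion-phase LDPE /
FFA time series — from configurable truth relationships, so every
estimator can be scored against the values that generated its input.

The default scenario mirrors the study design: 10 congeners spanning
log K_OW 5.24-8.18 with spikes of 30-124 ug/L; micelle vials at 5.7,
6.9, 11.6 and 64.5 g/L surfactant and oil vials at 1.3, 6.3 and 12.6 g/L
(each also carrying the 5.7 g/L bile-salt baseline); a 0.7 g LDPE /
7 g oil / ~80 mL digestion vessel sampled (one strip removed) at
0, 2, 4, 6, 8, 10, 24, 48 and 72 h; quadruplicate vessels.

Noise model: multiplicative mean-one lognormal on concentration readings
(they span orders of magnitude), additive Gaussian floored at zero on FFA
series (they do not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import (
    Congener,
    KineticParams,
    LogLinearRelation,
    K1_KOW_HIGH,
    K1_KOW_LOW,
    LOG_KOW_RANGE,
    MICELLE_KOW,
    OIL_KOW,
    POM_KOW_DEFAULT,
)
from .digestion import HIGH_ENZYME, LOW_ENZYME, DigestionParams, compartments_at, ffa_at
from .exchange import (
    DEFAULT_SCHEDULE,
    GutSystem,
    initialize_state,
    simulate,
    water_fraction,
)

__all__ = ["ScenarioSpec", "make_congeners", "make_partition_dataset",
           "make_kinetics_dataset"]

MICELLE_LEVELS = (5.7e-3, 6.9e-3, 11.6e-3, 64.5e-3)  # kg/L
OIL_LEVELS = (1.3e-3, 6.3e-3, 12.6e-3)  # kg/L
SPIKE_RANGE = (30.0, 124.0)  # ug/L


@dataclass(frozen=True)
class ScenarioSpec:
    """Truth parameterisation of one synthetic study.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal measurement noise (replicate scatter is not reported for
    the real assay; 0.1 is a documented placeholder).  ``k2_truth`` has
    no fitted hydrophobicity relation (desorption correlated only weakly
    with log K_OW), so a constant per enzyme level inside the observed
    ranges is used.  ``ldpe_start_fraction`` starts the fast reservoir at
    that fraction of its k1/k2 equilibrium, emulating the day-28
    disequilibrium that drives uptake during digestion.
    """

    n_congeners: int = 10
    log_kow_range: tuple[float, float] = LOG_KOW_RANGE
    rel_k_micelle: LogLinearRelation = MICELLE_KOW
    rel_k_oil: LogLinearRelation = OIL_KOW
    rel_k_pom: LogLinearRelation = POM_KOW_DEFAULT
    rel_k1: dict = field(default_factory=lambda: {"high": K1_KOW_HIGH, "low": K1_KOW_LOW})
    k2_truth: dict = field(default_factory=lambda: {"high": 1.0, "low": 0.15})
    digestion_truth: dict = field(default_factory=lambda: {"high": HIGH_ENZYME, "low": LOW_ENZYME})
    f1: float = 0.5
    noise_cv: float = 0.1
    ffa_noise_sd: float = 0.2
    seed: int = 0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    n_replicates: int = 4
    spike_range: tuple[float, float] = SPIKE_RANGE
    pom_conc: float = 0.11e-3 / 79.9e-3
    ldpe_start_fraction: float = 0.1
    #: sample strips destructively (one removed per schedule time); False
    #: emulates the plastic-retained exposure scenario
    apply_removals: bool = True

    def __post_init__(self) -> None:
        if self.n_congeners < 1:
            raise ValueError("n_congeners must be >= 1")
        if self.noise_cv < 0 or self.ffa_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not (0 < self.ldpe_start_fraction):
            raise ValueError("ldpe_start_fraction must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator per dataset stream."""
        return np.random.default_rng([self.seed, stream])


def _lognormal_factors(rng: np.random.Generator, cv: float, size=()) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def make_congeners(spec: ScenarioSpec) -> list[Congener]:
    """Evenly spaced hydrophobicity ladder with uniform random spikes."""
    lo, hi = spec.log_kow_range
    if spec.n_congeners == 1:
        log_kows = np.array([(lo + hi) / 2.0])
    else:
        log_kows = np.linspace(lo, hi, spec.n_congeners)
    rng = spec.rng(1)
    spikes = rng.uniform(*spec.spike_range, size=spec.n_congeners)
    return [
        Congener(id=f"C{i+1:02d}", log_kow=float(lk), c_total=float(ct))
        for i, (lk, ct) in enumerate(zip(log_kows, spikes))
    ]


def make_partition_dataset(
    spec: ScenarioSpec,
    micelle_levels: tuple[float, ...] = MICELLE_LEVELS,
    oil_levels: tuple[float, ...] = OIL_LEVELS,
    baseline_micelle: float = MICELLE_LEVELS[0],
) -> tuple[pd.DataFrame, dict]:
    """Forward-generate equilibrium partition vials for both experiments.

    Micelle vials vary the surfactant level with no oil; oil vials vary
    the oil level over the bile-salt baseline micelle pool.  The sampler
    reading C*_POM = K_POM * C_w carries the measurement noise.  Returns
    the tidy table plus a truth sidecar (per-congener K values).
    """
    congeners = make_congeners(spec)
    rng = spec.rng(2)
    rows = []
    truth = {}
    for cg in congeners:
        k_mic = 10.0 ** spec.rel_k_micelle.predict(cg.log_kow)
        k_oil = 10.0 ** spec.rel_k_oil.predict(cg.log_kow)
        k_pom = 10.0 ** spec.rel_k_pom.predict(cg.log_kow)
        truth[cg.id] = {"log_kow": cg.log_kow, "k_micelle": k_mic,
                        "k_oil": k_oil, "k_pom": k_pom}
        for level in micelle_levels:
            denom = 1.0 + k_pom * spec.pom_conc + k_mic * level
            c_w = cg.c_total / denom
            for rep in range(spec.n_replicates):
                noise = _lognormal_factors(rng, spec.noise_cv)
                rows.append((cg.id, cg.log_kow, "micelle", level, rep,
                             cg.c_total, k_pom * c_w * float(noise),
                             spec.pom_conc, level, 0.0, k_pom))
        for level in oil_levels:
            denom = (1.0 + k_pom * spec.pom_conc
                     + k_mic * baseline_micelle + k_oil * level)
            c_w = cg.c_total / denom
            for rep in range(spec.n_replicates):
                noise = _lognormal_factors(rng, spec.noise_cv)
                rows.append((cg.id, cg.log_kow, "oil", level, rep,
                             cg.c_total, k_pom * c_w * float(noise),
                             spec.pom_conc, baseline_micelle, level, k_pom))
    df = pd.DataFrame(rows, columns=[
        "congener", "log_kow", "phase", "level", "replicate",
        "c_init", "c_pom_star", "pom_conc", "micelle_conc", "oil_conc", "k_pom",
    ])
    return df, truth


def _truth_params(spec: ScenarioSpec, cg: Congener, enzyme: str) -> KineticParams:
    return KineticParams(
        k1=10.0 ** spec.rel_k1[enzyme].predict(cg.log_kow),
        k2=spec.k2_truth[enzyme],
        k_micelle=10.0 ** spec.rel_k_micelle.predict(cg.log_kow),
        k_oil=10.0 ** spec.rel_k_oil.predict(cg.log_kow),
        k_pom=10.0 ** spec.rel_k_pom.predict(cg.log_kow),
        f1=spec.f1,
    )


def make_kinetics_dataset(spec: ScenarioSpec, enzyme: str) -> dict:
    """Digestion-phase LDPE time series plus FFA curves for one treatment.

    For each congener the truth trajectory is simulated with the strip
    removal schedule from a day-28 state whose dissolved pool is at full
    equilibrium and whose LDPE fast reservoir sits at
    ``spec.ldpe_start_fraction`` of its k1/k2 equilibrium.  Replicate
    observations differ by measurement noise only.

    Returns a dict with keys ``ldpe`` (tidy observations), ``ffa``
    (replicate FFA series), ``truth`` (per-congener KineticParams),
    ``anchors`` (day-28 sampler reading and t=0 strip concentration per
    congener) and ``system`` (the GutSystem simulated).
    """
    if enzyme not in spec.digestion_truth:
        raise ValueError(f"unknown enzyme level {enzyme!r}")
    congeners = make_congeners(spec)
    sys = GutSystem(digestion=spec.digestion_truth[enzyme],
                    removal_times=spec.schedule, pom_conc=0.0)
    rng = spec.rng(3 if enzyme == "high" else 4)
    d = sys.dilution_factor
    times = np.asarray(spec.schedule, dtype=float)

    ldpe_rows = []
    truth: dict[str, KineticParams] = {}
    anchors: dict[str, dict[str, float]] = {}
    for cg in congeners:
        kp = _truth_params(spec, cg, enzyme)
        truth[cg.id] = kp
        # day-28 (pre-dilution) dissolved concentration from the total spike
        mic_pre = sys.digestion.micelle0 * d
        oil_pre = sys.digestion.oil0 * d
        c_w_pre = (cg.c_total * d) / (1.0 + kp.k_micelle * mic_pre + kp.k_oil * oil_pre)
        c_pom_star = kp.k_pom * c_w_pre
        # LDPE anchored at a fraction of its post-dilution k1/k2 equilibrium:
        # the t=0 disequilibrium drives digestion-phase uptake
        pool_only = initialize_state(sys, kp, c_pom_star_day28=c_pom_star,
                                     c_ldpe_star0=0.0)
        mic0, oil0 = compartments_at(0.0, sys.digestion)
        f_w = water_fraction(kp, float(mic0), float(oil0), sys.pom_conc)
        c_w_post = f_w * pool_only.m_pool / sys.v_w
        c_star_eq = (kp.k1 / kp.k2) / kp.f1 * c_w_post / sys.ldpe_conc0
        c_ldpe_star0 = spec.ldpe_start_fraction * c_star_eq
        anchors[cg.id] = {"c_pom_star_day28": c_pom_star,
                          "c_ldpe_star0": c_ldpe_star0}
        s0 = initialize_state(sys, kp, c_pom_star_day28=c_pom_star,
                              c_ldpe_star0=c_ldpe_star0)
        traj = simulate(sys, kp, s0, times, apply_removals=spec.apply_removals)
        clean = traj.c_ldpe_star
        for rep in range(spec.n_replicates):
            noise = _lognormal_factors(rng, spec.noise_cv, clean.shape)
            for t, v in zip(times, clean * noise):
                ldpe_rows.append((cg.id, cg.log_kow, rep, float(t), float(v)))

    ffa_rows = []
    clean_ffa = ffa_at(times, sys.digestion)
    for rep in range(spec.n_replicates):
        noisy = clean_ffa + rng.normal(0.0, spec.ffa_noise_sd, size=times.shape)
        noisy = np.maximum(noisy, 0.0)
        for t, v in zip(times, noisy):
            ffa_rows.append((rep, float(t), float(v)))

    return {
        "ldpe": pd.DataFrame(ldpe_rows, columns=[
            "congener", "log_kow", "replicate", "t_h", "c_ldpe_ug_per_kg"]),
        "ffa": pd.DataFrame(ffa_rows, columns=["replicate", "t_h", "ffa_uM"]),
        "truth": truth,
        "anchors": anchors,
        "system": sys,
    }
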