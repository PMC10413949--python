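"""Fitting uptake/desorption rate constants to LDPE time series.

Per congener (and replicate vessel) the fast-reservoir rate constants
(k1, k2) are estimated by nonlinear least squares between the observed
solid-basis LDPE concentration time series and the digestion-aware
forward simulation, with all partition coefficients, f1 and k3 held
fixed.  Optimisation runs in log10 parameter space (k1 spans several
orders of magnitude across the hydrophobicity range) within bounds
log10 k1 in [0, 9] and log10 k2 in [-4, 2], with a small multi-start
grid as fallback.  The plastic-water distribution coefficient follows
from the fitted rates, and all three quantities are regressed against
log K_OW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .chemistry import Congener, KineticParams, LogLinearRelation
from .exchange import GutSystem, initialize_state, simulate
from .partitioning import fit_loglinear

__all__ = ["KineticFitResult", "fit_k1k2", "derive_kp", "regress_rates"]

LOG10_K1_BOUNDS = (0.0, 9.0)
LOG10_K2_BOUNDS = (-4.0, 2.0)


@dataclass(frozen=True)
class KineticFitResult:
    """Least-squares estimates of the fast-reservoir rate constants."""

    k1_hat: float
    k2_hat: float
    se_k1: float
    se_k2: float
    p_k1: float
    p_k2: float
    kp_hat: float
    converged: bool
    flags: tuple[str, ...]
    residuals: np.ndarray
    n_obs: int


def derive_kp(k1: float, k2: float, ldpe_conc: float, f1: float) -> float:
    """Whole-polymer LDPE-water distribution coefficient (L/kg).

    K_p = (k1/k2) / ([LDPE] * f1): the fast reservoir equilibrates at
    C_fast = (k1/k2) C_w on the system basis, and the slow reservoir holds
    the remaining (1-f1) share at mutual equilibrium.
    """
    if k1 <= 0 or k2 <= 0 or ldpe_conc <= 0 or f1 <= 0:
        raise ValueError("k1, k2, ldpe_conc and f1 must all be > 0")
    return (k1 / k2) / (ldpe_conc * f1)


def _forward_c_star(log10_k: np.ndarray, times: np.ndarray, sys: GutSystem,
                    kp_fixed: KineticParams, c_pom_star_day28: float,
                    c_ldpe_star0: float, apply_removals: bool) -> np.ndarray:
    kp = replace(kp_fixed, k1=10.0 ** log10_k[0], k2=10.0 ** log10_k[1])
    s0 = initialize_state(sys, kp, c_pom_star_day28=c_pom_star_day28,
                          c_ldpe_star0=c_ldpe_star0)
    traj = simulate(sys, kp, s0, times, apply_removals=apply_removals)
    return traj.c_ldpe_star


def fit_k1k2(obs: pd.DataFrame, sys: GutSystem, kp_fixed: KineticParams, *,
             c_pom_star_day28: float, apply_removals: bool = True,
             n_starts: int = 5) -> KineticFitResult:
    """Fit (k1, k2) to one observed LDPE time series.

    ``obs`` needs columns ``t_h`` and ``c_ldpe_ug_per_kg`` with at least 4
    timepoints including t = 0; the t = 0 value anchors the LDPE boundary
    condition and the day-28 sampler reading anchors the dissolved pool.
    Residuals are unweighted, in ug/kg.  Flags report non-convergence,
    active bounds, and flat-series identifiability degeneracy (only the
    k1/k2 ratio identified).
    """
    obs = obs.sort_values("t_h")
    times = obs["t_h"].to_numpy(dtype=float)
    y = obs["c_ldpe_ug_per_kg"].to_numpy(dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 timepoints")
    if times[0] != 0.0:
        raise ValueError("observations must include t = 0")
    c0 = float(y[0])
    if c0 <= 0:
        raise ValueError("t = 0 LDPE concentration must be positive")

    def residual(log10_k: np.ndarray) -> np.ndarray:
        model = _forward_c_star(log10_k, times, sys, kp_fixed,
                                c_pom_star_day28, c0, apply_removals)
        return model - y

    # heuristic start: assume near-equilibrium at t_end, k2 ~ 1/h
    c_w0 = c_pom_star_day28 / kp_fixed.k_pom
    ratio = max(y[-1] * sys.ldpe_conc0 * kp_fixed.f1 / c_w0, 10.0)
    starts = [(math.log10(ratio), 0.0)]
    rng_a = np.linspace(2.0, 7.0, n_starts - 1)
    starts += [(a, b) for a, b in zip(rng_a, np.tile([-1.0, 0.5], n_starts)[: n_starts - 1])]

    lo = np.array([LOG10_K1_BOUNDS[0], LOG10_K2_BOUNDS[0]])
    hi = np.array([LOG10_K1_BOUNDS[1], LOG10_K2_BOUNDS[1]])
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except (RuntimeError, ValueError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        # accept the heuristic start unless it failed or stalled on a bound
        if sol.success and not np.any(
            np.isclose(sol.x, lo, atol=1e-6) | np.isclose(sol.x, hi, atol=1e-6)
        ):
            break
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    flags: list[str] = []
    if not best.success:
        flags.append("non-convergence")
    at_bounds = np.isclose(best.x, lo, atol=1e-6) | np.isclose(best.x, hi, atol=1e-6)
    if np.any(at_bounds):
        flags.append("active-bounds")
    # flat series: no dynamics to separate k1 from k2
    if np.ptp(y) <= 1e-10 * max(abs(c0), 1.0):
        flags.append("unidentifiable: flat series, only k1/k2 ratio constrained")

    k1_hat, k2_hat = 10.0 ** best.x
    n, p = times.size, 2
    dof = max(n - p, 1)
    sigma2 = 2.0 * best.cost / dof
    J = best.jac
    try:
        cov_log = sigma2 * np.linalg.inv(J.T @ J)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se_log = np.full(2, np.nan)
        flags.append("singular-jacobian")
    # delta method back to the natural scale
    se_k1 = math.log(10.0) * k1_hat * se_log[0]
    se_k2 = math.log(10.0) * k2_hat * se_log[1]

    def wald_p(est: float, se: float) -> float:
        if not np.isfinite(se) or se == 0:
            return float("nan")
        return float(2.0 * stats.t.sf(abs(est / se), dof))

    return KineticFitResult(
        k1_hat=float(k1_hat), k2_hat=float(k2_hat),
        se_k1=float(se_k1), se_k2=float(se_k2),
        p_k1=wald_p(k1_hat, se_k1), p_k2=wald_p(k2_hat, se_k2),
        kp_hat=derive_kp(k1_hat, k2_hat, sys.ldpe_conc0, kp_fixed.f1),
        converged=best.success and "active-bounds" not in flags,
        flags=tuple(flags), residuals=best.fun.copy(), n_obs=int(n),
    )


def regress_rates(results: list[KineticFitResult],
                  congeners: list[Congener]) -> dict[str, LogLinearRelation]:
    """OLS of log10(k1), log10(k2), log10(K_p) against log K_OW."""
    if len(results) != len(congeners):
        raise ValueError("results and congeners must be matched lists")
    if len(results) < 3:
        raise ValueError("need at least 3 congeners to regress")
    x = [c.log_kow for c in congeners]
    out = {}
    for name, vals in (
        ("k1", [r.k1_hat for r in results]),
        ("k2", [r.k2_hat for r in results]),
        ("k_p", [r.kp_hat for r in results]),
    ):
        vals = np.asarray(vals, dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"nonpositive {name} estimate; cannot take log10")
        out[name] = fit_loglinear(x, np.log10(vals))
    return out
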