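"""Lipolysis kinetics: free fatty acid liberation and the micelle/oil pools.

Lipase hydrolyses olive-oil triglycerides, liberating free fatty acids
(FFA).  The liberated FFA molar concentration follows a saturating
first-order curve

    [FFA](t) = FFA_max * (1 - exp(-k_FFA * t))        (uM, t in hours)

One proton is released per FFA, so the curve can be measured either
directly or via the pH drop of the (weakly buffered) medium.  The FFA
pool feeds two time-varying compartments of the exchange model: liberated
FFA aggregates with bile salt into mixed micelles (micelle mass grows) and
each three FFAs consume one triglyceride (oil mass shrinks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DigestionParams",
    "FfaFit",
    "ffa_at",
    "fit_ffa",
    "ph_to_ffa",
    "compartments_at",
    "HIGH_ENZYME",
    "LOW_ENZYME",
]

#: mass gained forming a triglyceride from 3 FFAs: glycerol - 3 H2O (g/mol)
GLYCEROL_BACKBONE = 38.05

#: oleic acid, the dominant olive-oil fatty acid (g/mol)
DEFAULT_MW_FFA = 282.46


def _default_mw_oil(mw_ffa: float) -> float:
    """Triglyceride MW from its mean fatty-acid MW via the ester backbone."""
    return 3.0 * mw_ffa + GLYCEROL_BACKBONE


@dataclass(frozen=True)
class DigestionParams:
    """Lipolysis parameters plus the baseline micelle and oil pools.

    ffa_max: maximum liberated FFA (uM); k_ffa: first-order rate (h^-1);
    mw_ffa / mw_oil: molecular weights (g/mol), mw_oil defaulting to the
    triglyceride backbone relation 3*MW_FFA + 38.05; micelle0 / oil0:
    baseline micelle and initial oil mass concentrations (kg/L system).
    """

    ffa_max: float
    k_ffa: float
    mw_ffa: float = DEFAULT_MW_FFA
    mw_oil: float | None = None
    micelle0: float = 5.7e-3
    oil0: float = 8.76e-2

    def __post_init__(self) -> None:
        if self.ffa_max < 0:
            raise ValueError("ffa_max must be >= 0")
        if self.k_ffa <= 0:
            raise ValueError("k_ffa must be > 0")
        if self.micelle0 < 0 or self.oil0 < 0:
            raise ValueError("micelle0 and oil0 must be >= 0")
        if self.mw_oil is None:
            object.__setattr__(self, "mw_oil", _default_mw_oil(self.mw_ffa))


#: Fitted lipolysis parameters for the two enzyme-activity treatments
#: (native and heat-inactivated lipase), from pH-derived FFA curves.
HIGH_ENZYME = DigestionParams(ffa_max=10.53, k_ffa=0.079)
LOW_ENZYME = DigestionParams(ffa_max=1.18, k_ffa=1.22)


def ffa_at(t, p: DigestionParams):
    """Liberated FFA concentration (uM) at time t (hours, scalar or array)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = p.ffa_max * (1.0 - np.exp(-p.k_ffa * t))
    return float(out) if out.ndim == 0 else out


def ph_to_ffa(ph0: float, ph_t: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """FFA (uM) from the pH drop, one proton per liberated FFA.

    Returns ``(ffa, flagged)``: ffa = (10^-pH(t) - 10^-pH0) * 1e6, floored
    at zero; flagged marks nonphysical upward pH excursions that were
    floored.  Buffering by protein and bile salts is deliberately ignored
    (proxy measure).
    """
    ph_t = np.asarray(ph_t, dtype=float)
    if not (0 < ph0 < 14) or np.any((ph_t <= 0) | (ph_t >= 14)):
        raise ValueError("pH values must lie in (0, 14)")
    ffa = (10.0 ** (-ph_t) - 10.0 ** (-ph0)) * 1e6
    flagged = ffa < 0
    return np.where(flagged, 0.0, ffa), flagged


@dataclass(frozen=True)
class FfaFit:
    """Nonlinear least-squares fit of the saturating FFA model."""

    ffa_max: float
    k_ffa: float
    se_ffa_max: float
    se_k_ffa: float
    converged: bool
    message: str = ""
    n_obs: int = 0

    def params(self, **overrides) -> DigestionParams:
        """Promote the fit to DigestionParams (baseline pools via overrides)."""
        if not self.converged:
            raise ValueError(f"fit did not converge: {self.message}")
        return DigestionParams(ffa_max=self.ffa_max, k_ffa=self.k_ffa, **overrides)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    a0 = float(np.max(y))
    # first time the curve passes half its plateau ~ one rate half-life
    above = t[(y >= 0.5 * a0) & (t > 0)]
    t_half = float(above[0]) if above.size else float(np.max(t[t > 0]))
    return a0, 1.0 / max(t_half, 1e-6)


def fit_ffa(times: Sequence[float], ffa: Sequence[float]) -> FfaFit:
    """Fit (FFA_max, k_FFA) to an FFA-vs-time series by least squares.

    Requires >= 3 points with at least one at t > 0.  A flat-zero series is
    degenerate (k unidentifiable) and returns a non-converged result rather
    than an arbitrary rate.  Initialisation uses the observed plateau and
    half-rise time, with a multi-start grid fallback for sparse early
    sampling.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(ffa, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 3:
        raise ValueError("need matched 1-d series with at least 3 points")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if not np.any(t > 0):
        raise ValueError("need at least one observation at t > 0")
    if np.all(y <= 0):
        return FfaFit(0.0, float("nan"), 0.0, float("nan"), False,
                      "degenerate series: no FFA signal, rate unidentifiable", t.size)

    def model(tt, a, k):
        return a * (1.0 - np.exp(-k * tt))

    guesses = [_initial_guess(t, y)]
    a0 = guesses[0][0]
    guesses += [(a0, k0) for k0 in (0.02, 0.1, 0.5, 2.0)]
    best = None
    for p0 in guesses:
        try:
            popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=10000,
                                   bounds=([0.0, 1e-8], [np.inf, np.inf]))
        except RuntimeError:
            continue
        rss = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        return FfaFit(float("nan"), float("nan"), float("nan"), float("nan"),
                      False, "nonlinear least squares failed to converge", t.size)
    _, popt, pcov = best
    se = np.sqrt(np.diag(pcov))
    return FfaFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]),
                  True, "converged", t.size)


def compartments_at(t, p: DigestionParams) -> tuple[np.ndarray, np.ndarray]:
    """Micelle and oil mass concentrations (kg/L) at time t (hours).

    [micelle]_t = micelle0 + [FFA](t) * MW_FFA * 1e-9   (uM * g/mol = ug/L)
    [oil]_t     = oil0 - ([FFA](t)/3) * MW_oil * 1e-9

    Raises if the parameterisation would deplete the oil pool below zero.
    """
    ffa = ffa_at(t, p)
    micelle = p.micelle0 + ffa * p.mw_ffa * 1e-9
    oil = p.oil0 - (ffa / 3.0) * p.mw_oil * 1e-9
    if np.any(np.asarray(oil) < 0):
        raise ValueError("inconsistent parameters: oil pool depleted below zero")
    return micelle, oil
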