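"""Micelle-water and oil-water partition coefficients from POM samplers.

A closed vial holds water, a POM passive-sampler strip, and either mixed
micelles (bile salt + fatty acid) or olive oil (which also carries the
baseline bile-salt micelles).  At equilibrium the chemical mass balance on
the system-volume basis reads

    C_init = C_w * (1 + K_POM*[POM] + K_micelle*[micelle] + K_oil*[oil])

with phase concentrations [phase] in kg per litre of system.  The freely
dissolved concentration C_w is inferred from the sampler reading
C*_POM / K_POM, and the one unknown partition coefficient per experiment
is obtained by rearranging the balance.  Estimated coefficients are then
regressed (log10) against log K_OW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemistry import LogLinearRelation

__all__ = [
    "PartitionExperiment",
    "PartitionEstimate",
    "pom_to_water",
    "estimate_k_micelle",
    "estimate_k_oil",
    "fit_loglinear",
    "estimate_partition_table",
]


@dataclass(frozen=True)
class PartitionExperiment:
    """One equilibrium partition vial.

    c_init: total spike concentration, ug/L system volume.
    c_pom_star: sampler reading, ug/kg POM (solid basis).
    pom_conc, micelle_conc, oil_conc: phase mass concentrations, kg/L.
    k_pom: POM-water partition coefficient, L/kg (literature calibration).
    """

    c_init: float
    c_pom_star: float
    pom_conc: float
    k_pom: float
    micelle_conc: float = 0.0
    oil_conc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_init", "c_pom_star", "micelle_conc", "oil_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pom_conc <= 0:
            raise ValueError("pom_conc must be > 0")
        if self.k_pom <= 0:
            raise ValueError("k_pom must be > 0")


class PartitionEstimate(NamedTuple):
    """A partition-coefficient estimate with a consistency flag.

    ``flagged`` marks a negative inversion result (the sampler reading and
    spike are mutually inconsistent, e.g. under heavy noise); the raw value
    is preserved rather than clipped so diagnostics stay meaningful.
    """

    value: float
    flagged: bool


def pom_to_water(c_pom_star: float, k_pom: float) -> float:
    """Freely dissolved water concentration C_w = C*_POM / K_POM (ug/L)."""
    if k_pom <= 0:
        raise ValueError(f"k_pom must be > 0, got {k_pom}")
    return c_pom_star / k_pom


def estimate_k_micelle(exp: PartitionExperiment) -> PartitionEstimate:
    """Invert the closed-system mass balance for K_micelle (L/kg)."""
    if exp.micelle_conc <= 0:
        raise ValueError("micelle_conc must be > 0 to estimate K_micelle")
    if exp.c_pom_star <= 0:
        raise ValueError("c_pom_star must be > 0 (no sampler signal)")
    c_w = pom_to_water(exp.c_pom_star, exp.k_pom)
    value = (exp.c_init / c_w - 1.0 - exp.k_pom * exp.pom_conc) / exp.micelle_conc
    return PartitionEstimate(value, flagged=value < 0)


def estimate_k_oil(exp: PartitionExperiment, k_micelle: float) -> PartitionEstimate:
    """Invert the mass balance for K_oil (L/kg), netting out micelle sorption.

    The oil vials also contain the baseline bile-salt micelle pool, whose
    contribution K_micelle*[micelle] is subtracted using an externally
    supplied (typically pooled-regression) K_micelle.
    """
    if exp.oil_conc <= 0:
        raise ValueError("oil_conc must be > 0 to estimate K_oil")
    if exp.c_pom_star <= 0:
        raise ValueError("c_pom_star must be > 0 (no sampler signal)")
    c_w = pom_to_water(exp.c_pom_star, exp.k_pom)
    value = (
        exp.c_init / c_w
        - 1.0
        - exp.k_pom * exp.pom_conc
        - k_micelle * exp.micelle_conc
    ) / exp.oil_conc
    return PartitionEstimate(value, flagged=value < 0)


def fit_loglinear(x: Sequence[float], y: Sequence[float]) -> LogLinearRelation:
    """Ordinary least squares of y (log10 quantity) on x (log K_OW)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size < 2:
        raise ValueError("need at least two points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope is undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    # two exactly collinear points carry rvalue 1 but nan stderr
    return LogLinearRelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=min(r2, 1.0),
        n=int(x.size),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
    )


def estimate_partition_table(
    df: pd.DataFrame,
    k_micelle_pooled: float | LogLinearRelation | None = None,
) -> pd.DataFrame:
    """Row-wise partition estimates for a tidy experiment table.

    Expects columns ``phase`` ('micelle' or 'oil'), ``c_init``,
    ``c_pom_star``, ``pom_conc``, ``micelle_conc``, ``oil_conc``,
    ``k_pom``; other columns (congener, log_kow, level, replicate) pass
    through.  Oil rows require ``k_micelle_pooled`` — a constant (L/kg)
    or a fitted micelle regression evaluated at each row's ``log_kow`` —
    to net out the baseline micelle pool.  Adds ``k_estimate``,
    ``log10_k`` and ``flagged`` columns.
    """
    out = df.copy()
    values = np.empty(len(df))
    flags = np.empty(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        exp = PartitionExperiment(
            c_init=row.c_init,
            c_pom_star=row.c_pom_star,
            pom_conc=row.pom_conc,
            k_pom=row.k_pom,
            micelle_conc=row.micelle_conc,
            oil_conc=row.oil_conc,
        )
        if row.phase == "micelle":
            est = estimate_k_micelle(exp)
        elif row.phase == "oil":
            if k_micelle_pooled is None:
                raise ValueError("k_micelle_pooled required for oil-phase rows")
            if isinstance(k_micelle_pooled, LogLinearRelation):
                k_mic = 10.0 ** k_micelle_pooled.predict(row.log_kow)
            else:
                k_mic = float(k_micelle_pooled)
            est = estimate_k_oil(exp, k_mic)
        else:
            raise ValueError(f"unknown phase {row.phase!r}")
        values[i] = est.value
        flags[i] = est.flagged
    out["k_estimate"] = values
    out["flagged"] = flags
    log10_k = np.full(len(df), np.nan)
    pos = values > 0
    log10_k[pos] = np.log10(values[pos])
    out["log10_k"] = log10_k
    return out


def fit_grouped(df: pd.DataFrame, group: str | None = None) -> dict[str, LogLinearRelation]:
    """Log-linear fits of estimates vs log K_OW, pooled and per group level.

    ``df`` must carry ``log_kow`` and ``log10_k`` columns (flagged rows are
    dropped).  Returns a mapping with key 'pooled' plus one key per group
    level when ``group`` names a column.
    """
    ok = df[~df["flagged"] & np.isfinite(df["log10_k"])]
    fits = {"pooled": fit_loglinear(ok["log_kow"], ok["log10_k"])}
    if group is not None:
        for level, sub in ok.groupby(group):
            fits[str(level)] = fit_loglinear(sub["log_kow"], sub["log10_k"])
    return fits
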