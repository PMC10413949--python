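"""Domain types and hydrophobicity (log K_OW) relationships.

Everything downstream — micelle/oil partition coefficients, plastic uptake
rate constants, POM sampler calibration — is organised around log-linear
free-energy relationships of the form

    log10(quantity) = slope * log K_OW + intercept

Concentration conventions used throughout the package:

* system-volume basis: chemical mass per litre of whole gut system (ug/L);
* solid-phase basis (starred): chemical mass per kg of a solid phase
  (ug/kg).  Conversion between the two goes through the phase mass
  concentration in kg per litre of system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Congener",
    "LogLinearRelation",
    "KineticParams",
    "predict_log_quantity",
    "oil_kow_enrichment",
    "first_order_half_life",
    "MICELLE_KOW",
    "OIL_KOW",
    "K1_KOW_HIGH",
    "K1_KOW_LOW",
    "KP_KOW",
    "POM_KOW_DEFAULT",
    "LOG_KOW_RANGE",
]

#: log K_OW span of the PCB congener set the study design uses.
LOG_KOW_RANGE = (5.24, 8.18)


@dataclass(frozen=True)
class Congener:
    """A chemical tracked through the gut system.

    Parameters
    ----------
    id
        Short label (e.g. an IUPAC PCB congener number).
    log_kow
        log10 octanol-water partition coefficient, the hydrophobicity
        covariate of every regression in the package.
    c_total
        Total chemical concentration in the system on the system-volume
        basis (ug/L); doubles as the initial spike concentration in the
        partition experiments.
    """

    id: str
    log_kow: float
    c_total: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_kow):
            raise ValueError(f"log_kow must be finite, got {self.log_kow}")
        if self.c_total < 0:
            raise ValueError(f"c_total must be >= 0, got {self.c_total}")


@dataclass(frozen=True)
class LogLinearRelation:
    """A fitted (or assumed) log-linear relationship against log K_OW.

    ``predict`` returns the log10 of the target quantity; slope is
    dimensionless and the intercept carries the log10 units of the target.
    """

    slope: float
    intercept: float
    r2: float = float("nan")
    n: int = 0
    se_slope: float = float("nan")
    se_intercept: float = float("nan")

    def __post_init__(self) -> None:
        if math.isfinite(self.r2) and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")

    def predict(self, log_kow: float) -> float:
        return self.slope * log_kow + self.intercept


@dataclass(frozen=True)
class KineticParams:
    """Per-congener kinetic and equilibrium parameters.

    k1/k2 govern the fast LDPE reservoir (uptake and desorption on the
    system-volume concentration basis, h^-1); k3 the slow intrapolymer
    reservoir; f1 is the fast fraction of plastic-bound chemical.  K's are
    phase-water partition coefficients in L/kg.
    """

    k1: float
    k2: float
    k_micelle: float
    k_oil: float
    k_pom: float
    f1: float = 0.5
    #: slow intrapolymer rate; default half-life 20 d (midpoint of the
    #: 13-32 d range for these strips), negligible over a 72 h digestion.
    k3: float = math.log(2) / (20.0 * 24.0)
    k_p: float | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k_micelle", "k_oil", "k_pom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.f1 <= 1.0):
            raise ValueError(f"f1 must lie in (0, 1], got {self.f1}")
        if self.k_p is not None and self.k_p < 0:
            raise ValueError("k_p must be >= 0")


def predict_log_quantity(rel: LogLinearRelation, log_kow: float) -> float:
    """log10 of a partition coefficient or rate constant at a given log K_OW."""
    return rel.predict(log_kow)


def oil_kow_enrichment(rel_oil: LogLinearRelation, log_kow: float) -> float:
    """Fold enrichment of K_oil over K_OW at a given hydrophobicity.

    Computed as 10**(log K_oil - log K_OW) with log K_oil from the
    oil-water regression.  For a sub-unit slope the factor shrinks as
    hydrophobicity grows.
    """
    return 10.0 ** (rel_oil.predict(log_kow) - log_kow)


def first_order_half_life(k: float) -> float:
    """Half-life ln(2)/k (hours) of a first-order rate constant (h^-1)."""
    if k <= 0:
        raise ValueError(f"rate constant must be > 0, got {k}")
    return math.log(2) / k


# ---------------------------------------------------------------------------
# Pooled regressions from the study design; used as generator truths by
# gutflux.synthetic and as reference relations in the analysis scripts.
# ---------------------------------------------------------------------------

#: Pooled micelle-water regression: log K_micelle = 0.99 logKow + 0.61.
MICELLE_KOW = LogLinearRelation(0.99, 0.61, r2=0.86, se_slope=0.03, se_intercept=0.22)

#: Pooled oil-water regression: log K_oil = 0.85 logKow + 2.21.
OIL_KOW = LogLinearRelation(0.85, 2.21, r2=0.84, se_slope=0.04, se_intercept=0.24)

#: Fast uptake rate vs hydrophobicity, high enzyme activity.
K1_KOW_HIGH = LogLinearRelation(1.04, -3.01, r2=0.87, n=10, se_slope=0.11, se_intercept=0.73)

#: Fast uptake rate vs hydrophobicity, low enzyme activity.
K1_KOW_LOW = LogLinearRelation(1.21, -4.28, r2=0.96, n=10, se_slope=0.08, se_intercept=0.51)

#: LDPE distribution coefficient vs hydrophobicity (both enzyme levels pooled).
KP_KOW = LogLinearRelation(1.04, 0.05, r2=0.98, n=20, se_slope=0.03, se_intercept=0.23)

#: Stand-in POM-water calibration (synthetic default).  The POM sampler
#: calibration is a literature input not reproduced here; this places
#: K_POM one decade below K_OW, a typical magnitude for PCBs on POM, and
#: is configurable everywhere it is consumed.  Round-trip estimators are
#: exactly invariant to this choice.
POM_KOW_DEFAULT = LogLinearRelation(1.0, -1.0)
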