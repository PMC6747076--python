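"""Exposure-dose and risk-index arithmetic, plus reaction thermochemistry.

Human-health exposure follows the standard EPA intake equation::

    ADD = C * IR * EF * ED / (BW * AT)      [mg/(kg*day)]

with C the medium concentration, IR the intake rate, EF/ED exposure
frequency and duration, BW body weight and AT the averaging time.  The
non-carcinogenic hazard index is ``HI = ADD / RfD`` (acceptable when
HI < 1); the lifetime cancer risk under the linear non-threshold model is
``RI = ADD * SF`` (negligible when RI < 1e-6, acceptable in [1e-6, 1e-4),
unacceptable above).  Threshold boundaries are closed/open exactly as
written.

Thermochemistry bookkeeping for substitution pathways: ``dG = sum G(products)
- sum G(reactants)`` (spontaneous when negative) and the barrier ``dE =
E(TS) - sum E(reactants)``; pathways rank by ascending barrier.  Energies
are taken verbatim in the unit the input declares — no conversion is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExposureScenario",
    "RiskResult",
    "ThermoRecord",
    "average_daily_dose",
    "hazard_index",
    "cancer_risk",
    "assess",
    "gibbs_change",
    "barrier",
    "rank_paths",
    "RI_NEGLIGIBLE",
    "RI_ACCEPTABLE",
]

RI_NEGLIGIBLE = 1e-6
RI_ACCEPTABLE = 1e-4


@dataclass(frozen=True)
class ExposureScenario:
    concentration: float  # mg/L in the exposure medium
    intake_rate: float  # L/day
    exposure_frequency: float  # days/year
    exposure_duration: float  # years
    body_weight: float  # kg
    averaging_time: float  # days
    sensitivity: str = "non-sensitive"
    carcinogenicity: str = "non-carcinogenic"

    def __post_init__(self):
        for name in ("concentration", "intake_rate", "exposure_frequency",
                     "exposure_duration", "body_weight", "averaging_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RiskResult:
    add: float
    hi: float | None = None
    ri: float | None = None
    hi_class: str | None = None
    ri_class: str | None = None


@dataclass
class ThermoRecord:
    path: str
    reactant_g: list[float] = field(default_factory=list)
    product_g: list[float] = field(default_factory=list)
    reactant_e: list[float] = field(default_factory=list)
    ts_energy: float | None = None
    lowest_frequency: float | None = None  # cm^-1
    energy_unit: str = "a.u."


def average_daily_dose(s: ExposureScenario) -> float:
    """ADD = C*IR*EF*ED / (BW*AT), mg/(kg*day); linear in C and IR."""
    return (
        s.concentration * s.intake_rate * s.exposure_frequency * s.exposure_duration
        / (s.body_weight * s.averaging_time)
    )


def hazard_index(add: float, rfd: float) -> tuple[float, str]:
    """Non-carcinogenic hazard index ADD/RfD; acceptable iff HI < 1."""
    if rfd <= 0:
        raise ValueError("RfD must be positive")
    hi = add / rfd
    return hi, ("acceptable" if hi < 1.0 else "unacceptable")


def cancer_risk(add: float, sf: float) -> tuple[float, str]:
    """Lifetime cancer risk ADD*SF with the standard bands:
    negligible < 1e-6 <= acceptable < 1e-4 <= unacceptable."""
    if sf < 0:
        raise ValueError("slope factor must be non-negative")
    ri = add * sf
    if ri < RI_NEGLIGIBLE:
        cls = "negligible"
    elif ri < RI_ACCEPTABLE:
        cls = "acceptable"
    else:
        cls = "unacceptable"
    return ri, cls


def assess(s: ExposureScenario, rfd: float | None = None, sf: float | None = None) -> RiskResult:
    """One-call ADD + HI + RI evaluation for a scenario."""
    add = average_daily_dose(s)
    result = RiskResult(add=add)
    if rfd is not None:
        result.hi, result.hi_class = hazard_index(add, rfd)
    if sf is not None:
        result.ri, result.ri_class = cancer_risk(add, sf)
    return result


def gibbs_change(record: ThermoRecord) -> tuple[float, bool]:
    """dG = sum G(products) - sum G(reactants); spontaneous iff dG < 0."""
    if not record.reactant_g or not record.product_g:
        raise ValueError(f"path {record.path!r}: missing free energies")
    dg = float(np.sum(record.product_g) - np.sum(record.reactant_g))
    return dg, dg < 0


def barrier(record: ThermoRecord) -> float:
    """dE = E(TS) - sum E(reactants)."""
    if record.ts_energy is None or not record.reactant_e:
        raise ValueError(f"path {record.path!r}: missing TS or reactant energies")
    return float(record.ts_energy - np.sum(record.reactant_e))


def rank_paths(records: list[ThermoRecord]) -> list[tuple[str, float]]:
    """Pathways ordered by ascending barrier (easiest reaction first)."""
    ranked = sorted(((r.path, barrier(r)) for r in records), key=lambda t: t[1])
    return ranked
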