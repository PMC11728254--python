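"""Severity-score calculators for emergency-department triage.

Implements the shock-index/lactate (SIL) score — the sum of a binned
shock-index sub-score (PIS, 0-3) and a binned arterial-lactate sub-score
(PL, 0-3) — together with three published comparators computed from the
same raw vitals and labs:

* NEWS (National Early Warning Score, 0-20; NEWS2 Scale 1 bands by
  default, the 2012 original selectable),
* qSOFA (Sepsis-3 bedside criteria, 0-3),
* SOFA (six organ-system sub-scores of 0-4 each, 0-24).

All calculators are pure functions over :class:`VitalSigns` /
:class:`LabPanel` records and raise :class:`~siltriage.errors.MissingDataError`
or :class:`~siltriage.errors.InvalidInputError` rather than guessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .errors import InvalidInputError, MissingDataError

__all__ = [
    "VitalSigns",
    "LabPanel",
    "SILBreakdown",
    "ScorePanel",
    "shock_index",
    "sil_points",
    "news_points",
    "qsofa_points",
    "sofa_points",
    "score_panel",
    "AVPU_LEVELS",
    "VASOPRESSOR_CATEGORIES",
    "NEWS_ADMISSION_THRESHOLD",
]

AVPU_LEVELS = ("alert", "voice", "pain", "unresponsive")

#: Pre-binned vasopressor dosing categories accepted by the SOFA
#: cardiovascular row (the source schema records a category, not µg/kg/min).
VASOPRESSOR_CATEGORIES = (
    "none",
    "dopamine_low",
    "dopamine_mid",
    "dopamine_high_or_epi",
    "high_dose",
)

#: NEWS total at or above which the study workflow admitted the patient.
NEWS_ADMISSION_THRESHOLD = 5

# Rough AVPU -> Glasgow Coma Scale equivalents, used only when a record
# carries an AVPU level but SOFA needs a GCS band.
_AVPU_TO_GCS = {"alert": 15, "voice": 13, "pain": 8, "unresponsive": 3}


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

Consciousness = Union[int, str]


@dataclass(frozen=True)
class VitalSigns:
    """One set of triage vital signs.

    ``consciousness`` is either an AVPU level (``"alert"``/``"voice"``/
    ``"pain"``/``"unresponsive"``) or a Glasgow Coma Scale integer in 3-15.
    Any field may be ``None``; calculators that need it will raise
    :class:`MissingDataError`.
    """

    heart_rate: Optional[float] = None  # beats/min
    systolic_bp: Optional[float] = None  # mmHg
    respiratory_rate: Optional[float] = None  # breaths/min
    temperature: Optional[float] = None  # degrees C
    spo2: Optional[float] = None  # percent
    supplemental_o2: Optional[bool] = None
    consciousness: Optional[Consciousness] = None

    def __post_init__(self):
        if self.heart_rate is not None and not self.heart_rate > 0:
            raise InvalidInputError("heart_rate", "must be strictly positive")
        if self.systolic_bp is not None and not self.systolic_bp > 0:
            raise InvalidInputError("systolic_bp", "must be strictly positive")
        if self.spo2 is not None and not (0 <= self.spo2 <= 100):
            raise InvalidInputError("spo2", "must lie in [0, 100]")
        c = self.consciousness
        if c is not None:
            if isinstance(c, str):
                if c not in AVPU_LEVELS:
                    raise InvalidInputError(
                        "consciousness", f"unknown AVPU level {c!r}"
                    )
            elif not (3 <= int(c) <= 15):
                raise InvalidInputError("consciousness", "GCS must lie in [3, 15]")

    @property
    def gcs(self) -> Optional[int]:
        """Glasgow Coma Scale, mapping AVPU levels to conventional equivalents."""
        c = self.consciousness
        if c is None:
            return None
        if isinstance(c, str):
            return _AVPU_TO_GCS[c]
        return int(c)

    @property
    def alert(self) -> Optional[bool]:
        c = self.consciousness
        if c is None:
            return None
        return c == "alert" if isinstance(c, str) else int(c) == 15


@dataclass(frozen=True)
class LabPanel:
    """Laboratory values; only lactate is needed for the SIL score."""

    lactate: Optional[float] = None  # mmol/L
    pao2_fio2: Optional[float] = None  # ratio
    platelets: Optional[float] = None  # 10^3 / uL
    bilirubin: Optional[float] = None  # mg/dL
    mean_arterial_pressure: Optional[float] = None  # mmHg
    vasopressor: Optional[str] = None  # VASOPRESSOR_CATEGORIES
    creatinine: Optional[float] = None  # mg/dL

    def __post_init__(self):
        if self.lactate is not None and self.lactate < 0:
            raise InvalidInputError("lactate", "must be non-negative")
        for name in ("pao2_fio2", "platelets", "bilirubin",
                     "mean_arterial_pressure", "creatinine"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise InvalidInputError(name, "must be strictly positive when given")
        if self.vasopressor is not None and self.vasopressor not in VASOPRESSOR_CATEGORIES:
            raise InvalidInputError(
                "vasopressor", f"unknown category {self.vasopressor!r}"
            )


@dataclass(frozen=True)
class SILBreakdown:
    """SIL score with its two sub-scores and the raw shock index."""

    shock_index: float
    pis: int
    pl: int

    @property
    def total(self) -> int:
        return self.pis + self.pl

    def __post_init__(self):
        if self.pis not in (0, 1, 2, 3):
            raise InvalidInputError("pis", "must be an integer in 0..3")
        if self.pl not in (0, 1, 2, 3):
            raise InvalidInputError("pl", "must be an integer in 0..3")


@dataclass(frozen=True)
class ScorePanel:
    """All four severity scores for one encounter.

    ``sofa`` is ``None`` when the required labs were missing and strict
    handling was requested.
    """

    sil: SILBreakdown
    news: int
    qsofa: int
    sofa: Optional[int]


# ---------------------------------------------------------------------------
# SIL
# ---------------------------------------------------------------------------

def shock_index(heart_rate: float, systolic_bp: float) -> float:
    """Heart rate divided by systolic blood pressure, rounded to 2 decimals.

    Rounding to the published 2-decimal precision makes the score's closed
    bin intervals tile the non-negative line exactly.
    """
    if heart_rate is None or not heart_rate > 0:
        raise InvalidInputError("heart_rate", "must be a strictly positive number")
    if systolic_bp is None or not systolic_bp > 0:
        raise InvalidInputError("systolic_bp", "must be a strictly positive number")
    return round(heart_rate / systolic_bp, 2)


def _to_cents(value: float) -> int:
    # round-half-away-from-zero at 2 decimals, then work in integer
    # hundredths so bin-edge comparisons are exact
    return int(math.floor(value * 100 + 0.5))


# bin upper edges in hundredths; the last bin is open above
_PIS_EDGES = (90, 135, 180)  # <=0.90 -> 0, <=1.35 -> 1, <=1.80 -> 2, else 3
_PL_EDGES = (200, 400, 600)  # <=2.00 -> 0, <=4.00 -> 1, <=6.00 -> 2, else 3


def _bin(cents: int, edges) -> int:
    for points, edge in enumerate(edges):
        if cents <= edge:
            return points
    return len(edges)


def sil_points(shock_index: float, lactate: float) -> SILBreakdown:
    """Bin a shock index and a lactate value into the SIL sub-scores.

    Inputs are rounded to 2 decimal places before binning, so e.g. a shock
    index of 0.904 scores PIS 0 while 0.905 scores PIS 1.
    """
    if shock_index is None or shock_index < 0:
        raise InvalidInputError("shock_index", "must be non-negative")
    if lactate is None or lactate < 0:
        raise InvalidInputError("lactate", "must be non-negative")
    si = round(shock_index, 2)
    pis = _bin(_to_cents(si), _PIS_EDGES)
    pl = _bin(_to_cents(lactate), _PL_EDGES)
    return SILBreakdown(shock_index=si, pis=pis, pl=pl)


# ---------------------------------------------------------------------------
# NEWS
# ---------------------------------------------------------------------------

def _news_respiratory_rate(rr: float) -> int:
    if rr <= 8:
        return 3
    if rr <= 11:
        return 1
    if rr <= 20:
        return 0
    if rr <= 24:
        return 2
    return 3


def _news_spo2(spo2: float) -> int:
    # NEWS2 Scale 1; numerically identical to the 2012 bands
    if spo2 <= 91:
        return 3
    if spo2 <= 93:
        return 2
    if spo2 <= 95:
        return 1
    return 0


def _news_temperature(t: float) -> int:
    if t <= 35.0:
        return 3
    if t <= 36.0:
        return 1
    if t <= 38.0:
        return 0
    if t <= 39.0:
        return 1
    return 2


def _news_systolic_bp(sbp: float) -> int:
    if sbp <= 90:
        return 3
    if sbp <= 100:
        return 2
    if sbp <= 110:
        return 1
    if sbp <= 219:
        return 0
    return 3


def _news_heart_rate(hr: float) -> int:
    if hr <= 40:
        return 3
    if hr <= 50:
        return 1
    if hr <= 90:
        return 0
    if hr <= 110:
        return 1
    if hr <= 130:
        return 2
    return 3


def news_points(vitals: VitalSigns, variant: str = "news2") -> int:
    """Total NEWS over the seven components (0-20).

    ``variant`` pins the published table: ``"news2"`` (2017, Scale 1;
    default) or ``"news2012"``.  For the components carried by
    :class:`VitalSigns` the two tables assign identical points; the switch
    exists so downstream reports can record which table was applied.
    Altered consciousness (not alert, or GCS < 15) scores 3.
    """
    if variant not in ("news2", "news2012"):
        raise InvalidInputError("variant", f"unknown NEWS variant {variant!r}")
    missing = [
        name
        for name in (
            "respiratory_rate", "spo2", "supplemental_o2",
            "temperature", "systolic_bp", "heart_rate", "consciousness",
        )
        if getattr(vitals, name) is None
    ]
    if missing:
        raise MissingDataError(missing)
    total = (
        _news_respiratory_rate(vitals.respiratory_rate)
        + _news_spo2(vitals.spo2)
        + (2 if vitals.supplemental_o2 else 0)
        + _news_temperature(vitals.temperature)
        + _news_systolic_bp(vitals.systolic_bp)
        + _news_heart_rate(vitals.heart_rate)
        + (0 if vitals.alert else 3)
    )
    return total


# ---------------------------------------------------------------------------
# qSOFA
# ---------------------------------------------------------------------------

def qsofa_points(vitals: VitalSigns) -> int:
    """Sepsis-3 quick SOFA: one point each for RR >= 22, SBP <= 100 and
    altered mentation (not alert / GCS < 15)."""
    missing = [
        name for name in ("respiratory_rate", "systolic_bp", "consciousness")
        if getattr(vitals, name) is None
    ]
    if missing:
        raise MissingDataError(missing)
    return (
        int(vitals.respiratory_rate >= 22)
        + int(vitals.systolic_bp <= 100)
        + int(not vitals.alert)
    )


# ---------------------------------------------------------------------------
# SOFA
# ---------------------------------------------------------------------------

def _sofa_respiration(pf: float) -> int:
    if pf >= 400:
        return 0
    if pf >= 300:
        return 1
    if pf >= 200:
        return 2
    if pf >= 100:
        return 3
    return 4


def _sofa_coagulation(platelets: float) -> int:
    if platelets >= 150:
        return 0
    if platelets >= 100:
        return 1
    if platelets >= 50:
        return 2
    if platelets >= 20:
        return 3
    return 4


def _sofa_liver(bilirubin: float) -> int:
    if bilirubin < 1.2:
        return 0
    if bilirubin < 2.0:
        return 1
    if bilirubin < 6.0:
        return 2
    if bilirubin < 12.0:
        return 3
    return 4


_VASOPRESSOR_POINTS = {
    "dopamine_low": 2,
    "dopamine_mid": 3,
    "dopamine_high_or_epi": 4,
    "high_dose": 4,
}


def _sofa_cardiovascular(map_: Optional[float], vasopressor: Optional[str]) -> Optional[int]:
    if vasopressor is not None and vasopressor != "none":
        return _VASOPRESSOR_POINTS[vasopressor]
    if map_ is None:
        return None
    return 0 if map_ >= 70 else 1


def _sofa_cns(gcs: int) -> int:
    if gcs == 15:
        return 0
    if gcs >= 13:
        return 1
    if gcs >= 10:
        return 2
    if gcs >= 6:
        return 3
    return 4


def _sofa_renal(creatinine: float) -> int:
    if creatinine < 1.2:
        return 0
    if creatinine < 2.0:
        return 1
    if creatinine < 3.5:
        return 2
    if creatinine < 5.0:
        return 3
    return 4


def sofa_points(
    vitals: VitalSigns, labs: LabPanel, missing: str = "strict"
) -> Optional[int]:
    """Total SOFA over the six organ systems (0-24).

    ``missing`` controls absent components: ``"strict"`` raises a
    :class:`MissingDataError` listing them, ``"skip"`` returns ``None``
    (score absent, record excluded from SOFA analyses), ``"zero"``
    imputes 0 points for each missing system.
    """
    if missing not in ("strict", "skip", "zero"):
        raise InvalidInputError("missing", f"unknown missing-data mode {missing!r}")
    gcs = vitals.gcs
    components = {
        "respiration": None if labs.pao2_fio2 is None else _sofa_respiration(labs.pao2_fio2),
        "coagulation": None if labs.platelets is None else _sofa_coagulation(labs.platelets),
        "liver": None if labs.bilirubin is None else _sofa_liver(labs.bilirubin),
        "cardiovascular": _sofa_cardiovascular(labs.mean_arterial_pressure, labs.vasopressor),
        "cns": None if gcs is None else _sofa_cns(gcs),
        "renal": None if labs.creatinine is None else _sofa_renal(labs.creatinine),
    }
    absent = [name for name, pts in components.items() if pts is None]
    if absent:
        if missing == "strict":
            raise MissingDataError(absent)
        if missing == "skip":
            return None
    return sum(pts for pts in components.values() if pts is not None)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def score_panel(
    vitals: VitalSigns,
    labs: LabPanel,
    news_variant: str = "news2",
    sofa_missing: str = "skip",
) -> ScorePanel:
    """Compute SIL, NEWS, qSOFA and SOFA for one encounter."""
    si = shock_index(vitals.heart_rate, vitals.systolic_bp)
    if labs.lactate is None:
        raise MissingDataError("lactate")
    return ScorePanel(
        sil=sil_points(si, labs.lactate),
        news=news_points(vitals, variant=news_variant),
        qsofa=qsofa_points(vitals),
        sofa=sofa_points(vitals, labs, missing=sofa_missing),
    )
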