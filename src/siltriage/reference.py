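"""Packaged summary counts from the published validation study.

The study did not deposit patient-level data; these printed summary
counts are the anchors for fixtures, the synthetic-cohort defaults and
the acceptance checks.  The expected-mortality percentages come from the
(unpublished) derivation study and are carried as constants only.
"""

from __future__ import annotations

from .diagnostics import Stratum, StratumTable

#: Patients screened for suspected sepsis and the number confirmed.
SUSPECTED_N = 315
CONFIRMED_N = 299

#: In-hospital outcome margin of the confirmed cohort.
DEATHS = 61
SURVIVORS = 238

#: Diagnosis-class margins and outcomes within each class.
SEPSIS_ONLY_N = 193
SEPSIS_ONLY_DEATHS = 19
SEPTIC_SHOCK_N = 106
SEPTIC_SHOCK_DEATHS = 42

MALE_N = 124

#: Comorbidity counts as (survivors_with, deaths_with) pairs.
COMORBIDITY_COUNTS = {
    "hypertension": (103, 29),
    "diabetes": (55, 16),
    "renal_insufficiency": (16, 14),
    "immunosuppression": (47, 13),
    "copd": (18, 10),
}

#: Published SIL operating characteristics (sensitivity/specificity).
SIL_SENSITIVITY = 0.694
SIL_SPECIFICITY = 0.678

#: Per-SIL-value strata: (score value, total n, deaths, expected mortality %).
#: The expected column is the derivation-study constant.
SIL_STRATA = (
    (0, 87, 6, 11.8),
    (1, 104, 15, 23.4),
    (2, 52, 11, 34.8),
    (3, 36, 17, 42.2),
    (4, 15, 8, 66.3),
    (5, 2, 1, 85.4),
    (6, 3, 3, 90.4),
)


def stratum_table() -> StratumTable:
    """The per-SIL-value stratum table as a :class:`StratumTable`."""
    return StratumTable(
        [
            Stratum(score_value=v, n_total=n, n_deaths=d, expected_mortality=e)
            for v, n, d, e in SIL_STRATA
        ]
    )


def comorbidity_prevalences() -> dict:
    """Marginal prevalence of each comorbidity flag in the confirmed cohort."""
    return {
        name: (s + d) / CONFIRMED_N for name, (s, d) in COMORBIDITY_COUNTS.items()
    }
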