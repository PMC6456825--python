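"""Published counts from the primary-care validation study this toolkit models.

A smartphone-PPG AF screening app was validated against cardiologist-read
12-lead ECG in 223 primary-care subjects aged 65+, each performing three
one-minute measurements with simultaneous PPG and single-lead ECG.  The
publication reports only aggregate 2×2 counts; this module records those
counts so the accuracy tables can be recomputed (and extended, e.g. with
recoding scenarios and prevalence-adjusted predictive values) from exact
integer arithmetic.

Only self-consistent published quantities are reproduced here.  Known
wrinkles, preserved deliberately:

* The single-lead-ECG participant-level row is internally inconsistent in
  the publication (90 positives + 111 matched negatives with 9 mismatches
  cannot give specificity 96.55%); only its sensitivity (90/95) is usable.
* The prevalence-adjusted PPV printed as 63% does not follow from the
  printed counts (Bayes' rule on 87/91 and 112/116 at 6% prevalence gives
  ≈ 64%); the recomputed value is reported as-is, not forced to 63%.
"""

from __future__ import annotations

from .aggregate import SCENARIOS
from .diagnostics import (
    AccuracyReport,
    ConfusionTable,
    _report_from_table,
    scenario_table,
)

__all__ = [
    "PPG_PARTICIPANT_EXCLUDE",
    "PPG_PARTICIPANT_INSUFFICIENT",
    "PPG_MEASUREMENT_EXCLUDE",
    "PPG_MEASUREMENT_INSUFFICIENT",
    "ECG_PARTICIPANT_EXCLUDE",
    "ECG_PARTICIPANT_INSUFFICIENT",
    "SUBJECT_AGREEMENT",
    "EXTERNAL_PREVALENCE",
    "participant_reports",
    "measurement_reports",
]

#: Expected AF prevalence in the 65+ screening population, used for the
#: prevalence-adjusted predictive values.
EXTERNAL_PREVALENCE = 0.06

# --- PPG, participant level -------------------------------------------------
# 223 subjects; 16 had no sufficient-quality PPG result (9 of them gold-AF).
# Among the 207 analysable: 91 positives (87 TP + 4 FP), 116 negatives
# (112 TN + 4 FN).
PPG_PARTICIPANT_EXCLUDE = ConfusionTable(tp=87, fp=4, fn=4, tn=112)
PPG_PARTICIPANT_INSUFFICIENT = {"af": 9, "no_af": 7}

# --- PPG, measurement level -------------------------------------------------
# 657 measurements, 110 insufficient; among the 547 analysable:
# 233 gold-AF (222 TP + 11 FN), 314 gold-non-AF (302 TN + 12 FP).
PPG_MEASUREMENT_EXCLUDE = ConfusionTable(tp=222, fp=12, fn=11, tn=302)
# 292 gold-AF measurements in all 657 → 59 insufficient were gold-AF.
PPG_MEASUREMENT_INSUFFICIENT = {"af": 59, "no_af": 51}

# --- single-lead ECG, participant level -------------------------------------
# 210 analysable subjects, 95 gold-AF; sensitivity 90/95.  The published
# negative-side counts do not add up (see module docstring); tn is stored as
# the matched-negative count implied by 201 concordant results and must not
# be used as an accuracy target.
ECG_PARTICIPANT_EXCLUDE = ConfusionTable(tp=90, fp=4, fn=5, tn=111)
ECG_PARTICIPANT_INSUFFICIENT = {"af": 5, "no_af": 8}

# --- PPG vs single-lead ECG consistency -------------------------------------
# (pairs with both signals sufficient, pairs agreeing)
SUBJECT_AGREEMENT = (196, 192)
MEASUREMENT_AGREEMENT = (516, 506)


def participant_reports(
    modality: str = "PPG", external_prevalence: float = EXTERNAL_PREVALENCE
) -> dict[str, AccuracyReport]:
    """Participant-level accuracy under all three insufficient-quality
    scenarios, recomputed from the published integer counts."""
    if modality == "PPG":
        base, insuff = PPG_PARTICIPANT_EXCLUDE, PPG_PARTICIPANT_INSUFFICIENT
    elif modality == "ECG":
        base, insuff = ECG_PARTICIPANT_EXCLUDE, ECG_PARTICIPANT_INSUFFICIENT
    else:
        raise ValueError(f"unknown modality {modality!r}")
    out = {}
    for scenario in SCENARIOS:
        t = scenario_table(base, insuff["af"], insuff["no_af"], scenario)
        excluded = sum(insuff.values()) if scenario == "exclude" else 0
        out[scenario] = _report_from_table(
            t, "participant", scenario, modality, external_prevalence, excluded
        )
    return out


def measurement_reports(
    external_prevalence: float = EXTERNAL_PREVALENCE,
) -> dict[str, AccuracyReport]:
    """Measurement-level PPG accuracy under all three scenarios."""
    out = {}
    for scenario in SCENARIOS:
        t = scenario_table(
            PPG_MEASUREMENT_EXCLUDE,
            PPG_MEASUREMENT_INSUFFICIENT["af"],
            PPG_MEASUREMENT_INSUFFICIENT["no_af"],
            scenario,
        )
        excluded = (sum(PPG_MEASUREMENT_INSUFFICIENT.values())
                    if scenario == "exclude" else 0)
        out[scenario] = _report_from_table(
            t, "measurement", scenario, "PPG", external_prevalence, excluded
        )
    return out
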