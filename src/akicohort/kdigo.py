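"""KDIGO-based classification of acute and chronic kidney disease.

Classifies each participant at three timepoints (admission, 48 h, 3 months):

* **AKI** — serum creatinine >= 1.5x an estimated baseline, staged by fold
  change: stage 1 [1.5, 2.0), stage 2 [2.0, 3.0), stage 3 [3.0, inf).
  Boundaries are half-open with the boundary assigned to the higher stage,
  reconciling the printed ranges 1.5-1.9x / 2.0-2.9x / >=3.0x with
  continuous ratios.
* **Incident AKI** — criteria not met at admission but creatinine rises
  >= 0.3 mg/dL by 48 h (KDIGO absolute criterion).
* **Recovery** — among AKI: creatinine falls >= 0.3 mg/dL by 48 h, or the
  3-month creatinine is normal (< 1.3 mg/dL).
* **AKD** — any of: combined eGFR < 60 mL/min/1.73 m², eGFR fall >= 35%,
  creatinine rise > 50% over baseline, or dipstick haematuria/proteinuria.
* **CKD** — combined eGFR < 60 at both admission and 3 months. Participants
  with admission eGFR >= 60 are not assessable (chronicity unproven), as are
  those missing the 3-month value.

Baseline creatinine is unknown for essentially all acute admissions in this
setting, so four estimation strategies are supported and compared: MDRD
back-calculation at an assumed GFR of 100 or 75 mL/min/1.73 m², FAS
back-calculation, and the lowest measured inpatient creatinine.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import equations
from .equations import EquationSpec, backcalc_creatinine, combined_egfr
from .records import (CreatinineSeries, DomainError, ParticipantRecord,
                      PersonParams, UrineFindings)

MDRD_G100 = "MDRD_G100"
MDRD_G75 = "MDRD_G75"
FAS_BACKCALC = "FAS_BACKCALC"
LOWEST_INPATIENT = "LOWEST_INPATIENT"

BASELINE_METHODS = (MDRD_G100, MDRD_G75, FAS_BACKCALC, LOWEST_INPATIENT)

#: staging thresholds as creatinine fold change over baseline
STAGE_THRESHOLDS = (1.5, 2.0, 3.0)

INCIDENT_RISE_MGDL = 0.3
RECOVERY_FALL_MGDL = 0.3
NORMAL_CREATININE_MGDL = 1.3
CKD_EGFR_THRESHOLD = 60.0
AKD_EGFR_DROP_FRACTION = 0.35
AKD_CR_RISE_FOLD = 1.5

#: absolute-threshold comparisons tolerate float representation error
_EPS = 1e-9

CKD_YES = "yes"
CKD_NO = "no"
CKD_INDETERMINATE = "indeterminate"


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class BaselineEstimate:
    """An estimated baseline creatinine (mg/dL) tagged with its method."""

    value: float
    method: str


@dataclass(frozen=True)
class KidneyClassification:
    """Per-participant kidney-disease flags under one baseline method."""

    baseline_cr: BaselineEstimate
    aki_stage: int                        # 0 = no AKI
    incident_aki_48h: Optional[bool]      # None = not assessable
    recovered: Optional[bool]             # None = not assessable / no AKI
    akd_admission: bool
    akd_3m: Optional[bool]                # None = not assessable
    ckd: str                              # yes / no / indeterminate


def estimate_baseline(person: PersonParams, series: CreatinineSeries,
                      method: str) -> BaselineEstimate:
    """Estimated baseline creatinine under one of the four study strategies."""
    if method == MDRD_G100:
        v = backcalc_creatinine(100.0, person, EquationSpec(equations.MDRD4))
    elif method == MDRD_G75:
        v = backcalc_creatinine(75.0, person, EquationSpec(equations.MDRD4))
    elif method == FAS_BACKCALC:
        v = backcalc_creatinine(
            equations.DEFAULT_CONSTANTS["default_assumed_gfr"], person,
            EquationSpec(equations.FAS))
    elif method == LOWEST_INPATIENT:
        measured = [v for v in (series.cr0, series.cr48) if not _missing(v)]
        if not measured:
            raise DomainError("LOWEST_INPATIENT requires at least one measured inpatient creatinine")
        v = min(measured)
    else:
        raise DomainError(f"unknown baseline method {method!r}; expected one of {BASELINE_METHODS}")
    return BaselineEstimate(value=v, method=method)


def stage_aki(measured: float, baseline: float) -> int:
    """AKI stage (0-3) from the creatinine fold change over baseline."""
    if _missing(measured) or not measured > 0:
        raise DomainError(f"measured creatinine must be positive, got {measured}")
    if _missing(baseline) or not baseline > 0:
        raise DomainError(f"baseline creatinine must be positive, got {baseline}")
    r = measured / baseline
    t1, t2, t3 = STAGE_THRESHOLDS
    if r < t1:
        return 0
    if r < t2:
        return 1
    if r < t3:
        return 2
    return 3


def incident_aki(baseline_flagged: bool, cr0: float, cr48: Optional[float]) -> Optional[bool]:
    """AKI arising by 48 h in participants without AKI at admission.

    Requires a creatinine rise >= 0.3 mg/dL within 48 h. None when the 48-h
    value is missing.
    """
    if _missing(cr0):
        raise DomainError("incident_aki requires an admission creatinine")
    if _missing(cr48):
        return None
    if baseline_flagged:
        return False
    return (cr48 - cr0) >= INCIDENT_RISE_MGDL - _EPS


def recovery(series: CreatinineSeries, aki_flag: bool) -> Optional[bool]:
    """AKI recovery: >= 0.3 mg/dL fall by 48 h or normal (< 1.3 mg/dL)
    creatinine at 3 months. Only defined for participants with AKI."""
    if not aki_flag:
        raise DomainError("recovery is only defined for participants with AKI")
    by_48h = (None if _missing(series.cr48)
              else (series.cr0 - series.cr48) >= RECOVERY_FALL_MGDL - _EPS)
    by_3m = None if _missing(series.cr3m) else series.cr3m < NORMAL_CREATININE_MGDL
    if by_48h is None and by_3m is None:
        return None
    return bool(by_48h) or bool(by_3m)


def classify_akd(person: PersonParams, cr: float, baseline_cr: float,
                 urine: UrineFindings) -> bool:
    """Acute kidney disease: any of low eGFR, large eGFR drop, large
    creatinine rise, or urinary blood/protein (disjunctive reading)."""
    if _missing(cr) or not cr > 0 or _missing(baseline_cr) or not baseline_cr > 0:
        raise DomainError(f"creatinine values must be positive, got cr={cr}, baseline={baseline_cr}")
    egfr_now = combined_egfr(cr, person).value
    egfr_base = combined_egfr(baseline_cr, person).value
    return bool(
        egfr_now < CKD_EGFR_THRESHOLD
        or egfr_now <= (1.0 - AKD_EGFR_DROP_FRACTION) * egfr_base
        or cr > AKD_CR_RISE_FOLD * baseline_cr
        or urine.haematuria
        or urine.proteinuria
    )


def classify_ckd(person: PersonParams, series: CreatinineSeries) -> str:
    """CKD: combined eGFR < 60 mL/min/1.73 m² at admission and 3 months.

    Admission eGFR >= 60 leaves the 3-month duration unproven -> indeterminate;
    likewise when the 3-month creatinine is missing.
    """
    egfr0 = combined_egfr(series.cr0, person).value
    if egfr0 >= CKD_EGFR_THRESHOLD:
        return CKD_INDETERMINATE
    if _missing(series.cr3m):
        return CKD_INDETERMINATE
    egfr3m = combined_egfr(series.cr3m, person).value
    return CKD_YES if egfr3m < CKD_EGFR_THRESHOLD else CKD_NO


def classify_participant(record: ParticipantRecord, method: str = MDRD_G100) -> KidneyClassification:
    """Full kidney classification of one participant under one baseline method."""
    person = record.person()
    series = record.series()
    urine = record.urine()
    baseline = estimate_baseline(person, series, method)

    aki_stage_admission = stage_aki(series.cr0, baseline.value)
    flagged = aki_stage_admission >= 1
    incident = incident_aki(flagged, series.cr0, series.cr48)

    # the participant's operative AKI flag covers admission or incident AKI
    any_aki = flagged or bool(incident)
    recovered = recovery(series, True) if any_aki else None

    akd0 = classify_akd(person, series.cr0, baseline.value, urine)
    if _missing(series.cr3m):
        akd3m: Optional[bool] = None
    else:
        # dipstick testing was an admission-only measurement; the 3-month AKD
        # call rests on the creatinine/eGFR criteria alone
        akd3m = classify_akd(person, series.cr3m, baseline.value, UrineFindings())

    ckd = classify_ckd(person, series)

    return KidneyClassification(
        baseline_cr=baseline,
        aki_stage=aki_stage_admission,
        incident_aki_48h=incident,
        recovered=recovered,
        akd_admission=akd0,
        akd_3m=akd3m,
        ckd=ckd,
    )


def sensitivity_table(cohort: list[ParticipantRecord],
                      methods: tuple[str, ...] = BASELINE_METHODS) -> pd.DataFrame:
    """AKI prevalence and stage distribution under each baseline strategy.

    One row per method: participants classified, AKI count, prevalence, and
    the stage split among AKI cases.
    """
    if not cohort:
        raise DomainError("sensitivity_table requires a non-empty cohort")
    rows = []
    for method in methods:
        stages = []
        for rec in cohort:
            if _missing(rec.cr0):
                continue
            cls = classify_participant(rec, method)
            stages.append(cls.aki_stage)
        n = len(stages)
        n_aki = sum(s >= 1 for s in stages)
        rows.append({
            "method": method,
            "n_classified": n,
            "n_aki": n_aki,
            "prevalence": n_aki / n if n else float("nan"),
            "n_stage1": sum(s == 1 for s in stages),
            "n_stage2": sum(s == 2 for s in stages),
            "n_stage3": sum(s == 3 for s in stages),
        })
    return pd.DataFrame(rows).set_index("method")
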