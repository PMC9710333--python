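"""Cohort CSV I/O and the column dictionary.

The interchange format is a flat CSV, one row per participant, with the
columns of :data:`akicohort.records.COHORT_COLUMNS`:

==============  =====================================================
column          meaning
==============  =====================================================
pid             participant identifier
age             years
sex             ``female`` / ``male``
hiv             HIV status (1/0; empty = unknown)
art             on antiretroviral therapy (1/0; empty = n/a or unknown)
sbp, dbp        systolic/diastolic blood pressure, mm Hg
rr              respiratory rate, breaths/min
gcs             Glasgow Coma Scale (3-15)
cr0,cr48,cr3m   serum creatinine mg/dL at admission / 48 h / 3 months
haematuria      dipstick blood (1/0)
proteinuria     dipstick protein (1/0)
ri              renal resistive index
weight, height  kg / cm
died            vital status at follow-up (1/0; empty = lost to follow-up)
followup_days   days of follow-up (time of death or last contact)
==============  =====================================================

Empty cells encode missing values. Creatinine columns are validated to lie
in (0, 25] mg/dL; larger values look like µmol/L and are rejected as unit
errors. Lines starting with ``#`` are metadata (seed, config hash) and are
skipped on read.
"""
from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import pandas as pd

from .records import (COHORT_COLUMNS, CREATININE_RANGE_MGDL, DomainError,
                      ParticipantRecord)


class UnitsError(DomainError):
    """A value's magnitude suggests it is in the wrong unit."""


_BOOL_COLS = ("hiv", "art", "haematuria", "proteinuria", "died")
_FLOAT_COLS = ("age", "sbp", "dbp", "rr", "cr0", "cr48", "cr3m", "ri",
               "weight", "height", "followup_days")
REQUIRED_COLUMNS = ("pid", "age", "sex", "cr0")


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str):
        v = v.strip().lower()
        if v in ("1", "true", "yes"):
            return True
        if v in ("0", "false", "no"):
            return False
        raise ValueError(f"cannot parse boolean {v!r}")
    return bool(int(v))


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in COHORT_COLUMNS}
        for c in _BOOL_COLS:
            row[c] = None if row[c] is None else int(row[c])
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(df: pd.DataFrame, source: str = "<frame>") -> list[ParticipantRecord]:
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(f"{source}: ignoring unknown columns {unknown}", stacklevel=2)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{source}: required columns missing: {missing}")

    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            kwargs = {"pid": str(row["pid"]), "age": float(row["age"]),
                      "sex": str(row["sex"]).strip().lower()}
            for c in _FLOAT_COLS:
                if c == "age":
                    continue
                kwargs[c] = _opt_float(row[c]) if c in df.columns else None
            for c in _BOOL_COLS:
                kwargs[c] = _opt_bool(row[c]) if c in df.columns else None
            gcs = row.get("gcs")
            kwargs["gcs"] = None if gcs is None or (isinstance(gcs, float) and math.isnan(gcs)) else int(gcs)
            lo, hi = CREATININE_RANGE_MGDL
            for c in ("cr0", "cr48", "cr3m"):
                v = kwargs[c]
                if v is not None and not (lo < v <= hi):
                    raise UnitsError(
                        f"{c}={v} outside ({lo}, {hi}] mg/dL — looks like µmol/L; "
                        "convert before loading (divide by 88.42)")
            records.append(ParticipantRecord(**kwargs))
        except UnitsError as e:
            raise UnitsError(f"{source}, row {rownum}: {e}") from e
        except (ValueError, TypeError, KeyError) as e:
            raise DomainError(f"{source}, row {rownum}: malformed row ({e})") from e
    return records


def read_cohort(path) -> list[ParticipantRecord]:
    """Read a cohort CSV into typed records, validating units and columns."""
    df = pd.read_csv(path, comment="#", dtype={"pid": str})
    return frame_to_records(df, source=str(path))


def write_cohort(records: Sequence[ParticipantRecord], path,
                 header_lines: Sequence[str] = ()) -> None:
    """Write a cohort CSV; ``header_lines`` become ``#`` metadata comments
    (e.g. the generating seed)."""
    df = records_to_frame(records)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def truths_to_frame(truths) -> pd.DataFrame:
    from dataclasses import asdict

    return pd.DataFrame([asdict(t) for t in truths])


def classifications_to_frame(cohort, classifications) -> pd.DataFrame:
    """Per-participant classification table for one baseline method."""
    rows = []
    for rec, cls in zip(cohort, classifications):
        rows.append({
            "pid": rec.pid,
            "baseline_method": cls.baseline_cr.method,
            "baseline_cr": cls.baseline_cr.value,
            "aki_stage": cls.aki_stage,
            "aki": int(cls.aki_stage >= 1),
            "incident_aki_48h": _fmt_opt(cls.incident_aki_48h),
            "recovered": _fmt_opt(cls.recovered),
            "akd_admission": int(cls.akd_admission),
            "akd_3m": _fmt_opt(cls.akd_3m),
            "ckd": cls.ckd,
        })
    return pd.DataFrame(rows)


def _fmt_opt(v) -> str:
    return "" if v is None else str(int(v))
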