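"""Illness-severity scoring (qSOFA)."""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .records import DomainError


@dataclass(frozen=True)
class VitalSigns:
    """Admission vital signs entering the qSOFA score."""

    sbp: float  # systolic blood pressure, mm Hg
    rr: float   # respiratory rate, breaths/min
    gcs: int    # Glasgow Coma Scale, 3-15

    def __post_init__(self):
        if not self.sbp > 0:
            raise DomainError(f"sbp must be positive, got {self.sbp}")
        if not self.rr > 0:
            raise DomainError(f"rr must be positive, got {self.rr}")
        if not 3 <= self.gcs <= 15:
            raise DomainError(f"gcs must lie in [3, 15], got {self.gcs}")


def qsofa(v: VitalSigns) -> int:
    """Quick Sepsis-related Organ Failure Assessment score (0-3).

    One point each for systolic BP <= 100 mm Hg, respiratory rate
    >= 22 breaths/min, and Glasgow Coma Scale < 15.
    """
    return int(v.sbp <= 100) + int(v.rr >= 22) + int(v.gcs < 15)


def qsofa_from_values(sbp: Optional[float], rr: Optional[float],
                      gcs: Optional[float]) -> Optional[int]:
    """qSOFA from possibly-missing vitals; None when not assessable."""
    vals = (sbp, rr, gcs)
    if any(x is None or (isinstance(x, float) and math.isnan(x)) for x in vals):
        return None
    return qsofa(VitalSigns(sbp=float(sbp), rr=float(rr), gcs=int(gcs)))
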