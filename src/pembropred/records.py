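"""Patient-level data containers shared by all pipeline stages."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InputError

#: Continuous pretreatment covariates (units: years, mm, lab units, %, mm).
CONTINUOUS_COVARIATES = ("age", "breslow", "ldh", "ly_pct", "baseline_sod")
#: Binary pretreatment covariates (0/1, NaN = undetermined).
BINARY_COVARIATES = ("cutaneous", "nodular", "braf_v600")
COVARIATE_FIELDS = CONTINUOUS_COVARIATES + BINARY_COVARIATES


class ScanPoint(NamedTuple):
    """One imaging assessment: days since treatment start and SOD in mm.

    The baseline scan has ``day <= 0``; every series must contain exactly
    one baseline.
    """

    day: float
    sod: float


@dataclass
class PatientRecord:
    """Pretreatment covariates plus the dated SOD series of one patient."""

    patient_id: str
    covariates: dict[str, float]
    scans: list[ScanPoint]
    followup_end: float          # days from treatment start
    center: str = ""

    def __post_init__(self) -> None:
        self.scans = sorted((ScanPoint(float(d), float(s)) for d, s in self.scans),
                            key=lambda p: p.day)
        baselines = [p for p in self.scans if p.day <= 0]
        if len(baselines) != 1:
            raise InputError(
                f"patient {self.patient_id!r}: need exactly one baseline scan "
                f"(day <= 0), got {len(baselines)}")
        if baselines[0].sod <= 0:
            raise InputError(f"patient {self.patient_id!r}: baseline SOD must be > 0")
        if self.followup_end <= 0:
            raise InputError(f"patient {self.patient_id!r}: follow-up end must be > 0")
        days = [p.day for p in self.scans]
        if len(set(days)) != len(days):
            raise InputError(f"patient {self.patient_id!r}: duplicate scan days")

    @property
    def baseline(self) -> ScanPoint:
        return next(p for p in self.scans if p.day <= 0)

    @property
    def baseline_sod(self) -> float:
        return self.baseline.sod

    @property
    def post_baseline(self) -> list[ScanPoint]:
        return [p for p in self.scans if p.day > 0]

    def covariate(self, name: str) -> float:
        """Covariate value, NaN if missing."""
        v = self.covariates.get(name)
        return float("nan") if v is None else float(v)


def has_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))
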