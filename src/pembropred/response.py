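"""RECIST 1.1 response classification and time to progression (TTP).

A patient's scan series is reduced to the SOD (sum of target-lesion
diameters, mm).  Each post-baseline scan receives exactly one category:

* CR -- complete response: SOD is zero (all target lesions disappeared);
* PD -- progressive disease: SOD increased >= 20% over the nadir (smallest
  SOD so far, baseline included) AND by >= 5 mm in absolute terms;
* PR -- partial response: SOD decreased >= 30% from baseline;
* SD -- stable disease: none of the above.

PD takes precedence over PR when both thresholds hold.  The 5-mm absolute
floor is part of RECIST 1.1 and applied by default; pass
``pd_abs_floor=None`` to disable it.  New lesions are deliberately *not* a
progression trigger here: progression is determined purely from the change
in size of the target lesions.

TTP is the day of the first PD-classified scan (no interpolation), censored
at the follow-up end otherwise, and is discretized into four intervals:
1: [0, 90) days, 2: [90, 150), 3: [150, 365), 4: censored or >= 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import DomainError, InputError
from .records import PatientRecord, ScanPoint

__all__ = [
    "CATEGORIES",
    "PD_REL_INCREASE",
    "PR_REL_DECREASE",
    "PD_ABS_FLOOR_MM",
    "TTP_INTERVAL_EDGES",
    "ScanPoint",
    "ResponseTimeline",
    "assess_scan",
    "build_timeline",
    "ttp_to_interval",
]

CATEGORIES = ("CR", "PR", "SD", "PD")

PD_REL_INCREASE = 0.20    # >= 20% over nadir
PR_REL_DECREASE = 0.30    # >= 30% below baseline
PD_ABS_FLOOR_MM = 5.0     # absolute PD requirement, mm

#: Half-open TTP interval boundaries (days): [0,90), [90,150), [150,365).
TTP_INTERVAL_EDGES = (90.0, 150.0, 365.0)


def assess_scan(baseline_sod: float, nadir_sod: float, current_sod: float,
                pd_abs_floor: float | None = PD_ABS_FLOOR_MM) -> str:
    """Classify a single scan given the baseline and nadir references."""
    if baseline_sod <= 0:
        raise DomainError("baseline SOD must be positive")
    if current_sod < 0:
        raise DomainError("SOD must be nonnegative")
    if nadir_sod > baseline_sod:
        raise DomainError("nadir cannot exceed baseline")
    if current_sod == 0:
        return "CR"
    grown = current_sod >= (1.0 + PD_REL_INCREASE) * nadir_sod
    if grown and (pd_abs_floor is None or current_sod - nadir_sod >= pd_abs_floor):
        return "PD"
    if current_sod <= (1.0 - PR_REL_DECREASE) * baseline_sod:
        return "PR"
    return "SD"


def ttp_to_interval(ttp_days: float | None, followup_end: float) -> int:
    """Map a (possibly censored) TTP to interval category 1-4."""
    if followup_end <= 0:
        raise DomainError("follow-up end must be positive")
    if ttp_days is None:
        return 4
    if ttp_days < 0:
        raise DomainError("TTP cannot be negative")
    for i, edge in enumerate(TTP_INTERVAL_EDGES, start=1):
        if ttp_days < edge:
            return i
    return 4


@dataclass(frozen=True)
class ResponseTimeline:
    """Per-scan RECIST categories and the derived TTP of one series."""

    baseline_day: float
    baseline_sod: float
    days: tuple[float, ...]          # post-baseline scan days
    sods: tuple[float, ...]
    categories: tuple[str, ...]
    nadir: tuple[float, ...]         # running minimum after each scan
    followup_end: float
    ttp_days: float | None           # None = censored
    ttp_interval: int

    @property
    def censored(self) -> bool:
        return self.ttp_days is None

    @property
    def best_response(self) -> str:
        order = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}
        return min(self.categories, key=order.__getitem__) if self.categories else "SD"


def build_timeline(scans: Iterable[ScanPoint] | Sequence[tuple[float, float]],
                   followup_end: float,
                   pd_abs_floor: float | None = PD_ABS_FLOOR_MM) -> ResponseTimeline:
    """Classify an entire scan series in time order and derive the TTP.

    ``scans`` must contain exactly one baseline (day <= 0).  The nadir is
    initialized at baseline and updated after each classification, so a
    scan is judged against the smallest SOD seen strictly before it.
    """
    pts = sorted((ScanPoint(float(d), float(s)) for d, s in scans), key=lambda p: p.day)
    if not pts:
        raise InputError("empty scan series")
    baselines = [p for p in pts if p.day <= 0]
    if len(baselines) != 1:
        raise InputError(f"need exactly one baseline scan (day <= 0), got {len(baselines)}")
    baseline = baselines[0]
    if baseline.sod <= 0:
        raise InputError("baseline SOD must be positive")

    nadir = baseline.sod
    days, sods, cats, nadirs = [], [], [], []
    ttp: float | None = None
    for p in pts:
        if p.day <= 0:
            continue
        cat = assess_scan(baseline.sod, nadir, p.sod, pd_abs_floor=pd_abs_floor)
        nadir = min(nadir, p.sod)
        days.append(p.day)
        sods.append(p.sod)
        cats.append(cat)
        nadirs.append(nadir)
        if cat == "PD" and ttp is None:
            ttp = p.day
    return ResponseTimeline(
        baseline_day=baseline.day,
        baseline_sod=baseline.sod,
        days=tuple(days),
        sods=tuple(sods),
        categories=tuple(cats),
        nadir=tuple(nadirs),
        followup_end=float(followup_end),
        ttp_days=ttp,
        ttp_interval=ttp_to_interval(ttp, followup_end),
    )


def observed_timeline(record: PatientRecord,
                      pd_abs_floor: float | None = PD_ABS_FLOOR_MM) -> ResponseTimeline:
    """Clinical response timeline of a patient record."""
    return build_timeline(record.scans, record.followup_end, pd_abs_floor=pd_abs_floor)
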