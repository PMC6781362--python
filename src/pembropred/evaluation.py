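"""Agreement statistics for TTP-interval predictions.

Predicted and observed TTP intervals (categories 1-4) are cross-tabulated
into a confusion table; chance-corrected agreement is the multidimensional
Cohen's kappa

    p1 = sum_c n_cc / N            (diagonal proportion)
    p2 = sum_c (row_c/N)(col_c/N)  (expected agreement from the marginals)
    kappa = (p1 - p2) / (1 - p2)

which for two raters over K categories is algebraically the classical
Cohen's kappa.  The module also provides the six-outcome taxonomy of a
prediction (hit / too early / too late / false progression / missed
progression / agreed non-progression), R-squared diagnostics against the
identity line, and the paired-TTP agreement restricted to patients who
progressed both clinically and in the prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, UndefinedStatisticError

__all__ = [
    "ConfusionTable",
    "KappaResult",
    "confusion_table",
    "multidim_kappa",
    "outcome_category",
    "r_squared",
    "ttp_agreement",
]


@dataclass(frozen=True)
class ConfusionTable:
    """K x K counts; rows = predicted/simulated interval, cols = observed."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] < 2:
            raise DomainError("confusion table must be square with K >= 2")
        if np.any(c < 0):
            raise DomainError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "n": self.n,
            "row_marginals": self.row_marginals.tolist(),
            "col_marginals": self.col_marginals.tolist(),
        }


def confusion_table(pred_intervals: Sequence[int], obs_intervals: Sequence[int],
                    k: int = 4) -> ConfusionTable:
    """Cross-tabulate predicted vs observed interval labels (values 1..k)."""
    pred = np.asarray(pred_intervals, dtype=int)
    obs = np.asarray(obs_intervals, dtype=int)
    if pred.shape != obs.shape:
        raise DomainError("label sequences must have equal length")
    counts = np.zeros((k, k), dtype=int)
    for p, o in zip(pred, obs):
        if not (1 <= p <= k and 1 <= o <= k):
            raise DomainError(f"label out of range 1..{k}: ({p}, {o})")
        counts[p - 1, o - 1] += 1
    return ConfusionTable(counts)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p1: float       # observed matched proportion
    p2: float       # chance-expected matched proportion
    n: int

    def to_dict(self) -> dict:
        return {"kappa": self.kappa, "p1": self.p1, "p2": self.p2, "n": self.n}


def multidim_kappa(table: ConfusionTable) -> KappaResult:
    """Multidimensional Cohen's kappa of a predicted-vs-observed table."""
    n = table.n
    if n < 1:
        raise UndefinedStatisticError("kappa undefined for an empty table")
    p1 = float(np.trace(table.counts)) / n
    p2 = float(np.dot(table.row_marginals, table.col_marginals)) / (n * n)
    if p2 >= 1.0:
        raise UndefinedStatisticError(
            "kappa undefined: all mass in one matched category (p2 = 1)")
    return KappaResult(kappa=(p1 - p2) / (1.0 - p2), p1=p1, p2=p2, n=n)


def outcome_category(t_r: int, t_s: int) -> int:
    """Six-outcome taxonomy of one (observed t_r, predicted t_s) pair.

    1: correct interval (t_r = t_s <= 3); 2: progression predicted too
    early (t_s < t_r, both <= 3); 3: predicted too late (t_s > t_r, both
    <= 3); 4: false progression call (t_r = 4, t_s in 1..3); 5: missed
    progression (t_r in 1..3, t_s = 4); 6: agreed non-progression
    (t_r = t_s = 4).
    """
    if not (1 <= t_r <= 4 and 1 <= t_s <= 4):
        raise DomainError("intervals must be in 1..4")
    if t_r == 4 and t_s == 4:
        return 6
    if t_s == 4:
        return 5
    if t_r == 4:
        return 4
    if t_r == t_s:
        return 1
    return 2 if t_s < t_r else 3


def outcome_tally(obs_intervals: Sequence[int],
                  pred_intervals: Sequence[int]) -> dict[int, int]:
    """Counts of the six outcome categories over a cohort."""
    tally = {i: 0 for i in range(1, 7)}
    for t_r, t_s in zip(obs_intervals, pred_intervals):
        tally[outcome_category(int(t_r), int(t_s))] += 1
    return tally


def r_squared(observed: Sequence[float], predicted: Sequence[float],
              log_scale: bool = False) -> float:
    """Coefficient of determination against the identity line.

    ``R^2 = 1 - SS_res / SS_tot`` with residuals taken about the identity
    (no refitted slope) and SS_tot about the observed mean.  In log mode
    both series are log-transformed after dropping every pair that
    contains a zero.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DomainError("observed and predicted must have equal length")
    if log_scale:
        keep = (obs > 0) & (pred > 0)
        obs, pred = np.log(obs[keep]), np.log(pred[keep])
    if obs.size < 2:
        raise UndefinedStatisticError("need >= 2 usable pairs for R^2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def ttp_agreement(pred_ttp_days: Sequence[float | None],
                  obs_ttp_days: Sequence[float | None]) -> float:
    """R^2 of predicted vs observed TTP over doubly-progressing patients.

    Patients censored in either series (``None``/NaN) are excluded; at
    least two patients must progress in both.
    """
    if len(pred_ttp_days) != len(obs_ttp_days):
        raise DomainError("TTP sequences must have equal length")

    def usable(v) -> bool:
        return v is not None and not (isinstance(v, float) and math.isnan(v))

    pairs = [(float(o), float(p)) for p, o in zip(pred_ttp_days, obs_ttp_days)
             if usable(p) and usable(o)]
    if len(pairs) < 2:
        raise UndefinedStatisticError("need >= 2 doubly-progressing patients")
    obs, pred = zip(*pairs)
    return r_squared(obs, pred)
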