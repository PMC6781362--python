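"""Virtual patient cohorts for exercising the full pipeline.

The clinical cohort behind the method (54 pembrolizumab-treated advanced
melanoma patients from two centers) is not publicly deposited, so this
module generates cohorts that emulate its published summary statistics:
age mean 68.5 y on [32.5, 91.5], Breslow thickness mean ~4.1 mm on
[0.37, 28], baseline SOD mean ~79 mm on [5, 247], 20% nodular melanoma,
follow-up median ~9 months on [2, 35], imaging roughly every 3 months, and
per-covariate missingness matching the published availability counts.

Hidden per-patient parameters follow the structure seen in the real fits:
``ln(a_pem)`` is Gaussian (truncated to [ln 10, ln 1e4]) with mean
decreasing linearly in the normalized baseline SOD (reproducing the strong
negative correlation between drug benefit and baseline burden), and the
growth-rate class is Bernoulli with log-odds increasing in Breslow
thickness and nodular status.  Each record is produced by forward
simulation of the personal model, observed on a jittered ~90-day scan
grid with multiplicative log-normal measurement noise and a 10-mm
per-lesion detection floor, and censored administratively at the follow-up
end.  The ground-truth parameter table is returned separately and never
leaks into the emitted records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dynamics
from .calibration import predict_sod
from .dynamics import CellSodConversion, ModelParameters, SimulationConfig
from .errors import ConfigError
from .records import PatientRecord, ScanPoint
from .response import build_timeline

__all__ = ["CohortConfig", "CohortResult", "sample_covariates",
           "sample_parameters", "generate_cohort", "parameter_grid_cohort"]

DAYS_PER_MONTH = 30.44

#: Missingness rates matching the published availability counts (x/54).
DEFAULT_MISSING_RATES = {
    "age": 0.0,
    "breslow": 11 / 54,
    "ldh": 3 / 54,
    "ly_pct": 1 / 54,
    "baseline_sod": 0.0,
    "cutaneous": 2 / 54,
    "nodular": 2 / 54,
    "braf_v600": 8 / 54,
}


@dataclass
class CohortConfig:
    """Distributions and observation model of a synthetic cohort."""

    n_patients: int = 54
    seed: int = 0

    # covariate marginals
    age_mean: float = 68.5
    age_sd: float = 12.0
    age_range: tuple[float, float] = (32.5, 91.5)
    breslow_median: float = 2.5          # mm; log-normal, mean ~4.1 after spread
    breslow_sigma: float = 1.0
    breslow_range: tuple[float, float] = (0.37, 28.0)
    sod_median: float = 64.0             # mm; log-normal, mean ~79 before truncation
    sod_sigma: float = 0.75
    sod_range: tuple[float, float] = (5.0, 247.0)
    ldh_median: float = 230.0            # U/L
    ldh_sigma: float = 0.4
    ldh_center_scale: dict[str, float] = field(default_factory=lambda: {"UMM": 1.1})
    ly_mean: float = 22.0                # %
    ly_sd: float = 8.0
    ly_range: tuple[float, float] = (2.0, 60.0)
    p_nodular: float = 0.20
    p_cutaneous: float = 0.90
    p_braf: float = 13 / 54
    p_center_a: float = 33 / 54          # fraction recruited at center "HMC"
    centers: tuple[str, str] = ("HMC", "UMM")
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))

    # parameter link
    ln_a_intercept: float = 4.6
    ln_a_slope: float = 5.0              # decrease per unit normalized baseline SOD
    ln_a_sd: float = 0.5
    ln_a_bounds: tuple[float, float] = (math.log(10.0), math.log(1.0e4))
    gamma_slow: float = dynamics.GAMMA_SLOW
    gamma_fast: float = dynamics.GAMMA_FAST
    gamma_logit_intercept: float = -0.6
    gamma_logit_breslow: float = 2.5     # per unit normalized Breslow
    gamma_logit_nodular: float = 1.5

    # observation model
    scan_interval: float = 90.0          # days
    scan_jitter: float = 14.0            # uniform +/- days
    noise_sigma: float = 0.1             # multiplicative log-normal SD
    detection_floor: float = 10.0        # mm per non-nodal lesion
    followup_months_median: float = 9.0
    followup_months_sigma: float = 0.55  # log-normal spread
    followup_months_range: tuple[float, float] = (2.0, 35.0)

    # simulation
    conversion: CellSodConversion = field(default_factory=CellSodConversion)
    rtol: float = 1e-6
    atol: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_nodular", "p_cutaneous", "p_braf", "p_center_a"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be a probability")
        for name, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"missing rate for {name!r} must be a probability")
        for name in ("age_range", "breslow_range", "sod_range", "ly_range",
                     "followup_months_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ConfigError(f"{name} must be an increasing positive range")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.noise_sigma < 0 or self.scan_jitter < 0:
            raise ConfigError("noise and jitter must be nonnegative")


@dataclass
class CohortResult:
    records: list[PatientRecord]
    truth: pd.DataFrame        # patient_id, a_pem, gamma_mel, true_ttp_day, true_interval
    covariates: pd.DataFrame   # observed covariates (with missingness), indexed by id


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    """Truncated normal by inverse-CDF sampling (stable even when the mean
    lies far outside the truncation window)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _trunc_lognormal(rng: np.random.Generator, median: float, sigma: float,
                     lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(_trunc_normal(rng, math.log(median), sigma,
                                math.log(lo), math.log(hi), size))


def _sample_covariates_full(config: CohortConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    center = np.where(rng.random(n) < config.p_center_a,
                      config.centers[0], config.centers[1])
    ldh = _trunc_lognormal(rng, config.ldh_median, config.ldh_sigma,
                           config.ldh_median / 20, config.ldh_median * 20, n)
    scale = np.array([config.ldh_center_scale.get(c, 1.0) for c in center])
    df = pd.DataFrame({
        "center": center,
        "age": _trunc_normal(rng, config.age_mean, config.age_sd,
                             *config.age_range, n),
        "breslow": _trunc_lognormal(rng, config.breslow_median, config.breslow_sigma,
                                    *config.breslow_range, n),
        "ldh": ldh * scale,
        "ly_pct": _trunc_normal(rng, config.ly_mean, config.ly_sd,
                                *config.ly_range, n),
        "baseline_sod": _trunc_lognormal(rng, config.sod_median, config.sod_sigma,
                                         *config.sod_range, n),
        "cutaneous": (rng.random(n) < config.p_cutaneous).astype(float),
        "nodular": (rng.random(n) < config.p_nodular).astype(float),
        "braf_v600": (rng.random(n) < config.p_braf).astype(float),
    }, index=[f"P{i + 1:03d}" for i in range(n)])
    df.index.name = "patient_id"
    return df


def _apply_missingness(df: pd.DataFrame, config: CohortConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    out = df.copy()
    for f, rate in config.missing_rates.items():
        if rate > 0 and f in out:
            mask = rng.random(len(out)) < rate
            out.loc[mask, f] = np.nan
    return out


def sample_covariates(config: CohortConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Observed covariate table (missingness already applied)."""
    rng = rng or np.random.default_rng(config.seed)
    return _apply_missingness(_sample_covariates_full(config, rng), config, rng)


def sample_parameters(covariates: pd.DataFrame, config: CohortConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Hidden personal parameters linked to the covariates.

    Missing Breslow values fall back to the cohort median of the observed
    values for the purpose of the growth-rate link; missing nodular status
    counts as 0.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(covariates)
    sod_lo, sod_hi = config.sod_range
    sod_norm = (covariates["baseline_sod"].to_numpy(float) - sod_lo) / (sod_hi - sod_lo)
    mean_ln_a = config.ln_a_intercept - config.ln_a_slope * sod_norm
    ln_a = np.array([
        _trunc_normal(rng, m, config.ln_a_sd, *config.ln_a_bounds, 1)[0]
        if config.ln_a_sd > 0 else np.clip(m, *config.ln_a_bounds)
        for m in mean_ln_a])

    br = covariates["breslow"].to_numpy(float)
    br = np.where(np.isfinite(br), br, np.nanmedian(br))
    br_lo, br_hi = config.breslow_range
    br_norm = (br - br_lo) / (br_hi - br_lo)
    nod = covariates["nodular"].to_numpy(float)
    nod = np.where(np.isfinite(nod), nod, 0.0)
    logit = (config.gamma_logit_intercept
             + config.gamma_logit_breslow * br_norm
             + config.gamma_logit_nodular * nod)
    p_fast = 1.0 / (1.0 + np.exp(-logit))
    gamma = np.where(rng.random(n) < p_fast, config.gamma_fast, config.gamma_slow)
    return pd.DataFrame({"a_pem": np.exp(ln_a), "gamma_mel": gamma},
                        index=covariates.index)


def _scan_days(config: CohortConfig, followup_end: float,
               rng: np.random.Generator) -> list[float]:
    days = [0.0]
    t = 0.0
    while True:
        jitter = rng.uniform(-config.scan_jitter, config.scan_jitter) \
            if config.scan_jitter > 0 else 0.0
        t += config.scan_interval + jitter
        if t > followup_end:
            break
        days.append(round(t))
    if len(days) == 1:
        # very short follow-up: a single end-of-follow-up assessment keeps
        # the record within the >=1 on-treatment measurement criterion
        days.append(round(followup_end))
    return days


def generate_cohort(config: CohortConfig = CohortConfig()) -> CohortResult:
    """Forward-simulate a full synthetic cohort.

    Returns the observable patient records (covariates with missingness and
    the noisy scan series) plus the hidden ground truth: the personal
    parameters and the TTP interval derived from the noise-free series.
    """
    rng = np.random.default_rng(config.seed)
    full_cov = _sample_covariates_full(config, rng)
    params_df = sample_parameters(full_cov, config, rng)
    observed_cov = _apply_missingness(full_cov, config, rng)

    base = ModelParameters()
    records: list[PatientRecord] = []
    truth_rows = []
    for pid in full_cov.index:
        baseline_sod = float(full_cov.at[pid, "baseline_sod"])
        followup_months = _trunc_lognormal(
            rng, config.followup_months_median, config.followup_months_sigma,
            *config.followup_months_range, 1)[0]
        followup = round(followup_months * DAYS_PER_MONTH)
        days = _scan_days(config, followup, rng)

        personal = base.personalized(a_pem=float(params_df.at[pid, "a_pem"]),
                                     gamma_mel=float(params_df.at[pid, "gamma_mel"]))
        record_stub = PatientRecord(
            patient_id=str(pid), covariates={"baseline_sod": baseline_sod},
            scans=[ScanPoint(0.0, baseline_sod)], followup_end=followup,
            center=str(full_cov.at[pid, "center"]))
        sim = SimulationConfig(t_end=max(days), rtol=config.rtol, atol=config.atol,
                               conversion=config.conversion)
        true_sod = predict_sod(personal, record_stub, config=sim, days=days)

        floor = config.detection_floor * config.conversion.n_lesions
        clean = np.array(true_sod)
        clean[0] = baseline_sod        # exact: day-0 burden is the baseline
        clean[1:] = np.where(clean[1:] < floor, 0.0, clean[1:])
        noisy = clean.copy()
        if config.noise_sigma > 0:
            z = rng.standard_normal(len(days) - 1)
            noisy[1:] = clean[1:] * np.exp(config.noise_sigma * z)
            noisy[1:] = np.where(noisy[1:] < floor, 0.0, noisy[1:])

        true_tl = build_timeline(list(zip(days, clean)), followup)
        cov = {k: float(observed_cov.at[pid, k])
               for k in ("age", "breslow", "ldh", "ly_pct",
                         "cutaneous", "nodular", "braf_v600")}
        cov["baseline_sod"] = baseline_sod
        records.append(PatientRecord(
            patient_id=str(pid), covariates=cov,
            scans=[ScanPoint(d, float(s)) for d, s in zip(days, noisy)],
            followup_end=followup, center=str(full_cov.at[pid, "center"])))
        truth_rows.append({
            "patient_id": str(pid),
            "a_pem": float(params_df.at[pid, "a_pem"]),
            "gamma_mel": float(params_df.at[pid, "gamma_mel"]),
            "true_ttp_day": np.nan if true_tl.ttp_days is None else true_tl.ttp_days,
            "true_interval": true_tl.ttp_interval,
        })

    truth = pd.DataFrame(truth_rows).set_index("patient_id")
    obs = observed_cov.copy()
    obs["baseline_sod"] = full_cov["baseline_sod"]
    return CohortResult(records=records, truth=truth, covariates=obs)


def parameter_grid_cohort(n_patients: int = 54,
                          followup_days: float = 365.0,
                          scan_interval: float = 90.0,
                          a_pem_bounds: tuple[float, float] = (10.0, 1.0e4),
                          gammas: tuple[float, float] = (dynamics.GAMMA_SLOW,
                                                         dynamics.GAMMA_FAST),
                          sod_range: tuple[float, float] = (5.0, 247.0),
                          conversion: CellSodConversion = CellSodConversion(),
                          ) -> CohortResult:
    """Deterministic noise-free cohort spanning the personalization box.

    A designed identifiability experiment rather than a random cohort:
    ``ln(a_pem)`` is laid out on an even grid over its full range, the two
    growth-rate classes alternate, and baseline SODs sweep the clinical
    range log-uniformly.  Every patient is observed noise-free on a regular
    scan grid over a full year, which is the schedule under which the two
    personal parameters are jointly identifiable (short noisy series are
    not -- see the random generator for those conditions).
    """
    ln_lo, ln_hi = math.log(a_pem_bounds[0]), math.log(a_pem_bounds[1])
    ln_a_grid = np.linspace(ln_lo, ln_hi, n_patients)
    sods = np.exp(np.linspace(math.log(sod_range[0]), math.log(sod_range[1]), 7))
    days = [0.0] + list(np.arange(scan_interval, followup_days + 1e-9,
                                  scan_interval))
    base = ModelParameters()
    records, truth_rows = [], []
    for i in range(n_patients):
        a_pem = float(np.exp(ln_a_grid[i]))
        gamma = gammas[i % 2]
        baseline = float(sods[i % len(sods)])
        personal = base.personalized(a_pem=a_pem, gamma_mel=gamma)
        stub = PatientRecord(patient_id=f"G{i + 1:03d}",
                             covariates={"baseline_sod": baseline},
                             scans=[ScanPoint(0.0, baseline)],
                             followup_end=followup_days)
        sim = SimulationConfig(t_end=max(days), conversion=conversion)
        sod = predict_sod(personal, stub, config=sim, days=days)
        records.append(PatientRecord(
            patient_id=f"G{i + 1:03d}",
            covariates={"baseline_sod": baseline},
            scans=[ScanPoint(d, float(s)) for d, s in zip(days, sod)],
            followup_end=followup_days))
        tl = build_timeline(list(zip(days, sod)), followup_days)
        truth_rows.append({"patient_id": f"G{i + 1:03d}", "a_pem": a_pem,
                           "gamma_mel": gamma,
                           "true_ttp_day": np.nan if tl.ttp_days is None else tl.ttp_days,
                           "true_interval": tl.ttp_interval})
    truth = pd.DataFrame(truth_rows).set_index("patient_id")
    cov = pd.DataFrame({"baseline_sod": [r.baseline_sod for r in records]},
                       index=truth.index)
    return CohortResult(records=records, truth=truth, covariates=cov)
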