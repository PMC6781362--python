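"""End-to-end pipeline orchestration and all external file formats.

Stages
------
* synth    -- generate a synthetic cohort and write ``patients.csv`` /
              ``scans.csv`` / ``truth.csv``;
* fit      -- per-patient calibration; writes ``fitted_params.csv`` and
              pooled fit metrics (R^2, fit-vs-observed interval confusion);
* train    -- covariate screening tables and leave-one-out predictions of
              the personal parameters;
* predict  -- pretreatment prediction: LOO-personalized parameters,
              simulation on a fixed assessment grid (default every 90 days
              up to min(365 d, follow-up end)), RECIST classification and
              TTP-interval scoring against the clinical series;
* pipeline -- all of the above in sequence, with a reproducibility
              manifest.

File formats (all plain CSV/JSON/YAML):
``patients.csv``: patient_id, center, age_years, breslow_mm, ldh, ly_pct,
cutaneous, nodular, braf_v600, followup_end_day (empty cell = missing,
binaries 0/1).  ``scans.csv``: patient_id, day, sod_mm with day 0 =
treatment start and exactly one baseline row (day <= 0) per patient.
``truth.csv`` (synthetic cohorts only): patient_id, a_pem, gamma_mel,
true_ttp_day, true_interval.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, personalization
from .calibration import FitBounds, FittedPatient, fit_cohort, predict_sod
from .cohort import CohortConfig, generate_cohort
from .dynamics import CellSodConversion, ModelParameters, SimulationConfig
from .errors import ConfigError, InputError, ParseError, UndefinedStatisticError
from .evaluation import (confusion_table, multidim_kappa, outcome_category,
                         outcome_tally, r_squared, ttp_agreement)
from .records import PatientRecord, ScanPoint
from .response import build_timeline, observed_timeline

__all__ = [
    "RunConfig", "read_cohort", "write_cohort_csvs", "covariate_frame",
    "run_fit_stage", "run_train_stage", "run_predict_stage", "run_pipeline",
]

PATIENT_COLUMNS = ["patient_id", "center", "age_years", "breslow_mm", "ldh",
                   "ly_pct", "cutaneous", "nodular", "braf_v600",
                   "followup_end_day"]
SCAN_COLUMNS = ["patient_id", "day", "sod_mm"]

_COV_RENAME = {"age_years": "age", "breslow_mm": "breslow"}


@dataclass
class RunConfig:
    """Run configuration; serializable to/from YAML."""

    patients_csv: str | None = None
    scans_csv: str | None = None
    truth_csv: str | None = None
    outdir: str = "out"
    seed: int = 0
    # synthetic-cohort stage
    n_patients: int = 54
    noise_sigma: float = 0.1
    # unit conversion and solver
    density: float = 15.0
    n_lesions: int = 1
    rtol: float = 1e-6
    atol: float = 1.0
    # personalization ranges
    a_pem_bounds: tuple[float, float] = (10.0, 1.0e4)
    gamma_candidates: tuple[float, ...] = (0.003269, 0.005)
    initial_guess: str = "log-mid"
    # response evaluation
    pd_abs_floor: float | None = 5.0
    assessment_interval: float = 90.0
    horizon: float = 365.0
    # personalization features
    knn_features: tuple[str, ...] = ("baseline_sod",)
    tree_features: tuple[str, ...] = ("breslow", "nodular")
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.assessment_interval <= 0 or self.horizon <= 0:
            raise ConfigError("assessment interval and horizon must be positive")
        self.fit_bounds()  # validates ranges
        CellSodConversion(self.density, self.n_lesions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ParseError(f"invalid YAML in {path}: {exc}") from exc
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("a_pem_bounds", "gamma_candidates", "knn_features",
                    "tree_features"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("a_pem_bounds", "gamma_candidates", "knn_features",
                    "tree_features"):
            d[key] = list(d[key])
        return d

    def fit_bounds(self) -> FitBounds:
        return FitBounds(a_pem_bounds=tuple(self.a_pem_bounds),
                         gamma_candidates=tuple(self.gamma_candidates),
                         initial_guess=self.initial_guess)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            t_end=max(self.horizon, 1.0), rtol=self.rtol, atol=self.atol,
            conversion=CellSodConversion(self.density, self.n_lesions))

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_patients=self.n_patients, seed=self.seed,
            noise_sigma=self.noise_sigma,
            conversion=CellSodConversion(self.density, self.n_lesions),
            rtol=self.rtol, atol=self.atol)


# ---------------------------------------------------------------------------
# CSV I/O


def write_cohort_csvs(records: Sequence[PatientRecord], outdir: str | Path,
                      truth: pd.DataFrame | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prows, srows = [], []
    for r in records:
        prows.append({
            "patient_id": r.patient_id,
            "center": r.center,
            "age_years": r.covariate("age"),
            "breslow_mm": r.covariate("breslow"),
            "ldh": r.covariate("ldh"),
            "ly_pct": r.covariate("ly_pct"),
            "cutaneous": r.covariate("cutaneous"),
            "nodular": r.covariate("nodular"),
            "braf_v600": r.covariate("braf_v600"),
            "followup_end_day": r.followup_end,
        })
        for p in r.scans:
            srows.append({"patient_id": r.patient_id, "day": p.day, "sod_mm": p.sod})
    paths = {
        "patients": outdir / "patients.csv",
        "scans": outdir / "scans.csv",
    }
    # %.17g round-trips doubles exactly through text
    pd.DataFrame(prows, columns=PATIENT_COLUMNS).to_csv(
        paths["patients"], index=False, float_format="%.17g")
    pd.DataFrame(srows, columns=SCAN_COLUMNS).to_csv(
        paths["scans"], index=False, float_format="%.17g")
    if truth is not None:
        paths["truth"] = outdir / "truth.csv"
        truth.to_csv(paths["truth"])
    return paths


def read_cohort(patients_csv: str | Path, scans_csv: str | Path,
                ) -> list[PatientRecord]:
    try:
        patients = pd.read_csv(patients_csv, float_precision="round_trip")
        scans = pd.read_csv(scans_csv, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"cannot read cohort CSVs: {exc}") from exc
    for cols, df, name in ((PATIENT_COLUMNS, patients, "patients"),
                           (SCAN_COLUMNS, scans, "scans")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ParseError(f"{name} CSV is missing columns {sorted(missing)}")
    by_patient = {pid: g for pid, g in scans.groupby("patient_id")}
    records = []
    for i, row in patients.iterrows():
        pid = str(row["patient_id"])
        if pid not in by_patient:
            raise ParseError(f"patients row {i + 2}: no scans for patient {pid!r}")
        g = by_patient[pid]
        cov = {"age": row["age_years"], "breslow": row["breslow_mm"],
               "ldh": row["ldh"], "ly_pct": row["ly_pct"],
               "cutaneous": row["cutaneous"], "nodular": row["nodular"],
               "braf_v600": row["braf_v600"]}
        cov = {k: (float(v) if pd.notna(v) else float("nan")) for k, v in cov.items()}
        try:
            scans_list = [ScanPoint(float(s["day"]), float(s["sod_mm"]))
                          for _, s in g.iterrows()]
            rec = PatientRecord(patient_id=pid, covariates=cov, scans=scans_list,
                                followup_end=float(row["followup_end_day"]),
                                center=str(row["center"]) if pd.notna(row["center"]) else "")
            rec.covariates["baseline_sod"] = rec.baseline_sod
        except (InputError, ValueError) as exc:
            raise ParseError(f"patients row {i + 2} ({pid}): {exc}") from exc
        records.append(rec)
    if not records:
        raise ParseError("empty patient table")
    return records


def read_truth(truth_csv: str | Path) -> pd.DataFrame:
    try:
        truth = pd.read_csv(truth_csv).set_index("patient_id")
    except (OSError, KeyError, pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"cannot read truth CSV: {exc}") from exc
    return truth


def covariate_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"center": r.center}
        for f in ("age", "breslow", "ldh", "ly_pct", "cutaneous", "nodular",
                  "braf_v600"):
            row[f] = r.covariate(f)
        row["baseline_sod"] = r.baseline_sod
        rows.append(row)
    df = pd.DataFrame(rows, index=[r.patient_id for r in records])
    df.index.name = "patient_id"
    return df


def _kappa_or_none(table) -> dict:
    try:
        return multidim_kappa(table).to_dict()
    except UndefinedStatisticError as exc:
        return {"kappa": None, "note": str(exc)}


# ---------------------------------------------------------------------------
# stages


def run_fit_stage(records: Sequence[PatientRecord], config: RunConfig,
                  outdir: str | Path | None = None,
                  ) -> tuple[list[FittedPatient], pd.DataFrame, dict]:
    """Calibrate every patient; return fits, a tidy table and pooled metrics."""
    fitted, diag = fit_cohort(records, bounds=config.fit_bounds(),
                              config=config.sim_config())
    by_id = {r.patient_id: r for r in records}
    rows = []
    for fp in fitted:
        obs_tl = observed_timeline(by_id[fp.patient_id],
                                   pd_abs_floor=config.pd_abs_floor)
        rows.append({
            "patient_id": fp.patient_id,
            "ln_a_pem": fp.ln_a_pem,
            "a_pem": fp.a_pem,
            "gamma_mel": fp.gamma_mel,
            "sse": fp.sse,
            "fit_ttp_day": np.nan if fp.timeline.ttp_days is None else fp.timeline.ttp_days,
            "fit_interval": fp.timeline.ttp_interval,
            "obs_ttp_day": np.nan if obs_tl.ttp_days is None else obs_tl.ttp_days,
            "obs_interval": obs_tl.ttp_interval,
            "converged": fp.converged,
        })
    table = pd.DataFrame(rows).set_index("patient_id")
    metrics = {"r2_linear": diag.get("r2_linear"), "r2_log": diag.get("r2_log"),
               "n_fitted": diag["n_fitted"], "errors": diag["errors"]}
    if len(table) >= 1:
        conf = confusion_table(table["fit_interval"], table["obs_interval"])
        metrics["fit_vs_observed"] = {"confusion": conf.to_dict(),
                                      "kappa": _kappa_or_none(conf)}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "fitted_params.csv")
        (outdir / "fit_metrics.json").write_text(json.dumps(metrics, indent=2))
    return fitted, table, metrics


def run_train_stage(records: Sequence[PatientRecord],
                    fitted_table: pd.DataFrame, config: RunConfig,
                    outdir: str | Path | None = None) -> dict:
    """Covariate screening plus LOO validation of the personalization maps."""
    cov = covariate_frame(records).loc[fitted_table.index]
    screens = personalization.screen_covariates(
        cov, fitted_table["ln_a_pem"], fitted_table["gamma_mel"])
    loo = personalization.loo_cross_validate(
        cov, fitted_table["ln_a_pem"], fitted_table["gamma_mel"],
        knn_features=tuple(config.knn_features),
        tree_features=tuple(config.tree_features))
    out = {"screen": {k: v.to_dict(orient="records") for k, v in screens.items()}}
    try:
        out["loo_r2_ln_a_pem"] = r_squared(fitted_table["ln_a_pem"], loo["ln_a_pem"])
    except UndefinedStatisticError:
        out["loo_r2_ln_a_pem"] = None
    gamma_conf = confusion_table(
        1 + (loo["gamma_mel"] == max(config.gamma_candidates)).astype(int),
        1 + (fitted_table["gamma_mel"] == max(config.gamma_candidates)).astype(int),
        k=2)
    out["gamma_tree"] = {"confusion": gamma_conf.to_dict(),
                         "kappa": _kappa_or_none(gamma_conf)}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        loo.to_csv(outdir / "loo_predictions.csv")
        (outdir / "train_metrics.json").write_text(json.dumps(out, indent=2))
    return out


def _assessment_grid(config: RunConfig, followup_end: float) -> np.ndarray:
    """Fixed prediction grid: every `assessment_interval` days up to
    min(horizon, follow-up end); a truncated single assessment if the
    patient is censored before the first scheduled one."""
    end = min(config.horizon, followup_end)
    grid = np.arange(config.assessment_interval, end + 1e-9,
                     config.assessment_interval)
    if grid.size == 0:
        grid = np.array([end])
    return grid


def run_predict_stage(records: Sequence[PatientRecord],
                      fitted_table: pd.DataFrame, config: RunConfig,
                      truth: pd.DataFrame | None = None, oracle: bool = False,
                      outdir: str | Path | None = None,
                      ) -> tuple[pd.DataFrame, dict]:
    """Pretreatment TTP prediction for every patient.

    With ``oracle=True`` the hidden true parameters (from ``truth``) drive
    the personal simulations instead of the LOO-personalized estimates --
    an upper bound on what the covariate mapping can achieve.
    """
    by_id = {r.patient_id: r for r in records}
    ids = list(fitted_table.index)
    if oracle:
        if truth is None:
            raise ConfigError("oracle prediction requires a ground-truth table")
        pred_params = pd.DataFrame(
            {"ln_a_pem": np.log(truth.loc[ids, "a_pem"].to_numpy(float)),
             "gamma_mel": truth.loc[ids, "gamma_mel"].to_numpy(float)}, index=ids)
    else:
        cov = covariate_frame(records).loc[ids]
        pred_params = personalization.loo_cross_validate(
            cov, fitted_table["ln_a_pem"], fitted_table["gamma_mel"],
            knn_features=tuple(config.knn_features),
            tree_features=tuple(config.tree_features))

    base = ModelParameters()
    sim = config.sim_config()
    rows = []
    sod_obs_pool: list[float] = []
    sod_pred_pool: list[float] = []
    for pid in ids:
        rec = by_id[pid]
        params = base.personalized(
            a_pem=math.exp(float(pred_params.at[pid, "ln_a_pem"])),
            gamma_mel=float(pred_params.at[pid, "gamma_mel"]))
        grid = _assessment_grid(config, rec.followup_end)
        scan_days = np.array([p.day for p in rec.post_baseline])
        all_days = np.union1d(grid, np.clip(scan_days, 0.0, None))
        pred = predict_sod(params, rec, config=sim, days=all_days)
        pred_at = dict(zip(all_days, pred))

        tl = build_timeline(
            [(0.0, rec.baseline_sod)] + [(d, pred_at[d]) for d in grid],
            min(config.horizon, rec.followup_end),
            pd_abs_floor=config.pd_abs_floor)
        obs_tl = observed_timeline(rec, pd_abs_floor=config.pd_abs_floor)
        for p in rec.post_baseline:
            sod_obs_pool.append(p.sod)
            sod_pred_pool.append(pred_at[max(p.day, 0.0)])
        row = {
            "patient_id": pid,
            "pred_ln_a_pem": float(pred_params.at[pid, "ln_a_pem"]),
            "pred_gamma_mel": float(pred_params.at[pid, "gamma_mel"]),
            "pred_ttp_day": np.nan if tl.ttp_days is None else tl.ttp_days,
            "pred_interval": tl.ttp_interval,
            "obs_ttp_day": np.nan if obs_tl.ttp_days is None else obs_tl.ttp_days,
            "obs_interval": obs_tl.ttp_interval,
            "outcome": outcome_category(obs_tl.ttp_interval, tl.ttp_interval),
        }
        if truth is not None and pid in truth.index:
            row["true_interval"] = int(truth.at[pid, "true_interval"])
        rows.append(row)

    table = pd.DataFrame(rows).set_index("patient_id")
    conf = confusion_table(table["pred_interval"], table["obs_interval"])
    metrics: dict = {
        "mode": "oracle" if oracle else "loo",
        "pred_vs_observed": {"confusion": conf.to_dict(),
                             "kappa": _kappa_or_none(conf)},
        "outcomes": outcome_tally(table["obs_interval"], table["pred_interval"]),
    }
    if "true_interval" in table:
        conf_t = confusion_table(table["pred_interval"], table["true_interval"])
        metrics["pred_vs_truth"] = {"confusion": conf_t.to_dict(),
                                    "kappa": _kappa_or_none(conf_t)}
    try:
        metrics["ttp_r2_double_progressors"] = ttp_agreement(
            [None if np.isnan(v) else v for v in table["pred_ttp_day"]],
            [None if np.isnan(v) else v for v in table["obs_ttp_day"]])
    except UndefinedStatisticError as exc:
        metrics["ttp_r2_double_progressors"] = None
    if len(sod_obs_pool) >= 2:
        metrics["sod_r2_linear"] = r_squared(sod_obs_pool, sod_pred_pool)
        try:
            metrics["sod_r2_log"] = r_squared(sod_obs_pool, sod_pred_pool,
                                              log_scale=True)
        except UndefinedStatisticError:
            metrics["sod_r2_log"] = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = "oracle_predictions" if oracle else "predictions"
        table.to_csv(outdir / f"{stem}.csv")
        (outdir / f"{stem.replace('predictions', 'evaluation')}.json").write_text(
            json.dumps(metrics, indent=2))
    return table, metrics


def _manifest(config: RunConfig) -> dict:
    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    return {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "pembropred": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Synth (if no input CSVs) -> fit -> train -> predict, with manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.patients_csv and config.scans_csv:
        records = read_cohort(config.patients_csv, config.scans_csv)
        if config.truth_csv:
            truth = read_truth(config.truth_csv)
    else:
        result = generate_cohort(config.cohort_config())
        records = result.records
        truth = result.truth
        write_cohort_csvs(records, outdir, truth=truth)

    fitted, fit_table, fit_metrics = run_fit_stage(records, config, outdir=outdir)
    train_metrics = run_train_stage(records, fit_table, config, outdir=outdir)
    pred_table, pred_metrics = run_predict_stage(records, fit_table, config,
                                                 truth=truth, outdir=outdir)
    summary = {"fit": fit_metrics, "train": train_metrics, "predict": pred_metrics}
    if truth is not None:
        _, oracle_metrics = run_predict_stage(records, fit_table, config,
                                              truth=truth, oracle=True,
                                              outdir=outdir)
        summary["oracle"] = oracle_metrics
    (outdir / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
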