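"""Mapping pretreatment covariates to the personal model parameters.

The learning layer estimates the two personal parameters from covariates
available before treatment:

* ``ln(a_pem)`` by unweighted k-nearest-neighbor regression (k = floor of
  the square root of the training-set size) over min-max-normalized
  features -- by default the baseline SOD alone, which is the covariate
  most strongly (negatively) correlated with ``ln(a_pem)``;
* ``gamma_mel`` by a shallow classification tree over Breslow thickness
  and nodular-melanoma status.

Covariates are min-max normalized per recruiting center (Eq.-style
``(x - min)/(max - min)``) to absorb between-center calibration
differences; a query from an unseen center falls back to pooled bounds.
Missing continuous values are imputed with the training-set mean, missing
binary values with 0.  Everything is validated by leave-one-out
cross-validation: the bounds, imputation values, neighbor store and tree
are all re-learned with the held-out patient removed.

Screening utilities (Pearson correlation, ROC AUC, maximal
threshold-kappa) reproduce the covariate-selection step on any cohort.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .errors import DomainError, InputError, UndefinedStatisticError
from .evaluation import ConfusionTable, multidim_kappa
from .records import BINARY_COVARIATES, CONTINUOUS_COVARIATES

__all__ = [
    "normalize",
    "NormalizationBounds",
    "impute",
    "knn_rule_k",
    "knn_estimate",
    "train_gamma_tree",
    "classify_gamma",
    "PersonalizationModel",
    "loo_cross_validate",
    "pearson_screen",
    "roc_auc",
    "max_threshold_kappa",
    "screen_covariates",
]

DEFAULT_KNN_FEATURES = ("baseline_sod",)
DEFAULT_TREE_FEATURES = ("breslow", "nodular")


def normalize(x: float | np.ndarray, x_min: float, x_max: float) -> float | np.ndarray:
    """Min-max normalization ``(x - min)/(max - min)``; not clipped."""
    if x_max <= x_min:
        raise DomainError("degenerate normalization bounds: max <= min")
    return (x - x_min) / (x_max - x_min)


@dataclass
class NormalizationBounds:
    """Per-center (and pooled) min-max bounds learned from training data."""

    per_center: dict[str, dict[str, tuple[float, float]]]
    pooled: dict[str, tuple[float, float]]

    @classmethod
    def fit(cls, df: pd.DataFrame, features: tuple[str, ...]) -> "NormalizationBounds":
        continuous = [f for f in features if f in CONTINUOUS_COVARIATES]
        pooled = {}
        for f in continuous:
            vals = df[f].dropna()
            if vals.empty:
                raise InputError(f"covariate {f!r} missing in all patients")
            # a constant feature keeps degenerate bounds; transform() maps it
            # to 0 since it carries no between-patient information
            pooled[f] = (float(vals.min()), float(vals.max()))
        per_center: dict[str, dict[str, tuple[float, float]]] = {}
        centers = df["center"] if "center" in df else pd.Series([""] * len(df), index=df.index)
        for center, sub in df.groupby(centers):
            entry = {}
            for f in continuous:
                vals = sub[f].dropna()
                lo, hi = (float(vals.min()), float(vals.max())) if not vals.empty else pooled[f]
                # single-patient centers give degenerate bounds: fall back to pooled
                entry[f] = (lo, hi) if hi > lo else pooled[f]
            per_center[str(center)] = entry
        return cls(per_center=per_center, pooled=pooled)

    def bounds_for(self, feature: str, center: str) -> tuple[float, float]:
        entry = self.per_center.get(str(center))
        if entry is not None and feature in entry:
            return entry[feature]
        return self.pooled[feature]

    def transform(self, df: pd.DataFrame, features: tuple[str, ...]) -> pd.DataFrame:
        """Normalize the continuous members of ``features``; binaries pass through."""
        out = df[list(features)].astype(float).copy()
        centers = df["center"] if "center" in df else pd.Series([""] * len(df), index=df.index)
        for f in features:
            if f not in CONTINUOUS_COVARIATES:
                continue
            lo_hi = centers.map(lambda c, f=f: self.bounds_for(f, c))
            lo = lo_hi.map(lambda b: b[0]).astype(float)
            hi = lo_hi.map(lambda b: b[1]).astype(float)
            denom = hi - lo
            scaled = (out[f] - lo) / denom.where(denom > 0, 1.0)
            out[f] = scaled.where(denom > 0, 0.0)
        return out


def impute(df: pd.DataFrame, values: dict[str, float] | None = None,
           ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fill missing covariates: continuous -> training mean, binary -> 0.

    When ``values`` is given (a previously learned imputation map) it is
    applied as-is; otherwise the map is learned from ``df``.
    """
    out = df.copy()
    if values is None:
        values = {}
        for f in CONTINUOUS_COVARIATES:
            if f in out:
                observed = out[f].dropna()
                if observed.empty:
                    raise InputError(f"covariate {f!r} missing in all patients")
                values[f] = float(observed.mean())
        for f in BINARY_COVARIATES:
            if f in out:
                values[f] = 0.0
    for f, v in values.items():
        if f in out:
            out[f] = out[f].fillna(v)
    return out, values


def knn_rule_k(n: int) -> int:
    """Neighbor count: integer part of sqrt(n), clamped to >= 1."""
    if n < 1:
        raise DomainError("cohort size must be >= 1")
    return max(1, int(math.isqrt(int(n))))


def knn_estimate(x_train: np.ndarray, y_train: np.ndarray,
                 query: np.ndarray, k: int) -> float:
    """Unweighted mean of the k nearest training responses.

    Euclidean distance over the feature columns; distance ties broken by
    training-set order (stable sort).
    """
    x = np.atleast_2d(np.asarray(x_train, float))
    y = np.asarray(y_train, float)
    if x.shape[0] == 0:
        raise InputError("empty k-NN training store")
    if not 1 <= k <= x.shape[0]:
        raise DomainError("k must be in [1, n_train]")
    q = np.asarray(query, float).reshape(1, -1)
    d = np.sqrt(((x - q) ** 2).sum(axis=1))
    idx = np.argsort(d, kind="stable")[:k]
    return float(y[idx].mean())


def train_gamma_tree(features: pd.DataFrame, labels: np.ndarray,
                     max_depth: int = 2, min_leaf: int = 3) -> DecisionTreeClassifier:
    """Shallow axis-aligned classification tree for the growth-rate class.

    Depth <= 2, impurity-minimizing (Gini) splits with at least
    ``min_leaf`` patients per leaf; leaves labeled by majority.  A
    single-class training set yields a degenerate one-leaf tree (warned).
    """
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class gamma labels: degenerate one-leaf tree",
                      stacklevel=2)
    min_leaf = max(1, min(min_leaf, len(y)))
    tree = DecisionTreeClassifier(max_depth=max_depth, min_samples_leaf=min_leaf,
                                  criterion="gini", random_state=0)
    # classifier wants discrete labels: encode the gamma values as strings
    tree.fit(np.asarray(features, float), np.array([f"{float(v):.17g}" for v in y]))
    return tree


def classify_gamma(tree: DecisionTreeClassifier, features: pd.DataFrame | np.ndarray,
                   ) -> np.ndarray:
    """Leaf label (a gamma value) for each feature row."""
    labels = tree.predict(np.atleast_2d(np.asarray(features, float)))
    return np.array([float(v) for v in labels])


@dataclass
class PersonalizationModel:
    """Trained covariate -> (ln a_pem, gamma_mel) mapping."""

    bounds: NormalizationBounds
    imputation: dict[str, float]
    knn_features: tuple[str, ...]
    tree_features: tuple[str, ...]
    x_train: np.ndarray
    y_train: np.ndarray
    k: int
    tree: DecisionTreeClassifier

    @classmethod
    def fit(cls, cov_df: pd.DataFrame, ln_a_pem: pd.Series | np.ndarray,
            gamma: pd.Series | np.ndarray,
            knn_features: tuple[str, ...] = DEFAULT_KNN_FEATURES,
            tree_features: tuple[str, ...] = DEFAULT_TREE_FEATURES,
            k: int | None = None) -> "PersonalizationModel":
        n = len(cov_df)
        if n < 1:
            raise InputError("empty training cohort")
        if k is None:
            k = knn_rule_k(n)
        if not 1 <= k <= n:
            raise DomainError("k must be in [1, n_train]")
        needed = sorted(set(knn_features) | set(tree_features))
        cols = needed + (["center"] if "center" in cov_df else [])
        completed, imp = impute(cov_df[cols])
        bounds = NormalizationBounds.fit(completed, tuple(needed))
        x = bounds.transform(completed, knn_features).to_numpy(float)
        tree = train_gamma_tree(completed[list(tree_features)], np.asarray(gamma, float))
        return cls(bounds=bounds, imputation=imp, knn_features=tuple(knn_features),
                   tree_features=tuple(tree_features), x_train=x,
                   y_train=np.asarray(ln_a_pem, float), k=k, tree=tree)

    def _prepare(self, cov_df: pd.DataFrame) -> pd.DataFrame:
        needed = sorted(set(self.knn_features) | set(self.tree_features))
        cols = needed + (["center"] if "center" in cov_df else [])
        completed, _ = impute(cov_df[cols], values=self.imputation)
        return completed

    def predict_ln_a_pem(self, cov_df: pd.DataFrame) -> np.ndarray:
        completed = self._prepare(cov_df)
        q = self.bounds.transform(completed, self.knn_features).to_numpy(float)
        return np.array([knn_estimate(self.x_train, self.y_train, row, self.k)
                         for row in q])

    def predict_gamma(self, cov_df: pd.DataFrame) -> np.ndarray:
        completed = self._prepare(cov_df)
        return classify_gamma(self.tree, completed[list(self.tree_features)])

    def predict(self, cov_df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {"ln_a_pem": self.predict_ln_a_pem(cov_df),
             "gamma_mel": self.predict_gamma(cov_df)},
            index=cov_df.index)


def loo_cross_validate(cov_df: pd.DataFrame, ln_a_pem: pd.Series,
                       gamma: pd.Series,
                       knn_features: tuple[str, ...] = DEFAULT_KNN_FEATURES,
                       tree_features: tuple[str, ...] = DEFAULT_TREE_FEATURES,
                       ) -> pd.DataFrame:
    """Leave-one-out predictions of (ln a_pem, gamma) for every patient.

    For each held-out patient the full learning stack (imputation values,
    normalization bounds, neighbor store with k = floor(sqrt(n-1)), and
    the gamma tree) is re-learned on the remaining n-1 patients.
    """
    n = len(cov_df)
    if n < 3:
        raise InputError("LOO cross-validation needs >= 3 patients")
    preds = []
    for idx in cov_df.index:
        train = cov_df.drop(index=idx)
        model = PersonalizationModel.fit(
            train, ln_a_pem.drop(index=idx), gamma.drop(index=idx),
            knn_features=knn_features, tree_features=tree_features,
            k=knn_rule_k(n - 1))
        row = model.predict(cov_df.loc[[idx]])
        preds.append(row)
    return pd.concat(preds)


# ---------------------------------------------------------------------------
# covariate screening


def pearson_screen(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-test p-value (NaN pairs dropped)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise UndefinedStatisticError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined under zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (probability of correct ordering; ties count 1/2)."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise UndefinedStatisticError("ROC AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def _binary_kappa(pred: np.ndarray, labels: np.ndarray) -> float:
    counts = np.array([[np.sum(pred & labels), np.sum(pred & ~labels)],
                       [np.sum(~pred & labels), np.sum(~pred & ~labels)]], dtype=int)
    try:
        return multidim_kappa(ConfusionTable(counts)).kappa
    except UndefinedStatisticError:
        return 0.0


def max_threshold_kappa(scores, labels) -> float:
    """Maximal two-class Cohen's kappa over all score thresholds.

    Thresholds are the midpoints between consecutive sorted unique scores
    plus one below and one above the score range; the positive call is
    ``score >= threshold``.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int).astype(bool)
    if len(np.unique(labels)) < 2:
        raise UndefinedStatisticError("kappa screening requires both classes")
    uniq = np.unique(scores)
    thresholds = np.concatenate(([uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2.0,
                                 [uniq[-1] + 1.0]))
    return max(_binary_kappa(scores >= thr, labels) for thr in thresholds)


def screen_covariates(cov_df: pd.DataFrame, ln_a_pem: pd.Series,
                      gamma: pd.Series) -> dict[str, pd.DataFrame]:
    """Covariate screening tables for both personal parameters.

    Continuous covariates are screened against ``ln(a_pem)`` by Pearson
    correlation and against the gamma class by ROC AUC / maximal
    threshold-kappa; binary covariates against the gamma class by plain
    two-class kappa.
    """
    gamma_cls = (np.asarray(gamma, float) == np.max(np.asarray(gamma, float))).astype(int)
    rows_a, rows_g, rows_b = [], [], []
    for f in CONTINUOUS_COVARIATES:
        if f not in cov_df:
            continue
        vals = cov_df[f].to_numpy(float)
        try:
            r, p = pearson_screen(vals, np.asarray(ln_a_pem, float))
            rows_a.append({"covariate": f, "pearson_r": r, "p_value": p})
        except UndefinedStatisticError:
            pass
        keep = np.isfinite(vals)
        if keep.sum() >= 3 and len(np.unique(gamma_cls[keep])) == 2:
            auc = roc_auc(vals[keep], gamma_cls[keep])
            auc = max(auc, 1.0 - auc)    # orientation-free separability
            rows_g.append({"covariate": f, "roc_auc": auc,
                           "max_kappa": max(max_threshold_kappa(vals[keep], gamma_cls[keep]),
                                            max_threshold_kappa(-vals[keep], gamma_cls[keep]))})
    for f in BINARY_COVARIATES:
        if f not in cov_df:
            continue
        vals = cov_df[f].to_numpy(float)
        keep = np.isfinite(vals)
        if keep.sum() >= 3 and len(np.unique(gamma_cls[keep])) == 2:
            pred = vals[keep].astype(bool)
            kap = _binary_kappa(pred, gamma_cls[keep].astype(bool))
            rows_b.append({"covariate": f, "kappa": abs(kap)})
    return {
        "ln_a_pem": pd.DataFrame(rows_a),
        "gamma_continuous": pd.DataFrame(rows_g),
        "gamma_binary": pd.DataFrame(rows_b),
    }
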