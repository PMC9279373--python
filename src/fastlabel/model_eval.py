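"""Classifiers of nonfasting status and the evaluation battery.

Two model families predict the probability that a glucose draw is
nonfasting: maximum-likelihood logistic regression (with odds-ratio export)
and a gradient-boosted tree ensemble with fixed hyperparameters (tree depth
8, learning rate 0.1, gamma 0.5, minimum child weight 7, 300 estimators).

Evaluation utilities: an exact Mann–Whitney AUROC, confusion metrics at a
0.5 operating point, a paired-bootstrap AUROC comparison (2000 replicates
by default), stratified 5-fold cross-validation and calibration tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "MetricsReport",
    "FittedModel",
    "design_matrix",
    "fit_model",
    "compute_auroc",
    "confusion_metrics",
    "bootstrap_auroc_difference",
    "crossvalidate",
    "calibration",
]

_TIMING_REF = "07:00-12:59"
_DIVISION_REF = "health_management_center"


@dataclass
class ModelConfig:
    """Model family, hyperparameters and feature set."""

    model_kind: str = "logistic"  # {"logistic", "gbt"}
    gbt_hyperparams: dict = field(
        default_factory=lambda: {
            "max_depth": 8,
            "learning_rate": 0.1,
            "gamma": 0.5,
            "min_child_weight": 7,
            "n_estimators": 300,
        }
    )
    feature_set: str = "model2_14"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in ("logistic", "gbt"):
            raise ValueError("model_kind must be 'logistic' or 'gbt'")
        for k, v in self.gbt_hyperparams.items():
            if not v > 0:
                raise ValueError(f"gbt hyperparameter {k!r} must be positive")


@dataclass
class MetricsReport:
    """Confusion metrics and AUROC (with optional bootstrap CI)."""

    sensitivity: float
    specificity: float
    precision: float | None
    f1: float | None
    accuracy: float
    auroc: float
    auroc_ci: tuple[float, float] | None
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "auroc": self.auroc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        if self.auroc_ci is not None:
            d["auroc_ci_lower"], d["auroc_ci_upper"] = self.auroc_ci
        return d


def design_matrix(features: pd.DataFrame, feature_cols=None) -> pd.DataFrame:
    """Reference-coded numeric design matrix (no intercept column).

    Timing is coded against the morning bin and division against the
    health-management-center reference, so exponentiated logistic
    coefficients read as the usual odds-ratio table.
    """
    from fastlabel.cohort_features import MODEL2_FEATURES

    cols = list(feature_cols) if feature_cols is not None else list(MODEL2_FEATURES)
    X = features[cols].copy()
    if "timing_bin" in X.columns:
        d = pd.get_dummies(X["timing_bin"], prefix="timing")
        d = d.drop(columns=[f"timing_{_TIMING_REF}"], errors="ignore")
        X = pd.concat([X.drop(columns=["timing_bin"]), d], axis=1)
    if "division" in X.columns:
        d = pd.get_dummies(X["division"], prefix="division")
        d = d.drop(columns=[f"division_{_DIVISION_REF}"], errors="ignore")
        X = pd.concat([X.drop(columns=["division"]), d], axis=1)
    return X.astype(float)


class FittedModel:
    """A fitted scorer: feature rows → probability of nonfasting."""

    def __init__(self, kind, predictor, columns, config, n_dropped=0, result=None,
                 feature_cols=None):
        self.kind = kind
        self._predictor = predictor
        self.columns = list(columns)
        self.feature_cols = list(feature_cols) if feature_cols is not None else None
        self.config = config
        self.n_dropped_rows = n_dropped
        self._result = result  # statsmodels result for logistic fits

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = design_matrix(features, self.feature_cols)
        X = X.reindex(columns=self.columns, fill_value=0.0)
        if self.kind == "logistic":
            return np.asarray(
                self._result.predict(sm.add_constant(X, has_constant="add"))
            )
        return self._predictor.predict_proba(X.to_numpy())[:, 1]

    def odds_ratios(self) -> pd.DataFrame:
        """Odds ratios with 95 % CIs (logistic fits only)."""
        if self._result is None:
            raise ValueError("odds ratios are defined for logistic fits only")
        params = self._result.params
        ci = self._result.conf_int()
        out = pd.DataFrame(
            {
                "OR": np.exp(params),
                "ci_lower": np.exp(ci[0]),
                "ci_upper": np.exp(ci[1]),
                "p_value": self._result.pvalues,
            }
        )
        return out

    def coefficients(self) -> pd.Series:
        if self._result is None:
            raise ValueError("coefficients are exported for logistic fits only")
        return self._result.params

    def standard_errors(self) -> pd.Series:
        if self._result is None:
            raise ValueError("standard errors are exported for logistic fits only")
        return self._result.bse

    def feature_importance(self) -> pd.Series:
        """Native gain-based feature importance (boosted model only)."""
        if self.kind != "gbt":
            raise ValueError("feature importance is exported for the boosted model")
        booster = self._predictor.get_booster()
        gain = booster.get_score(importance_type="gain")
        named = {self.columns[int(k[1:])] if k.startswith("f") else k: v
                 for k, v in gain.items()}
        return pd.Series(named).sort_values(ascending=False)


def fit_model(
    train: pd.DataFrame,
    config: ModelConfig | None = None,
    label_col: str = "label_nonfasting",
    feature_cols=None,
) -> FittedModel:
    """Fit the configured classifier on a feature table.

    Logistic regression is fit by maximum likelihood on complete cases (the
    row reduction is logged); the boosted model handles missing values
    natively.  Perfect separation is reported with a warning, never
    silently.
    """
    config = config or ModelConfig()
    y_all = train[label_col].to_numpy(dtype=bool)
    if y_all.all() or not y_all.any():
        raise ValueError("labels are constant; cannot fit a classifier")
    X = design_matrix(train, feature_cols)

    if config.model_kind == "logistic":
        complete = X.notna().all(axis=1).to_numpy()
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("logistic fit: %d rows dropped for missingness", n_dropped)
        Xc = sm.add_constant(X[complete], has_constant="add")
        yc = y_all[complete].astype(float)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = sm.Logit(yc, Xc).fit(disp=0, maxiter=200)
            except Exception:  # perfect separation can abort Newton steps
                warnings.simplefilter("ignore")
                res = sm.Logit(yc, Xc).fit(disp=0, maxiter=500, method="bfgs")
                warnings.warn("logistic fit fell back to BFGS "
                              "(possible separation)", RuntimeWarning,
                              stacklevel=2)
        for w in caught:
            if "separation" in str(w.message).lower():
                warnings.warn(str(w.message), RuntimeWarning, stacklevel=2)
        p = np.asarray(res.predict(Xc))
        if np.any((p > 1 - 1e-10) | (p < 1e-10)):
            warnings.warn(
                "fitted probabilities reach 0/1: possible perfect separation",
                RuntimeWarning, stacklevel=2,
            )
        return FittedModel("logistic", None, X.columns, config,
                           n_dropped, result=res, feature_cols=feature_cols)

    from xgboost import XGBClassifier

    clf = XGBClassifier(
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=config.seed,
        **config.gbt_hyperparams,
    )
    clf.fit(X.to_numpy(), y_all.astype(int))
    return FittedModel("gbt", clf, X.columns, config, feature_cols=feature_cols)


def compute_auroc(scores, labels) -> float:
    """Exact Mann–Whitney AUROC: P(score⁺ > score⁻) + ½·P(tie).

    Computed from mid-ranks, so ties contribute exactly one half.  Raises
    if only one class is present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _auroc_bootstrap_ci(scores, labels, reps, seed, alpha=0.05):
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    vals = np.empty(reps)
    for i in range(reps):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True),
             rng.choice(neg, neg.size, replace=True)]
        )
        vals[i] = compute_auroc(s[idx], y[idx])
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def confusion_metrics(
    scores,
    labels,
    threshold: float = 0.5,
    auroc_ci_reps: int = 0,
    seed: int = 0,
) -> MetricsReport:
    """Confusion metrics at a fixed operating point plus AUROC.

    Predicted positive means score ≥ threshold.  With an empty predicted
    positive set, precision (and hence F1) is undefined and reported as
    missing.  ``auroc_ci_reps > 0`` adds a stratified-bootstrap percentile
    CI for the AUROC.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics need both classes present")
    sens = tp / n_pos
    spec = tn / n_neg
    prec = tp / (tp + fp) if (tp + fp) else None
    f1 = (2 * prec * sens / (prec + sens)
          if prec is not None and (prec + sens) > 0 else None)
    auroc = compute_auroc(s, y)
    ci = (_auroc_bootstrap_ci(s, y, auroc_ci_reps, seed)
          if auroc_ci_reps > 0 else None)
    return MetricsReport(
        sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        accuracy=(tp + tn) / y.size, auroc=auroc, auroc_ci=ci,
        n_pos=n_pos, n_neg=n_neg,
    )


def bootstrap_auroc_difference(
    scores_a, scores_b, labels, reps: int = 2000, seed: int = 0
) -> dict:
    """Paired-bootstrap test of ΔAUROC = AUROC(A) − AUROC(B).

    Rows are resampled with replacement (stratified by class so every
    replicate contains both classes); both scorers are re-evaluated on each
    replicate.  Returns the observed Δ, the percentile 95 % CI and a
    two-sided p-value 2·min(P(Δ ≤ 0), P(Δ ≥ 0)) with +1 smoothing.
    """
    if reps < 100:
        warnings.warn(f"reps={reps} is small for a bootstrap test",
                      UserWarning, stacklevel=2)
    y = np.asarray(labels, dtype=bool)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (a.size == b.size == y.size):
        raise ValueError("scores_a, scores_b and labels must align")
    delta_obs = compute_auroc(a, y) - compute_auroc(b, y)
    rng = np.random.default_rng(seed)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    deltas = np.empty(reps)
    for i in range(reps):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True),
             rng.choice(neg, neg.size, replace=True)]
        )
        deltas[i] = compute_auroc(a[idx], y[idx]) - compute_auroc(b[idx], y[idx])
    lo, hi = np.quantile(deltas, [0.025, 0.975])
    p = 2.0 * min(
        (np.sum(deltas <= 0) + 1) / (reps + 1),
        (np.sum(deltas >= 0) + 1) / (reps + 1),
    )
    return {
        "delta_auroc": float(delta_obs),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "p_value": float(min(p, 1.0)),
        "reps": reps,
    }


def crossvalidate(
    features: pd.DataFrame,
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    label_col: str = "label_nonfasting",
    feature_cols=None,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation.

    Returns per-fold reports and a pooled report whose entries are
    fold-size-weighted means.
    """
    config = config or ModelConfig()
    y = features[label_col].to_numpy(dtype=bool)
    if len(features) < 5 * k:
        raise ValueError(f"need at least {5 * k} rows for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, sizes = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = fit_model(features.iloc[train_idx], config, label_col,
                          feature_cols=feature_cols)
        s = model.predict_proba(features.iloc[test_idx])
        reports.append(confusion_metrics(s, y[test_idx]))
        sizes.append(len(test_idx))
    w = np.asarray(sizes, dtype=float)
    w /= w.sum()

    def _wmean(attr):
        vals = [getattr(r, attr) for r in reports]
        if any(v is None for v in vals):
            return None
        return float(np.dot(w, vals))

    pooled = MetricsReport(
        sensitivity=_wmean("sensitivity"),
        specificity=_wmean("specificity"),
        precision=_wmean("precision"),
        f1=_wmean("f1"),
        accuracy=_wmean("accuracy"),
        auroc=_wmean("auroc"),
        auroc_ci=None,
        n_pos=int(sum(r.n_pos for r in reports)),
        n_neg=int(sum(r.n_neg for r in reports)),
    )
    return reports, pooled


def calibration(scores, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration table on [0, 1].

    Returns per-bin count, mean predicted probability and observed
    nonfasting fraction; empty bins keep count 0 with missing means.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(s, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        rows.append(
            {
                "bin_lower": edges[b],
                "bin_upper": edges[b + 1],
                "count": n,
                "mean_predicted": float(s[mask].mean()) if n else np.nan,
                "observed_fraction": float(y[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
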