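"""Random-forest backward elimination to a compact module signature.

Module activities are the features; the class label is death within a fixed
horizon (default three years; samples censored before the horizon cannot be
labelled and are excluded from training).  An initial large forest estimates
feature importance; each iteration removes the lowest-importance tenth of the
features (at least one), refits a smaller forest, and records stratified
cross-validation error.  The signature is the smallest feature set whose
error is within one standard error of the minimum; risk is the fraction of
trees voting the poor-prognosis class (out-of-bag for training samples) and
cohorts are split at their own median risk.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix, GeneList, GeneModule, ModuleActivity
from .preprocessing import ztransform
from .scoring import module_activity

__all__ = [
    "RFEConfig",
    "ErrorTrace",
    "SignatureModel",
    "make_outcome_labels",
    "rfe_run",
    "select_signature",
    "fit_signature",
    "RandomForestSignature",
    "score_risk",
    "apply_to_validation",
    "gene_cox_signature",
]


@dataclass
class RFEConfig:
    """Backward-elimination settings; tree counts default to the published run."""

    n_trees_initial: int = 5000
    n_trees_iter: int = 3000
    drop_fraction: float = 0.1
    stop_at: int = 2
    outcome_horizon_days: float = 1095.0
    cv_folds: int = 5
    seed: int = 0
    importance: str = "permutation"  # or "gini"
    importance_repeats: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.stop_at < 2:
            raise ValueError("stop_at must be >= 2")
        if self.importance not in ("permutation", "gini"):
            raise ValueError("importance must be 'permutation' or 'gini'")


@dataclass
class TraceStep:
    n_features: int
    features: list[str]
    cv_error: float
    cv_error_se: float
    importances: dict[str, float]


@dataclass
class ErrorTrace:
    steps: list[TraceStep] = field(default_factory=list)

    def counts(self) -> list[int]:
        return [s.n_features for s in self.steps]

    def errors(self) -> list[float]:
        return [s.cv_error for s in self.steps]


@dataclass
class SignatureModel:
    selected_module_ids: list[str]
    modules: list[GeneModule]
    forest: RandomForestClassifier
    threshold: float
    trace: ErrorTrace
    config: RFEConfig
    train_sample_ids: list[str]
    oob_scores: pd.Series
    normalization: str = "sum_over_sqrt_m"


def make_outcome_labels(clinical: pd.DataFrame, horizon: float = 1095.0) -> tuple[pd.Series, pd.Series]:
    """Binary poor-prognosis labels: death before ``horizon`` days.

    Samples censored before the horizon are unlabeled (mask False) and are
    excluded from training.  Returns (labels over usable samples, usable mask
    over all samples).
    """
    time = clinical["os_days"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    died_early = (event == 1) & (time <= horizon)
    followed_past = time > horizon
    usable = died_early | followed_past
    if not usable.any():
        raise ValueError("no sample can be labelled at this horizon")
    labels = pd.Series(
        died_early[usable].astype(int), index=clinical.loc[usable, "sample"], name="label"
    )
    mask = pd.Series(usable, index=clinical["sample"], name="usable")
    return labels, mask


def _cv_error(X: np.ndarray, y: np.ndarray, n_trees: int, folds: int, seed: int) -> tuple[float, float]:
    """Stratified CV misclassification error (mean, standard error over folds)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        rf.fit(X[tr], y[tr])
        errs.append(1.0 - rf.score(X[te], y[te]))
    errs = np.asarray(errs)
    return float(errs.mean()), float(errs.std(ddof=1) / math.sqrt(len(errs)))


def _importances(rf, X, y, feature_names, kind: str, seed: int, repeats: int = 5) -> dict[str, float]:
    if kind == "gini":
        vals = rf.feature_importances_
    else:
        res = permutation_importance(rf, X, y, n_repeats=repeats, random_state=seed, scoring="accuracy")
        vals = res.importances_mean
    return dict(zip(feature_names, map(float, vals)))


def rfe_run(features: pd.DataFrame, labels: pd.Series, cfg: RFEConfig | None = None) -> ErrorTrace:
    """Backward elimination over a samples x modules feature frame.

    Feature counts strictly decrease down to ``stop_at``; each step records
    the retained features, their importance ranking, and the stratified CV
    error of a forest on exactly those features.
    """
    cfg = cfg or RFEConfig()
    common = features.index.intersection(labels.index)
    if len(common) < 10:
        raise ValueError("need at least 10 labelled samples")
    X_df = features.loc[common]
    y = labels.loc[common].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; cannot train")
    if X_df.shape[1] < cfg.stop_at:
        raise ValueError(f"need at least {cfg.stop_at} features")

    current = list(X_df.columns)
    trace = ErrorTrace()
    iteration = 0
    while True:
        n_trees = cfg.n_trees_initial if iteration == 0 else cfg.n_trees_iter
        X = X_df[current].to_numpy(dtype=float)
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=cfg.seed + iteration, n_jobs=1)
        rf.fit(X, y)
        imp = _importances(rf, X, y, current, cfg.importance, cfg.seed + iteration, cfg.importance_repeats)
        err, se = _cv_error(X, y, n_trees, cfg.cv_folds, cfg.seed + iteration)
        trace.steps.append(
            TraceStep(len(current), list(current), err, se, imp)
        )
        if len(current) <= cfg.stop_at:
            break
        drop = max(1, math.ceil(cfg.drop_fraction * len(current)))
        drop = min(drop, len(current) - cfg.stop_at)
        # lowest importance first; ties broken by feature order for determinism
        order = sorted(current, key=lambda f: (imp[f], current.index(f)))
        dropped = set(order[:drop])
        current = [f for f in current if f not in dropped]
        iteration += 1
    return trace


def select_signature(trace: ErrorTrace) -> TraceStep:
    """One-standard-error rule: smallest feature count with error within one SE
    of the minimum CV error."""
    if not trace.steps:
        raise ValueError("empty trace")
    errs = np.array(trace.errors())
    i_min = int(np.argmin(errs))
    band = errs[i_min] + trace.steps[i_min].cv_error_se
    eligible = [s for s in trace.steps if s.cv_error <= band]
    return min(eligible, key=lambda s: s.n_features)


def fit_signature(
    activity: ModuleActivity,
    clinical: pd.DataFrame,
    modules: list[GeneModule],
    cfg: RFEConfig | None = None,
) -> SignatureModel:
    """Run backward elimination on module activities and fit the final forest."""
    cfg = cfg or RFEConfig()
    labels, _ = make_outcome_labels(clinical, cfg.outcome_horizon_days)
    features = activity.values.T  # samples x modules
    trace = rfe_run(features, labels, cfg)
    chosen = select_signature(trace)
    common = features.index.intersection(labels.index)
    X = features.loc[common, chosen.features].to_numpy(dtype=float)
    y = labels.loc[common].to_numpy(dtype=int)
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees_initial, random_state=cfg.seed, oob_score=True, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # some samples may miss OOB coverage
        forest.fit(X, y)
    oob = forest.oob_decision_function_[:, list(forest.classes_).index(1)]
    oob = np.nan_to_num(oob, nan=0.5)
    oob_scores = pd.Series(oob, index=common, name="oob_risk")
    module_map = {m.id: m for m in modules}
    return SignatureModel(
        selected_module_ids=list(chosen.features),
        modules=[module_map[f] for f in chosen.features if f in module_map],
        forest=forest,
        threshold=float(np.median(oob)),
        trace=trace,
        config=cfg,
        train_sample_ids=list(common),
        oob_scores=oob_scores,
        normalization=activity.normalization,
    )


class RandomForestSignature(ClassifierMixin, BaseEstimator):
    """sklearn-style estimator around backward elimination + final forest.

    ``fit`` expects X as a samples x modules DataFrame (or array) and binary
    labels; fitted attributes: ``trace_``, ``selected_features_``,
    ``forest_``, ``threshold_``.  ``predict_proba`` returns risk from the
    final forest restricted to the selected features.
    """

    def __init__(self, n_trees_initial: int = 5000, n_trees_iter: int = 3000,
                 drop_fraction: float = 0.1, stop_at: int = 2, cv_folds: int = 5,
                 seed: int = 0, importance: str = "permutation"):
        self.n_trees_initial = n_trees_initial
        self.n_trees_iter = n_trees_iter
        self.drop_fraction = drop_fraction
        self.stop_at = stop_at
        self.cv_folds = cv_folds
        self.seed = seed
        self.importance = importance

    def _config(self) -> RFEConfig:
        return RFEConfig(
            n_trees_initial=self.n_trees_initial, n_trees_iter=self.n_trees_iter,
            drop_fraction=self.drop_fraction, stop_at=self.stop_at,
            cv_folds=self.cv_folds, seed=self.seed, importance=self.importance,
        )

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        y_s = pd.Series(np.asarray(y), index=X_df.index)
        cfg = self._config()
        self.trace_ = rfe_run(X_df, y_s, cfg)
        chosen = select_signature(self.trace_)
        self.selected_features_ = list(chosen.features)
        self.classes_ = np.array([0, 1])
        Xs = X_df[self.selected_features_].to_numpy(dtype=float)
        self.forest_ = RandomForestClassifier(
            n_estimators=cfg.n_trees_initial, random_state=cfg.seed, oob_score=True, n_jobs=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.forest_.fit(Xs, np.asarray(y, dtype=int))
        oob = self.forest_.oob_decision_function_[:, list(self.forest_.classes_).index(1)]
        self.oob_scores_ = np.nan_to_num(oob, nan=0.5)
        self.threshold_ = float(np.median(self.oob_scores_))
        return self

    def predict_proba(self, X):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        return self.forest_.predict_proba(X_df[self.selected_features_].to_numpy(dtype=float))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > self.threshold_).astype(int)


def score_risk(
    model: SignatureModel,
    activity: ModuleActivity,
    use_own_median: bool = True,
) -> pd.DataFrame:
    """Risk score and median-split group per sample.

    Training samples are scored with out-of-bag votes; any other cohort with
    all-tree votes.  The split threshold is the scored cohort's own median
    (ties go to the low group).
    """
    missing = [m for m in model.selected_module_ids if m not in activity.values.index]
    if missing:
        raise ValueError(f"activity matrix lacks signature modules: {missing}")
    samples = list(activity.sample_ids)
    X = activity.values.loc[model.selected_module_ids, samples].T.to_numpy(dtype=float)
    proba = model.forest.predict_proba(X)
    scores = proba[:, list(model.forest.classes_).index(1)]
    # training samples are scored out-of-bag to avoid in-bag optimism
    train = set(model.train_sample_ids)
    scores = np.array(
        [
            model.oob_scores.loc[s] if s in train else sc
            for s, sc in zip(samples, scores)
        ]
    )
    threshold = float(np.median(scores)) if use_own_median else model.threshold
    group = np.where(scores > threshold, "high", "low")
    return pd.DataFrame({"sample": samples, "score": scores, "group": group})


def apply_to_validation(
    model: SignatureModel,
    raw_expr: ExpressionMatrix,
    clinical: pd.DataFrame,
) -> dict:
    """Score an independent cohort: z-transform within the cohort, recompute the
    selected modules' activities, median-split, and evaluate survival."""
    from . import survival as _surv

    if raw_expr.n_samples < 2:
        raise ValueError("validation cohort must contain at least 2 samples")
    z = raw_expr if raw_expr.scale == "zscore" else ztransform(raw_expr)
    act = module_activity(z, model.modules, model.normalization)
    risk = score_risk(model, act)
    data = clinical.merge(risk, on="sample")
    results = {
        "risk": risk,
        "logrank": _surv.logrank(data),
        "km": _surv.km_estimate(data),
    }
    try:
        results["cox"] = _surv.cox_fit(data, terms=["group"])
    except RuntimeError as exc:
        results["cox"] = {"error": str(exc)}
    results["auc"] = _surv.time_dependent_auc(
        data.set_index("sample")["score"], data
    )
    return results


def gene_cox_signature(
    z: ExpressionMatrix,
    genes: GeneList,
    clinical: pd.DataFrame,
) -> pd.DataFrame:
    """Comparator signature: multivariable Cox on individual gene z-rows.

    Risk is the linear predictor; groups split at the cohort median.  A fit
    failure (non-convergence, collinearity) raises rather than passing
    silently.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    present = [g for g in genes.genes if g in z.values.index]
    if len(present) < 2:
        raise ValueError("need at least 2 signature genes present")
    X = z.values.loc[present].T  # samples x genes
    if X.T.duplicated().any():
        raise ValueError("duplicate gene expression rows; collinear design")
    df = X.copy()
    clin = clinical.set_index("sample").loc[df.index]
    if clin["event"].sum() == 0:
        raise ValueError("no events in cohort")
    df["os_days"] = clin["os_days"].to_numpy(dtype=float)
    df["event"] = clin["event"].to_numpy(dtype=int)
    cph = CoxPHFitter(penalizer=1e-6)
    try:
        cph.fit(df, duration_col="os_days", event_col="event")
    except ConvergenceError as exc:  # pragma: no cover - guarded input
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    lp = cph.predict_log_partial_hazard(X)
    threshold = float(np.median(lp))
    group = np.where(lp > threshold, "high", "low")
    return pd.DataFrame({"sample": df.index, "score": lp.to_numpy(), "group": group})
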