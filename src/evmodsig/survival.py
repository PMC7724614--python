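"""Survival evaluation: Kaplan-Meier, log-rank, Cox, time-dependent AUC.

Thin, validated wrappers over lifelines (product-limit estimator, log-rank
test, Cox proportional hazards with Efron tie handling) and scikit-survival
(IPCW cumulative/dynamic AUC).  Input is a tidy table with ``os_days``,
``event`` and a two-level ``group`` column plus optional covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = ["km_estimate", "logrank", "cox_fit", "time_dependent_auc", "DEFAULT_HORIZONS"]

DEFAULT_HORIZONS = (365.0, 1095.0, 1825.0)  # 1, 3, 5 years in days


def _check(data: pd.DataFrame) -> None:
    for col in ("os_days", "event"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if (data["os_days"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not data["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")


def km_estimate(data: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Product-limit survival curve per group: (group, time, survival, at_risk)."""
    _check(data)
    rows = []
    for g, sub in data.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_days"], event_observed=sub["event"])
        table = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        observed = set(sub["os_days"])
        for t in (t for t in table.index if t in observed):
            rows.append(
                {
                    "group": g,
                    "time": float(t),
                    "survival": float(surv.loc[t]),
                    "at_risk": int(table.loc[t, "at_risk"]),
                }
            )
    return pd.DataFrame(rows)


def logrank(data: pd.DataFrame, group_col: str = "group") -> dict:
    """Two-sample log-rank test (chi-square, 1 df)."""
    _check(data)
    groups = data[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(groups)}")
    if data["event"].sum() == 0:
        raise ValueError("log-rank undefined with no events")
    res = multivariate_logrank_test(data["os_days"], data[group_col], data["event"])
    return {"statistic": float(res.test_statistic), "p": float(res.p_value), "df": 1}


_REFERENCE_FIRST = {"group": ["low", "high"]}


def _design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design matrix: categorical terms one-hot encoded, reference dropped.

    For the risk-group indicator the low-risk group is the reference, so the
    reported hazard ratio is high vs low.
    """
    cols = {}
    for term in terms:
        v = data[term]
        if v.dtype.kind in "ifb":
            cols[term] = v.astype(float)
        else:
            levels = sorted(v.astype(str).unique())
            preferred = _REFERENCE_FIRST.get(term)
            if preferred and set(levels) <= set(preferred):
                levels = [l for l in preferred if l in levels]
            for lev in levels[1:]:
                cols[f"{term}_{lev}"] = (v.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=data.index)


def cox_fit(data: pd.DataFrame, terms: list[str] | None = None, penalizer: float = 0.01) -> dict:
    """Multivariate Cox PH fit (Efron ties); HR with 95% CI and p per term.

    Default terms: the risk-group indicator adjusted for age, sex and stage
    where those columns are present.  A light ridge penalty guards against
    separation in sparse categorical levels; its bias is negligible at the
    cohort sizes used here.
    """
    from lifelines.exceptions import ConvergenceError

    _check(data)
    if terms is None:
        terms = [t for t in ("group", "age", "sex", "stage") if t in data.columns]
    design = _design(data, terms)
    n_events = int(data["event"].sum())
    if n_events < design.shape[1]:
        raise ValueError("fewer events than model terms")
    df = design.copy()
    df["os_days"] = data["os_days"].to_numpy(dtype=float)
    df["event"] = data["event"].to_numpy(dtype=int)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="os_days", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    out = {"log_likelihood": float(cph.log_likelihood_), "terms": {}}
    for term in summary.index:
        out["terms"][term] = {
            "hr": float(summary.loc[term, "exp(coef)"]),
            "ci_low": float(summary.loc[term, "exp(coef) lower 95%"]),
            "ci_high": float(summary.loc[term, "exp(coef) upper 95%"]),
            "p": float(summary.loc[term, "p"]),
            "coef": float(summary.loc[term, "coef"]),
        }
    return out


def time_dependent_auc(
    scores: pd.Series,
    data: pd.DataFrame,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
) -> dict:
    """IPCW cumulative-case / dynamic-control AUC at each horizon.

    Horizons with no case or no control (or beyond follow-up) are reported as
    absent (None).  Censoring weights are estimated from the same cohort.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    _check(data)
    idx = data["sample"] if "sample" in data.columns else data.index
    aligned = scores.loc[idx].to_numpy(dtype=float)
    y = Surv.from_arrays(event=data["event"].astype(bool), time=data["os_days"].astype(float))
    t = data["os_days"].to_numpy(dtype=float)
    e = data["event"].to_numpy(dtype=int)
    out = {"method": "IPCW cumulative/dynamic"}
    for h in horizons:
        has_case = np.any((t <= h) & (e == 1))
        has_control = np.any(t > h)
        if not (has_case and has_control) or h >= t.max():
            out[f"auc_{int(h)}d"] = None
            continue
        try:
            auc, _ = cumulative_dynamic_auc(y, y, aligned, [h])
            out[f"auc_{int(h)}d"] = float(auc[0])
        except ValueError:
            out[f"auc_{int(h)}d"] = None
    return out
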