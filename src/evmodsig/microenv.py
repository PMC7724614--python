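"""Tumor-microenvironment context scores and their links to module activity.

Context scores (hypoxia, angiogenesis, inflammation) are the per-sample mean
of the z-scored expression of configurable biomarker gene sets.  Module
activities are correlated (Pearson) against context scores and cell-type
abundances with Benjamini-Hochberg adjustment across the full grid, and any
per-sample quantity can be contrasted between risk groups with a Welch t-test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ModuleActivity

__all__ = ["context_score", "correlate_modules", "group_contrast"]


def context_score(z: ExpressionMatrix, sets: dict[str, list[str]]) -> pd.DataFrame:
    """Mean z-scored expression of each context's biomarker genes, per sample."""
    if z.scale != "zscore":
        raise ValueError("context scores require a z-scored matrix")
    rows = {}
    for ctx, genes in sets.items():
        present = [g for g in genes if g in z.values.index]
        if not present:
            warnings.warn(f"context {ctx!r}: no biomarker gene present; skipped", stacklevel=2)
            continue
        rows[ctx] = z.values.loc[present].mean(axis=0)
    if not rows:
        raise ValueError("no context has any biomarker gene in the matrix")
    return pd.DataFrame(rows).T


def correlate_modules(activity: ModuleActivity, variables: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each module against each variable row.

    ``variables`` is variable x sample (context scores and/or abundances).
    BH adjustment spans the entire module x variable grid.  Zero-variance
    pairs are reported absent.
    """
    shared = activity.sample_ids.intersection(variables.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for mod in activity.module_ids:
        a = activity.values.loc[mod, shared].to_numpy(dtype=float)
        for var in variables.index:
            v = variables.loc[var, shared].to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(v) == 0:
                continue
            r, p = stats.pearsonr(a, v)
            rows.append({"module": mod, "variable": var, "r": r, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def group_contrast(values: pd.Series, risk: pd.DataFrame) -> dict:
    """Welch t-test of a per-sample quantity between low- and high-risk groups."""
    merged = risk.set_index("sample").join(values.rename("value"), how="inner")
    groups = merged.groupby("group")["value"]
    if len(groups) < 2:
        raise ValueError("need both risk groups")
    low = groups.get_group("low").to_numpy(dtype=float)
    high = groups.get_group("high").to_numpy(dtype=float)
    if min(len(low), len(high)) < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(high, low, equal_var=False)
    return {
        "mean_high": float(high.mean()),
        "mean_low": float(low.mean()),
        "difference": float(high.mean() - low.mean()),
        "t": float(t),
        "p": float(p),
    }
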