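"""Expression normalization and candidate-gene selection.

The candidate gene universe for network analysis is the intersection of
tumor-vs-normal differential genes with the list of extracellular-vesicle
(EV) associated genes.  Differential expression is assessed with a two-sided
Wilcoxon rank-sum test per gene with Benjamini-Hochberg adjustment; a
pre-computed differential gene list (e.g. from an empirical-Bayes caller run
elsewhere) can be supplied verbatim instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneList

__all__ = ["ztransform", "select_de_genes", "intersect_candidates"]


def ztransform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score across samples (sample sd, ddof=1).

    Constant genes map to all-zero rows so the matrix shape is stable; they
    contribute nothing to any module activity.
    """
    if expr.scale == "zscore":
        raise ValueError("matrix is already z-scored")
    if expr.n_samples < 2:
        raise ValueError("z-transform requires at least 2 samples")
    vals = expr.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns), scale="zscore"
    )


def select_de_genes(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    provided: GeneList | None = None,
) -> GeneList:
    """Tumor-vs-normal differential genes at a BH-adjusted threshold.

    With ``provided`` set, the externally supplied list is returned verbatim
    (bypass mode for a differential call made outside this package).
    """
    if provided is not None:
        return GeneList(list(provided.genes), provenance=f"provided: {provided.provenance}")
    shared = tumor.genes.intersection(normal.genes)
    if len(shared) == 0:
        raise ValueError("tumor and normal matrices share no genes")
    t = tumor.values.loc[shared].to_numpy(dtype=float)
    n = normal.values.loc[shared].to_numpy(dtype=float)
    pvals = np.ones(len(shared))
    for i in range(len(shared)):
        if np.ptp(t[i]) == 0 and np.ptp(n[i]) == 0 and (t[i][:1] == n[i][:1]).all():
            continue  # identical constants: no evidence
        pvals[i] = stats.mannwhitneyu(t[i], n[i], alternative="two-sided").pvalue
    reject, padj, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")
    hits = [g for g, ok, p in zip(shared, reject, padj) if ok and p <= fdr_threshold]
    return GeneList(hits, provenance=f"rank-sum BH fdr<={fdr_threshold}")


def intersect_candidates(de: GeneList, ev: GeneList) -> GeneList:
    """Intersection of differential and EV-associated genes, in DE order."""
    ev_set = set(ev.genes)
    return GeneList(
        [g for g in de.genes if g in ev_set],
        provenance="differential ∩ EV-associated",
    )
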