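"""Core data containers shared across the pipeline.

Expression matrices are genes x samples with an explicit scale tag so that
operations that require z-scored input can enforce it.  PPI networks are plain
:class:`networkx.Graph` objects whose edges carry a ``confidence`` attribute in
[0, 1]; gene modules are small frozen records produced by dense-module
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneList",
    "GeneModule",
    "ModuleActivity",
    "validate_clinical",
    "CLINICAL_COLUMNS",
]

VALID_SCALES = ("counts", "normalized", "zscore")

#: required columns of a clinical table
CLINICAL_COLUMNS = ("sample", "os_days", "event", "stage", "age", "sex", "grade")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression matrix with a declared measurement scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id.
    scale : str
        One of ``counts``, ``normalized`` or ``zscore``.
    """

    values: pd.DataFrame
    scale: str = "normalized"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return replace(self, values=self.values.loc[keep])


@dataclass
class GeneList:
    """An ordered, duplicate-free list of gene symbols with provenance."""

    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene list contains duplicates")
        self.genes = list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in set(self.genes)


@dataclass(frozen=True)
class GeneModule:
    """A dense PPI module: a gene set with its seed node and MCODE score."""

    id: str
    genes: frozenset[str]
    seed: str
    score: float

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"module {self.id} has fewer than 2 genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class ModuleActivity:
    """Module-by-sample activity scores derived from z-scored expression."""

    values: pd.DataFrame  # modules x samples
    normalization: str = "sum_over_sqrt_m"

    def __post_init__(self) -> None:
        if self.normalization not in ("sum", "mean", "sum_over_sqrt_m"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("activities must be finite")

    @property
    def module_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def validate_clinical(clinical: pd.DataFrame, require: Sequence[str] = CLINICAL_COLUMNS) -> pd.DataFrame:
    """Check a clinical table for the required columns and basic sanity.

    Returns the table unchanged; raises ``ValueError`` on problems.  Survival
    times must be positive, events binary.
    """
    missing = [c for c in require if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if len(clinical):
        if "os_days" in clinical and (clinical["os_days"] <= 0).any():
            raise ValueError("survival times must be strictly positive")
        if "event" in clinical and not clinical["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if clinical["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
    return clinical
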