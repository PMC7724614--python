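"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: expression TSV (first column ``gene``, remaining columns sample ids),
clinical TSV, confidence-scored edge-list TSV (``node_a  node_b  confidence``),
GMT gene sets, one-symbol-per-line gene lists, and a JSON ground-truth sidecar
for synthetic cohorts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .containers import ExpressionMatrix, GeneList, validate_clinical

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_json",
    "write_json",
]


def read_expression(path: str | Path, scale: str = "normalized") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    # default float formatting is shortest-round-trip, so read-back is exact
    df.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "stage": str, "sex": str, "grade": str})
    if len(df):
        validate_clinical(df)
    return df


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected confidence-scored edge list into a simple graph."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    g = nx.Graph()
    for a, b, c in df[["node_a", "node_b", "confidence"]].itertuples(index=False):
        if a == b:
            continue
        g.add_edge(a, b, confidence=float(c))
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = sorted((min(a, b), max(a, b), d.get("confidence", 1.0)) for a, b, d in g.edges(data=True))
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "confidence"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, _desc, *genes = parts
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_list(path: str | Path, provenance: str | None = None) -> GeneList:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GeneList(genes=genes, provenance=provenance or str(path))


def write_gene_list(genes: GeneList | list[str], path: str | Path) -> None:
    symbols = list(genes.genes) if isinstance(genes, GeneList) else list(genes)
    Path(path).write_text("\n".join(symbols) + ("\n" if symbols else ""))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
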