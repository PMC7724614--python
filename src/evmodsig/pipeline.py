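"""End-to-end orchestration: simulate -> preprocess -> modules -> score ->
signature -> evaluate -> microenvironment.

A single declarative config carries every stage parameter (edge-confidence
filter 0.4, MCODE settings, 1000 permutations with the P < 0.001 gate, the
forest sizes and 10% backward elimination, survival horizons) plus a master
seed that fans out to per-stage seeds recorded in the run manifest.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import microenv as _micro
from . import network as _net
from . import preprocessing as _pre
from . import scoring as _score
from . import signature as _sig
from . import survival as _surv
from .containers import GeneList
from .simulate import SyntheticCohortConfig, generate_cohort, generate_network, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "cmd_simulate", "cmd_run", "cmd_report", "run_analysis", "run_bundle"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters and input paths for one run."""

    # inputs (paths; required for cmd_run)
    tumor_expression: str = ""
    normal_expression: str = ""
    clinical: str = ""
    edges: str = ""
    ev_genes: str = ""
    gene_sets: str = ""  # GMT with context_* sets (optional)
    abundance: str = ""  # cell_type x sample TSV (optional)
    de_genes: str = ""  # optional bypass list for differential genes

    # stage parameters (defaults mirror the published analysis)
    fdr_threshold: float = 0.05
    edge_confidence: float = 0.4
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_max_depth: int = 100
    normalization: str = "sum_over_sqrt_m"
    n_perm: int = 1000
    alpha: float = 0.001
    rfe_n_trees_initial: int = 5000
    rfe_n_trees_iter: int = 3000
    rfe_drop_fraction: float = 0.1
    rfe_stop_at: int = 2
    rfe_cv_folds: int = 5
    rfe_importance: str = "permutation"
    outcome_horizon_days: float = 1095.0
    auc_horizons: tuple = (365.0, 1095.0, 1825.0)
    alpha_corr: float = 0.05
    seed: int = 0

    # synthetic-cohort block used by cmd_simulate
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "auc_horizons" in raw:
            raw["auc_horizons"] = tuple(raw["auc_horizons"])
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds fanned out from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("simulate", "permutation", "rfe")
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def cmd_simulate(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic cohort (network + expression + clinical + TME)."""
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.stage_seeds()["simulate"])
    cohort_cfg = SyntheticCohortConfig(**sim_kwargs)
    net = generate_network(cohort_cfg)
    bundle = generate_cohort(cohort_cfg, net)
    return write_cohort(bundle, outdir)


def run_analysis(
    tumor,
    clinical,
    graph,
    ev,
    config: PipelineConfig,
    outdir: str | Path | None = None,
    normal=None,
    de_list: GeneList | None = None,
    context_sets: dict | None = None,
    abundance: pd.DataFrame | None = None,
) -> dict:
    """Run the analysis stages on in-memory inputs.

    Intermediates are written under ``outdir`` when given; any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    # --- candidate genes ----------------------------------------------------
    name = "candidates"
    try:
        z = _pre.ztransform(tumor) if tumor.scale != "zscore" else tumor
        if de_list is not None:
            de = _pre.select_de_genes(tumor, tumor, provided=de_list)
        else:
            if normal is None:
                raise ValueError("either a normal cohort or a differential gene list is required")
            de = _pre.select_de_genes(tumor, normal, config.fdr_threshold)
        candidates = _pre.intersect_candidates(de, ev)
        logger.info("candidates: %d differential, %d EV, %d intersect", len(de), len(ev), len(candidates))
        if out is not None:
            _io.write_gene_list(candidates, out / "candidate_genes.txt")
    except (ValueError, KeyError) as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- PPI modules --------------------------------------------------------
    name = "ppi_modules"
    try:
        filtered = _net.filter_edges(graph, config.edge_confidence)
        sub = _net.induced_subnetwork(filtered, candidates)
        params = _net.MCODEParams(
            degree_cutoff=config.mcode_degree_cutoff,
            node_score_cutoff=config.mcode_node_score_cutoff,
            k_core=config.mcode_k_core,
            max_depth=config.mcode_max_depth,
        )
        modules = _net.mcode_find_modules(sub, params)
        if not modules:
            raise ValueError("no dense module found in the candidate network")
        logger.info("network: %d nodes / %d edges; %d modules", sub.number_of_nodes(),
                    sub.number_of_edges(), len(modules))
        if out is not None:
            _io.write_gmt({m.id: m.sorted_genes() for m in modules}, out / "modules.gmt")
    except ValueError as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- module scoring and stage gate --------------------------------------
    name = "module_scoring"
    try:
        selector = _score.StageModuleSelector(
            n_perm=config.n_perm, alpha=config.alpha,
            seed=seeds["permutation"], normalization=config.normalization,
        )
        net_nodes = GeneList(sorted(sub.nodes), provenance="filtered candidate network")
        selector.fit_modules(z, modules, net_nodes, clinical)
        disc = pd.DataFrame(
            [
                {
                    "module": r.module_id,
                    "m": next(m.size for m in modules if m.id == r.module_id),
                    "mi_bits": r.mi_observed,
                    "n_bins": r.n_bins,
                    "n_perm": r.n_perm,
                    "p": r.p_value,
                }
                for r in selector.results_
            ]
        )
        selected = [m for m in modules if m.id in selector.selected_ids_]
        if len(selected) < config.rfe_stop_at:
            raise ValueError(
                f"only {len(selected)} modules pass the P<{config.alpha} gate; "
                f"need at least {config.rfe_stop_at}"
            )
        activity = _score.module_activity(z, modules, config.normalization)
        clusters, assoc = _score.cluster_and_associate(activity, clinical)
        if out is not None:
            disc.to_csv(out / "discriminant.tsv", sep="\t", index=False)
            assoc.to_csv(out / "cluster_association.tsv", sep="\t", index=False)
            activity.values.to_csv(out / "module_activity.tsv", sep="\t")
    except ValueError as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- signature ----------------------------------------------------------
    name = "signature"
    try:
        sel_activity = _score.module_activity(z, selected, config.normalization)
        cfg = _sig.RFEConfig(
            n_trees_initial=config.rfe_n_trees_initial,
            n_trees_iter=config.rfe_n_trees_iter,
            drop_fraction=config.rfe_drop_fraction,
            stop_at=config.rfe_stop_at,
            outcome_horizon_days=config.outcome_horizon_days,
            cv_folds=config.rfe_cv_folds,
            seed=seeds["rfe"],
            importance=config.rfe_importance,
        )
        model = _sig.fit_signature(sel_activity, clinical, selected, cfg)
        risk = _sig.score_risk(model, sel_activity)
        if out is not None:
            pd.DataFrame(
                [
                    {"n_features": s.n_features, "cv_error": s.cv_error,
                     "cv_error_se": s.cv_error_se, "features": ",".join(s.features)}
                    for s in model.trace.steps
                ]
            ).to_csv(out / "rfe_trace.tsv", sep="\t", index=False)
            risk.to_csv(out / "risk.tsv", sep="\t", index=False)
            _io.write_json(
                {
                    "selected_modules": model.selected_module_ids,
                    "module_genes": {m.id: m.sorted_genes() for m in model.modules},
                    "threshold": model.threshold,
                    "config": dataclasses.asdict(cfg),
                },
                out / "model.json",
            )
    except ValueError as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- survival evaluation ------------------------------------------------
    name = "survival"
    try:
        data = clinical.merge(risk, on="sample")
        surv_results = {
            "logrank": _surv.logrank(data),
            "cox": _surv.cox_fit(data),
            "cox_unadjusted": _surv.cox_fit(data, terms=["group"]),
            "auc": _surv.time_dependent_auc(
                data.set_index("sample")["score"], data, tuple(config.auc_horizons)
            ),
        }
        if out is not None:
            _surv.km_estimate(data).to_csv(out / "km_curves.tsv", sep="\t", index=False)
            _io.write_json(surv_results, out / "survival.json")
    except (ValueError, RuntimeError) as exc:
        raise PipelineError(name, str(exc)) from exc

    # --- microenvironment ----------------------------------------------------
    name = "microenvironment"
    micro_results = {}
    try:
        variables = []
        context_scores = None
        if context_sets:
            context_scores = _micro.context_score(z, context_sets)
            variables.append(context_scores)
        if abundance is not None:
            variables.append(abundance)
        if variables:
            grid = pd.concat(variables, axis=0)
            corr = _micro.correlate_modules(activity, grid)
            if out is not None:
                corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
            micro_results["n_correlations"] = int(len(corr))
            micro_results["correlations"] = corr
        if context_scores is not None and "hypoxia" in context_scores.index:
            micro_results["hypoxia_contrast"] = _micro.group_contrast(
                context_scores.loc["hypoxia"], risk
            )
        if out is not None:
            _io.write_json(
                {k: v for k, v in micro_results.items() if k != "correlations"},
                out / "microenvironment.json",
            )
    except (ValueError, KeyError) as exc:
        raise PipelineError(name, str(exc)) from exc

    manifest = {
        "parameters": {
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config)
            if f.name != "simulate"
        },
        "stage_seeds": seeds,
        "n_candidates": len(candidates),
        "n_modules": len(modules),
        "selected_by_gate": selector.selected_ids_,
        "signature": model.selected_module_ids,
    }
    if out is not None:
        _io.write_json(manifest, out / "manifest.json")
    results = dict(manifest)
    results["survival"] = surv_results
    results["microenvironment"] = micro_results
    results["model"] = model
    results["risk"] = risk
    results["modules"] = modules
    results["discriminant"] = disc
    return results


def run_bundle(bundle, config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the analysis directly on an in-memory synthetic cohort bundle."""
    return run_analysis(
        tumor=bundle.tumor,
        clinical=bundle.clinical,
        graph=bundle.network,
        ev=bundle.ev_genes,
        config=config,
        outdir=outdir,
        normal=bundle.normal,
        context_sets=bundle.context_sets,
        abundance=bundle.abundance,
    )


def cmd_run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis from files, writing every intermediate plus a manifest."""
    name = "load"
    try:
        tumor = _io.read_expression(config.tumor_expression)
        clinical = _io.read_clinical(config.clinical)
        graph = _io.read_edge_list(config.edges)
        ev = _io.read_gene_list(config.ev_genes)
        normal = _io.read_expression(config.normal_expression) if config.normal_expression else None
        de_list = _io.read_gene_list(config.de_genes) if config.de_genes else None
        context_sets = None
        if config.gene_sets:
            context_sets = {
                k.removeprefix("context_"): v
                for k, v in _io.read_gmt(config.gene_sets).items()
                if k.startswith("context_")
            }
        abundance = (
            pd.read_csv(config.abundance, sep="\t", index_col=0) if config.abundance else None
        )
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError(name, str(exc)) from exc
    return run_analysis(
        tumor, clinical, graph, ev, config, outdir,
        normal=normal, de_list=de_list, context_sets=context_sets, abundance=abundance,
    )


def cmd_report(results_dir: str | Path) -> dict:
    """Read-only one-page summary of a finished run."""
    d = Path(results_dir)
    needed = ["manifest.json", "survival.json", "model.json"]
    missing = [f for f in needed if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"results directory incomplete; missing {missing}")
    manifest = _io.read_json(d / "manifest.json")
    surv = _io.read_json(d / "survival.json")
    model = _io.read_json(d / "model.json")
    group_term = next((t for t in surv["cox"]["terms"] if t.startswith("group")), None)
    report = {
        "signature": model["selected_modules"],
        "signature_genes": model["module_genes"],
        "selected_by_gate": manifest["selected_by_gate"],
        "logrank_p": surv["logrank"]["p"],
        "cox_hr": surv["cox"]["terms"][group_term]["hr"] if group_term else None,
        "cox_ci": [
            surv["cox"]["terms"][group_term]["ci_low"],
            surv["cox"]["terms"][group_term]["ci_high"],
        ]
        if group_term
        else None,
        "auc": {k: v for k, v in surv["auc"].items() if k.startswith("auc")},
    }
    corr_path = d / "correlations.tsv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path, sep="\t")
        if len(corr):
            top = corr.reindex(corr["r"].abs().sort_values(ascending=False).index).head(5)
            report["top_correlations"] = top.to_dict(orient="records")
    return report
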