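"""Outcome labelling, backward elimination, signature selection and risk scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from evmodsig.containers import GeneList, GeneModule
from evmodsig.preprocessing import ztransform
from evmodsig.scoring import module_activity
from evmodsig.signature import (
    ErrorTrace,
    RFEConfig,
    TraceStep,
    apply_to_validation,
    fit_signature,
    gene_cox_signature,
    make_outcome_labels,
    rfe_run,
    score_risk,
    select_signature,
)
from evmodsig.simulate import generate_cohort, generate_network
from tests.conftest import small_config

FAST_RFE = dict(n_trees_initial=60, n_trees_iter=40, importance_repeats=2)


class TestOutcomeLabels:
    def test_documented_conventions(self):
        clin = pd.DataFrame(
            {
                "sample": ["died_early", "followed_past", "censored_early"],
                "os_days": [100.0, 2000.0, 200.0],
                "event": [1, 0, 0],
            }
        )
        labels, mask = make_outcome_labels(clin, horizon=1095)
        assert labels.loc["died_early"] == 1
        assert labels.loc["followed_past"] == 0
        assert "censored_early" not in labels.index
        assert not mask.loc["censored_early"]

    def test_no_usable_samples_rejected(self):
        clin = pd.DataFrame({"sample": ["a"], "os_days": [10.0], "event": [0]})
        with pytest.raises(ValueError, match="no sample"):
            make_outcome_labels(clin, horizon=1095)


def _features(rng, n=80, k=12):
    X = pd.DataFrame(
        rng.normal(size=(n, k)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(k)],
    )
    y = pd.Series((X["m0"] + rng.normal(scale=0.5, size=n) > 0).astype(int), index=X.index)
    return X, y


class TestRFE:
    def test_elimination_count_schedule(self, rng):
        X, y = _features(rng, n=80, k=12)
        trace = rfe_run(X, y, RFEConfig(seed=1, **FAST_RFE))
        assert trace.counts() == [12, 10, 9, 8, 7, 6, 5, 4, 3, 2]
        # retained + removed partition the previous step's features
        for prev, nxt in zip(trace.steps, trace.steps[1:]):
            assert set(nxt.features) < set(prev.features)

    def test_two_features_single_step(self, rng):
        X, y = _features(rng, k=2)
        trace = rfe_run(X, y, RFEConfig(seed=1, **FAST_RFE))
        assert trace.counts() == [2]

    def test_single_class_labels_rejected(self, rng):
        X, y = _features(rng)
        with pytest.raises(ValueError, match="single-class"):
            rfe_run(X, pd.Series(1, index=X.index), RFEConfig(**FAST_RFE))

    def test_determinism(self, rng):
        X, y = _features(rng)
        cfg = RFEConfig(seed=5, **FAST_RFE)
        t1, t2 = rfe_run(X, y, cfg), rfe_run(X, y, cfg)
        assert [s.features for s in t1.steps] == [s.features for s in t2.steps]
        assert t1.errors() == t2.errors()


class TestSelectSignature:
    def _trace(self, counts, errors, se):
        steps = [
            TraceStep(c, [f"f{i}" for i in range(c)], e, se, {})
            for c, e in zip(counts, errors)
        ]
        return ErrorTrace(steps)

    def test_one_se_rule(self):
        trace = self._trace([12, 10, 4, 3, 2], [0.40, 0.32, 0.30, 0.31, 0.30], 0.02)
        # min err 0.30 (count 4 and 2), band 0.32: count 2 is inside
        assert select_signature(trace).n_features == 2

    def test_tight_band_keeps_minimum(self):
        trace = self._trace([4, 3, 2], [0.30, 0.31, 0.40], 0.005)
        assert select_signature(trace).n_features == 4

    def test_single_entry(self):
        trace = self._trace([2], [0.2], 0.01)
        assert select_signature(trace).n_features == 2

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            select_signature(ErrorTrace([]))


@pytest.fixture(scope="module")
def fitted_model():
    cfg = small_config(n_tumor=120, seed=31)
    b = generate_cohort(cfg, generate_network(cfg))
    z = ztransform(b.tumor)
    mods = [
        GeneModule(id=f"planted_{i}", genes=frozenset(m), seed=sorted(m)[0], score=1.0)
        for i, m in enumerate(b.ground_truth.planted_modules)
    ]
    act = module_activity(z, mods)
    rcfg = RFEConfig(seed=2, outcome_horizon_days=600, **FAST_RFE)
    model = fit_signature(act, b.clinical, mods, rcfg)
    return b, z, mods, act, model


class TestRiskScoring:
    def test_training_median_split_balanced(self, fitted_model):
        b, z, mods, act, model = fitted_model
        risk = score_risk(model, act)
        counts = risk["group"].value_counts()
        assert abs(counts.get("high", 0) - counts.get("low", 0)) <= max(
            1, (risk["score"] == risk["score"].median()).sum()
        )
        # group assignment is exactly score > median (ties low)
        med = risk["score"].median()
        assert ((risk["score"] > med) == (risk["group"] == "high")).all()

    def test_missing_module_rejected(self, fitted_model):
        b, z, mods, act, model = fitted_model
        reduced = act.values.drop(index=model.selected_module_ids[0])
        from evmodsig.containers import ModuleActivity

        with pytest.raises(ValueError, match="lacks signature modules"):
            score_risk(model, ModuleActivity(reduced))

    def test_validation_cohort_direction(self, fitted_model):
        """On an independent cohort from the same generator family the
        high-risk group has the higher observed event rate."""
        b, z, mods, act, model = fitted_model
        vcfg = small_config(n_tumor=150, seed=77)
        vb = generate_cohort(vcfg, generate_network(vcfg))
        res = apply_to_validation(model, vb.tumor, vb.clinical)
        merged = vb.clinical.merge(res["risk"], on="sample")
        rates = merged.groupby("group")["event"].mean()
        assert rates["high"] > rates["low"]
        assert {"risk", "logrank", "km", "cox", "auc"} <= set(res)

    def test_single_sample_validation_rejected(self, fitted_model):
        b, z, mods, act, model = fitted_model
        from evmodsig.containers import ExpressionMatrix

        one = ExpressionMatrix(b.tumor.values.iloc[:, :1], "normalized")
        with pytest.raises(ValueError, match="at least 2"):
            apply_to_validation(model, one, b.clinical.iloc[:1])


class TestGeneCoxSignature:
    def test_duplicate_gene_rows_rejected(self, fitted_model):
        b, z, *_ = fitted_model
        z2 = z.values.copy()
        z2.loc["dup1"] = z2.iloc[0]
        z2.loc["dup2"] = z2.iloc[0]
        from evmodsig.containers import ExpressionMatrix

        zm = ExpressionMatrix(z2, "zscore")
        with pytest.raises(ValueError, match="duplicate"):
            gene_cox_signature(zm, GeneList(["dup1", "dup2"]), b.clinical)

    def test_prognostic_gene_sign_recovered(self, fitted_model):
        """A strongly prognostic gene among nulls gets a positive Cox weight
        and its high-score group shows the worse outcome."""
        b, z, *_ = fitted_model
        genes = sorted(b.ground_truth.planted_modules[0])[:3] + [
            g for g in list(z.values.index) if g.startswith("G08")
        ][:5]
        risk = gene_cox_signature(z, GeneList(genes), b.clinical)
        merged = b.clinical.merge(risk, on="sample")
        rates = merged.groupby("group")["event"].mean()
        assert rates["high"] > rates["low"]
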