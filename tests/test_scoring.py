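"""Module activity, discretization, mutual information and the permutation gate."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from evmodsig.containers import ExpressionMatrix, GeneList, GeneModule
from evmodsig.scoring import (
    cluster_and_associate,
    dichotomize_stage,
    discretize,
    module_activity,
    mutual_information,
    n_bins,
    permutation_test,
    select_modules,
)
from evmodsig.scoring import DiscriminantResult, StageLabels


def brute_force_mi(table: np.ndarray) -> float:
    """Independent oracle: plug-in MI from an explicit double loop, in bits."""
    n = table.sum()
    if n == 0:
        return 0.0
    total = 0.0
    px = table.sum(axis=1) / n
    py = table.sum(axis=0) / n
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            pxy = table[i, j] / n
            if pxy > 0:
                total += pxy * math.log2(pxy / (px[i] * py[j]))
    return total


def zmat(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(rows).T.astype(float), scale="zscore")


def module(mid, genes):
    return GeneModule(id=mid, genes=frozenset(genes), seed=sorted(genes)[0], score=1.0)


class TestModuleActivity:
    def test_single_gene_module_equals_gene_row(self):
        z = zmat({"g1": [0.5, -1.0, 2.0], "g2": [1.0, 1.0, 1.0]})
        mod = GeneModule(id="m", genes=frozenset(["g1", "gX"]), seed="g1", score=1.0)
        with pytest.warns(UserWarning, match="absent"):
            act = module_activity(z, [mod])
        np.testing.assert_allclose(act.values.loc["m"], z.values.loc["g1"])

    def test_all_zero_matrix(self):
        z = zmat({"g1": [0.0, 0.0], "g2": [0.0, 0.0]})
        act = module_activity(z, [module("m", ["g1", "g2"])])
        assert (act.values.to_numpy() == 0).all()

    def test_sqrt_m_normalization_hand_value(self):
        z = zmat({"g1": [1.0], "g2": [3.0]})
        act = module_activity(z, [module("m", ["g1", "g2"])], "sum_over_sqrt_m")
        assert abs(act.values.iloc[0, 0] - 4.0 / math.sqrt(2)) < 1e-12

    def test_no_genes_present_rejected(self):
        z = zmat({"g1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no member gene"):
            module_activity(z, [module("m", ["x", "y"])])

    def test_requires_zscore_scale(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["g1"]), "normalized")
        with pytest.raises(ValueError, match="z-scored"):
            module_activity(m, [module("m", ["g1", "g1b"])])


class TestStageDichotomy:
    def test_mapping_and_unknown_dropped(self):
        clin = pd.DataFrame(
            {"sample": ["s1", "s2", "s3", "s4", "s5"],
             "stage": ["I", "II", "III", "IV", "Unknown"]}
        )
        labels = dichotomize_stage(clin)
        assert labels.stage_class == ["low", "low", "high", "high"]
        assert "s5" not in labels.sample_ids

    def test_all_unknown_rejected(self):
        clin = pd.DataFrame({"sample": ["s1"], "stage": ["NA"]})
        with pytest.raises(ValueError):
            dichotomize_stage(clin)


class TestDiscretize:
    @pytest.mark.parametrize("n,expected", [(167, 9), (2, 2), (256, 9), (257, 10)])
    def test_bin_count_rule(self, n, expected):
        assert n_bins(n) == expected

    def test_equal_width_labels(self):
        labels, _ = discretize(np.arange(9.0), k=3)
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 1, 2, 2, 2])

    def test_constant_vector_single_label(self):
        labels, _ = discretize(np.full(10, 3.3), n_samples=10)
        assert set(labels) == {0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discretize(np.array([]), n_samples=5)


class TestMutualInformation:
    def test_constant_labels_zero(self):
        assert mutual_information(np.zeros(8), np.array([0, 1] * 4)) == 0.0

    def test_perfect_balanced_association(self):
        x = np.array([0, 0, 1, 1])
        y = np.array([0, 0, 1, 1])
        assert abs(mutual_information(x, y) - 1.0) < 1e-12

    def test_hand_computed_table(self):
        # joint counts [[3,1],[1,3]]
        x = np.array([0] * 4 + [1] * 4)
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        expected = brute_force_mi(np.array([[3, 1], [1, 3]]))
        assert abs(mutual_information(x, y) - expected) < 1e-12
        assert abs(expected - 0.18872) < 5e-6

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        kx, ky = int(rng.integers(2, 5)), int(rng.integers(2, 10))
        n = int(rng.integers(5, 80))
        x = rng.integers(0, kx, n)
        y = rng.integers(0, ky, n)
        mi = mutual_information(x, y)
        table = np.zeros((kx, ky))
        for a, b in zip(x, y):
            table[a, b] += 1
        assert abs(mi - brute_force_mi(table)) < 1e-12
        hx = brute_force_mi(np.diag(np.bincount(x, minlength=1)))
        hy = brute_force_mi(np.diag(np.bincount(y, minlength=1)))
        assert -1e-12 <= mi <= min(hx, hy) + 1e-12


def _stage(n_low, n_high):
    return StageLabels(
        sample_ids=[f"s{i}" for i in range(n_low + n_high)],
        raw_stage=["I"] * n_low + ["IV"] * n_high,
        stage_class=["low"] * n_low + ["high"] * n_high,
    )


class TestPermutationTest:
    def _setup(self, rng, n_genes=40, n_samples=60):
        rows = {f"g{i}": rng.normal(size=n_samples) for i in range(n_genes)}
        z = ExpressionMatrix(pd.DataFrame(rows).T, scale="zscore")
        z.values.columns = [f"s{i}" for i in range(n_samples)]
        return z, GeneList(list(z.values.index))

    def test_zero_mi_gives_p_one(self, rng):
        z, nodes = self._setup(rng)
        mod = module("m", ["g0", "g1"])
        # constant activity => MI 0 => every random draw >= observed
        z.values.loc["g0"] = 1.0
        z.values.loc["g1"] = -1.0
        res = permutation_test(mod, nodes, z, _stage(30, 30), n_perm=99, seed=0)
        assert res.mi_observed == 0.0
        assert res.p_value == 1.0

    def test_seed_reproducibility(self, rng):
        z, nodes = self._setup(rng)
        mod = module("m", ["g0", "g1", "g2"])
        r1 = permutation_test(mod, nodes, z, _stage(30, 30), n_perm=50, seed=3)
        r2 = permutation_test(mod, nodes, z, _stage(30, 30), n_perm=50, seed=3)
        np.testing.assert_array_equal(r1.random_mi, r2.random_mi)

    def test_p_respects_attainable_floor(self, rng):
        z, _ = self._setup(rng)
        stage = _stage(30, 30)
        # plant a separation so observed MI beats every draw; the random-set
        # universe excludes the shifted genes so no draw can tie
        cols = z.values.columns
        z.values.loc[["g0", "g1", "g2"], cols[30:]] += 4.0
        nodes = GeneList([g for g in z.values.index if g not in ("g0", "g1", "g2")])
        res = permutation_test(module("m", ["g0", "g1", "g2"]), nodes, z, stage, n_perm=200, seed=1)
        assert res.p_value == 1.0 / 201.0

    def test_module_larger_than_universe_rejected(self, rng):
        z, nodes = self._setup(rng, n_genes=3)
        with pytest.raises(ValueError):
            permutation_test(module("m", ["g0", "g1", "g2"]), nodes, z, _stage(30, 30))


def test_select_modules_strict_inequality():
    mk = lambda mid, p: DiscriminantResult(mid, 0.5, 9, 1000, p)
    res = [mk("a", 0.0009), mk("b", 0.001), mk("c", 0.5)]
    assert select_modules(res, alpha=0.001) == ["a"]
    assert select_modules([], 0.001) == []
    assert select_modules([mk("a", 1.0)], 0.001) == []


class TestClusterAssociate:
    def test_separated_groups_recovered(self, rng):
        from evmodsig.containers import ModuleActivity

        a = rng.normal(0, 0.3, size=(3, 20))
        b = rng.normal(5, 0.3, size=(3, 20))
        vals = pd.DataFrame(
            np.hstack([a, b]),
            index=["m1", "m2", "m3"],
            columns=[f"s{i}" for i in range(40)],
        )
        clin = pd.DataFrame(
            {
                "sample": vals.columns,
                "stage": ["I"] * 20 + ["IV"] * 20,
                "grade": ["G1"] * 40,
                "age": [50] * 40,
                "sex": ["F", "M"] * 20,
            }
        )
        labels, assoc = cluster_and_associate(ModuleActivity(vals), clin)
        first, second = labels.iloc[:20], labels.iloc[20:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]
        stage_row = assoc.set_index("factor").loc["stage"]
        assert stage_row["p"] < 1e-6
        # single-level factors (grade) are excluded
        assert "grade" not in assoc["factor"].tolist()

    def test_identical_samples_single_cluster(self):
        from evmodsig.containers import ModuleActivity

        vals = pd.DataFrame(np.ones((2, 5)), index=["m1", "m2"],
                            columns=[f"s{i}" for i in range(5)])
        clin = pd.DataFrame({"sample": vals.columns, "stage": ["I"] * 5,
                             "grade": ["G1"] * 5, "age": [50] * 5, "sex": ["F"] * 5})
        with pytest.warns(UserWarning, match="identical"):
            labels, assoc = cluster_and_associate(ModuleActivity(vals), clin)
        assert labels.nunique() == 1 and len(assoc) == 0

    def test_bh_adjustment_hand_value(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
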