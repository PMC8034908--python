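"""Network construction, module detection and the lncRNA-proportion test."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from milncnet.coexpression import (ModuleAssignment, UNASSIGNED, adjacency,
                                   detect_modules, lnc_proportion_test,
                                   module_eigengenes, module_trait_correlation,
                                   pick_soft_threshold, scale_free_fit,
                                   tom_similarity)
from milncnet.datasets import ExpressionDataset
from milncnet.synthdata import SynthConfig, generate_dataset


def make_expr(values, biotypes=None, groups=None):
    values = pd.DataFrame(
        np.asarray(values, float),
        index=[f"F{i}" for i in range(len(values))],
        columns=[f"S{j}" for j in range(np.shape(values)[1])],
    )
    biotype = pd.Series(biotypes or ["coding"] * len(values), index=values.index)
    group = pd.Series(groups or ["CAD"] * values.shape[1], index=values.columns)
    return ExpressionDataset(values=values, biotype=biotype, group=group)


def tom_oracle(a):
    """Literal O(n^3) triple loop over the defining formula."""
    a = np.asarray(a, float).copy()
    np.fill_diagonal(a, 0.0)
    n = len(a)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_perfect_correlation_fixed_point(self):
        t = np.arange(6.0)
        expr = make_expr([t, 2 * t + 1])
        for beta in (1, 6, 12):
            assert adjacency(expr, beta).iloc[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_is_rectified(self):
        t = np.arange(6.0)
        expr = make_expr([t, -0.5 * t])
        assert adjacency(expr, 2).iloc[0, 1] == pytest.approx(1.0)  # |cor| = 1
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        # construct a pair with exact correlation -0.5
        y = -0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * rng.normal(size=50)
        expr2 = make_expr([x, y])
        r = np.corrcoef(x, y)[0, 1]
        assert adjacency(expr2, 2).iloc[0, 1] == pytest.approx(r**2)

    def test_zero_variance_feature_is_named(self):
        expr = make_expr([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="F0"):
            adjacency(expr, 6)

    def test_beta_below_one_rejected(self):
        expr = make_expr([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError, match="beta"):
            adjacency(expr, 0)


class TestTOM:
    def test_complete_triangle(self):
        a = np.ones((3, 3))
        assert np.allclose(tom_similarity(a), 1.0)

    def test_isolated_pair(self):
        a = np.eye(4)
        tom = tom_similarity(a)
        assert tom[0, 1] == 0.0

    def test_path_formula_value(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.5
        a[1, 2] = a[2, 1] = 0.5
        tom = tom_similarity(a)
        assert tom[0, 2] == pytest.approx(0.25 / 1.5)

    @pytest.mark.parametrize("n,seed", [(5, 0), (12, 1), (20, 2)])
    def test_matches_triple_loop_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom_similarity(a), tom_oracle(a), atol=1e-12)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestSoftThreshold:
    def test_planted_power_law_high_r2(self):
        # connectivities laid out as exact Pareto quantiles: scale-free by design
        u = (np.arange(5000) + 0.5) / 5000
        k = (1 - u) ** (-1 / 1.5)
        r2, slope = scale_free_fit(k)
        assert r2 >= 0.99
        assert slope < 0

    def test_too_few_features_rejected(self):
        expr = make_expr([[1, 2, 3, 4], [4, 1, 2, 9]])
        with pytest.raises(ValueError, match="few"):
            pick_soft_threshold(expr)

    def test_fallback_warns(self, synth_data):
        with pytest.warns(UserWarning, match="falling back"):
            table, beta = pick_soft_threshold(synth_data.expression)
        assert beta == 6
        assert (table["mean_connectivity"].diff().dropna() < 0).all()


class TestEigengenes:
    def test_identical_rows_give_profile_itself(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = make_expr([base, base * 2 + 1, base * 0.5])
        labels = pd.Series(["M1"] * 3, index=expr.feature_ids)
        mes, ve = module_eigengenes(expr, labels)
        z = (base - base.mean()) / base.std(ddof=1)
        assert np.allclose(mes["M1"], z, atol=1e-10)
        assert ve["M1"] == pytest.approx(1.0)

    def test_sign_contract_with_anticorrelated_pair(self):
        # two members with correlation exactly -1: the mean profile vanishes and
        # the orientation anchors on the first member instead of crashing
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = make_expr([base, -base])
        labels = pd.Series(["M1"] * 2, index=expr.feature_ids)
        mes, _ = module_eigengenes(expr, labels)
        me = mes["M1"].to_numpy()
        assert np.isfinite(me).all()
        z0 = (base - base.mean()) / base.std(ddof=1)
        assert np.corrcoef(me, z0)[0, 1] >= 0

    def test_sign_contract_with_negative_majority(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=40)
        rows = [-f + 0.1 * rng.normal(size=40) for _ in range(5)]
        rows.append(f)
        expr = make_expr(rows)
        labels = pd.Series(["M1"] * 6, index=expr.feature_ids)
        mes, _ = module_eigengenes(expr, labels)
        z = expr.values.apply(lambda r: (r - r.mean()) / r.std(ddof=1), axis=1)
        assert np.corrcoef(mes["M1"], z.mean(axis=0))[0, 1] >= 0

    def test_factor_model_variance_explained(self):
        # rho = 0.8, m = 40 members: leading eigenvalue share ~ rho + (1-rho)/m
        cfg = SynthConfig(n_genes=150, n_lncrnas=30, n_modules=1,
                          module_sizes=[40], within_module_cor=0.8,
                          noise_sd=0.0, marker_effect=0.0, module_trait_map={},
                          trend_features_per_cluster=2, n_trend_clusters=4,
                          cerna_pairs=16, seed=3)
        data = generate_dataset(cfg)
        labels = pd.Series(data.truth_modules)
        _, ve = module_eigengenes(data.expression, labels)
        assert 0.7 <= ve["M1"] <= 0.9

    def test_invariant_to_feature_order(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(6, 30))
        expr = make_expr(vals)
        labels = pd.Series(["M1"] * 6, index=expr.feature_ids)
        mes1, _ = module_eigengenes(expr, labels)
        perm = rng.permutation(6)
        expr2 = ExpressionDataset(values=expr.values.iloc[perm],
                                  biotype=expr.biotype.iloc[perm],
                                  group=expr.group)
        mes2, _ = module_eigengenes(expr2, labels.iloc[perm])
        agreement = abs(np.corrcoef(mes1["M1"], mes2["M1"])[0, 1])
        assert agreement == pytest.approx(1.0, abs=1e-10)


class TestDetectModules:
    def test_noiseless_disjoint_modules_recovered_exactly(self):
        cfg = SynthConfig(n_genes=160, n_lncrnas=20, n_modules=3,
                          module_sizes=[40, 40, 40], within_module_cor=0.999999,
                          noise_sd=0.0, marker_effect=0.0, module_trait_map={},
                          trend_features_per_cluster=0, n_trend_clusters=1,
                          cerna_pairs=16,
                          samples_per_group={"CAD": 30, "MI_S1": 30}, seed=2)
        data = generate_dataset(cfg)
        expr = data.expression.subset_features(sorted(data.truth_modules))
        tom = tom_similarity(adjacency(expr, 6))
        result = detect_modules(1 - tom, expr)
        truth = pd.Series(data.truth_modules).loc[result.module_of.index]
        assert len(result.modules) == 3
        assert adjusted_rand_score(truth, result.module_of) == pytest.approx(1.0)

    def test_default_recovery_on_planted_study(self, synth_data, pipeline_run):
        truth = pd.Series(synth_data.truth_modules)
        detected = pipeline_run.modules.module_of.loc[truth.index]
        assert adjusted_rand_score(truth, detected) >= 0.8

    def test_min_size_relegates_small_clusters(self, synth_data, pipeline_run):
        sizes = pipeline_run.modules.module_sizes
        assert (sizes >= 30).all()

    def test_highly_correlated_modules_merge(self):
        # two blocks driven by almost the same factor -> eigengene cor ~ 0.97
        rng = np.random.default_rng(4)
        f = rng.normal(size=60)
        rows = []
        for _ in range(35):
            rows.append(0.9 * f + 0.2 * rng.normal(size=60))
        f2 = 0.97 * f + np.sqrt(1 - 0.97**2) * rng.normal(size=60)
        for _ in range(35):
            rows.append(0.9 * f2 + 0.2 * rng.normal(size=60))
        expr = make_expr(rows)
        tom = tom_similarity(adjacency(expr, 6))
        result = detect_modules(1 - tom, expr, min_size=10, merge_cut=0.25)
        assert len(result.modules) == 1

    def test_unmergeable_cut_warns_and_returns_unassigned(self):
        rng = np.random.default_rng(5)
        expr = make_expr(rng.normal(size=(40, 30)))
        tom = tom_similarity(adjacency(expr, 6))
        with pytest.warns(UserWarning, match="no module"):
            result = detect_modules(1 - tom, expr, min_size=30)
        assert (result.module_of == UNASSIGNED).all()


class TestModuleTrait:
    def test_indicator_equal_to_eigengene(self):
        ind = np.array([1.0, 1, 1, 0, 0, 0, 1, 0, 1, 0] * 4)
        me = pd.DataFrame({"M1": (ind - ind.mean()) / ind.std(ddof=1)},
                          index=[f"S{j}" for j in range(40)])
        group = pd.Series(np.where(ind == 1, "MI_S1", "CAD"), index=me.index)
        table = module_trait_correlation(me, group, ["MI_S1"])
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert table["p"].iloc[0] < 1e-30

    def test_zero_correlation_gives_p_one(self):
        me = pd.DataFrame({"M1": [1.0, -1, 1, -1, 1, -1, 1, -1]},
                          index=[f"S{j}" for j in range(8)])
        group = pd.Series(["MI_S1", "MI_S1", "CAD", "CAD"] * 2, index=me.index)
        table = module_trait_correlation(me, group, ["MI_S1"])
        assert table["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_null_correlations_stay_small(self):
        rng = np.random.default_rng(6)
        n = 119
        group = pd.Series(["MI_S1"] * 73 + ["CAD"] * 46,
                          index=[f"S{j}" for j in range(n)])
        hits = 0
        for _ in range(200):
            me = pd.DataFrame({"M1": rng.normal(size=n)}, index=group.index)
            r = module_trait_correlation(me, group, ["MI_S1"])["r"].iloc[0]
            hits += abs(r) < 0.3
        assert hits / 200 >= 0.97

    def test_absent_trait_rejected(self):
        me = pd.DataFrame({"M1": [0.1, 0.4, -0.2, 0.6]},
                          index=[f"S{j}" for j in range(4)])
        group = pd.Series(["CAD"] * 4, index=me.index)
        with pytest.raises(ValueError, match="constant"):
            module_trait_correlation(me, group, ["MI_S1"])


class TestLncProportion:
    def enumeration(self, k, total, lnc, draw):
        return sum(
            math.comb(lnc, x) * math.comb(total - lnc, draw - x)
            for x in range(k + 1)
        ) / math.comb(total, draw)

    def test_tiny_urn_examples(self):
        counts = pd.DataFrame({"tag": ["a", "b"], "lnc_count": [1, 0],
                               "pcg_count": [4, 5]})
        out = lnc_proportion_test(counts, background_lnc=2, background_pcg=8)
        assert out["p"].iloc[0] == pytest.approx(196 / 252, rel=1e-12)
        assert out["p"].iloc[1] == pytest.approx(56 / 252, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_enumeration_on_small_urns(self, seed):
        rng = np.random.default_rng(seed)
        lnc_bg, pcg_bg = 8, 20
        rows = []
        for i in range(6):
            draw = rng.integers(2, 12)
            lnc = int(rng.integers(0, min(draw, lnc_bg) + 1))
            rows.append((f"m{i}", lnc, draw - lnc))
        counts = pd.DataFrame(rows, columns=["tag", "lnc_count", "pcg_count"])
        out = lnc_proportion_test(counts, background_lnc=lnc_bg, background_pcg=pcg_bg)
        for _, row in out.iterrows():
            expect = self.enumeration(int(row["lnc_count"]), lnc_bg + pcg_bg,
                                      lnc_bg, int(row["lnc_count"] + row["pcg_count"]))
            assert row["p"] == pytest.approx(expect, rel=1e-12)

    def test_empty_row_rejected(self):
        counts = pd.DataFrame({"tag": ["x"], "lnc_count": [0], "pcg_count": [0]})
        with pytest.raises(ValueError, match="zero members"):
            lnc_proportion_test(counts)

    def test_module_exceeding_background_rejected(self):
        counts = pd.DataFrame({"tag": ["x"], "lnc_count": [5], "pcg_count": [0]})
        with pytest.raises(ValueError, match="background"):
            lnc_proportion_test(counts, background_lnc=2, background_pcg=10)

    def test_adjusted_at_least_raw(self, pipeline_run):
        table = pd.read_csv(pipeline_run.outdir / "lnc_proportion.tsv", sep="\t")
        assert (table["p_adjusted"] >= table["p"] - 1e-15).all()
        assert (table["p_adjusted"] <= 1.0).all()
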