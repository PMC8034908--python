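"""Generator contracts: determinism, planted moments, interaction and drug structure."""

import numpy as np
import pandas as pd
import pytest

from milncnet.synthdata import (SynthConfig, TREND_TEMPLATES, generate_dataset,
                                generate_drug_network, generate_interactions)


def small_config(**kw):
    defaults = dict(n_genes=150, n_lncrnas=30, n_modules=3,
                    module_sizes=[40, 40, 40],
                    samples_per_group={"CAD": 20, "MI_S1": 25, "MI_S2": 25,
                                       "MI_S3": 25, "MI_S4": 25},
                    trend_features_per_cluster=2, n_trend_clusters=4, seed=1)
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,match",
        [
            (dict(within_module_cor=1.0), "within_module_cor"),
            (dict(within_module_cor=0.0), "within_module_cor"),
            (dict(n_genes=-5), "n_genes"),
            (dict(module_sizes=[1000, 1000, 1000]), "module_sizes"),
            (dict(n_near_drugs=99), "n_near_drugs"),
            (dict(samples_per_group={"CAD": 0, "MI_S1": 5}), "CAD"),
        ],
    )
    def test_invalid_configs_name_the_violation(self, kw, match):
        with pytest.raises(ValueError, match=match):
            small_config(**kw)


class TestExpression:
    def test_default_group_counts_match_study_design(self, synth_data):
        counts = synth_data.expression.group.value_counts().to_dict()
        assert counts["CAD"] == 46
        for stage in ("MI_S1", "MI_S2", "MI_S3", "MI_S4"):
            assert counts[stage] == 73

    def test_feature_counts_match_config(self, synth_config, synth_data):
        expr = synth_data.expression
        assert len(expr.lnc_ids) == synth_config.n_lncrnas
        assert len(expr.gene_ids) == synth_config.n_genes

    def test_noiseless_unit_cor_factor_model(self):
        cfg = small_config(within_module_cor=0.999999, noise_sd=0.0,
                           marker_effect=0.0, module_trait_map={})
        data = generate_dataset(cfg)
        mods = pd.Series(data.truth_modules)
        members = mods.index[mods == "M1"]
        c = np.corrcoef(data.expression.values.loc[members])
        assert np.allclose(c, 1.0, atol=1e-4)

    def test_factor_model_moments(self):
        # rho=0.8 with extra noise sd 0.5 -> expected cor 0.8/1.25 = 0.64
        cfg = small_config(within_module_cor=0.8, noise_sd=0.5,
                           module_trait_map={})
        data = generate_dataset(cfg)
        mods = pd.Series(data.truth_modules)
        vals = data.expression.values
        within, between = [], []
        for mod in ("M1", "M2", "M3"):
            sub = np.corrcoef(vals.loc[mods.index[mods == mod]])
            within.append(np.abs(sub[np.triu_indices_from(sub, 1)]).mean())
        a = vals.loc[mods.index[mods == "M1"]].to_numpy()
        b = vals.loc[mods.index[mods == "M2"]].to_numpy()
        cross = np.corrcoef(a, b)[: len(a), len(a):]
        between.append(np.abs(cross).mean())
        assert 0.6 <= np.mean(within) <= 0.9
        assert np.mean(between) < 0.2

    def test_determinism_byte_identical(self):
        d1 = generate_dataset(small_config(seed=5))
        d2 = generate_dataset(small_config(seed=5))
        assert d1.expression.values.equals(d2.expression.values)
        assert d1.mirna_mrna_edges.equals(d2.mirna_mrna_edges)
        assert d1.ppi_edges.equals(d2.ppi_edges)
        assert d1.truth_cerna == d2.truth_cerna
        assert (d1.prognosis_labels == d2.prognosis_labels).all()

    def test_trend_templates_are_standardized_and_distinct(self):
        assert TREND_TEMPLATES.shape == (12, 4)
        assert np.allclose(TREND_TEMPLATES.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(TREND_TEMPLATES.std(axis=1, ddof=1), 1, atol=1e-12)
        for i in range(12):
            for j in range(i + 1, 12):
                assert not np.allclose(TREND_TEMPLATES[i], TREND_TEMPLATES[j])

    def test_prognosis_only_for_mi_patients(self, synth_data):
        labels = synth_data.prognosis_labels
        groups = synth_data.expression.group.loc[labels.index]
        assert (groups != "CAD").all()
        assert set(labels.unique()) == {"HF", "noHF"}

    def test_marker_shift_between_groups(self, synth_config, synth_data):
        expr = synth_data.expression
        for marker in synth_data.truth_markers:
            v = expr.values.loc[marker]
            mi = v[expr.samples_in("MI_S1")].mean()
            cad = v[expr.samples_in("CAD")].mean()
            assert mi - cad > 0.5 * synth_config.marker_effect


class TestInteractions:
    def test_every_planted_pair_shares_mirnas(self, synth_data):
        lnc_reg = synth_data.mirna_lnc_edges.groupby("target")["mirna"].agg(set)
        mrna_reg = synth_data.mirna_mrna_edges.groupby("target")["mirna"].agg(set)
        for lnc, mrna in synth_data.truth_cerna:
            assert len(lnc_reg[lnc] & mrna_reg[mrna]) >= 1

    def test_edges_are_unique(self, synth_data):
        for frame in (synth_data.mirna_mrna_edges, synth_data.mirna_lnc_edges):
            assert not frame.duplicated().any()

    def test_full_sharing_at_rate_one(self):
        cfg = small_config(shared_mirna_rate=1.0, mrna_mirna_degree=8,
                           lnc_mirna_degree=8)
        rng = np.random.default_rng(0)
        mrna_e, lnc_e, _ = generate_interactions(
            cfg, [("LNC0001", "G00001")], ["LNC0001"], ["G00001"], rng)
        lset = set(lnc_e["mirna"])
        mset = set(mrna_e["mirna"])
        assert lset & mset == mset or lset & mset == lset

    def test_planted_enrichment_is_strong(self, synth_config, synth_data):
        from milncnet.stats import hypergeom_upper_tail

        lnc_reg = synth_data.mirna_lnc_edges.groupby("target")["mirna"].agg(set)
        mrna_reg = synth_data.mirna_mrna_edges.groupby("target")["mirna"].agg(set)
        n = synth_config.n_mirnas
        for lnc, mrna in synth_data.truth_cerna:
            shared = len(lnc_reg[lnc] & mrna_reg[mrna])
            p = hypergeom_upper_tail(shared, n, len(mrna_reg[mrna]), len(lnc_reg[lnc]))
            assert p < 1e-4

    def test_low_rate_sets_warning_flag(self):
        cfg = small_config(shared_mirna_rate=0.05)
        _, _, meta = generate_interactions(
            cfg, [], ["LNC0001"], ["G00001"], np.random.default_rng(0))
        assert meta["rate_warning"]


class TestDrugNetwork:
    @staticmethod
    def bfs_oracle(edges_drug, edges_ppi, source, targets):
        """Plain BFS over the merged adjacency, other drugs excluded."""
        adj: dict[str, set[str]] = {}
        drugs = set(edges_drug["drug"])
        for a, b in edges_ppi.itertuples(index=False):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for d, g in edges_drug.itertuples(index=False):
            adj.setdefault(d, set()).add(g)
            adj.setdefault(g, set()).add(d)
        dist = {source: 0}
        frontier = [source]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v in dist or (v in drugs and v != source):
                        continue
                    dist[v] = dist[u] + 1
                    nxt.append(v)
            frontier = nxt
        found = [dist[t] for t in targets if t in dist]
        return sum(found) / len(found) if found else None

    def test_near_drugs_short_paths(self, synth_data):
        for drug in synth_data.near_drugs:
            mean = self.bfs_oracle(synth_data.drug_target_edges,
                                   synth_data.ppi_edges, drug,
                                   synth_data.truth_markers)
            assert mean is not None and mean <= 4

    def test_background_drugs_long_paths(self, synth_data):
        near = set(synth_data.near_drugs)
        far = set(synth_data.drug_target_edges["drug"]) - near
        for drug in far:
            mean = self.bfs_oracle(synth_data.drug_target_edges,
                                   synth_data.ppi_edges, drug,
                                   synth_data.truth_markers)
            assert mean is not None and mean >= 8

    def test_zero_near_drugs(self):
        cfg = small_config(n_near_drugs=0, n_drugs=5)
        data = generate_dataset(cfg)
        assert data.near_drugs == []
        for drug in set(data.drug_target_edges["drug"]):
            mean = self.bfs_oracle(data.drug_target_edges, data.ppi_edges,
                                   drug, data.truth_markers)
            assert mean >= 8

    def test_direct_edge_gives_path_one(self):
        cfg = small_config()
        drug_df, ppi_df, near = generate_drug_network(
            cfg, ["G00001"], [f"X{i}" for i in range(12)])
        drug_df = pd.concat(
            [drug_df, pd.DataFrame([("DRUGX", "G00001")], columns=["drug", "gene"])],
            ignore_index=True)
        assert self.bfs_oracle(drug_df, ppi_df, "DRUGX", ["G00001"]) == 1

    def test_graph_is_simple_no_drug_drug_edges(self, synth_data):
        drugs = set(synth_data.drug_target_edges["drug"])
        assert not synth_data.drug_target_edges["gene"].isin(drugs).any()
        ppi = synth_data.ppi_edges
        assert not ppi.duplicated().any()
        assert (ppi["gene_a"] != ppi["gene_b"]).all()
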