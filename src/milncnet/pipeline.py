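"""End-to-end orchestration of the discovery pipeline.

Stage order: coexpress -> timecluster -> [enrich] -> cerna -> topology ->
markers -> drugs -> classify.  Each stage writes its outputs under the run
directory and records its counts in a machine-readable manifest; a later
invocation restricted to downstream stages reloads the written artifacts, so
partial runs resume at stage boundaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarker import (accuracy_distributions, diagnosis_labels,
                        prognosis_labels, select_markers)
from .cerna import CeRNANetwork, InteractionTable, build_cerna_network
from .classifier import evaluate, make_splits, train_svm
from .coexpression import (ModuleAssignment, UNASSIGNED, adjacency, detect_modules,
                           lnc_proportion_test, module_eigengenes,
                           module_trait_correlation, pick_soft_threshold,
                           tom_similarity)
from .datasets import ExpressionDataset
from .drugpath import build_drug_gene_graph, rank_drugs
from .enrichment import ora_test, read_gmt
from .io import read_edge_list, read_expression, write_json, write_table
from .timecluster import fuzzy_cmeans, monotone_clusters, standardize_profiles
from .topology import centralities, degree_by_kind, select_hubs

log = logging.getLogger(__name__)

STAGES = ("coexpress", "timecluster", "enrich", "cerna", "topology",
          "markers", "drugs", "classify")

# fixed per-stage seed offsets fanned out from the global seed
_SEED_OFFSETS = {"timecluster": 10, "markers": 20, "splits": 30, "svm": 40}


@dataclass
class PipelineConfig:
    """All pipeline inputs and tunables; unknown keys are rejected on load."""

    outdir: str = "results"
    seed: int = 0
    # input paths (written by `milncnet simulate` or user-supplied)
    expression: str | None = None
    features: str | None = None
    samples: str | None = None
    mirna_mrna: str | None = None
    mirna_lnc: str | None = None
    drug_targets: str | None = None
    ppi: str | None = None
    gmt: str | None = None
    external_expression: str | None = None
    external_features: str | None = None
    external_samples: str | None = None
    # stage tunables (defaults follow the study design)
    beta: int | str = "auto"
    r2_cut: float = 0.85
    min_size: int = 30
    cut_height: float | None = None
    merge_cut: float = 0.25
    trait_significance: float = 1e-4
    n_trend_clusters: int = 12
    fuzzifier: float = 1.25
    fdr_cut: float = 0.01
    cor_cut: float = 0.3
    hub_quantile: float = 0.10
    accuracy_threshold: float = 0.7
    n_folds: int = 10
    kernel: str = "linear"
    c_param: float = 1.0
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for name, lo, hi in (("fdr_cut", 0, 1), ("cor_cut", 0, 1),
                             ("hub_quantile", 0, 1), ("accuracy_threshold", 0, 1.01),
                             ("r2_cut", 0, 1)):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineRun:
    """Executes the configured stages against in-memory or on-disk inputs."""

    def __init__(self, config: PipelineConfig,
                 expr: ExpressionDataset | None = None,
                 external: ExpressionDataset | None = None,
                 mir_mrna: pd.DataFrame | None = None,
                 mir_lnc: pd.DataFrame | None = None,
                 drug_targets: pd.DataFrame | None = None,
                 ppi: pd.DataFrame | None = None):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.expr = expr if expr is not None else self._load_expression()
        self.external = external if external is not None else self._load_external()
        self.mir_mrna = mir_mrna if mir_mrna is not None else self._load_table(config.mirna_mrna)
        self.mir_lnc = mir_lnc if mir_lnc is not None else self._load_table(config.mirna_lnc)
        self.drug_targets = drug_targets if drug_targets is not None \
            else self._load_table(config.drug_targets)
        self.ppi = ppi if ppi is not None else self._load_table(config.ppi)
        self.manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "parameters": {k: v for k, v in asdict(config).items()
                           if not isinstance(v, (list,)) or k == "stages"},
            "stages": {},
        }
        # stage products
        self.modules: ModuleAssignment | None = None
        self.trait_table: pd.DataFrame | None = None
        self.cluster_labels: pd.Series | None = None
        self.cluster_model = None
        self.network: CeRNANetwork | None = None
        self.centrality_table: pd.DataFrame | None = None
        self.hubs: set[str] | None = None
        self.marker_report = None
        self.drug_ranking: pd.DataFrame | None = None
        self.classifier_report: dict | None = None

    # -- input loading -----------------------------------------------------
    def _load_expression(self) -> ExpressionDataset:
        c = self.config
        if not (c.expression and c.features and c.samples):
            raise ValueError("expression/features/samples paths are required")
        return read_expression(c.expression, c.features, c.samples)

    def _load_external(self) -> ExpressionDataset | None:
        c = self.config
        if c.external_expression and c.external_features and c.external_samples:
            return read_expression(c.external_expression, c.external_features,
                                   c.external_samples)
        return None

    @staticmethod
    def _load_table(path) -> pd.DataFrame | None:
        return read_edge_list(path) if path else None

    # -- artifact persistence / resumption ---------------------------------
    def _write(self, name: str, frame: pd.DataFrame, index: bool = False) -> None:
        write_table(frame, self.outdir / name, index=index)

    def _require_modules(self) -> ModuleAssignment:
        if self.modules is None:
            path = self.outdir / "module_assignment.tsv"
            if not path.exists():
                raise RuntimeError("coexpress stage has not run and no artifact found")
            frame = pd.read_csv(path, sep="\t").set_index("feature_id")
            labels = frame["module"]
            mes, ve = module_eigengenes(self.expr, labels)
            self.modules = ModuleAssignment(labels, mes, ve)
            self.trait_table = pd.read_csv(self.outdir / "module_trait.tsv", sep="\t")
        return self.modules

    def _require_clusters(self) -> pd.Series | None:
        if self.cluster_labels is None:
            path = self.outdir / "trend_labels.tsv"
            if path.exists():
                frame = pd.read_csv(path, sep="\t").set_index("feature_id")
                self.cluster_labels = frame["cluster"]
        return self.cluster_labels

    def _require_network(self) -> CeRNANetwork:
        if self.network is None:
            path = self.outdir / "cerna_edges.tsv"
            if not path.exists():
                raise RuntimeError("cerna stage has not run and no artifact found")
            edges = pd.read_csv(path, sep="\t")
            kinds = {f: "lncRNA" for f in edges["lnc_id"]}
            kinds.update({f: "mRNA" for f in edges["mrna_id"]})
            self.network = CeRNANetwork(edges=edges, candidates=edges,
                                        node_kind=kinds)
        return self.network

    def _require_markers(self) -> list[str]:
        if self.marker_report is None:
            path = self.outdir / "final_markers.tsv"
            if not path.exists():
                raise RuntimeError("markers stage has not run and no artifact found")
            return pd.read_csv(path, sep="\t")["feature_id"].tolist()
        return self.marker_report.final_markers

    # -- stages ------------------------------------------------------------
    def stage_coexpress(self) -> None:
        c = self.config
        if c.beta == "auto":
            power_table, beta = pick_soft_threshold(self.expr, r2_cut=c.r2_cut)
            self._write("soft_threshold.tsv", power_table)
        else:
            beta = int(c.beta)
        adj = adjacency(self.expr, beta)
        tom = tom_similarity(adj)
        dissim = 1.0 - tom
        self.modules = detect_modules(dissim, self.expr, min_size=c.min_size,
                                      cut_height=c.cut_height, merge_cut=c.merge_cut)
        groups_present = sorted(self.expr.group.unique())
        self.trait_table = module_trait_correlation(
            self.modules.eigengenes, self.expr.group, groups_present,
            significance=c.trait_significance,
        ) if len(self.modules.eigengenes.columns) else pd.DataFrame(
            columns=["module", "trait", "r", "p", "significant"])

        assignment = self.modules.module_of.rename("module").rename_axis("feature_id")
        self._write("module_assignment.tsv", assignment.reset_index())
        self._write("module_eigengenes.tsv",
                    self.modules.eigengenes.rename_axis("sample_id"), index=True)
        self._write("module_trait.tsv", self.trait_table)

        counts = []
        biotype = self.expr.biotype
        for mod in self.modules.modules:
            members = assignment.index[assignment == mod]
            counts.append((mod, int((biotype[members] == "lncRNA").sum()),
                           int((biotype[members] == "coding").sum())))
        if counts:
            count_frame = pd.DataFrame(counts, columns=["tag", "lnc_count", "pcg_count"])
            n_lnc = int((biotype == "lncRNA").sum())
            n_pcg = int((biotype == "coding").sum())
            proportion = lnc_proportion_test(count_frame, background_lnc=n_lnc,
                                             background_pcg=n_pcg)
            self._write("lnc_proportion.tsv", proportion)
        self.manifest["stages"]["coexpress"] = {
            "beta": int(beta),
            "n_modules": len(self.modules.modules),
            "module_sizes": {k: int(v) for k, v in
                             self.modules.module_sizes.items()},
            "n_unassigned": int((self.modules.module_of == UNASSIGNED).sum()),
        }

    def stage_timecluster(self) -> None:
        c = self.config
        stages = [g for g in ("MI_S1", "MI_S2", "MI_S3", "MI_S4")
                  if g in set(self.expr.group)]
        profiles = standardize_profiles(self.expr, stages)
        self.cluster_model, self.cluster_labels = fuzzy_cmeans(
            profiles, c=c.n_trend_clusters, m=c.fuzzifier,
            seed=c.seed + _SEED_OFFSETS["timecluster"],
        )
        self._write("trend_labels.tsv",
                    self.cluster_labels.rename("cluster")
                    .rename_axis("feature_id").reset_index())
        self._write("trend_centroids.tsv",
                    pd.DataFrame(self.cluster_model.cluster_centers_,
                                 columns=stages,
                                 index=[f"Cluster{k + 1}" for k in
                                        range(c.n_trend_clusters)])
                    .rename_axis("cluster"), index=True)
        membership = pd.DataFrame(
            self.cluster_model.membership_, index=profiles.index,
            columns=[f"Cluster{k + 1}" for k in range(c.n_trend_clusters)],
        )
        self._write("trend_membership.tsv",
                    membership.rename_axis("feature_id"), index=True)
        self.manifest["stages"]["timecluster"] = {
            "n_clusters": c.n_trend_clusters,
            "n_features": int(len(profiles)),
            "monotone_clusters": monotone_clusters(self.cluster_model),
        }

    def stage_enrich(self) -> None:
        if not self.config.gmt:
            self.manifest["stages"]["enrich"] = {"skipped": "no GMT collection supplied"}
            log.info("enrich: skipped, no GMT collection supplied")
            return
        modules = self._require_modules()
        collection = read_gmt(self.config.gmt)
        universe = self.expr.feature_ids
        results = []
        for mod in modules.modules:
            query = modules.module_of.index[modules.module_of == mod]
            table = ora_test(query, collection, universe)
            table.insert(0, "module", mod)
            results.append(table)
        enrich = pd.concat(results, ignore_index=True)
        self._write("enrichment.tsv", enrich)
        self.manifest["stages"]["enrich"] = {
            "n_sets": len(collection),
            "n_significant": int((enrich["fdr"] < 0.01).sum()),
        }

    def _mi_contexts(self) -> list[str]:
        modules = self._require_modules()
        sig = self.trait_table[self.trait_table["significant"]]
        contexts = sorted(set(sig["module"]))
        clusters = self._require_clusters()
        if clusters is not None:
            if self.cluster_model is not None:
                contexts += monotone_clusters(self.cluster_model)
            else:
                path = self.outdir / "trend_centroids.tsv"
                if path.exists():
                    centroids = pd.read_csv(path, sep="\t", index_col=0)
                    for label, row in centroids.iterrows():
                        diffs = np.diff(row.to_numpy())
                        if (diffs > 0).all() or (diffs < 0).all():
                            contexts.append(label)
        return contexts

    def stage_cerna(self) -> None:
        c = self.config
        if self.mir_lnc is None or self.mir_mrna is None:
            raise ValueError("cerna stage requires both miRNA interaction tables")
        contexts = self._mi_contexts()
        self.network = build_cerna_network(
            self._require_modules(), self._require_clusters(), contexts,
            self.expr,
            InteractionTable(self.mir_lnc.rename(
                columns=dict(zip(self.mir_lnc.columns[:2], ["mirna", "target"]))),
                "lncRNA"),
            InteractionTable(self.mir_mrna.rename(
                columns=dict(zip(self.mir_mrna.columns[:2], ["mirna", "target"]))),
                "mRNA"),
            fdr_cut=c.fdr_cut, cor_cut=c.cor_cut,
        )
        self._write("cerna_edges.tsv", self.network.edges)
        self._write("cerna_candidates.tsv", self.network.candidates)
        self.manifest["stages"]["cerna"] = {
            "contexts": contexts,
            "n_candidates": int(len(self.network.candidates)),
            "n_edges": int(len(self.network)),
            "n_lncrnas": len(self.network.lnc_ids),
            "n_mrnas": len(self.network.mrna_ids),
        }

    def stage_topology(self) -> None:
        network = self._require_network()
        if len(network) == 0:
            raise RuntimeError("topology stage requires a nonempty ceRNA network")
        graph = network.graph()
        self.centrality_table = centralities(graph)
        self.hubs = select_hubs(self.centrality_table, q=self.config.hub_quantile)
        self._write("centralities.tsv",
                    self.centrality_table.rename_axis("node_id"), index=True)
        self._write("hubs.tsv", pd.DataFrame({"node_id": sorted(self.hubs)}))
        self.manifest["stages"]["topology"] = {
            "n_nodes": int(len(self.centrality_table)),
            "n_hubs": len(self.hubs),
            "degree_by_kind": degree_by_kind(self.centrality_table),
        }

    def stage_markers(self) -> None:
        c = self.config
        network = self._require_network()
        if self.hubs is None:
            hub_path = self.outdir / "hubs.tsv"
            if not hub_path.exists():
                raise RuntimeError("markers stage requires the topology stage")
            self.hubs = set(pd.read_csv(hub_path, sep="\t")["node_id"])
        labels = {
            "diagnosis": diagnosis_labels(self.expr),
            "prognosis": prognosis_labels(self.expr),
        }
        records = accuracy_distributions(
            network, self.expr, labels, n_folds=c.n_folds,
            seed=c.seed + _SEED_OFFSETS["markers"],
        )
        self.marker_report = select_markers(records, self.hubs,
                                            threshold=c.accuracy_threshold)
        self._write("accuracy_records.tsv", records)
        self._write("marker_candidates.tsv", self.marker_report.candidates)
        self._write("final_markers.tsv",
                    pd.DataFrame({"feature_id": self.marker_report.final_markers}))
        means = records.groupby(["unit_kind", "task"])["accuracy"].mean()
        self.manifest["stages"]["markers"] = {
            "n_units": int(records["unit_id"].nunique()),
            "n_candidates": int(len(self.marker_report.candidates)),
            "final_markers": self.marker_report.final_markers,
            "mean_accuracy": {f"{k[0]}/{k[1]}": round(float(v), 4)
                              for k, v in means.items()},
        }

    def stage_drugs(self) -> None:
        if self.drug_targets is None or self.ppi is None:
            raise ValueError("drugs stage requires drug-target and PPI edge tables")
        markers = self._require_markers()
        genes = [m for m in markers]
        graph = build_drug_gene_graph(self.drug_targets, self.ppi)
        self.drug_ranking = rank_drugs(graph, genes)
        self._write("drug_ranking.tsv", self.drug_ranking)
        ranked = self.drug_ranking[self.drug_ranking["n_reachable"] > 0]
        self.manifest["stages"]["drugs"] = {
            "n_drugs_ranked": int(len(ranked)),
            "best_drug": (ranked["drug"].iloc[0] if len(ranked) else None),
            "best_mean_path": (float(ranked["mean_path"].iloc[0])
                               if len(ranked) else None),
        }

    def stage_classify(self) -> None:
        c = self.config
        markers = self._require_markers()
        if not markers:
            raise RuntimeError("classify stage requires a nonempty marker set")
        splits = make_splits(self.expr, self.external,
                             seed=c.seed + _SEED_OFFSETS["splits"])
        model, cv_auc = train_svm(self.expr, splits, markers, kernel=c.kernel,
                                  c_param=c.c_param, n_folds=c.n_folds,
                                  seed=c.seed + _SEED_OFFSETS["svm"])
        report: dict[str, dict] = {"cv_auc": cv_auc}
        for name, labels in splits.labels.items():
            data = self.expr if not name.startswith("validation") else self.external
            entry = evaluate(model, data, labels)
            if entry["roc"] is not None:
                self._write(f"roc_{name}.tsv", entry["roc"])
            report[name] = {"auc": entry["auc"], "accuracy": entry["accuracy"]}
        self.classifier_report = report
        write_json(report, self.outdir / "classifier_report.json")
        self.manifest["stages"]["classify"] = {
            "markers": markers,
            "cv_auc": round(cv_auc, 4),
            "splits": {k: v for k, v in report.items() if k != "cv_auc"},
        }

    # -- driver ------------------------------------------------------------
    def run(self) -> dict:
        runners = {
            "coexpress": self.stage_coexpress,
            "timecluster": self.stage_timecluster,
            "enrich": self.stage_enrich,
            "cerna": self.stage_cerna,
            "topology": self.stage_topology,
            "markers": self.stage_markers,
            "drugs": self.stage_drugs,
            "classify": self.stage_classify,
        }
        for stage in STAGES:
            if stage not in self.config.stages:
                log.info("stage %s skipped by configuration", stage)
                continue
            try:
                runners[stage]()
            except Exception:
                log.error("stage %s failed; earlier artifacts are intact", stage)
                raise
        write_json(self.manifest, self.outdir / "manifest.json")
        return self.manifest


def run_pipeline(config: PipelineConfig, **inputs) -> dict:
    """Run the configured stages; returns the manifest (also written to disk)."""
    return PipelineRun(config, **inputs).run()
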