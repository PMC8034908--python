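"""ceRNA network inference: lncRNA-mRNA pairs competing for shared miRNAs.

A lncRNA-mRNA pair enters the network when three conditions hold jointly:
(1) the miRNAs shared by the pair are enriched beyond chance (hypergeometric
    test, BH FDR below ``fdr_cut``),
(2) the pair co-occurs in a disease-associated co-expression module or in the
    same temporal expression pattern (the "context"), and
(3) their expression correlation over all samples exceeds ``cor_cut``
    (positive, as competing-endogenous regulation implies co-expression).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .coexpression import UNASSIGNED, ModuleAssignment
from .datasets import ExpressionDataset
from .stats import bh_adjust, hypergeom_upper_tail

__all__ = ["InteractionTable", "CeRNANetwork", "shared_mirna_test", "build_cerna_network"]

log = logging.getLogger(__name__)


@dataclass
class InteractionTable:
    """Unique miRNA->target interactions for one target kind."""

    edges: pd.DataFrame  # columns: mirna, target
    target_kind: str  # "mRNA" | "lncRNA"

    def __post_init__(self) -> None:
        required = {"mirna", "target"}
        if not required.issubset(self.edges.columns):
            raise ValueError("interaction table needs columns ['mirna', 'target']")
        self.edges = self.edges[["mirna", "target"]].drop_duplicates(ignore_index=True)
        if (self.edges["mirna"] == self.edges["target"]).any():
            raise ValueError("self-loop in interaction table")

    @property
    def mirna_universe(self) -> set[str]:
        return set(self.edges["mirna"])

    def regulators(self) -> dict[str, set[str]]:
        return {
            t: set(g["mirna"]) for t, g in self.edges.groupby("target", sort=True)
        }


@dataclass
class CeRNANetwork:
    """Bipartite lncRNA-mRNA network with shared-miRNA statistics per edge."""

    edges: pd.DataFrame  # lnc_id, mrna_id, shared, lnc_degree, mrna_degree,
    #                      universe, p, fdr, correlation, context
    candidates: pd.DataFrame  # pre-filter candidate table (same columns)
    node_kind: dict[str, str] = field(default_factory=dict)

    @property
    def lnc_ids(self) -> list[str]:
        return sorted(set(self.edges["lnc_id"]))

    @property
    def mrna_ids(self) -> list[str]:
        return sorted(set(self.edges["mrna_id"]))

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["lnc_id"]) | set(self.edges["mrna_id"]))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, kind=self.node_kind.get(node, "unknown"))
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.lnc_id, row.mrna_id, correlation=row.correlation,
                       shared=row.shared, fdr=row.fdr)
        return g

    def __len__(self) -> int:
        return len(self.edges)


def shared_mirna_test(lnc_id: str, mrna_id: str, mir_lnc: InteractionTable,
                      mir_mrna: InteractionTable,
                      universe: set[str] | None = None) -> tuple[int, float]:
    """Shared-miRNA count and hypergeometric upper-tail p for one pair.

    The urn is the union of miRNAs in both tables (size N); the mRNA's
    regulators are the K successes and the lncRNA's regulators the n draws.
    """
    lnc_reg = set(mir_lnc.edges.loc[mir_lnc.edges["target"] == lnc_id, "mirna"])
    mrna_reg = set(mir_mrna.edges.loc[mir_mrna.edges["target"] == mrna_id, "mirna"])
    if not lnc_reg or not mrna_reg:
        raise ValueError(f"pair ({lnc_id}, {mrna_id}) has a regulator-free endpoint")
    if universe is None:
        universe = mir_lnc.mirna_universe | mir_mrna.mirna_universe
    shared = len(lnc_reg & mrna_reg)
    p = hypergeom_upper_tail(shared, len(universe), len(mrna_reg), len(lnc_reg))
    return shared, p


def _context_map(modules: ModuleAssignment | None,
                 cluster_labels: pd.Series | None,
                 mi_contexts: list[str]) -> dict[str, set[str]]:
    contexts: dict[str, set[str]] = {}
    wanted = set(mi_contexts)
    if modules is not None:
        for feat, mod in modules.module_of.items():
            if mod != UNASSIGNED and mod in wanted:
                contexts.setdefault(feat, set()).add(mod)
    if cluster_labels is not None:
        for feat, lab in cluster_labels.items():
            if lab in wanted:
                contexts.setdefault(feat, set()).add(lab)
    return contexts


def build_cerna_network(modules: ModuleAssignment | None,
                        cluster_labels: pd.Series | None,
                        mi_contexts: list[str],
                        expr: ExpressionDataset,
                        mir_lnc: InteractionTable,
                        mir_mrna: InteractionTable,
                        fdr_cut: float = 0.01,
                        cor_cut: float = 0.3,
                        absolute_correlation: bool = False) -> CeRNANetwork:
    """Assemble the ceRNA network from contexts, sharing statistics and correlation.

    Candidate pairs are every (lncRNA, mRNA) co-occurring in one of the
    ``mi_contexts`` (disease modules and/or trend clusters); the BH FDR is
    computed across all candidates; retained edges satisfy fdr < ``fdr_cut``
    and correlation > ``cor_cut``.
    """
    if not mi_contexts:
        raise ValueError("mi_contexts must be nonempty")
    contexts = _context_map(modules, cluster_labels, mi_contexts)
    lnc_reg = mir_lnc.regulators()
    mrna_reg = mir_mrna.regulators()
    universe = mir_lnc.mirna_universe | mir_mrna.mirna_universe
    n_univ = len(universe)

    biotype = expr.biotype
    in_expr = set(expr.feature_ids)
    lncs = sorted(f for f in contexts if f in in_expr and biotype.get(f) == "lncRNA")
    mrnas = sorted(f for f in contexts if f in in_expr and biotype.get(f) == "coding")

    skipped = 0
    rows = []
    seen = set()
    for lnc in lncs:
        lr = lnc_reg.get(lnc)
        if not lr:
            skipped += 1
            continue
        for mrna in mrnas:
            shared_ctx = contexts[lnc] & contexts[mrna]
            if not shared_ctx or (lnc, mrna) in seen:
                continue
            mr = mrna_reg.get(mrna)
            if not mr:
                skipped += 1
                continue
            seen.add((lnc, mrna))
            k = len(lr & mr)
            p = hypergeom_upper_tail(k, n_univ, len(mr), len(lr))
            rows.append(
                (lnc, mrna, k, len(lr), len(mr), n_univ, p,
                 "|".join(sorted(shared_ctx)))
            )
    if skipped:
        log.info("build_cerna_network: skipped %d regulator-free endpoints/pairs", skipped)

    candidates = pd.DataFrame(
        rows, columns=["lnc_id", "mrna_id", "shared", "lnc_degree",
                       "mrna_degree", "universe", "p", "context"],
    )
    if candidates.empty:
        warnings.warn("no candidate ceRNA pairs in the given contexts", stacklevel=2)
        empty = candidates.assign(fdr=[], correlation=[])
        return CeRNANetwork(edges=empty, candidates=empty)

    candidates["fdr"] = bh_adjust(candidates["p"].to_numpy())
    values = expr.values
    cors = []
    for row in candidates.itertuples(index=False):
        c = float(np.corrcoef(values.loc[row.lnc_id], values.loc[row.mrna_id])[0, 1])
        cors.append(c)
    candidates["correlation"] = cors

    cor_stat = candidates["correlation"].abs() if absolute_correlation \
        else candidates["correlation"]
    kept = candidates[(candidates["fdr"] < fdr_cut) & (cor_stat > cor_cut)]
    kept = kept.sort_values(["lnc_id", "mrna_id"], ignore_index=True)

    # every retained pair satisfies all three conditions simultaneously
    assert (kept["fdr"] < fdr_cut).all()
    assert ((kept["correlation"].abs() if absolute_correlation
             else kept["correlation"]) > cor_cut).all()
    assert kept["context"].str.len().gt(0).all()

    if kept.empty:
        warnings.warn("no ceRNA pair survived the FDR/correlation filters",
                      stacklevel=2)
    node_kind = {f: "lncRNA" for f in kept["lnc_id"]}
    node_kind.update({f: "mRNA" for f in kept["mrna_id"]})
    return CeRNANetwork(edges=kept, candidates=candidates, node_kind=node_kind)
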