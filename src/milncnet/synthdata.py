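"""Synthetic study generator with planted ground truth for every pipeline stage.

The generator emulates the shape of a PBMC time-course myocardial-infarction
cohort: 46 stable-CAD controls and 73 MI patients sampled at four stages
(admission, discharge, 1 month, 6 months), over a feature universe of coding
genes and lncRNAs (scaled down from the ~14k genes / ~1.1k lncRNAs of a full
array platform).  Planted structure:

* co-expression modules from a latent-factor Gaussian model
  x = sqrt(rho) * f + sqrt(1 - rho) * eps + noise_sd * eta,
  whose factor is mean-shifted in the module's associated sample group;
* 12 temporal trend archetypes (piecewise-linear 4-point templates) written
  into disjoint feature blocks of the MI samples;
* ceRNA lncRNA-mRNA pairs that share significantly many miRNA regulators,
  arranged so that two nodes (one lncRNA, one mRNA) are clear network hubs;
* marker features with a class-separating shift (MI vs CAD, HF vs noHF);
* a drug-gene graph in which designated "near" drugs sit a short path from
  the markers and background drugs sit far away.

All randomness flows from one seeded numpy Generator; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import GROUPS, ExpressionDataset, SyntheticDataset

__all__ = [
    "SynthConfig",
    "TREND_TEMPLATES",
    "generate_dataset",
    "generate_external_dataset",
    "generate_interactions",
    "generate_drug_network",
]

MI_STAGES = ("MI_S1", "MI_S2", "MI_S3", "MI_S4")


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def _trend_templates(n: int) -> np.ndarray:
    """n piecewise-linear 4-point archetypes, each standardized to mean 0, sd 1.

    The first twelve are the qualitative families seen in staged-MI time
    courses: monotone up/down, early/mid/late steps, transient peaks and dips.
    """
    raw = [
        (1, 2, 3, 4),  # monotone up
        (4, 3, 2, 1),  # monotone down
        (0, 1, 1, 1),  # early step up
        (1, 0, 0, 0),  # early step down
        (0, 0, 1, 1),  # mid step up
        (1, 1, 0, 0),  # mid step down
        (0, 0, 0, 1),  # late step up
        (1, 1, 1, 0),  # late step down
        (0, 1, 0, 0),  # transient peak at stage 2
        (1, 0, 1, 1),  # transient dip at stage 2
        (0, 0, 1, 0),  # transient peak at stage 3
        (1, 1, 0, 1),  # transient dip at stage 3
    ]
    if n > len(raw):
        raise ValueError(f"at most {len(raw)} trend archetypes available, requested {n}")
    return np.array([_standardize(np.asarray(r, float)) for r in raw[:n]])


TREND_TEMPLATES = _trend_templates(12)


@dataclass
class SynthConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Sample sizes follow the emulated cohort (46 CAD controls, 73 MI patients
    with complete four-stage profiles, plus a 28 MI / 14 CAD external cohort,
    see :func:`generate_external_dataset`).  Feature counts are a scaled-down
    universe; effect sizes and noise levels are calibrated for testability,
    not measured from any real cohort.
    """

    n_genes: int = 600
    n_lncrnas: int = 80
    n_modules: int = 5
    module_sizes: list[int] | None = None  # default [60] * n_modules
    samples_per_group: dict[str, int] | None = None  # default CAD=46, MI_S*=73
    module_trait_map: dict[str, str] | None = None  # module -> associated group
    within_module_cor: float = 0.75
    noise_sd: float = 0.25
    trait_shift: float = 1.5
    n_trend_clusters: int = 12
    trend_features_per_cluster: int = 25
    trend_amplitude: float = 1.5
    n_mirnas: int = 150
    cerna_pairs: int = 20
    shared_mirna_rate: float = 0.9
    lnc_mirna_degree: int = 30
    mrna_mirna_degree: int = 10
    marker_effect: float = 2.0
    hf_fraction: float = 0.3
    n_drugs: int = 20
    n_near_drugs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [60] * self.n_modules
        if self.samples_per_group is None:
            self.samples_per_group = {"CAD": 46, **{s: 73 for s in MI_STAGES}}
        if self.module_trait_map is None:
            default_traits = ["MI_S1", "CAD", "MI_S1", "CAD", "MI_S2"]
            self.module_trait_map = {
                f"M{j + 1}": default_traits[j % len(default_traits)]
                for j in range(self.n_modules)
            }
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_lncrnas": self.n_lncrnas,
            "n_modules": self.n_modules,
            "n_trend_clusters": self.n_trend_clusters,
            "n_mirnas": self.n_mirnas,
            "n_drugs": self.n_drugs,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"invalid config: {name} must be positive, got {value}")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("invalid config: module_sizes length must equal n_modules")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("invalid config: module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes + self.n_lncrnas:
            raise ValueError(
                "invalid config: sum of module_sizes exceeds n_genes + n_lncrnas"
            )
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("invalid config: within_module_cor must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("invalid config: noise_sd must be nonnegative")
        for g, c in self.samples_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"invalid config: unknown group {g!r}")
            if c <= 0:
                raise ValueError(f"invalid config: sample count for {g} must be positive")
        for mod, grp in self.module_trait_map.items():
            if grp not in self.samples_per_group:
                raise ValueError(
                    f"invalid config: module {mod} mapped to absent group {grp!r}"
                )
        if not 0.0 <= self.shared_mirna_rate <= 1.0:
            raise ValueError("invalid config: shared_mirna_rate must lie in [0, 1]")
        if not 0.0 <= self.hf_fraction <= 1.0:
            raise ValueError("invalid config: hf_fraction must lie in [0, 1]")
        if self.n_near_drugs > self.n_drugs:
            raise ValueError("invalid config: n_near_drugs exceeds n_drugs")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# feature / sample bookkeeping


def _feature_ids(config: SynthConfig) -> tuple[list[str], list[str]]:
    lncs = [f"LNC{i + 1:04d}" for i in range(config.n_lncrnas)]
    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    return lncs, genes


def _sample_frame(samples_per_group: dict[str, int]) -> pd.DataFrame:
    """Sample ids with group and patient columns; MI patients recur across stages."""
    rows = []
    for group in GROUPS:
        if group not in samples_per_group:
            continue
        n = samples_per_group[group]
        for i in range(n):
            if group == "CAD":
                rows.append((f"CAD_{i + 1:03d}", group, f"C{i + 1:03d}"))
            else:
                rows.append((f"{group}_P{i + 1:03d}", group, f"P{i + 1:03d}"))
    frame = pd.DataFrame(rows, columns=["sample", "group", "patient"])
    return frame.set_index("sample")


def _plan_modules(config: SynthConfig, lncs: list[str], genes: list[str]):
    """Assign lncRNAs and genes to modules; ~15% of each module is lncRNA."""
    members: dict[str, list[str]] = {}
    li, gi = 0, 0
    for j, size in enumerate(config.module_sizes):
        n_lnc = min(max(1, round(0.15 * size)), config.n_lncrnas - li)
        n_gene = size - n_lnc
        if gi + n_gene > len(genes):
            raise ValueError(
                "invalid config: module_sizes require more coding genes than n_genes"
            )
        mod = f"M{j + 1}"
        members[mod] = lncs[li : li + n_lnc] + genes[gi : gi + n_gene]
        li += n_lnc
        gi += n_gene
    return members, lncs[li:], genes[gi:]


def _plan_cerna(config: SynthConfig, module_members: dict[str, list[str]],
                biotype: pd.Series):
    """Choose planted ceRNA pairs inside the first module, one connected graph.

    The planted network is a connected double star with leaf decorations: the
    first lncRNA (hub) pairs with many mRNAs, the first mRNA (hub) pairs with
    several lncRNAs, and the remaining lncRNAs hang as leaves off the outer
    star mRNAs.  The two hub nodes dominate all four centralities of the
    resulting graph and are the planted markers.  Extra requested pairs extend
    the lncRNA hub's star.
    """
    mods = sorted(module_members)
    mem = module_members[mods[0]]
    lncs = [f for f in mem if biotype[f] == "lncRNA"]
    genes = [f for f in mem if biotype[f] == "coding"]
    if len(lncs) < 5 or len(genes) < 12:
        raise ValueError(
            "invalid config: the first module needs >= 5 lncRNAs and >= 12 "
            "coding genes to host the planted ceRNA graph"
        )
    hub_lnc, hub_mrna = lncs[0], genes[0]
    pairs: list[tuple[str, str]] = [(hub_lnc, m) for m in genes[:12]]
    pairs += [(l, hub_mrna) for l in lncs[1:5]]
    leaf_lncs = lncs[5:]
    for i, leaf in enumerate(leaf_lncs):
        if len(pairs) >= config.cerna_pairs:
            break
        pairs.append((leaf, genes[1 + (i % 4)]))
    extra = genes[12:]
    while len(pairs) < config.cerna_pairs and extra:
        pairs.append((hub_lnc, extra.pop(0)))
    return pairs[: max(config.cerna_pairs, 16)], [hub_lnc, hub_mrna]


# ---------------------------------------------------------------------------
# expression


def _build_expression(config: SynthConfig, sample_frame: pd.DataFrame,
                      module_members: dict[str, list[str]],
                      trend_members: dict[int, list[str]],
                      markers: list[str],
                      feature_order: list[str],
                      prognosis: pd.Series,
                      rng: np.random.Generator) -> pd.DataFrame:
    n_samples = len(sample_frame)
    groups = sample_frame["group"].to_numpy()
    feat_index = {f: i for i, f in enumerate(feature_order)}
    x = rng.normal(size=(len(feature_order), n_samples))  # eps for everyone

    rho = config.within_module_cor
    templates = _trend_templates(config.n_trend_clusters)
    stage_of = {s: k for k, s in enumerate(MI_STAGES)}

    # modules: shared factor with group-associated mean shift
    for mod in sorted(module_members):
        factor = rng.normal(size=n_samples)
        trait = config.module_trait_map.get(mod)
        if trait is not None:
            factor = factor + config.trait_shift * (groups == trait)
        rows = [feat_index[f] for f in module_members[mod]]
        x[rows, :] = (
            np.sqrt(rho) * factor[None, :]
            + np.sqrt(1.0 - rho) * x[rows, :]
            + config.noise_sd * rng.normal(size=(len(rows), n_samples))
        )

    # trends: archetype template written into MI samples
    stage_idx = np.array([stage_of.get(g, -1) for g in groups])
    for cluster in sorted(trend_members):
        rows = [feat_index[f] for f in trend_members[cluster]]
        profile = np.zeros(n_samples)
        mi = stage_idx >= 0
        profile[mi] = config.trend_amplitude * templates[cluster][stage_idx[mi]]
        x[rows, :] += profile[None, :]

    # markers: diagnostic (MI vs CAD) and prognostic (HF vs noHF) shifts
    is_mi = np.array([g != "CAD" for g in groups])
    z_diag = np.where(is_mi, 0.5, -0.5)
    hf = sample_frame.index.map(prognosis).to_numpy(dtype=object)
    z_prog = np.where(hf == "HF", 0.5, np.where(hf == "noHF", -0.5, 0.0))
    for f in markers:
        x[feat_index[f], :] += config.marker_effect * (z_diag + z_prog)

    return pd.DataFrame(x, index=feature_order, columns=sample_frame.index)


def _prognosis_labels(sample_frame: pd.DataFrame, hf_fraction: float,
                      rng: np.random.Generator) -> pd.Series:
    mi = sample_frame[sample_frame["group"] != "CAD"]
    patients = sorted(mi["patient"].unique())
    n_hf = int(round(hf_fraction * len(patients)))
    hf_patients = set(rng.permutation(patients)[:n_hf])
    labels = mi["patient"].map(lambda p: "HF" if p in hf_patients else "noHF")
    return labels.rename("prognosis")


# ---------------------------------------------------------------------------
# miRNA interaction tables


def generate_interactions(config: SynthConfig, truth_cerna: list[tuple[str, str]],
                          lnc_ids: list[str], mrna_ids: list[str],
                          rng: np.random.Generator | None = None):
    """miRNA->lncRNA and miRNA->mRNA edge tables with planted shared regulators.

    Every feature gets a random base regulator set; each planted ceRNA pair is
    then forced to share ``round(shared_mirna_rate * min(base degrees))``
    miRNAs.  The endpoint with fewer planted pairs is the one modified, so a
    hub node keeps its own regulator set and partners converge onto it; shared
    miRNAs are protected from later replacement.  Returns
    (mirna_mrna_edges, mirna_lnc_edges, metadata).
    """
    if config.n_mirnas < 10:
        raise ValueError("miRNA universe must contain at least 10 miRNAs")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    mirnas = [f"MIR{i + 1:03d}" for i in range(config.n_mirnas)]

    def base_set(deg: int) -> set[str]:
        deg = min(deg, config.n_mirnas)
        return set(rng.choice(mirnas, size=deg, replace=False))

    sets: dict[str, set[str]] = {}
    for l in lnc_ids:
        sets[l] = base_set(config.lnc_mirna_degree)
    for m in mrna_ids:
        sets[m] = base_set(config.mrna_mirna_degree)

    pair_count: dict[str, int] = {}
    for l, m in truth_cerna:
        pair_count[l] = pair_count.get(l, 0) + 1
        pair_count[m] = pair_count.get(m, 0) + 1

    protected: dict[str, set[str]] = {f: set() for f in sets}
    base_l = min(config.lnc_mirna_degree, config.n_mirnas)
    base_m = min(config.mrna_mirna_degree, config.n_mirnas)
    target = int(round(config.shared_mirna_rate * min(base_l, base_m)))
    target = max(target, 1)  # every planted pair shares at least one miRNA

    for l, m in truth_cerna:
        if l not in sets or m not in sets:
            raise ValueError(f"planted pair ({l}, {m}) outside the feature universe")
        # modify the endpoint engaged in fewer planted pairs (ties: the mRNA)
        if pair_count[l] < pair_count[m]:
            recv, donor = l, m
        else:
            recv, donor = m, l
        shared = sets[recv] & sets[donor]
        need = target - len(shared)
        addable = sorted(sets[donor] - sets[recv])
        rng.shuffle(addable)
        droppable = sorted(sets[recv] - protected[recv] - sets[donor])
        rng.shuffle(droppable)
        for mir in addable[:max(need, 0)]:
            if droppable:
                sets[recv].discard(droppable.pop())
            sets[recv].add(mir)
        shared = sets[recv] & sets[donor]
        protected[recv] |= shared
        protected[donor] |= shared

    def edge_frame(ids: list[str]) -> pd.DataFrame:
        rows = [(mir, f) for f in ids for mir in sorted(sets[f])]
        return pd.DataFrame(rows, columns=["mirna", "target"]).drop_duplicates(
            ignore_index=True
        )

    background_rate = base_l / config.n_mirnas
    metadata = {
        "shared_target": target,
        "background_rate": background_rate,
        "rate_warning": config.shared_mirna_rate <= background_rate,
    }
    return edge_frame(mrna_ids), edge_frame(lnc_ids), metadata


# ---------------------------------------------------------------------------
# drug-gene graph


def generate_drug_network(config: SynthConfig, truth_markers: list[str],
                          connector_genes: list[str],
                          rng: np.random.Generator | None = None):
    """Drug->target and gene-gene edge tables with planted path structure.

    A backbone chain of connector genes J0-J1-...-J9 is built, every marker is
    attached to J0, "near" drugs target J2 (average shortest path to every
    marker = 4) and background drugs target J8 (average path = 10).  Remaining
    connector genes hang off the chain as leaves so the graph is not bare.
    Returns (drug_target_edges, ppi_edges, near_drugs).
    """
    if not truth_markers:
        raise ValueError("at least one marker is required")
    chain_len = 10
    if len(connector_genes) < chain_len:
        raise ValueError(f"need at least {chain_len} connector genes")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    chain = connector_genes[:chain_len]
    leaves = connector_genes[chain_len:]
    ppi = [(chain[i], chain[i + 1]) for i in range(chain_len - 1)]
    ppi += [(marker, chain[0]) for marker in sorted(truth_markers)]
    for i, leaf in enumerate(leaves):
        ppi.append((chain[3 + (i % (chain_len - 4))], leaf))

    drugs = [f"DRUG{i + 1:03d}" for i in range(config.n_drugs)]
    near = drugs[: config.n_near_drugs]
    drug_edges = [(d, chain[2]) for d in near]
    drug_edges += [(d, chain[8]) for d in drugs[config.n_near_drugs:]]

    drug_df = pd.DataFrame(drug_edges, columns=["drug", "gene"])
    ppi_df = pd.DataFrame(ppi, columns=["gene_a", "gene_b"]).drop_duplicates(
        ignore_index=True
    )
    return drug_df, ppi_df, near


# ---------------------------------------------------------------------------
# top-level generators


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Generate the full synthetic study (expression + truth + interaction tables)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lncs, genes = _feature_ids(config)
    sample_frame = _sample_frame(config.samples_per_group)

    module_members, free_lncs, free_genes = _plan_modules(config, lncs, genes)
    feature_order = lncs + genes
    biotype = pd.Series(
        ["lncRNA"] * len(lncs) + ["coding"] * len(genes), index=feature_order
    )

    # trend blocks drawn from the unassigned features, a couple of lncRNAs each
    trend_members: dict[int, list[str]] = {}
    li, gi = 0, 0
    for cluster in range(config.n_trend_clusters):
        size = config.trend_features_per_cluster
        n_lnc = min(2, max(0, len(free_lncs) - li - 10))  # keep some pure-noise lncRNAs
        block = free_lncs[li : li + n_lnc]
        li += n_lnc
        n_gene = size - len(block)
        if gi + n_gene > len(free_genes):
            raise ValueError("invalid config: not enough free features for trend clusters")
        block += free_genes[gi : gi + n_gene]
        gi += n_gene
        trend_members[cluster] = block
    noise_features = free_lncs[li:] + free_genes[gi:]

    truth_cerna, markers = _plan_cerna(config, module_members, biotype)
    prognosis = _prognosis_labels(sample_frame, config.hf_fraction, rng)

    values = _build_expression(
        config, sample_frame, module_members, trend_members, markers,
        feature_order, prognosis, rng,
    )
    expression = ExpressionDataset(
        values=values,
        biotype=biotype,
        group=sample_frame["group"],
        prognosis=prognosis,
    )

    lnc_universe = sorted(lncs)
    mrna_universe = sorted(genes)
    mir_mrna, mir_lnc, meta = generate_interactions(
        config, truth_cerna, lnc_universe, mrna_universe,
        rng=np.random.default_rng(config.seed + 1),
    )
    drug_edges, ppi_edges, near_drugs = generate_drug_network(
        config, markers, [g for g in noise_features if biotype[g] == "coding"],
        rng=np.random.default_rng(config.seed + 2),
    )

    truth_modules = {f: mod for mod, mem in module_members.items() for f in mem}
    truth_trends = {f: c for c, mem in trend_members.items() for f in mem}
    return SyntheticDataset(
        expression=expression,
        truth_modules=truth_modules,
        truth_trends=truth_trends,
        truth_cerna=truth_cerna,
        truth_markers=markers,
        mirna_mrna_edges=mir_mrna,
        mirna_lnc_edges=mir_lnc,
        drug_target_edges=drug_edges,
        ppi_edges=ppi_edges,
        prognosis_labels=prognosis,
        near_drugs=near_drugs,
        metadata={"interactions": meta, "noise_features": noise_features},
    )


def generate_external_dataset(config: SynthConfig,
                              samples_per_group: dict[str, int] | None = None,
                              seed_offset: int = 1000) -> SyntheticDataset:
    """An external validation cohort sharing the feature universe and effects.

    Defaults emulate the second cohort of the study design: 14 CAD controls and
    28 MI patients profiled at admission, discharge and 6 months.
    """
    if samples_per_group is None:
        samples_per_group = {"CAD": 14, "MI_S1": 28, "MI_S2": 28, "MI_S4": 28}
    ext = config.replace(
        samples_per_group=samples_per_group, seed=config.seed + seed_offset
    )
    return generate_dataset(ext)
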