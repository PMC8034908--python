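"""Core in-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("CAD", "MI_S1", "MI_S2", "MI_S3", "MI_S4")
BIOTYPES = ("coding", "lncRNA")


@dataclass
class ExpressionDataset:
    """Expression matrix (features x samples) with feature and sample annotation.

    values   : DataFrame, rows = feature ids, columns = sample ids.
    biotype  : Series over features, values in {"coding", "lncRNA"}.
    group    : Series over samples, values in GROUPS.
    prognosis: optional Series over (a subset of) samples, values in {"HF", "noHF"};
               only MI samples carry a prognosis label.
    """

    values: pd.DataFrame
    biotype: pd.Series
    group: pd.Series
    prognosis: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.values.isna().any().any():
            rows = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(f"missing expression values in features: {rows[:10]}")
        missing_bio = self.values.index.difference(self.biotype.index)
        if len(missing_bio):
            raise ValueError(f"features without biotype annotation: {missing_bio.tolist()[:10]}")
        self.biotype = self.biotype.reindex(self.values.index)
        bad = set(self.biotype.unique()) - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")
        missing_grp = self.values.columns.difference(self.group.index)
        if len(missing_grp):
            raise ValueError(f"samples without group annotation: {missing_grp.tolist()[:10]}")
        self.group = self.group.reindex(self.values.columns)
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")
        if self.prognosis is not None:
            extra = self.prognosis.index.difference(self.values.columns)
            if len(extra):
                raise ValueError(f"prognosis labels for unknown samples: {extra.tolist()[:10]}")
            bad = set(self.prognosis.dropna().unique()) - {"HF", "noHF"}
            if bad:
                raise ValueError(f"unknown prognosis labels: {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def lnc_ids(self) -> list[str]:
        return self.biotype.index[self.biotype == "lncRNA"].tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.biotype.index[self.biotype == "coding"].tolist()

    def samples_in(self, *groups: str) -> list[str]:
        return self.group.index[self.group.isin(groups)].tolist()

    def subset_features(self, features) -> "ExpressionDataset":
        feats = [f for f in features if f in self.values.index]
        return ExpressionDataset(
            values=self.values.loc[feats],
            biotype=self.biotype.loc[feats],
            group=self.group,
            prognosis=self.prognosis,
        )


@dataclass
class SyntheticDataset:
    """A generated study with full ground truth for every pipeline stage."""

    expression: ExpressionDataset
    truth_modules: dict[str, str]
    truth_trends: dict[str, int]
    truth_cerna: list[tuple[str, str]]
    truth_markers: list[str]
    mirna_mrna_edges: pd.DataFrame
    mirna_lnc_edges: pd.DataFrame
    drug_target_edges: pd.DataFrame
    ppi_edges: pd.DataFrame
    prognosis_labels: pd.Series
    near_drugs: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
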