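"""Readers and writers for all tabular inputs and outputs (TSV/GMT/JSON).

All writers produce deterministic byte-stable output for fixed inputs: rows
keep a fixed sort order and floats are formatted at 6 significant digits,
except p-values which keep full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, SyntheticDataset

__all__ = [
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "write_table",
    "write_json",
    "write_synthetic_inputs",
]

_PVALUE_COLUMNS = {"p", "fdr", "p_adjusted", "p.value"}


def _fmt(value, column: str) -> str:
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        if column in _PVALUE_COLUMNS:
            return repr(float(value))
        return f"{value:.6g}"
    return str(value)


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame = frame.reset_index() if index else frame
    with open(path, "w") as handle:
        handle.write("\t".join(map(str, frame.columns)) + "\n")
        for row in frame.itertuples(index=False):
            handle.write(
                "\t".join(_fmt(v, c) for v, c in zip(row, frame.columns)) + "\n"
            )


def write_json(obj, path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def write_expression(expr: ExpressionDataset, prefix) -> dict[str, Path]:
    """Write matrix + feature/sample annotation next to ``prefix``.

    Produces <prefix>_expression.tsv (feature_id + one column per sample,
    full float precision for lossless round trips), <prefix>_features.tsv
    (feature_id, biotype) and <prefix>_samples.tsv (sample_id, group,
    prognosis).
    """
    prefix = Path(prefix)
    paths = {
        "expression": prefix.parent / f"{prefix.name}_expression.tsv",
        "features": prefix.parent / f"{prefix.name}_features.tsv",
        "samples": prefix.parent / f"{prefix.name}_samples.tsv",
    }
    matrix = expr.values.copy()
    matrix.insert(0, "feature_id", matrix.index)
    with open(paths["expression"], "w") as handle:
        handle.write("\t".join(map(str, matrix.columns)) + "\n")
        for row in matrix.itertuples(index=False):
            handle.write(row[0] + "\t" + "\t".join(repr(float(v)) for v in row[1:]) + "\n")
    write_table(
        pd.DataFrame({"feature_id": expr.feature_ids,
                      "biotype": expr.biotype.to_numpy()}),
        paths["features"],
    )
    prog = (expr.prognosis.reindex(expr.sample_ids).fillna("NA")
            if expr.prognosis is not None else ["NA"] * len(expr.sample_ids))
    write_table(
        pd.DataFrame({"sample_id": expr.sample_ids,
                      "group": expr.group.to_numpy(),
                      "prognosis": list(prog)}),
        paths["samples"],
    )
    return paths


def read_expression(expression_path, features_path, samples_path) -> ExpressionDataset:
    """Read the matrix + annotations written by :func:`write_expression`.

    Errors name duplicated feature ids and any annotation/sample mismatch.
    """
    values = pd.read_csv(expression_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids in {expression_path}: {dup}")
    if values.isna().any().any():
        bad_rows = values.index[values.isna().any(axis=1)].tolist()
        bad_cols = values.columns[values.isna().any(axis=0)].tolist()
        raise ValueError(
            f"missing values in {expression_path}: rows {bad_rows[:5]}, "
            f"columns {bad_cols[:5]}"
        )
    feats = pd.read_csv(features_path, sep="\t").set_index("feature_id")
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    missing = values.columns.difference(samples.index).tolist()
    if missing:
        raise ValueError(f"sample annotation missing samples: {missing}")
    missing = values.index.difference(feats.index).tolist()
    if missing:
        raise ValueError(f"feature annotation missing features: {missing[:10]}")
    prognosis = None
    if "prognosis" in samples.columns:
        prog = samples["prognosis"].replace("NA", np.nan).dropna()
        if len(prog):
            prognosis = prog
    return ExpressionDataset(
        values=values,
        biotype=feats["biotype"],
        group=samples["group"],
        prognosis=prognosis,
    )


def write_edge_list(frame: pd.DataFrame, path) -> None:
    write_table(frame, path)


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_synthetic_inputs(data: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every pipeline input of a synthetic study into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_expression(data.expression, outdir / "study")
    tables = {
        "mirna_mrna": data.mirna_mrna_edges,
        "mirna_lnc": data.mirna_lnc_edges,
        "drug_targets": data.drug_target_edges,
        "ppi": data.ppi_edges,
    }
    for name, frame in tables.items():
        paths[name] = outdir / f"{name}.tsv"
        write_edge_list(frame, paths[name])
    truth = {
        "truth_modules": pd.DataFrame(
            sorted(data.truth_modules.items()), columns=["feature_id", "module"]
        ),
        "truth_trends": pd.DataFrame(
            sorted(data.truth_trends.items()), columns=["feature_id", "trend_cluster"]
        ),
        "truth_cerna": pd.DataFrame(data.truth_cerna, columns=["lnc_id", "mrna_id"]),
        "truth_markers": pd.DataFrame({"feature_id": data.truth_markers}),
    }
    for name, frame in truth.items():
        paths[name] = outdir / f"{name}.tsv"
        write_table(frame, paths[name])
    return paths
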