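"""Readers and writers for the pipeline's plain-text formats.

Expression and Ct matrices are TSV (genes x samples, header row of sample
ids, ``NA`` for missing) with the scale recorded in a ``# scale=...``
comment line; clinical tables are CSV; raw array batches are long-format
TSV; ground truth is JSON; evaluation reports are CSV with percentages to
one decimal plus a human-readable summary. Every writer embeds the seed
and configuration it was produced with, so re-running a command with the
same config reproduces its outputs byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ClinicalTable, ExpressionMatrix, validate_raw_batch
from .evaluate import EvaluationResult
from .synthetic import GroundTruth

__all__ = [
    "RunConfig",
    "load_config",
    "read_expression_table",
    "write_expression_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_raw_batch",
    "write_raw_batch",
    "read_ct_table",
    "write_ct_table",
    "read_ground_truth",
    "write_ground_truth",
    "write_report",
    "format_percent",
]

_SPECIAL_CLINICAL_COLUMNS = ("diagnosis", "activity")


@dataclass
class RunConfig:
    """Stage parameters shared by the CLI commands; echoed into outputs."""

    seed: int = 0
    out_dir: str = "."
    drop_frac: float = 0.75
    alpha: float = 0.05
    k: int = 100
    n_neighbors: int = 5
    rho: float = 0.5
    n_splits: int = 200
    hk_gene: str = "RN18S"
    outlier_sd: float = 3.0
    model: str = "combined"


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _read_table(path, sep):
    comments = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            comments.append(line[1:].strip())
            pos = fh.tell()
            line = fh.readline()
        # check the raw header before pandas mangles duplicate names
        header = line.rstrip("\n").split(sep)
        dups = pd.Index(header[1:])
        dups = dups[dups.duplicated()].unique().tolist()
        if dups:
            raise ValueError(f"duplicate column ids in {path}: {dups}")
        fh.seek(pos)
        df = pd.read_csv(fh, sep=sep, index_col=0, na_values=["NA"])
    df.index.name = None
    return df, comments


def read_expression_table(path) -> ExpressionMatrix:
    """Read a genes x samples TSV; the scale tag is parsed from a leading
    ``# scale=...`` comment (default log2). Duplicate ids and non-numeric
    cells are rejected."""
    df, comments = _read_table(path, "\t")
    scale = "log2"
    for c in comments:
        if c.startswith("scale="):
            scale = c.split("=", 1)[1]
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"non-numeric values in columns {bad} of {path}")
    return ExpressionMatrix(df.astype(float), scale)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", na_rep="NA", index_label="gene")


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct matrix (genes x samples TSV, NA for missing)."""
    df, _ = _read_table(path, "\t")
    return df.astype(float)


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def read_clinical_table(path, known_classes=None) -> ClinicalTable:
    """Read a clinical CSV: sample id index, ``diagnosis`` label column,
    binary attribute columns, optional continuous ``activity``. Attribute
    values other than 0/1 are rejected; with ``known_classes`` given,
    unknown diagnosis labels are rejected too. An ``acr_eular_2010``
    attribute is also exposed as the criteria flag."""
    df, _ = _read_table(path, ",")
    if "diagnosis" not in df.columns:
        raise ValueError(f"{path} lacks a 'diagnosis' column")
    diagnosis = df["diagnosis"].astype(str)
    if known_classes is not None:
        unknown = sorted(set(diagnosis) - set(known_classes))
        if unknown:
            raise ValueError(f"unknown diagnosis labels in {path}: {unknown}")
    activity = None
    if "activity" in df.columns:
        activity = df["activity"].astype(float)
    attr_cols = [c for c in df.columns if c not in _SPECIAL_CLINICAL_COLUMNS]
    attrs = df[attr_cols]
    for c in attr_cols:
        if not attrs[c].dropna().isin([0, 1]).all():
            raise ValueError(f"non-binary value in attribute column {c!r} of {path}")
    attrs = attrs.astype(int)
    flag = attrs["acr_eular_2010"].astype(bool) if "acr_eular_2010" in attrs else None
    return ClinicalTable(attrs, diagnosis, activity=activity, criteria_flag=flag)


def write_clinical_table(table: ClinicalTable, path) -> None:
    out = table.attributes.copy()
    out.insert(0, "diagnosis", table.diagnosis)
    if table.activity is not None:
        out["activity"] = table.activity
    out.to_csv(path, index_label="sample")


def read_raw_batch(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_raw_batch(df)


def write_raw_batch(batch: pd.DataFrame, path) -> None:
    validate_raw_batch(batch)
    batch.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_genes": {c: sorted(g) for c, g in truth.planted_genes.items()},
        "true_sample_bias": truth.true_sample_bias,
        "true_probe_bias": truth.true_probe_bias,
        "outlier_spots": sorted(list(t) for t in truth.outlier_spots),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        planted_genes={c: set(g) for c, g in payload["planted_genes"].items()},
        true_sample_bias=payload["true_sample_bias"],
        true_probe_bias=payload["true_probe_bias"],
        outlier_spots={tuple(t) for t in payload["outlier_spots"]},
    )


def format_percent(x: float) -> str:
    """0.568 -> '56.8'; missing -> 'NA'."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{100.0 * x:.1f}"


def _msd(mean: float, sd: float) -> str:
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return "NA"
    return f"{format_percent(mean)} ± {format_percent(sd)}"


def write_report(results: list[EvaluationResult], path, config: RunConfig | None = None) -> None:
    """Write evaluation results as a model x metric CSV of 'mean ± sd'
    percentages (one decimal), plus a plain-text summary alongside."""
    if not results:
        raise ValueError("no results to report")
    path = Path(path)
    rows = []
    for r in results:
        row = {
            "model": r.model,
            "rho": r.rho,
            "n_neighbors": r.n_neighbors,
            "n_splits": r.n_splits,
            "seed": r.seed,
            "bcr_3class": _msd(r.bcr3_mean, r.bcr3_sd),
            "bcr_2class": _msd(r.bcr2_mean, r.bcr2_sd),
        }
        for c in r.classes:
            row[f"sensitivity_{c}"] = _msd(r.sensitivity.at[c, "mean"], r.sensitivity.at[c, "sd"])
            row[f"ppv_{c}"] = _msd(r.ppv.at[c, "mean"], r.ppv.at[c, "sd"])
        rows.append(row)
    header = [f"# synovclass {__version__}"]
    if config is not None:
        header.append(f"# config: {vars(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    summary = path.with_suffix(".txt")
    with open(summary, "w") as fh:
        for r in results:
            fh.write(
                f"{r.model} (rho={r.rho:g}, k={r.n_neighbors}, "
                f"{r.n_splits} splits, seed={r.seed}): "
                f"3-class BCR {_msd(r.bcr3_mean, r.bcr3_sd)}%, "
                f"2-class BCR {_msd(r.bcr2_mean, r.bcr2_sd)}%\n"
            )
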