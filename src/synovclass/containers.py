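"""Shared tabular containers used across the pipeline.

Expression matrices are genes x samples DataFrames tagged with the scale
their values live on; raw spotted-array data are long-format records of
per-spot foreground/background intensities with a probe role and a
replicate index; clinical tables carry binary symptom attributes, an
optional disease-activity score and the diagnosis label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("raw", "glog", "log2", "delta_ct")

PROBE_ROLES = (
    "diagnostic",
    "housekeeping",
    "internal_standard",
    "hybridization_control",
)
#: roles whose spots enter the additive normalization model
CONTROL_ROLES = ("housekeeping", "internal_standard")

RAW_SPOT_COLUMNS = ("sample", "probe", "role", "replicate", "foreground", "background")


@dataclass(eq=False)
class ExpressionMatrix:
    """Genes x samples real-valued matrix with a scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with sample ids as columns.
    scale:
        One of ``raw``, ``glog``, ``log2``, ``delta_ct``.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.scale)


@dataclass(eq=False)
class ClinicalTable:
    """Per-sample clinical information.

    ``attributes`` holds binary symptom/serology attributes coded {0, 1}
    (samples x attributes); ``diagnosis`` the class label per sample;
    ``activity`` an optional continuous disease-activity score (DAS28-like);
    ``criteria_flag`` an optional boolean classification-criteria positivity
    flag consumed as-is (used only as a comparator prediction).
    """

    attributes: pd.DataFrame
    diagnosis: pd.Series
    activity: pd.Series | None = None
    criteria_flag: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.attributes.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical attributes")
        vals = self.attributes.to_numpy()
        if vals.size and not np.isin(vals[~pd.isna(vals)], [0, 1]).all():
            bad = sorted(
                c
                for c in self.attributes.columns
                if not self.attributes[c].dropna().isin([0, 1]).all()
            )
            raise ValueError(f"non-binary values in attribute columns: {bad}")
        if not self.diagnosis.index.equals(self.attributes.index):
            self.diagnosis = self.diagnosis.reindex(self.attributes.index)
            if self.diagnosis.isna().any():
                raise ValueError("diagnosis missing for some samples")

    @property
    def samples(self) -> pd.Index:
        return self.attributes.index

    def subset(self, samples) -> "ClinicalTable":
        samples = list(samples)
        return ClinicalTable(
            self.attributes.loc[samples],
            self.diagnosis.loc[samples],
            None if self.activity is None else self.activity.loc[samples],
            None if self.criteria_flag is None else self.criteria_flag.loc[samples],
        )


@dataclass(eq=False)
class Dataset:
    """Aligned expression + clinical view of a cohort, ready for evaluation.

    ``patient_id`` (optional) groups repeat biopsies from the same patient so
    resampling never splits a patient across train and test.
    """

    expression: ExpressionMatrix
    clinical: ClinicalTable
    patient_id: pd.Series | None = None

    def __post_init__(self) -> None:
        expr_samples = list(self.expression.samples)
        if set(expr_samples) != set(self.clinical.samples):
            raise ValueError("expression and clinical tables cover different samples")
        # align clinical (and patient ids) to expression column order
        self.clinical = self.clinical.subset(expr_samples)
        if self.patient_id is not None:
            self.patient_id = self.patient_id.loc[expr_samples]

    @property
    def samples(self) -> pd.Index:
        return self.expression.samples

    @property
    def labels(self) -> pd.Series:
        return self.clinical.diagnosis

    @property
    def n_samples(self) -> int:
        return len(self.expression.samples)


def validate_raw_batch(batch: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format raw array batch and return it unchanged."""
    missing = [c for c in RAW_SPOT_COLUMNS if c not in batch.columns]
    if missing:
        raise ValueError(f"raw batch missing columns: {missing}")
    bad_roles = set(batch["role"].unique()) - set(PROBE_ROLES)
    if bad_roles:
        raise ValueError(f"unknown probe roles: {sorted(bad_roles)}")
    key = batch[["sample", "probe", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (sample, probe, replicate) spots in raw batch")
    if (batch["replicate"] < 1).any():
        raise ValueError("replicate indices must start at 1")
    return batch
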