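"""Probe-level expression container and tab-delimited I/O.

An :class:`ExpressionMatrix` holds log2 intensities (probes x samples)
with paired per-cell detection p-values, the unit of data exchanged by
every stage of the pipeline. Matrices are written as plain tab-delimited
text (header row of sample IDs, first column ``probe_id``) with the
detection p-values in a companion file of identical shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix", "read_annotation", "write_annotation"]


@dataclass
class ExpressionMatrix:
    """Log2 intensities with paired detection p-values.

    Parameters
    ----------
    values
        probes x samples DataFrame of log2 intensities.
    detection_p
        DataFrame of detection p-values, same index/columns as ``values``.
        May be None for derived matrices (e.g. post-normalization copies
        keep it; instance rankings never carry one).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise ValidationError("probe_ids must be unique")
        if not self.values.columns.is_unique:
            raise ValidationError("sample_ids must be unique")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValidationError("values and detection_p must have identical shape")
            if not (self.detection_p.index.equals(self.values.index)
                    and self.detection_p.columns.equals(self.values.columns)):
                raise ValidationError("values and detection_p must share probe and sample ids")
            p = self.detection_p.to_numpy()
            if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
                raise ValidationError("detection_p must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes) -> "ExpressionMatrix":
        dp = None if self.detection_p is None else self.detection_p.loc[probes]
        return ExpressionMatrix(self.values.loc[probes], dp)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        dp = None if self.detection_p is None else self.detection_p[samples]
        return ExpressionMatrix(self.values[samples], dp)


def write_matrix(matrix: ExpressionMatrix, values_path, detection_path=None) -> None:
    """Write a matrix (and optionally its detection p-values) as TSV."""
    matrix.values.to_csv(values_path, sep="\t", index_label="probe_id")
    if detection_path is not None:
        if matrix.detection_p is None:
            raise ValidationError("matrix carries no detection p-values to write")
        matrix.detection_p.to_csv(detection_path, sep="\t", index_label="probe_id")


def read_matrix(values_path, detection_path=None) -> ExpressionMatrix:
    """Read a tab-delimited matrix, with an optional companion detection file."""
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    detection = None
    if detection_path is not None and Path(detection_path).exists():
        detection = pd.read_csv(detection_path, sep="\t", index_col="probe_id")
    return ExpressionMatrix(values, detection)


def write_annotation(annotation: pd.Series, path) -> None:
    """Write a probe -> gene-symbol map as two-column TSV."""
    annotation.rename("gene_symbol").to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path) -> pd.Series:
    """Read a two-column (probe_id, gene_symbol) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    ann = df["gene_symbol"]
    if ann.isna().any() or (ann.astype(str).str.len() == 0).any():
        raise ValidationError("annotation contains empty gene symbols")
    if not ann.index.is_unique:
        raise ValidationError("annotation probe_ids must be unique")
    return ann.astype(str)
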