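"""Core in-memory containers for probe- and feature-level expression data.

Tabular inputs (spot tables, probe annotations, sample sheets) are plain
pandas DataFrames with documented column contracts; the feature x sample
expression matrix carries an explicit linear/log2 scale flag because the
preprocessing chain mixes both scales and silent mismatches are the
classic failure mode of this kind of pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: required columns of a spot-level signal table
SPOT_COLUMNS = ("spot_id", "probe_id", "array_id", "intensity")
#: required columns of a probe annotation table
ANNOT_COLUMNS = ("probe_id", "feature_id", "is_background", "gc_bin", "species")
#: required columns of a sample sheet
SHEET_COLUMNS = ("array_id", "sample_id", "cell_line", "tissue", "day", "batch")


class ConfigurationError(ValueError):
    """Raised when an input table or parameter violates its contract."""


def validate_spot_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Check the spot-table contract: required columns, positive intensities,
    unique (spot_id, array_id)."""
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ConfigurationError(f"spot table missing columns: {missing}")
    if (spots["intensity"] <= 0).any():
        n = int((spots["intensity"] <= 0).sum())
        raise ConfigurationError(f"spot table has {n} non-positive intensities")
    if spots.duplicated(subset=["spot_id", "array_id"]).any():
        raise ConfigurationError("duplicate (spot_id, array_id) entries in spot table")
    return spots


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ConfigurationError(f"sample sheet missing columns: {missing}")
    if sheet["array_id"].duplicated().any():
        raise ConfigurationError("duplicate array_id in sample sheet")
    return sheet


@dataclass
class ExpressionMatrix:
    """A feature x sample signal matrix with an explicit scale flag.

    Parameters
    ----------
    data
        DataFrame indexed by feature id with one column per sample.
    scale
        ``"linear"`` or ``"log2"``. Conversions are explicit operations;
        callers are responsible for passing matrices on the scale an
        operation's contract demands.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.data.isna().any().any():
            raise ConfigurationError("expression matrix contains missing values")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        if (self.data.to_numpy() <= 0).any():
            raise ConfigurationError("cannot log2-transform non-positive values")
        return ExpressionMatrix(np.log2(self.data), scale="log2")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.data), scale="linear")

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(features)], scale=self.scale)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str) -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(data, scale=scale)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.scale == other.scale and self.data.equals(other.data)


@dataclass
class DetectionCalls:
    """Per feature x sample present/absent calls with their p-values.

    ``present`` is definitionally ``p_values < alpha``; the invariant is
    enforced at construction.
    """

    p_values: pd.DataFrame
    alpha: float
    present: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = self.p_values.to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ConfigurationError("detection p-values outside [0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.present is None:
            self.present = self.p_values < self.alpha
        elif not self.present.equals(self.p_values < self.alpha):
            raise ConfigurationError("present flags inconsistent with p < alpha")

    @property
    def present_anywhere(self) -> pd.Series:
        """Features called present in at least one sample."""
        return self.present.any(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        self.p_values.to_csv(path, sep="\t", index_label="feature_id")
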