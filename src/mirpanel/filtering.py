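"""Two-stage expressed-feature selection.

Stage one removes features with 'absent' detection calls in every
sample; stage two removes features whose linear-scale normalized signal
never reaches a presence threshold defined as a multiple (default 4) of
the mean per-array inter-quartile range.  The IQR filter operates on the
linear scale: the magnitudes involved (mean IQRs around 18 signal units)
only make sense for anti-logged normalized signals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mirpanel.matrix import ConfigurationError, DetectionCalls, ExpressionMatrix


@dataclass
class FilterReport:
    """Bookkeeping of the two filter stages.

    Invariant: ``n_input - n_removed_by_detection - n_removed_by_iqr ==
    len(retained_features)``, and ``threshold == multiplier * mean_iqr``.
    """

    n_input: int
    n_removed_by_detection: int
    n_removed_by_iqr: int
    per_array_iqrs: dict[str, float]
    mean_iqr: float
    multiplier: float
    threshold: float
    retained_features: list[str]

    def __post_init__(self) -> None:
        if self.n_input - self.n_removed_by_detection - self.n_removed_by_iqr != len(
            self.retained_features
        ):
            raise ConfigurationError("filter report counts do not add up")
        if self.mean_iqr > 0 and not np.isclose(
            self.threshold, self.multiplier * self.mean_iqr
        ):
            raise ConfigurationError("threshold inconsistent with multiplier * mean IQR")

    @property
    def n_detected(self) -> int:
        return self.n_input - self.n_removed_by_detection

    @property
    def detected_pct(self) -> float:
        """Percentage of input features detected in at least one sample."""
        return 100.0 * self.n_detected / self.n_input

    @property
    def expressed_pct(self) -> float:
        """Percentage of input features surviving both filters."""
        return 100.0 * len(self.retained_features) / self.n_input

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_detected"] = self.n_detected
        d["detected_pct"] = self.detected_pct
        d["expressed_pct"] = self.expressed_pct
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def detection_filter(matrix: ExpressionMatrix, calls: DetectionCalls) -> ExpressionMatrix:
    """Retain features called present in at least one sample."""
    if not set(matrix.features) <= set(calls.p_values.index):
        missing = sorted(set(matrix.features) - set(calls.p_values.index))
        raise ConfigurationError(f"features without detection calls: {missing[:5]}")
    if not set(matrix.samples) <= set(calls.p_values.columns):
        raise ConfigurationError("samples without detection calls")
    present = calls.present.loc[matrix.features, matrix.samples].any(axis=1)
    return matrix.subset_features(matrix.features[present])


def per_array_iqr(matrix: ExpressionMatrix) -> dict[str, float]:
    """Inter-quartile range (Q3 - Q1, linear-interpolation quantiles) of
    each array's linear-scale values over all features."""
    if matrix.scale != "linear":
        raise ConfigurationError("IQR filter operates on linear-scale signals")
    if matrix.data.shape[0] < 4:
        raise ConfigurationError("need at least 4 features for a meaningful IQR")
    q1 = matrix.data.quantile(0.25, interpolation="linear")
    q3 = matrix.data.quantile(0.75, interpolation="linear")
    return (q3 - q1).to_dict()


def presence_threshold(iqrs: dict[str, float] | np.ndarray, multiplier: float) -> float:
    """Signal-presence threshold: ``multiplier`` times the mean IQR."""
    values = np.asarray(list(iqrs.values()) if isinstance(iqrs, dict) else iqrs, float)
    if values.size == 0:
        raise ConfigurationError("empty IQR vector")
    if multiplier <= 0:
        raise ConfigurationError("multiplier must be > 0")
    return float(multiplier * values.mean())


def iqr_filter(
    matrix: ExpressionMatrix, threshold: float, *, multiplier: float | None = None,
    iqrs: dict[str, float] | None = None, n_removed_by_detection: int = 0,
    n_input: int | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain features whose linear signal reaches ``threshold`` (inclusive)
    in at least one sample; return the filtered matrix and a report.

    The optional keyword arguments let the caller thread through stage-one
    bookkeeping so the report covers both stages.
    """
    if matrix.scale != "linear":
        raise ConfigurationError("IQR filter operates on linear-scale signals")
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    keep = (matrix.data >= threshold).any(axis=1)
    retained = matrix.subset_features(matrix.features[keep])
    iqrs = iqrs if iqrs is not None else per_array_iqr(matrix)
    mean_iqr = float(np.mean(list(iqrs.values())))
    if multiplier is not None:
        mult = multiplier
    else:
        mult = threshold / mean_iqr if mean_iqr > 0 else float("nan")
    report = FilterReport(
        n_input=n_input if n_input is not None else matrix.data.shape[0],
        n_removed_by_detection=n_removed_by_detection,
        n_removed_by_iqr=int((~keep).sum()),
        per_array_iqrs={k: float(v) for k, v in iqrs.items()},
        mean_iqr=mean_iqr,
        multiplier=mult,
        threshold=float(threshold),
        retained_features=list(retained.features),
    )
    return retained, report


def filter_pipeline(
    matrix: ExpressionMatrix,
    calls: DetectionCalls,
    multiplier: float = 4.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply both filter stages to a log2 feature x sample matrix.

    Detection filtering happens first; the IQR threshold is then derived
    from the detected features' linear-scale signals and applied
    inclusively.  The returned matrix is on the log2 scale.
    """
    detected = detection_filter(matrix, calls)
    linear = detected.to_linear()
    iqrs = per_array_iqr(linear)
    threshold = presence_threshold(iqrs, multiplier)
    retained_linear, report = iqr_filter(
        linear,
        threshold,
        multiplier=multiplier,
        iqrs=iqrs,
        n_removed_by_detection=matrix.data.shape[0] - detected.data.shape[0],
        n_input=matrix.data.shape[0],
    )
    retained = detected.subset_features(retained_linear.features)
    return retained, report
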