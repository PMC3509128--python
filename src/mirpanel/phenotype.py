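"""Phenotype correlation screens and distribution-shape diagnostics.

Continuous phenotypes (radiation survival fractions, doubling times) are
screened against log2 expression by Pearson correlation.  Before
treating a phenotype as continuous, its distribution is inspected with a
Gaussian kernel density estimate: a clearly bimodal phenotype would
instead support a two-group split.  A robustness check repeats the
screen with a named tissue group excluded, exposing correlations driven
entirely by one extreme group rather than by a trend across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as scipy_signal
from scipy import stats

from mirpanel.matrix import ConfigurationError, ExpressionMatrix
from mirpanel.stats import pearson_with_p


def log2_zscore(values: np.ndarray) -> np.ndarray:
    """log2-transform then z-score a positive-valued vector -- the
    standard pre-transform before density estimation."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ConfigurationError("phenotype values must be positive before log2")
    logged = np.log2(values)
    sd = logged.std(ddof=1)
    if sd == 0:
        raise ConfigurationError("zero variance after log2 transform")
    return (logged - logged.mean()) / sd


@dataclass
class KDEResult:
    """Gaussian kernel density estimate on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_modes: int

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def gaussian_kde(values: np.ndarray, bandwidth: float | str = "auto") -> KDEResult:
    """Sum-of-Gaussian-kernels density on a 512-point grid.

    The grid spans the data plus three bandwidths on each side, so the
    density integrates to ~1 on it.  ``bandwidth="auto"`` applies
    Silverman's rule of thumb.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ConfigurationError("need >= 3 values for density estimation")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ConfigurationError("zero-variance sample")
    if bandwidth == "auto":
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        bw = 0.9 * spread * values.size ** (-0.2)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ConfigurationError("bandwidth must be positive")
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / bw) ** 2).sum(axis=1)
    dens /= values.size * bw * np.sqrt(2 * np.pi)
    result = KDEResult(grid=grid, density=dens, bandwidth=bw, n_modes=0)
    result.n_modes = count_modes(result)
    return result


def count_modes(kde: KDEResult, min_prominence: float = 0.05) -> int:
    """Number of local density maxima with prominence at least
    ``min_prominence`` times the global maximum.

    At ``min_prominence = 1.0`` only the global mode can survive, so the
    count is 1 for any density.
    """
    peak_level = kde.density.max()
    peaks, _ = scipy_signal.find_peaks(
        kde.density, prominence=min(min_prominence, 1.0 - 1e-12) * peak_level
    )
    return max(int(peaks.size), 1)


def correlation_screen(
    matrix: ExpressionMatrix,
    pheno: pd.DataFrame,
    parameter: str,
    cutoff: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Pearson correlation of log2 expression with the log2
    phenotype.

    ``pheno`` is a long table (cell_line, parameter, value), values
    positive.  Returns columns ``feature, parameter, n, r, p,
    passes_cutoff`` where passing requires |r| > cutoff and p below
    ``p_threshold`` (two-tailed t, df = n - 2).
    """
    if matrix.scale != "log2":
        raise ConfigurationError("correlation screen expects log2 expression")
    rows = pheno[pheno["parameter"] == parameter]
    if rows.empty:
        raise ConfigurationError(f"phenotype parameter {parameter!r} not found")
    values = rows.drop_duplicates("cell_line").set_index("cell_line")["value"]
    if (values <= 0).any():
        raise ConfigurationError("phenotype values must be positive")
    lines = [s for s in matrix.samples if s in values.index]
    if len(lines) < 3:
        raise ConfigurationError("need >= 3 lines with both expression and phenotype")
    y = np.log2(values[lines].to_numpy(float))
    x = matrix.data[lines].to_numpy(float)
    r, p = pearson_with_p(x, np.tile(y, (x.shape[0], 1)))
    out = pd.DataFrame(
        {
            "feature": matrix.features,
            "parameter": parameter,
            "n": len(lines),
            "r": r,
            "p": p,
            "passes_cutoff": (np.abs(r) > cutoff) & (p < p_threshold),
        }
    ).reset_index(drop=True)
    return out


def robustness_exclude_group(
    matrix: ExpressionMatrix,
    pheno: pd.DataFrame,
    parameter: str,
    sheet: pd.DataFrame,
    exclude_tissue: str,
    cutoff: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Screen with and without one tissue's lines.

    Returns (full screen, reduced screen, dropped features) where the
    dropped list holds features passing the cutoff in the full panel but
    not after the exclusion -- the signature of a group-driven
    correlation.
    """
    tissue_of = sheet.drop_duplicates("sample_id").set_index("sample_id")["tissue"]
    excluded = [s for s in matrix.samples if tissue_of.get(s) == exclude_tissue]
    kept = [s for s in matrix.samples if s not in set(excluded)]
    if len(kept) < 3:
        raise ConfigurationError("exclusion leaves fewer than 3 lines")
    full = correlation_screen(matrix, pheno, parameter, cutoff)
    reduced_matrix = ExpressionMatrix(matrix.data[kept], scale=matrix.scale)
    reduced = correlation_screen(reduced_matrix, pheno, parameter, cutoff)
    full_pass = set(full.loc[full["passes_cutoff"], "feature"])
    reduced_pass = set(reduced.loc[reduced["passes_cutoff"], "feature"])
    dropped = sorted(full_pass - reduced_pass)
    return full, reduced, dropped
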