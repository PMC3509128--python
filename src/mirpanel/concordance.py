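"""Cross-dataset concordance of expression measurements.

Two datasets measuring the same panel on different platforms are
compared feature by feature: Pearson r over the shared samples, a
cumulative distribution of the coefficients, the fraction above a
high-concordance cutoff, and a sample-label resampling control that
destroys the correspondence.  Values are correlated untransformed --
each dataset as delivered, with no rescaling -- since Pearson r is
invariant to per-feature affine recalibration anyway.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mirpanel.matrix import ConfigurationError, ExpressionMatrix
from mirpanel.stats import pearson_rows


@dataclass
class ConcordanceResult:
    """Per-feature Pearson correlations between two datasets with summaries."""

    per_feature_r: pd.Series  # indexed by feature id
    n_shared_samples: int
    n_zero_variance_excluded: int
    mean_r: float
    sd_r: float

    def fraction_above(self, cutoff: float) -> float:
        return fraction_above(self.per_feature_r.to_numpy(), cutoff)

    def cdf(self, bin_width: float) -> pd.DataFrame:
        return cdf_bins(self.per_feature_r.to_numpy(), bin_width)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_feature_r"] = self.per_feature_r.to_dict()
        return d


def per_feature_correlation(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> ConcordanceResult:
    """Pearson r per shared feature across the shared-sample intersection.

    Sample matching is by exact name after whitespace trimming.  Features
    with zero variance in either dataset have undefined r; they are
    excluded and counted rather than assigned a value.
    """
    a_data = a.data.rename(columns=str.strip)
    b_data = b.data.rename(columns=str.strip)
    shared_samples = a_data.columns.intersection(b_data.columns)
    if len(shared_samples) < 3:
        raise ConfigurationError(
            f"only {len(shared_samples)} shared samples; need >= 3"
        )
    shared_features = a_data.index.intersection(b_data.index)
    if len(shared_features) < 1:
        raise ConfigurationError("no shared features between datasets")
    x = a_data.loc[shared_features, shared_samples].to_numpy(float)
    y = b_data.loc[shared_features, shared_samples].to_numpy(float)
    r = pearson_rows(x, y)
    series = pd.Series(r, index=shared_features)
    defined = series.dropna()
    return ConcordanceResult(
        per_feature_r=defined,
        n_shared_samples=len(shared_samples),
        n_zero_variance_excluded=int(series.isna().sum()),
        mean_r=float(defined.mean()),
        sd_r=float(defined.std(ddof=1)) if len(defined) > 1 else 0.0,
    )


def cdf_bins(rs: np.ndarray, bin_width: float) -> pd.DataFrame:
    """Cumulative fraction of correlation coefficients up to each bin edge.

    Bins tile [-1, 1]; ``bin_width`` must divide the interval evenly.
    Returns a DataFrame with the right edge of each bin and the fraction
    of values <= that edge; the last entry is 1 by construction.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise ConfigurationError("empty correlation vector")
    n_bins_f = 2.0 / bin_width
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ConfigurationError("bin width must divide [-1, 1] evenly")
    edges = -1.0 + bin_width * np.arange(1, n_bins + 1)
    edges[-1] = 1.0
    cum = np.searchsorted(np.sort(rs), edges, side="right") / rs.size
    return pd.DataFrame({"edge": edges, "cumulative_fraction": cum})


def fraction_above(rs: np.ndarray, cutoff: float) -> float:
    """Fraction of coefficients strictly above ``cutoff``."""
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise ConfigurationError("empty correlation vector")
    return float((rs > cutoff).sum() / rs.size)


def resample_control(b: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Permute sample labels uniformly at random, breaking the cross-dataset
    sample correspondence while keeping every feature's values intact."""
    if b.data.shape[1] < 2:
        raise ConfigurationError("need >= 2 samples to resample")
    rng = np.random.default_rng(seed)
    samples = list(b.data.columns)
    perm = rng.permutation(len(samples))
    shuffled = b.data.copy()
    shuffled.columns = [samples[i] for i in perm]
    return ExpressionMatrix(shuffled[samples], scale=b.scale)


def cross_platform_validation(
    signal: np.ndarray, cq: np.ndarray
) -> tuple[float, float, float, float]:
    """Validate array measurements against PCR quantification cycles.

    Returns (r, p, slope, intercept): Pearson r of log2 signal vs Cq with
    a two-tailed t-test p (df = n - 2), and the least-squares regression
    of Cq on log2 signal.  Higher abundance means higher signal but lower
    Cq, so a negative slope indicates agreement.
    """
    signal = np.asarray(signal, dtype=float)
    cq = np.asarray(cq, dtype=float)
    if signal.size != cq.size or signal.size < 3:
        raise ConfigurationError("need >= 3 matched (signal, Cq) pairs")
    if np.ptp(signal) == 0 or np.ptp(cq) == 0:
        raise ConfigurationError("zero variance in signal or Cq values")
    r, p = stats.pearsonr(signal, cq)
    fit = stats.linregress(signal, cq)
    return float(r), float(p), float(fit.slope), float(fit.intercept)
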