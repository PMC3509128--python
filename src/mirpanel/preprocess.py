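"""Probe-level preprocessing: from spot intensities to a summarized matrix.

The chain follows the standard order for this array generation:
detection calls against GC-matched background probes, RMA-style
convolution-model background correction, quantile normalization, log2
transform, and median-polish summarization, with replicate selection and
QC at the end.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from mirpanel.matrix import (
    ConfigurationError,
    DetectionCalls,
    ExpressionMatrix,
    validate_sample_sheet,
    validate_spot_table,
)
from mirpanel.stats import rank_sum_p_greater, rank_sum_p_greater_batch


# ---------------------------------------------------------------------------
# detection calls


def detection_calls(
    spots: pd.DataFrame, annot: pd.DataFrame, alpha: float = 0.05
) -> DetectionCalls:
    """Present/absent calls per feature x array.

    For every feature on every array, the spot intensities of its probes
    are compared with the pooled spot intensities of background probes in
    the same GC bin by a one-sided (greater) Wilcoxon rank-sum test; the
    feature is called present when p < alpha.  Exact null distributions
    are used whenever the pooled values are tie-free.
    """
    validate_spot_table(spots)
    merged = spots.merge(annot, on="probe_id", how="left", validate="many_to_one")
    if merged["is_background"].isna().any():
        missing = merged.loc[merged["is_background"].isna(), "probe_id"].unique()
        raise ConfigurationError(f"probes without annotation: {list(missing[:5])}")
    bg = merged[merged["is_background"]]
    tg = merged[~merged["is_background"]]
    target_bins = set(tg["gc_bin"].unique())
    orphan = sorted(target_bins - set(bg["gc_bin"].unique()))
    if orphan:
        raise ConfigurationError(f"gc bins without background probes: {orphan}")

    features = np.sort(tg["feature_id"].unique())
    arrays = np.sort(spots["array_id"].unique())
    pmat = pd.DataFrame(np.nan, index=features, columns=arrays)

    for array_id, tg_arr in tg.groupby("array_id", sort=False):
        bg_arr = bg[bg["array_id"] == array_id]
        for bin_label, tg_bin in tg_arr.groupby("gc_bin", sort=False):
            pool = np.sort(bg_arr.loc[bg_arr["gc_bin"] == bin_label, "intensity"].to_numpy())
            ordered = tg_bin.sort_values("feature_id", kind="mergesort")
            feats_here = ordered["feature_id"].to_numpy()
            values = ordered["intensity"].to_numpy()
            starts = np.nonzero(np.r_[True, feats_here[1:] != feats_here[:-1]])[0]
            sizes = np.diff(np.r_[starts, feats_here.size])
            tie_free = np.unique(np.concatenate([values, pool])).size == values.size + pool.size
            if tie_free and np.unique(sizes).size == 1:
                counts = np.searchsorted(pool, values, side="left")
                u = np.add.reduceat(counts, starts)
                pmat.loc[feats_here[starts], array_id] = rank_sum_p_greater_batch(
                    u, int(sizes[0]), pool.size
                )
            else:
                for feat, v in ordered.groupby("feature_id", sort=False)["intensity"]:
                    pmat.loc[feat, array_id] = rank_sum_p_greater(v.to_numpy(), pool)
    if pmat.isna().any().any():
        raise ConfigurationError("features missing spots on some arrays")
    return DetectionCalls(p_values=pmat, alpha=alpha)


# ---------------------------------------------------------------------------
# RMA background correction


def _kde_mode(x: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    grid = np.linspace(x.min(), x.max(), 512)
    dens = stats.gaussian_kde(x)(grid)
    return float(grid[int(np.argmax(dens))]), grid, dens


def _normexp_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Estimate (mu, sigma, alpha) of the normal+exponential convolution.

    A first kernel-density pass locates a provisional mode; the density
    is then re-estimated on the sub-mode values only (whose spread
    reflects just the background, so Silverman's bandwidth is no longer
    inflated by the signal tail).  mu is the refined mode, sigma comes
    from the left half-width at half maximum of the refined density, and
    the exponential rate alpha from the mean exceedance above the mode.
    """
    mode1, grid, dens = _kde_mode(x)
    below1 = x[x < mode1]
    if below1.size >= 10 and np.ptp(below1) > 0:
        mu, grid, dens = _kde_mode(below1)
    else:
        mu = mode1
    imode = int(np.argmin(np.abs(grid - mu)))
    half = dens[imode] / 2.0
    under = np.nonzero(dens[: imode + 1] < half)[0]
    if under.size:
        hwhm = mu - float(grid[under[-1]])
    else:  # mode at the left edge of the support
        hwhm = max(float(grid[1] - grid[0]), mu - float(grid[0]))
    sigma = max(hwhm / np.sqrt(2.0 * np.log(2.0)), 1e-6)
    upper = x[x > mu]
    mean_exceed = float((upper - mu).mean()) if upper.size else sigma
    alpha = 1.0 / max(mean_exceed, 1e-6)
    # The density mode of the convolution sits above the background mean:
    # at the mode, phi(t)/Phi(t) = alpha * sigma with t = (mode - mu)/sigma.
    # Invert that relation to de-bias the location estimate.
    target = alpha * sigma
    if target < stats.norm.pdf(0) / 0.5:  # solvable for finite t
        from scipy import optimize

        t_star = optimize.brentq(
            lambda t: stats.norm.pdf(t) / stats.norm.cdf(t) - target, -8.0, 40.0
        )
        mu = mu - max(t_star, 0.0) * sigma
    return mu, sigma, alpha


def _normexp_correct(x: np.ndarray) -> np.ndarray:
    """Posterior expected true signal under signal ~ Exp(alpha) plus
    background ~ N(mu, sigma^2): E[s | x] = a + sigma * phi(a/sigma) /
    Phi(a/sigma) with a = x - mu - sigma^2 * alpha.  Strictly positive
    and strictly increasing in x."""
    if np.ptp(x) == 0:
        return np.full_like(x, 1e-6)
    mu, sigma, alpha = _normexp_parameters(x)
    a = x - mu - sigma**2 * alpha
    t = a / sigma
    # phi(t)/Phi(t) via scipy's log-forms for numerical stability far left
    log_ratio = -0.5 * t**2 - 0.5 * np.log(2 * np.pi) - special.log_ndtr(t)
    corrected = a + sigma * np.exp(log_ratio)
    return np.maximum(corrected, 1e-12)


def rma_background_correct(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """RMA-style background correction, independently per array (column)."""
    if matrix.scale != "linear":
        raise ConfigurationError("background correction expects linear-scale input")
    if (matrix.values <= 0).any():
        raise ConfigurationError("background correction requires positive intensities")
    out = pd.DataFrame(
        np.column_stack([_normexp_correct(matrix.data[c].to_numpy()) for c in matrix.data]),
        index=matrix.data.index,
        columns=matrix.data.columns,
    )
    return ExpressionMatrix(out, scale="linear")


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the across-column mean empirical distribution.

    Tied values within a column receive the mean of the quantile values
    their ranks span, so the result is permutation-consistent.
    """
    df = matrix.data
    if df.shape[1] < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return ExpressionMatrix(df.copy(), scale=matrix.scale)
    vals = df.to_numpy(dtype=float)
    n = vals.shape[0]
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        order = np.argsort(vals[:, j], kind="mergesort")
        col = np.empty(n)
        col[order] = ref
        sv = vals[order, j]
        # average the reference values across runs of tied input values
        boundaries = np.nonzero(np.diff(sv))[0] + 1
        starts = np.concatenate([[0], boundaries])
        run_means = np.add.reduceat(ref, starts) / np.diff(np.concatenate([starts, [n]]))
        expanded = np.repeat(run_means, np.diff(np.concatenate([starts, [n]])))
        col[order] = expanded
        out[:, j] = col
    return ExpressionMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns), scale=matrix.scale
    )


# ---------------------------------------------------------------------------
# median polish


def median_polish(
    x: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a 2-d array.

    Returns (overall, row_effects, col_effects, residuals).  Iteration
    stops when the sum of absolute residuals shrinks by less than ``tol``
    relative per sweep, or after ``max_iter`` sweeps.
    """
    z = np.array(x, dtype=float)
    if z.ndim != 2:
        raise ConfigurationError("median polish expects a 2-d array")
    nr, nc = z.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    oldsum = 0.0
    for _ in range(max_iter):
        rm = np.median(z, axis=1)
        z -= rm[:, None]
        row_eff += rm
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta
        cm = np.median(z, axis=0)
        z -= cm[None, :]
        col_eff += cm
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta
        newsum = np.abs(z).sum()
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            break
        oldsum = newsum
    return overall, row_eff, col_eff, z


def median_polish_summarize(
    spot_matrix: pd.DataFrame,
    spot_features: pd.Series,
    tol: float = 0.01,
    max_iter: int = 10,
) -> ExpressionMatrix:
    """Summarize a log2 spot x array matrix to one value per feature x array.

    Each feature's spot x array submatrix is median-polished; the array
    summary is overall effect + array (column) effect.  A feature with a
    single spot degenerates to that spot's values.
    """
    missing = spot_matrix.index.difference(spot_features.index)
    if len(missing):
        raise ConfigurationError(f"spots without feature mapping: {list(missing[:5])}")
    feats = spot_features.loc[spot_matrix.index]
    rows = {}
    for feature, idx in spot_matrix.groupby(feats).groups.items():
        sub = spot_matrix.loc[idx].to_numpy(dtype=float)
        if sub.shape[0] == 1:
            rows[feature] = sub[0]
        else:
            overall, _, col_eff, _ = median_polish(sub, tol=tol, max_iter=max_iter)
            rows[feature] = overall + col_eff
    out = pd.DataFrame.from_dict(rows, orient="index", columns=spot_matrix.columns)
    return ExpressionMatrix(out.sort_index(), scale="log2")


# ---------------------------------------------------------------------------
# replicate QC


def rolling_window_correlation(
    x: np.ndarray, y: np.ndarray, width: int
) -> pd.DataFrame:
    """Pearson r in a rolling window along x-sorted pairs.

    The series must already be sorted by x; each window of ``width``
    consecutive points is reported at its middle x value.  Width must be
    odd and no larger than the series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be matched 1-d series")
    if width % 2 == 0:
        raise ConfigurationError("window width must be odd")
    if width > x.size:
        raise ConfigurationError("window width exceeds series length")
    if (np.diff(x) < 0).any():
        raise ConfigurationError("series must be sorted by x")
    half = width // 2
    records = []
    for start in range(x.size - width + 1):
        xs = x[start : start + width]
        ys = y[start : start + width]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(xs, ys)[0, 1]
        records.append((x[start + half], r))
    return pd.DataFrame(records, columns=["abscissa", "r"])


def select_best_replicate(replicates: list[np.ndarray]) -> int:
    """Index of the replicate with the highest mean Pearson correlation to
    the other replicates; ties break to the lowest index."""
    if len(replicates) < 2:
        raise ConfigurationError("need at least two replicates")
    arrs = [np.asarray(r, dtype=float) for r in replicates]
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise ConfigurationError("replicate length mismatch")
    k = len(arrs)
    corr = np.corrcoef(np.vstack(arrs))
    mean_r = (corr.sum(axis=1) - 1.0) / (k - 1)
    return int(np.argmax(mean_r))


# ---------------------------------------------------------------------------
# full pipeline


def preprocess_pipeline(
    spots: pd.DataFrame,
    annot: pd.DataFrame,
    sheet: pd.DataFrame,
    detection_alpha: float = 0.05,
) -> tuple[ExpressionMatrix, DetectionCalls, dict]:
    """Run the full preprocessing chain on a spot table.

    Steps in order: detection calls, RMA background correction, quantile
    normalization, log2 transform, median-polish summarization; then the
    best replicate array is retained for samples assayed more than once.
    Returns the feature x sample log2 matrix, feature x sample detection
    calls, and a QC report (per-array signal percentiles and
    inter-replicate correlations).
    """
    validate_spot_table(spots)
    validate_sample_sheet(sheet)
    calls_by_array = detection_calls(spots, annot, alpha=detection_alpha)

    target_probes = set(annot.loc[~annot["is_background"], "probe_id"])
    tspots = spots[spots["probe_id"].isin(target_probes)]
    wide = tspots.pivot(index="spot_id", columns="array_id", values="intensity")
    if wide.isna().any().any():
        raise ConfigurationError("target spots missing on some arrays")
    spot_mat = ExpressionMatrix(wide, scale="linear")
    corrected = rma_background_correct(spot_mat)
    normalized = quantile_normalize(corrected)
    logged = normalized.to_log2()

    probe_feature = annot.set_index("probe_id")["feature_id"]
    spot_probe = tspots.drop_duplicates("spot_id").set_index("spot_id")["probe_id"]
    spot_feature = spot_probe.map(probe_feature)
    summarized = median_polish_summarize(logged.data, spot_feature)

    # replicate selection: one retained array per sample
    arrays_of = sheet.groupby("sample_id")["array_id"].apply(list)
    kept_arrays: dict[str, str] = {}
    replicate_corr: dict[str, list] = {}
    for sample_id, array_ids in arrays_of.items():
        if len(array_ids) == 1:
            kept_arrays[sample_id] = array_ids[0]
            continue
        vectors = [summarized.data[a].to_numpy() for a in array_ids]
        best = select_best_replicate(vectors)
        kept_arrays[sample_id] = array_ids[best]
        cmat = np.corrcoef(np.vstack(vectors))
        replicate_corr[sample_id] = {
            "arrays": list(array_ids),
            "best": array_ids[best],
            "pairwise_r": cmat[np.triu_indices(len(array_ids), k=1)].tolist(),
        }

    sample_order = sorted(kept_arrays)
    expr = ExpressionMatrix(
        summarized.data[[kept_arrays[s] for s in sample_order]].set_axis(
            sample_order, axis=1
        ),
        scale="log2",
    )
    calls = DetectionCalls(
        p_values=calls_by_array.p_values[[kept_arrays[s] for s in sample_order]].set_axis(
            sample_order, axis=1
        ),
        alpha=calls_by_array.alpha,
    )

    log_vals = summarized.data
    qc = {
        "per_array_pct75": log_vals.quantile(0.75).to_dict(),
        "per_array_pct95": log_vals.quantile(0.95).to_dict(),
        "mean_pct75": float(log_vals.quantile(0.75).mean()),
        "sd_pct75": float(log_vals.quantile(0.75).std()),
        "replicate_correlations": replicate_corr,
        "n_arrays": int(log_vals.shape[1]),
        "n_samples": len(sample_order),
    }
    return expr, calls, qc
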