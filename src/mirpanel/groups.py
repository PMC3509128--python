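"""Sample clustering and group differential expression.

Clustering uses the uncentered-Pearson (cosine) distance with average
linkage and optional optimal leaf ordering.  Differential expression
uses self-implemented empirical-Bayes moderated t-statistics: per-feature
variances are shrunk toward a prior (d0, s0^2) estimated by matching the
first two moments of log s_g^2 against the scaled-F marginal implied by
the hierarchical model, and p-values gain d0 extra degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy

from mirpanel.matrix import ConfigurationError, ExpressionMatrix
from mirpanel.stats import bh_adjust, trigamma_inverse

__all__ = [
    "EBHyperparams",
    "Dendrogram",
    "uncentered_pearson_distance",
    "cluster_samples",
    "estimate_eb_hyperparameters",
    "fit_moderated_t",
    "bh_adjust",
    "one_vs_rest_de",
    "mutation_de",
    "top_k_by_p",
    "z_scale_rows",
]


# ---------------------------------------------------------------------------
# clustering


def uncentered_pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - sum(xy) / sqrt(sum(x^2) * sum(y^2)), in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("vectors must have equal length")
    nx, ny = np.sqrt((x**2).sum()), np.sqrt((y**2).sum())
    if nx == 0 or ny == 0:
        raise ConfigurationError("uncentered Pearson undefined for zero-norm vector")
    return float(np.clip(1.0 - (x * y).sum() / (nx * ny), 0.0, 2.0))


def _uncentered_condensed(values: np.ndarray) -> np.ndarray:
    """Condensed pairwise uncentered-Pearson distance over matrix rows."""
    norms = np.sqrt((values**2).sum(axis=1))
    if (norms == 0).any():
        raise ConfigurationError("zero-norm sample vector in distance computation")
    sim = (values @ values.T) / np.outer(norms, norms)
    dist = np.clip(1.0 - sim, 0.0, 2.0)
    iu = np.triu_indices(values.shape[0], k=1)
    return dist[iu]


@dataclass
class Dendrogram:
    """Agglomerative clustering result: a scipy linkage matrix, the sample
    labels, and the displayed leaf order."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster membership when the tree is cut into ``k`` clusters."""
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return walk(tree) + ";"


def cluster_samples(
    matrix: ExpressionMatrix, optimize_leaf_order: bool = True
) -> Dendrogram:
    """Average-linkage hierarchical clustering of samples.

    Distances are uncentered Pearson over the feature profiles.  With
    ``optimize_leaf_order`` the leaves are reordered by the dynamic
    program that minimizes the sum of adjacent-leaf distances.
    """
    if matrix.data.shape[1] < 2:
        raise ConfigurationError("need >= 2 samples to cluster")
    values = matrix.data.to_numpy(float).T  # samples x features
    condensed = _uncentered_condensed(values)
    z = hierarchy.linkage(condensed, method="average")
    if optimize_leaf_order:
        z = hierarchy.optimal_leaf_ordering(z, condensed)
    labels = list(matrix.samples)
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return Dendrogram(linkage=z, labels=labels, leaf_order=order)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


@dataclass(frozen=True)
class EBHyperparams:
    """Prior degrees of freedom and prior variance of the EB variance model.

    d0 may be ``inf`` (all features share one variance); both must be
    positive.  d0 = 0 is accepted as the no-shrinkage limit in which the
    moderated t degenerates to the ordinary pooled two-sample t.
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or not self.s0_sq > 0:
            raise ConfigurationError("require d0 >= 0 and s0_sq > 0")


def estimate_eb_hyperparameters(s_sq: np.ndarray, d_g: float) -> EBHyperparams:
    """Moment-matching fit of the scaled-F marginal of sample variances.

    Under the hierarchical model, z = log s_g^2 has mean
    log s0^2 + digamma(d_g/2) - log(d_g/2) - (digamma(d0/2) - log(d0/2))
    and excess variance trigamma(d0/2) beyond trigamma(d_g/2); inverting
    the trigamma relation gives d0, then s0^2 from the mean.  When the
    observed dispersion does not exceed trigamma(d_g/2), d0 is infinite.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if s_sq.size < 10:
        raise ConfigurationError("need >= 10 features to estimate hyperparameters")
    if (s_sq <= 0).any():
        raise ConfigurationError("variances must be positive")
    z = np.log(s_sq)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, d_g / 2.0)
    if excess <= 0:
        return EBHyperparams(d0=float("inf"), s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * trigamma_inverse(float(excess))
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return EBHyperparams(d0=float(d0), s0_sq=float(s0_sq))


def fit_moderated_t(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    hyper: EBHyperparams | str = "estimate",
    group_label: str = "",
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group comparison, one row per feature.

    The moderated t replaces each feature's pooled variance s_g^2 with
    the shrunken value (d0 s0^2 + d_g s_g^2) / (d0 + d_g) and refers the
    statistic to a t distribution with d0 + d_g degrees of freedom.
    Returns columns ``feature, group, diff, s2, df, t, p, q``; ``diff``
    is mean(A) - mean(B) on the log2 scale.
    """
    a = list(group_a)
    b = list(group_b)
    if set(a) & set(b):
        raise ConfigurationError("groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("both groups need >= 2 samples")
    xa = matrix.data[a].to_numpy(float)
    xb = matrix.data[b].to_numpy(float)
    na, nb = len(a), len(b)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    d_g = na + nb - 2
    s_sq = (xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)) / d_g
    if isinstance(hyper, str):
        hyper = estimate_eb_hyperparameters(np.clip(s_sq, 1e-300, None), d_g)
    if np.isinf(hyper.d0):
        s_tilde_sq = np.full_like(s_sq, hyper.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (hyper.d0 * hyper.s0_sq + d_g * s_sq) / (hyper.d0 + d_g)
        df_total = hyper.d0 + d_g
    se = np.sqrt(s_tilde_sq * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    return pd.DataFrame(
        {
            "feature": matrix.features,
            "group": group_label,
            "diff": diff,
            "s2": s_sq,
            "df": d_g,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
        }
    ).reset_index(drop=True)


def _shared_hyperparameters(
    matrix: ExpressionMatrix, groups: dict[str, list[str]]
) -> tuple[EBHyperparams, float]:
    """One hyperparameter fit per matrix: pooled within-group variances
    across all groups, df = n - k."""
    ss = np.zeros(matrix.data.shape[0])
    d_resid = 0
    for members in groups.values():
        if len(members) < 2:  # singleton groups contribute no residual df
            continue
        x = matrix.data[members].to_numpy(float)
        ss += x.var(axis=1, ddof=1) * (len(members) - 1)
        d_resid += len(members) - 1
    if d_resid < 1:
        raise ConfigurationError("not enough residual degrees of freedom")
    s_sq = np.clip(ss / d_resid, 1e-300, None)
    return estimate_eb_hyperparameters(s_sq, d_resid), d_resid


def one_vs_rest_de(
    matrix: ExpressionMatrix, sheet: pd.DataFrame, fdr: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Each tissue group versus all other samples, with a single shared
    hyperparameter estimate for the whole matrix.

    Tissues with fewer than 2 samples are skipped with a warning (a
    2-sample prostate-style group is the smallest testable).  The
    significant set per tissue is q < fdr.
    """
    tissue_of = sheet.drop_duplicates("sample_id").set_index("sample_id")["tissue"]
    samples = [s for s in matrix.samples if s in tissue_of.index]
    if len(samples) < len(matrix.samples):
        raise ConfigurationError("samples missing from sample sheet")
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(str(tissue_of[s]), []).append(s)
    hyper, _ = _shared_hyperparameters(matrix, groups)
    results: dict[str, pd.DataFrame] = {}
    for tissue, members in sorted(groups.items()):
        rest = [s for s in samples if s not in members]
        if len(members) < 2 or len(rest) < 2:
            warnings.warn(f"skipping tissue {tissue!r} with <2 samples per side")
            continue
        records = fit_moderated_t(matrix, members, rest, hyper, group_label=tissue)
        records["significant"] = records["q"] < fdr
        results[tissue] = records
    return results


def mutation_de(
    matrix: ExpressionMatrix,
    mutations: pd.DataFrame,
    gene: str,
    min_mutants: int = 10,
    fdr: float = 0.05,
    hyper: EBHyperparams | str = "estimate",
) -> pd.DataFrame:
    """Mutant versus wild-type comparison for one gene.

    ``mutations`` is a long table (cell_line, gene, status) with status 1
    for carriers.  Requires at least ``min_mutants`` mutant lines among
    the samples present in the matrix.
    """
    rows = mutations[mutations["gene"] == gene]
    if rows.empty:
        raise ConfigurationError(f"gene {gene!r} absent from mutation table")
    status = rows.set_index("cell_line")["status"]
    present = [s for s in matrix.samples if s in status.index]
    mutant = [s for s in present if status[s] == 1]
    wild = [s for s in present if status[s] == 0]
    if len(mutant) < min_mutants:
        raise ConfigurationError(
            f"{gene}: only {len(mutant)} mutant lines; need >= {min_mutants} "
            "for a mutant-vs-wild-type comparison"
        )
    if len(wild) < 2:
        raise ConfigurationError(f"{gene}: fewer than 2 wild-type lines")
    records = fit_moderated_t(matrix, mutant, wild, hyper, group_label=gene)
    records["significant"] = records["q"] < fdr
    return records


def top_k_by_p(records: pd.DataFrame, k: int) -> list[str]:
    """The k features with smallest p; ties break by feature id; asking for
    more than available returns everything with a warning."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(records):
        warnings.warn(f"requested top {k} of {len(records)} records; returning all")
        k = len(records)
    ordered = records.sort_values(["p", "feature"], kind="mergesort")
    return list(ordered["feature"].head(k))


def z_scale_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each feature row to mean 0, sample SD 1."""
    sd = matrix.data.std(axis=1, ddof=1)
    flat = sd[sd == 0].index
    if len(flat):
        raise ConfigurationError(f"zero-variance rows: {list(flat[:5])}")
    scaled = matrix.data.sub(matrix.data.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(scaled, scale=matrix.scale)
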