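"""miRNA--target-mRNA correlation analysis.

MicroRNA families (sets of miRNAs sharing a seed sequence) are predicted
to repress common target genes; each target gene may be measured by
several mRNA array probes.  This module expands a family-level target
map into (miRNA feature, mRNA probe) pairs, mass-computes Pearson
correlations of their expression across shared samples, controls the FDR
jointly across all pairs with Benjamini-Hochberg, and calibrates the
result against a sample-label permutation null.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mirpanel.matrix import ConfigurationError, ExpressionMatrix
from mirpanel.stats import bh_adjust, pearson_rows


@dataclass(frozen=True)
class TargetMap:
    """Three-relation target-prediction map.

    ``family_mirna`` links a miRNA family to its member miRNAs,
    ``family_gene`` links it to predicted target gene symbols, and
    ``gene_probe`` links gene symbols to mRNA array probes.  Relations
    are duplicate-free tuples of (key, value) pairs.
    """

    family_mirna: tuple[tuple[str, str], ...]
    family_gene: tuple[tuple[str, str], ...]
    gene_probe: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for name in ("family_mirna", "family_gene", "gene_probe"):
            rel = getattr(self, name)
            if len(set(rel)) != len(rel):
                raise ConfigurationError(f"duplicate relations in {name}")
        families = {f for f, _ in self.family_mirna}
        if families != {f for f, _ in self.family_gene}:
            raise ConfigurationError("families with no members or no genes")
        genes_with_probes = {g for g, _ in self.gene_probe}
        orphan = {g for _, g in self.family_gene} - genes_with_probes
        if orphan:
            raise ConfigurationError(f"genes without probes: {sorted(orphan)[:5]}")

    @property
    def families(self) -> set[str]:
        return {f for f, _ in self.family_mirna}

    def probe_gene(self) -> dict[str, str]:
        return {p: g for g, p in self.gene_probe}

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("family_mirna", k, v) for k, v in self.family_mirna]
            + [("family_gene", k, v) for k, v in self.family_gene]
            + [("gene_probe", k, v) for k, v in self.gene_probe]
        )
        return pd.DataFrame(rows, columns=["relation", "key", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TargetMap":
        df = pd.read_csv(path, sep="\t")
        rels = {
            name: tuple(
                (str(k), str(v))
                for k, v in df[df["relation"] == name][["key", "value"]].itertuples(index=False)
            )
            for name in ("family_mirna", "family_gene", "gene_probe")
        }
        return cls(rels["family_mirna"], rels["family_gene"], rels["gene_probe"])


def range_filter(mrna: ExpressionMatrix, min_range: float) -> ExpressionMatrix:
    """Keep probes whose log2 sample range (max - min) is >= ``min_range``.

    Low-range probes carry no usable variation for correlation analysis;
    the boundary is inclusive.
    """
    if mrna.scale != "log2":
        raise ConfigurationError("range_filter expects a log2 matrix")
    rng = mrna.data.max(axis=1) - mrna.data.min(axis=1)
    return ExpressionMatrix(mrna.data.loc[rng >= min_range], scale="log2")


def expand_pairs(
    target_map: TargetMap,
    expressed_mirnas: set[str],
    mrna_probes: set[str],
) -> list[tuple[str, str, str]]:
    """Expand the family map into unique (miRNA, probe, gene) pairs.

    Only expressed member miRNAs and retained mRNA probes contribute;
    a miRNA reached through two families targeting the same gene yields
    one pair (duplicates collapse).  Output order is deterministic.
    """
    fam_members: dict[str, list[str]] = {}
    for fam, mir in target_map.family_mirna:
        if mir in expressed_mirnas:
            fam_members.setdefault(fam, []).append(mir)
    gene_probes: dict[str, list[str]] = {}
    for gene, probe in target_map.gene_probe:
        if probe in mrna_probes:
            gene_probes.setdefault(gene, []).append(probe)
    pairs: set[tuple[str, str, str]] = set()
    for fam, gene in target_map.family_gene:
        for mir in fam_members.get(fam, ()):
            for probe in gene_probes.get(gene, ()):
                pairs.add((mir, probe, gene))
    return sorted(pairs)


def mass_correlations(
    pairs: list[tuple[str, str, str]],
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    fdr: float,
) -> pd.DataFrame:
    """Pearson r for every pair over shared samples, BH-adjusted jointly.

    Returns a DataFrame with columns ``mirna, probe, gene, n, r, p, q,
    significant``; the two-tailed p uses the t transform with n-2
    degrees of freedom and BH is applied across all pairs as one family.
    """
    shared = mirna.samples.intersection(mrna.samples)
    if len(shared) < 3:
        raise ConfigurationError(f"only {len(shared)} shared samples; need >= 3")
    miss_m = {m for m, _, _ in pairs} - set(mirna.features)
    miss_p = {p for _, p, _ in pairs} - set(mrna.features)
    if miss_m or miss_p:
        raise ConfigurationError(
            f"pairs reference missing features: miRNAs {sorted(miss_m)[:5]}, "
            f"probes {sorted(miss_p)[:5]}"
        )
    if not pairs:
        return pd.DataFrame(
            columns=["mirna", "probe", "gene", "n", "r", "p", "q", "significant"]
        )
    mir_names = [m for m, _, _ in pairs]
    probe_names = [p for _, p, _ in pairs]
    x = mirna.data.loc[mir_names, shared].to_numpy(float)
    y = mrna.data.loc[probe_names, shared].to_numpy(float)
    n = len(shared)
    r = pearson_rows(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.clip(p, 0.0, 1.0))
    q = bh_adjust(np.nan_to_num(p, nan=1.0))
    out = pd.DataFrame(
        {
            "mirna": mir_names,
            "probe": probe_names,
            "gene": [g for _, _, g in pairs],
            "n": n,
            "r": r,
            "p": p,
            "q": q,
            "significant": q < fdr,
        }
    )
    return out


@dataclass
class PermutationSummary:
    """Significant-pair counts under sample-label permutations of the mRNA
    matrix, with rank-sum comparisons of observed vs permuted r values."""

    counts: list[int]
    mean: float
    sd: float
    rank_sum_ps: list[float]
    observed_significant: int

    def __post_init__(self) -> None:
        if self.counts:
            if not np.isclose(self.mean, float(np.mean(self.counts))):
                raise ConfigurationError("permutation mean inconsistent with counts")

    @property
    def max_rank_sum_p(self) -> float:
        return max(self.rank_sum_ps) if self.rank_sum_ps else float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["max_rank_sum_p"] = self.max_rank_sum_p
        return d


def permutation_null(
    pairs: list[tuple[str, str, str]],
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    n_perm: int,
    fdr: float,
    seed: int,
) -> PermutationSummary:
    """Recompute the mass correlation under ``n_perm`` random permutations
    of the mRNA matrix's sample labels (the miRNA matrix stays fixed).

    Each permutation destroys the cell-line correspondence between the
    two matrices while preserving both marginal distributions.  The
    summary records per-permutation significant counts and, per
    permutation, a two-sided Wilcoxon rank-sum p comparing the observed
    r values with the permuted ones.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = mass_correlations(pairs, mirna, mrna, fdr)
    obs_r = observed["r"].dropna().to_numpy()
    counts: list[int] = []
    ps: list[float] = []
    samples = list(mrna.samples)
    for _ in range(n_perm):
        perm = rng.permutation(len(samples))
        shuffled = mrna.data.copy()
        shuffled.columns = [samples[i] for i in perm]
        res = mass_correlations(pairs, mirna, ExpressionMatrix(shuffled, "log2"), fdr)
        counts.append(int(res["significant"].sum()))
        perm_r = res["r"].dropna().to_numpy()
        ps.append(float(stats.mannwhitneyu(obs_r, perm_r, alternative="two-sided").pvalue))
    return PermutationSummary(
        counts=counts,
        mean=float(np.mean(counts)),
        sd=float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
        rank_sum_ps=ps,
        observed_significant=int(observed["significant"].sum()),
    )


def sign_summary(records: pd.DataFrame) -> tuple[int, int, float]:
    """(n_negative, n_positive, fraction_negative) over significant pairs.

    r = 0 counts as positive; with no significant pairs the fraction is
    reported as 0.
    """
    sig = records[records["significant"]]
    n_neg = int((sig["r"] < 0).sum())
    n_pos = int((sig["r"] >= 0).sum())
    total = n_neg + n_pos
    return n_neg, n_pos, (n_neg / total if total else 0.0)


def expected_false_discoveries(n_significant: int, fdr: float) -> float:
    """Expected number of false discoveries among ``n_significant`` calls
    under BH control at level ``fdr``."""
    if not 0 < fdr < 1:
        raise ConfigurationError("fdr must lie in (0, 1)")
    return fdr * n_significant
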