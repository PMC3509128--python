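"""Synthetic microRNA panel generator with planted ground truth.

Emulates the data structure of a 60-line, nine-tissue cell-line panel
profiled on a spotted oligonucleotide miRNA array: ~850 target probes
spotted in quadruplicate plus GC-binned non-specific background probes,
hybridized in nine batches of eight arrays over three days, with four
samples assayed in quadruplicate for replicate QC.

The spot-level signal model is the convolution the RMA background
correction inverts: intensity = true signal + Gaussian optical
background whose mean depends on the probe's GC bin.  True per-feature
abundances are log-uniform across the platform's dynamic range (so the
panel presents a full signal continuum to rank-based normalization),
scaled by multiplicative -- log2-additive -- tissue / mutation / batch /
noise effects.  Background probes carry background only.
Every planted effect is recorded in a TruthSet so downstream recovery
tests can score sensitivity against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from mirpanel.matrix import ConfigurationError, ExpressionMatrix
from mirpanel.targets import TargetMap

#: default tissue composition: nine tissues, sixty lines
DEFAULT_TISSUE_GROUPS: tuple[tuple[str, int], ...] = (
    ("breast", 6),
    ("cns", 6),
    ("colon", 7),
    ("leukemia", 6),
    ("melanoma", 9),
    ("nsclc", 9),
    ("ovarian", 7),
    ("prostate", 2),
    ("renal", 8),
)

#: per-GC-bin background intensity means (linear scale)
GC_BIN_BACKGROUND_MEANS: dict[str, float] = {
    "gc1": 40.0,
    "gc2": 55.0,
    "gc3": 70.0,
    "gc4": 85.0,
    "gc5": 100.0,
}


@dataclass
class PanelDesign:
    """Physical layout of the simulated panel.

    Defaults mirror the emulated study: 60 samples over nine tissues,
    847 miRNA probes in quadruplicate, 95 background probes in five GC
    bins, 72 arrays in nine batches of eight over three days, and four
    samples assayed in quadruplicate.
    """

    n_samples: int = 60
    tissue_groups: tuple[tuple[str, int], ...] = DEFAULT_TISSUE_GROUPS
    n_mirna_probes: int = 847
    n_background_probes_per_gc_bin: int = 19
    gc_bins: tuple[str, ...] = tuple(GC_BIN_BACKGROUND_MEANS)
    spots_per_probe: int = 4
    n_batches: int = 9
    batches_per_day: tuple[int, ...] = (2, 3, 4)
    n_replicate_samples: int = 4
    replicate_arrays: int = 4  # total hybridizations for a replicated sample

    def __post_init__(self) -> None:
        total = sum(size for _, size in self.tissue_groups)
        if total != self.n_samples:
            raise ConfigurationError(
                f"tissue_groups sizes sum to {total}, expected n_samples={self.n_samples}"
            )
        if self.spots_per_probe < 1:
            raise ConfigurationError("spots_per_probe must be >= 1")
        if self.n_mirna_probes < 1:
            raise ConfigurationError("n_mirna_probes must be >= 1")
        if self.n_background_probes_per_gc_bin < 1:
            raise ConfigurationError("n_background_probes_per_gc_bin must be >= 1")
        if sum(self.batches_per_day) != self.n_batches:
            raise ConfigurationError("batches_per_day must sum to n_batches")
        if self.n_replicate_samples > self.n_samples:
            raise ConfigurationError("n_replicate_samples exceeds n_samples")

    @property
    def feature_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(1, self.n_mirna_probes + 1)]

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for tissue, size in self.tissue_groups:
            for i in range(1, size + 1):
                rows.append({"sample_id": f"{tissue}-{i:02d}", "tissue": tissue})
        return pd.DataFrame(rows)


@dataclass
class EffectSpec:
    """Planted effects and noise levels of the generator.

    All shifts and couplings act on the log2 scale.  ``noise_sd`` is the
    per-sample biological noise SD and ``batch_sd`` the SD of additive
    log2 batch offsets (multiplicative on the linear scale).
    ``expressed_fraction`` controls how many features carry signal at
    all; the rest are background-only and should end up called absent.
    """

    de_features: dict[str, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    mutation_effects: dict[str, tuple[tuple[str, ...], float, tuple[str, ...]]] = field(
        default_factory=dict
    )
    phenotype_effects: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=dict
    )
    target_pairs: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 0.5
    batch_sd: float = 0.25
    expressed_fraction: float = 0.35
    log2_expressed_range: tuple[float, float] = (1.0, 11.0)
    log2_effect_range: tuple[float, float] = (7.0, 8.5)
    background_sd: float = 15.0
    extreme_phenotype_group: str | None = None
    extreme_phenotype_offset: float = -4.0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.batch_sd < 0:
            raise ConfigurationError("batch_sd must be >= 0")
        if not 0 < self.expressed_fraction <= 1:
            raise ConfigurationError("expressed_fraction must lie in (0, 1]")
        for tissue, (feats, shift) in self.de_features.items():
            if not np.isfinite(shift):
                raise ConfigurationError(f"non-finite DE shift for {tissue}")
        for _, (_, shift, _) in self.mutation_effects.items():
            if not np.isfinite(shift):
                raise ConfigurationError("non-finite mutation shift")
        for pheno, (_, rho) in self.phenotype_effects.items():
            if not abs(rho) <= 1:
                raise ConfigurationError(f"|planted correlation| > 1 for {pheno}")
        for _, _, rho in self.target_pairs:
            if not abs(rho) <= 1:
                raise ConfigurationError("|planted pair correlation| > 1")

    @property
    def effect_features(self) -> set[str]:
        out: set[str] = set()
        for feats, _ in self.de_features.values():
            out |= set(feats)
        for feats, _, _ in self.mutation_effects.values():
            out |= set(feats)
        for feats, _ in self.phenotype_effects.values():
            out |= set(feats)
        out |= {m for m, _, _ in self.target_pairs}
        return out


@dataclass
class TruthSet:
    """Everything needed to score recovery of planted effects."""

    effects: EffectSpec
    seed: int
    expressed_features: list[str]
    feature_base_log2: pd.Series  # realized baseline log2 true signal per feature
    sample_log2: pd.DataFrame  # realized true log2 signal, feature x sample
    group_means: pd.DataFrame  # realized mean log2 per feature x tissue
    phenotype_latents: pd.DataFrame  # per-sample latent factor per phenotype
    batch_offsets: pd.Series  # realized log2 offset per batch

    def write_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "effects": _effects_to_jsonable(self.effects),
            "expressed_features": self.expressed_features,
            "feature_base_log2": self.feature_base_log2.round(6).to_dict(),
            "batch_offsets": self.batch_offsets.round(6).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _effects_to_jsonable(effects: EffectSpec) -> dict:
    d = dataclasses.asdict(effects)
    d["de_features"] = {k: [list(v[0]), v[1]] for k, v in effects.de_features.items()}
    d["mutation_effects"] = {
        k: [list(v[0]), v[1], list(v[2])] for k, v in effects.mutation_effects.items()
    }
    d["phenotype_effects"] = {
        k: [list(v[0]), v[1]] for k, v in effects.phenotype_effects.items()
    }
    d["target_pairs"] = [list(t) for t in effects.target_pairs]
    return d


def default_effect_spec(design: PanelDesign, seed: int = 0) -> EffectSpec:
    """A study-shaped default effect spec: +2 log2 tissue shifts on 20
    features each for two well-separating tissues, a mutation effect on
    two features, one phenotype with 10 correlated features (r = 0.7),
    and 30 negatively correlated miRNA-target pairs (r = -0.6)."""
    rng = np.random.default_rng(seed)
    feats = design.feature_ids
    picks = rng.choice(len(feats), size=min(92, len(feats)), replace=False)
    pool = [feats[i] for i in picks]
    leukemia_feats = tuple(pool[0:20])
    melanoma_feats = tuple(pool[20:40])
    mutation_feats = tuple(pool[40:42])
    pheno_feats = tuple(pool[42:52])
    target_mirnas = pool[52:82]
    samples = design.sample_frame()
    non_melanoma = samples.loc[samples["tissue"] != "melanoma", "sample_id"]
    mutant_lines = tuple(
        samples.loc[samples["tissue"] == "melanoma", "sample_id"].tolist()
        + non_melanoma.sample(n=4, random_state=int(rng.integers(2**31))).tolist()
    )
    return EffectSpec(
        de_features={"leukemia": (leukemia_feats, 2.0), "melanoma": (melanoma_feats, 2.0)},
        mutation_effects={"GENE1": (mutation_feats, 1.5, mutant_lines)},
        phenotype_effects={"SF2": (pheno_feats, 0.7), "doubling_time": ((), 0.0)},
        target_pairs=tuple(
            (m, f"probe-{i:05d}", -0.6) for i, m in enumerate(target_mirnas, start=1)
        ),
    )


# ---------------------------------------------------------------------------
# panel simulation


def simulate_panel(
    design: PanelDesign, effects: EffectSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthSet]:
    """Generate (spot table, probe annotation, sample sheet, truth).

    Spot intensity = true linear signal + N(bin mean, background_sd),
    clipped at a small positive floor.  True per-feature abundance is
    log-uniform over ``log2_expressed_range`` and shared by a probe's
    quadruplicate spots; per-sample log2 effects are multiplicative on
    the linear scale.  Unexpressed features and background probes carry
    background noise only.
    """
    rng = np.random.default_rng(seed)
    features = design.feature_ids
    m = len(features)
    samples = design.sample_frame()
    sample_ids = samples["sample_id"].tolist()
    tissue_of = samples.set_index("sample_id")["tissue"]

    unknown = effects.effect_features - set(features)
    if unknown - {p for _, p, _ in effects.target_pairs}:
        raise ConfigurationError(
            f"effect features not in panel: {sorted(unknown)[:5]}"
        )
    for gene, (_, _, mutants) in effects.mutation_effects.items():
        bad = set(mutants) - set(sample_ids)
        if bad:
            raise ConfigurationError(f"{gene}: unknown mutant lines {sorted(bad)[:5]}")

    # expressed stratum and baseline abundances: log-uniform over the
    # platform dynamic range so rank-based normalization can represent
    # planted log2 shifts; effect carriers sit mid-continuum, clearly
    # above the presence threshold yet with rank headroom on both sides
    n_expr = int(round(effects.expressed_fraction * m))
    expressed_idx = rng.choice(m, size=n_expr, replace=False)
    expressed = np.zeros(m, dtype=bool)
    expressed[expressed_idx] = True
    effect_feats = effects.effect_features & set(features)
    feat_pos = {f: i for i, f in enumerate(features)}
    for f in effect_feats:
        expressed[feat_pos[f]] = True
    base_log2 = np.full(m, -np.inf)
    lo, hi = effects.log2_expressed_range
    base_log2[expressed] = rng.uniform(lo, hi, size=int(expressed.sum()))
    elo, ehi = effects.log2_effect_range
    for f in sorted(effect_feats):
        base_log2[feat_pos[f]] = rng.uniform(elo, ehi)

    # per-sample log2 effect matrix
    delta = rng.normal(0.0, effects.noise_sd, size=(m, len(sample_ids)))
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    for tissue, (feats, shift) in effects.de_features.items():
        cols = [sample_pos[s] for s in sample_ids if tissue_of[s] == tissue]
        rows = [feat_pos[f] for f in feats]
        delta[np.ix_(rows, cols)] += shift
    for gene, (feats, shift, mutants) in effects.mutation_effects.items():
        cols = [sample_pos[s] for s in mutants]
        rows = [feat_pos[f] for f in feats]
        delta[np.ix_(rows, cols)] += shift
    latents = {}
    total_sd = float(np.hypot(effects.noise_sd, effects.batch_sd))
    for pheno, (feats, rho) in effects.phenotype_effects.items():
        u = rng.normal(0.0, 1.0, size=len(sample_ids))
        latents[pheno] = u
        if feats and rho != 0:
            alpha = total_sd * abs(rho) / np.sqrt(1.0 - rho**2)
            rows = [feat_pos[f] for f in feats]
            delta[rows, :] += np.sign(rho) * alpha * u[None, :]
    phenotype_latents = pd.DataFrame(latents, index=sample_ids)

    true_sample_log2 = base_log2[:, None] + delta  # -inf rows stay -inf
    truth_log2 = pd.DataFrame(true_sample_log2, index=features, columns=sample_ids)

    # arrays, batches, replicates
    replicate_samples = [
        samples["sample_id"].iloc[int(round(k * len(sample_ids) / design.n_replicate_samples))]
        for k in range(design.n_replicate_samples)
    ]
    array_rows = []
    for s in sample_ids:
        array_rows.append({"array_id": f"arr-{s}-r1", "sample_id": s})
    for s in replicate_samples:
        for r in range(2, design.replicate_arrays + 1):
            array_rows.append({"array_id": f"arr-{s}-r{r}", "sample_id": s})
    arrays = pd.DataFrame(array_rows)
    n_arrays = len(arrays)
    batch_of = [i % design.n_batches for i in range(n_arrays)]
    day_of_batch = np.repeat(
        np.arange(1, len(design.batches_per_day) + 1), design.batches_per_day
    )
    arrays["batch"] = [f"batch-{b + 1}" for b in batch_of]
    arrays["day"] = [int(day_of_batch[b]) for b in batch_of]
    arrays["cell_line"] = arrays["sample_id"]
    arrays["tissue"] = arrays["sample_id"].map(tissue_of)
    sheet = arrays[["array_id", "sample_id", "cell_line", "tissue", "day", "batch"]]

    batch_names = [f"batch-{b + 1}" for b in range(design.n_batches)]
    batch_offsets = pd.Series(
        rng.normal(0.0, effects.batch_sd, size=design.n_batches), index=batch_names
    )

    # probe annotation
    annot_rows = []
    for i, f in enumerate(features):
        annot_rows.append(
            {
                "probe_id": f"p-{i + 1:04d}",
                "feature_id": f,
                "is_background": False,
                "gc_bin": design.gc_bins[i % len(design.gc_bins)],
                "species": "hsa",
            }
        )
    for bin_label in design.gc_bins:
        for k in range(design.n_background_probes_per_gc_bin):
            annot_rows.append(
                {
                    "probe_id": f"bg-{bin_label}-{k + 1:02d}",
                    "feature_id": "",
                    "is_background": True,
                    "gc_bin": bin_label,
                    "species": "none",
                }
            )
    annot = pd.DataFrame(annot_rows)

    # spot intensities
    bg_mean = {b: GC_BIN_BACKGROUND_MEANS.get(b, 70.0) for b in design.gc_bins}
    target_bins = np.array([bg_mean[design.gc_bins[i % len(design.gc_bins)]] for i in range(m)])
    spot_frames = []
    linear_true = np.exp2(np.where(np.isfinite(true_sample_log2), true_sample_log2, -np.inf))
    linear_true = np.where(np.isfinite(true_sample_log2), linear_true, 0.0)
    s_per = design.spots_per_probe
    n_bg = design.n_background_probes_per_gc_bin
    for _, arr in sheet.iterrows():
        j = sample_pos[arr["sample_id"]]
        bmult = 2.0 ** batch_offsets[arr["batch"]]
        true_arr = linear_true[:, j] * bmult  # (m,)
        noise = rng.normal(0.0, effects.background_sd, size=(m, s_per))
        intensities = true_arr[:, None] + target_bins[:, None] + noise
        spot_frames.append(
            pd.DataFrame(
                {
                    "spot_id": [
                        f"p-{i + 1:04d}-s{s + 1}" for i in range(m) for s in range(s_per)
                    ],
                    "probe_id": np.repeat([f"p-{i + 1:04d}" for i in range(m)], s_per),
                    "array_id": arr["array_id"],
                    "intensity": np.clip(intensities.ravel(), 0.5, None),
                }
            )
        )
        bg_rows = []
        for bin_label in design.gc_bins:
            vals = rng.normal(bg_mean[bin_label], effects.background_sd, size=(n_bg, s_per))
            for k in range(n_bg):
                for s in range(s_per):
                    bg_rows.append(
                        (
                            f"bg-{bin_label}-{k + 1:02d}-s{s + 1}",
                            f"bg-{bin_label}-{k + 1:02d}",
                            arr["array_id"],
                            max(vals[k, s], 0.5),
                        )
                    )
        spot_frames.append(
            pd.DataFrame(bg_rows, columns=["spot_id", "probe_id", "array_id", "intensity"])
        )
    spots = pd.concat(spot_frames, ignore_index=True)

    group_means = {}
    for tissue, _ in design.tissue_groups:
        cols = [s for s in sample_ids if tissue_of[s] == tissue]
        group_means[tissue] = truth_log2[cols].mean(axis=1)
    truth = TruthSet(
        effects=effects,
        seed=seed,
        expressed_features=[f for f, e in zip(features, expressed) if e],
        feature_base_log2=pd.Series(base_log2, index=features),
        sample_log2=truth_log2,
        group_means=pd.DataFrame(group_means),
        phenotype_latents=phenotype_latents,
        batch_offsets=batch_offsets,
    )
    return spots, annot, sheet, truth


# ---------------------------------------------------------------------------
# companion datasets


def simulate_companion_dataset(
    expr: ExpressionMatrix,
    feature_subset: float,
    noise_sd: float,
    seed: int,
    distortion: bool = True,
) -> ExpressionMatrix:
    """A second platform measuring the same biology.

    Keeps a random fraction of features, applies a per-feature affine
    recalibration (slope and offset differ by feature, emulating
    platform-specific response curves), and adds independent Gaussian
    noise of SD ``noise_sd``.
    """
    if not 0 < feature_subset <= 1:
        raise ConfigurationError("feature_subset must lie in (0, 1]")
    if expr.scale != "log2":
        raise ConfigurationError("companion simulation expects a log2 matrix")
    rng = np.random.default_rng(seed)
    m = expr.data.shape[0]
    k = int(round(feature_subset * m))
    keep_idx = np.sort(rng.choice(m, size=k, replace=False))
    sub = expr.data.iloc[keep_idx]
    if distortion:
        slope = rng.uniform(0.5, 2.0, size=k)
        offset = rng.normal(0.0, 2.0, size=k)
    else:
        slope = np.ones(k)
        offset = np.zeros(k)
    noisy = sub.mul(slope, axis=0).add(offset, axis=0) + rng.normal(
        0.0, noise_sd, size=sub.shape
    )
    return ExpressionMatrix(noisy, scale="log2")


def companion_noise_for_mean_r(expr: ExpressionMatrix, target_mean_r: float) -> float:
    """Noise SD at which the companion's expected per-feature r equals
    ``target_mean_r``.

    For a feature with cross-sample SD sigma_f, added noise of SD tau
    attenuates the correlation to sigma_f / sqrt(sigma_f^2 + tau^2);
    the calibration solves for tau so the mean over features hits the
    target.  Assumes no per-feature slope distortion (``distortion=False``
    in :func:`simulate_companion_dataset`); a slope b rescales the signal
    and with it the attenuation.
    """
    if not 0 < target_mean_r < 1:
        raise ConfigurationError("target mean r must lie in (0, 1)")
    sds = expr.data.std(axis=1, ddof=1).to_numpy()
    sds = sds[sds > 0]
    if sds.size == 0:
        raise ConfigurationError("matrix has no feature with positive variance")

    def mean_r(tau: float) -> float:
        return float(np.mean(sds / np.hypot(sds, tau)))

    hi = 10.0 * sds.max() / np.sqrt(max(target_mean_r, 1e-6))
    return float(optimize.brentq(lambda t: mean_r(t) - target_mean_r, 1e-9, hi))


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    sheet: pd.DataFrame,
    truth: TruthSet,
    params: list[str],
    seed: int,
) -> pd.DataFrame:
    """Continuous positive phenotype values per cell line.

    Each requested parameter must have a phenotype effect in the truth
    set; its per-sample latent factor becomes the log2 phenotype, so
    features planted on that latent correlate with the phenotype at the
    planted magnitude.  If the effect spec names an extreme phenotype
    group, that tissue's lines additionally receive a large log2 offset,
    reproducing the group-driven-correlation hazard.
    """
    rng = np.random.default_rng(seed)
    known = set(truth.effects.phenotype_effects)
    unknown = set(params) - known
    if unknown:
        raise ConfigurationError(f"unknown phenotype names: {sorted(unknown)}")
    lines = sheet.drop_duplicates("sample_id")
    tissue_of = lines.set_index("sample_id")["tissue"]
    rows = []
    for param in params:
        u = truth.phenotype_latents[param].copy()
        log2_value = 3.0 + u
        if truth.effects.extreme_phenotype_group is not None:
            mask = tissue_of.reindex(u.index) == truth.effects.extreme_phenotype_group
            log2_value = log2_value + truth.effects.extreme_phenotype_offset * mask.astype(float)
        # tiny measurement jitter so repeated phenotypes are not collinear
        log2_value = log2_value + rng.normal(0.0, 1e-3, size=len(u))
        for s, v in zip(u.index, np.exp2(log2_value)):
            rows.append({"cell_line": s, "parameter": param, "value": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target maps and mRNA data


def make_target_map(
    n_families: int,
    members_per_family: int,
    genes_per_family: int,
    probes_per_gene: int,
    mirna_names: list[str] | None = None,
) -> TargetMap:
    """Deterministic synthetic family -> miRNA / gene -> probe map.

    Member miRNA names default to generated identifiers; passing
    ``mirna_names`` (length n_families * members_per_family) aligns the
    map with an existing panel's feature ids.
    """
    for name, v in (
        ("n_families", n_families),
        ("members_per_family", members_per_family),
        ("genes_per_family", genes_per_family),
        ("probes_per_gene", probes_per_gene),
    ):
        if v < 1:
            raise ConfigurationError(f"{name} must be >= 1")
    n_members = n_families * members_per_family
    if mirna_names is not None and len(mirna_names) != n_members:
        raise ConfigurationError(
            f"need {n_members} miRNA names, got {len(mirna_names)}"
        )
    family_mirna = []
    family_gene = []
    gene_probe = []
    idx = 0
    for f in range(1, n_families + 1):
        fam = f"fam-{f:03d}"
        for _ in range(members_per_family):
            name = (
                mirna_names[idx] if mirna_names is not None else f"miR-syn-{idx + 1:04d}"
            )
            family_mirna.append((fam, name))
            idx += 1
        for g in range(1, genes_per_family + 1):
            gene = f"gene-{f:03d}-{g:02d}"
            family_gene.append((fam, gene))
            for p in range(1, probes_per_gene + 1):
                gene_probe.append((gene, f"{gene}-probe{p}"))
    return TargetMap(tuple(family_mirna), tuple(family_gene), tuple(gene_probe))


def simulate_target_mrna(
    mirna: ExpressionMatrix,
    pairs: list[tuple[str, str, float]],
    extra_probes: int | list[str],
    seed: int,
    samples: list[str] | None = None,
) -> ExpressionMatrix:
    """mRNA probe x sample log2 matrix with planted pair correlations.

    For each (miRNA, probe, rho) the probe's profile is rho times the
    z-scored miRNA profile plus sqrt(1 - rho^2) independent noise, mapped
    onto a log2-like location/scale; ``extra_probes`` uncorrelated probes
    are appended.  Only samples shared with the miRNA matrix (or the
    given subset) are produced.
    """
    rng = np.random.default_rng(seed)
    cols = list(samples) if samples is not None else list(mirna.samples)
    missing = set(cols) - set(mirna.samples)
    if missing:
        raise ConfigurationError(f"samples absent from miRNA matrix: {sorted(missing)[:5]}")
    n = len(cols)
    rows = {}
    for mir, probe, rho in pairs:
        if mir not in mirna.features:
            raise ConfigurationError(f"pair references unknown miRNA {mir!r}")
        x = mirna.data.loc[mir, cols].to_numpy(float)
        sd = x.std(ddof=1)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        profile = rho * z + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(size=n)
        rows[probe] = 7.0 + 1.5 * profile
    null_names = (
        [f"null-probe-{k:05d}" for k in range(1, extra_probes + 1)]
        if isinstance(extra_probes, int)
        else list(extra_probes)
    )
    for name in null_names:
        rows[name] = 7.0 + 1.5 * rng.normal(size=n)
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=cols), scale="log2"
    )
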