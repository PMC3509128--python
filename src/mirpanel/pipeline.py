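"""End-to-end orchestration of the analysis stages.

``run_all`` executes simulate -> preprocess -> filter -> concordance ->
cluster -> de -> phenotype -> targets, writing each stage's tables under
one output directory together with a manifest (config snapshot, output
digests, stage timings).  Stage boundaries are file-based: any stage can
be re-run alone against the cached outputs of its upstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import mirpanel
from mirpanel import concordance as conc
from mirpanel import filtering, groups, phenotype, preprocess, synthetic, targets
from mirpanel.config import AnalysisConfig
from mirpanel.matrix import ConfigurationError, DetectionCalls, ExpressionMatrix

STAGES = (
    "simulate",
    "preprocess",
    "filter",
    "concordance",
    "cluster",
    "de",
    "phenotype",
    "targets",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    package_version: str
    stages_run: list[str]
    outputs: dict[str, dict] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def comparable(self) -> dict:
        """Manifest content without timings, for determinism checks."""
        d = dataclasses.asdict(self)
        d.pop("timings")
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, out: Path, name: str) -> None:
    p = out / name
    manifest.outputs[name] = {"path": name, "sha256": _sha256(p)}


def run_all(
    config: AnalysisConfig,
    out_dir: str | Path,
    simulate: bool = True,
    design: synthetic.PanelDesign | None = None,
    effects: synthetic.EffectSpec | None = None,
    stages: list[str] | None = None,
) -> RunManifest:
    """Run the requested stages (default: all) and return the manifest.

    With ``simulate`` the panel and all companion tables come from the
    synthetic generator; otherwise the simulate-stage files must already
    exist in ``out_dir``.  A stage failure raises :class:`StageError`
    after dropping a ``<stage>.partial`` marker next to any partial
    outputs.
    """
    requested = list(stages) if stages is not None else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    if not simulate and "simulate" in requested:
        requested.remove("simulate")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        package_version=mirpanel.__version__,
        stages_run=[s for s in STAGES if s in requested],
    )
    for stage in STAGES:
        if stage not in requested:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, out, manifest, design, effects)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            (out / f"{stage}.partial").write_text(str(exc))
            raise StageError(stage, exc) from exc
        manifest.timings[stage] = time.perf_counter() - t0
    manifest.write_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(config, out: Path, manifest, design, effects) -> None:
    seed = int(config.seeds.get("simulate", 0))
    design = design if design is not None else synthetic.PanelDesign()
    effects = (
        effects if effects is not None else synthetic.default_effect_spec(design, seed)
    )
    spots, annot, sheet, truth = synthetic.simulate_panel(design, effects, seed)
    spots.to_csv(out / "spots.tsv", sep="\t", index=False)
    annot.to_csv(out / "probe_annotation.tsv", sep="\t", index=False)
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    truth.write_json(out / "truth.json")

    pheno = synthetic.simulate_phenotypes(
        sheet, truth, list(effects.phenotype_effects), int(config.seeds.get("phenotype", 0))
    )
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    lines = sheet["sample_id"].drop_duplicates()
    mut_rows = []
    for gene, (_, _, mutants) in effects.mutation_effects.items():
        mutant_set = set(mutants)
        for line in lines:
            mut_rows.append(
                {"cell_line": line, "gene": gene, "status": int(line in mutant_set)}
            )
    pd.DataFrame(mut_rows, columns=["cell_line", "gene", "status"]).to_csv(
        out / "mutations.tsv", sep="\t", index=False
    )

    # target map embedding the planted pairs plus null families over other features
    planted = list(effects.target_pairs)
    fam_mirna = [(f"fam-planted-{i:03d}", m) for i, (m, _, _) in enumerate(planted, 1)]
    fam_gene = [(f"fam-planted-{i:03d}", f"gene-pl-{i:03d}") for i in range(1, len(planted) + 1)]
    gene_probe = [(f"gene-pl-{i:03d}", p) for i, (_, p, _) in enumerate(planted, 1)]
    planted_mirnas = {m for m, _, _ in planted}
    others = [f for f in design.feature_ids if f not in planted_mirnas]
    n_null_fams = min(30, len(others) // 2)
    if n_null_fams >= 1:
        null_map = synthetic.make_target_map(
            n_families=n_null_fams,
            members_per_family=2,
            genes_per_family=6,
            probes_per_gene=2,
            mirna_names=others[: n_null_fams * 2],
        )
        null_rels = (null_map.family_mirna, null_map.family_gene, null_map.gene_probe)
    else:
        null_rels = ((), (), ())
    tmap = targets.TargetMap(
        tuple(fam_mirna) + null_rels[0],
        tuple(fam_gene) + null_rels[1],
        tuple(gene_probe) + null_rels[2],
    )
    tmap.write_tsv(out / "target_map.tsv")

    # companion mRNA matrix: planted pairs correlated with the TRUE miRNA
    # profiles; every other mapped probe is independent noise
    expressed_true = ExpressionMatrix(
        truth.sample_log2.loc[truth.expressed_features], scale="log2"
    )
    null_probes = sorted({p for _, p in null_rels[2]})
    mrna = synthetic.simulate_target_mrna(
        expressed_true,
        planted,
        null_probes,
        int(config.seeds.get("companion", 0)),
    )
    mrna.write_tsv(out / "mrna_expression.tsv")
    for name in (
        "spots.tsv",
        "probe_annotation.tsv",
        "sample_sheet.tsv",
        "truth.json",
        "phenotypes.tsv",
        "mutations.tsv",
        "target_map.tsv",
        "mrna_expression.tsv",
    ):
        _register(manifest, out, name)


def _stage_preprocess(config, out: Path, manifest, design, effects) -> None:
    spots = pd.read_csv(out / "spots.tsv", sep="\t")
    annot = pd.read_csv(out / "probe_annotation.tsv", sep="\t", keep_default_na=False)
    sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    expr, calls, qc = preprocess.preprocess_pipeline(
        spots, annot, sheet, detection_alpha=config.detection_alpha
    )
    expr.write_tsv(out / "expression_log2.tsv")
    calls.write_tsv(out / "detection_p.tsv")
    (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
    for name in ("expression_log2.tsv", "detection_p.tsv", "qc.json"):
        _register(manifest, out, name)


def _load_expr_and_calls(config, out: Path) -> tuple[ExpressionMatrix, DetectionCalls]:
    expr = ExpressionMatrix.read_tsv(out / "expression_log2.tsv", scale="log2")
    pvals = pd.read_csv(out / "detection_p.tsv", sep="\t", index_col="feature_id")
    return expr, DetectionCalls(p_values=pvals, alpha=config.detection_alpha)


def _stage_filter(config, out: Path, manifest, design, effects) -> None:
    expr, calls = _load_expr_and_calls(config, out)
    filtered, report = filtering.filter_pipeline(expr, calls, config.iqr_multiplier)
    filtered.write_tsv(out / "expression_filtered.tsv")
    report.write_json(out / "filter_report.json")
    for name in ("expression_filtered.tsv", "filter_report.json"):
        _register(manifest, out, name)


def _stage_concordance(config, out: Path, manifest, design, effects) -> None:
    expr = ExpressionMatrix.read_tsv(out / "expression_filtered.tsv", scale="log2")
    seed = int(config.seeds.get("companion", 0))
    noise = synthetic.companion_noise_for_mean_r(expr, 0.5)
    companion = synthetic.simulate_companion_dataset(expr, 0.6, noise, seed)
    result = conc.per_feature_correlation(expr, companion)
    control = conc.per_feature_correlation(expr, conc.resample_control(companion, seed + 1))
    result.per_feature_r.rename("r").to_csv(
        out / "concordance_r.tsv", sep="\t", index_label="feature_id"
    )
    cdf = result.cdf(config.concordance_bin)
    cdf["control_cumulative_fraction"] = conc.cdf_bins(
        control.per_feature_r.to_numpy(), config.concordance_bin
    )["cumulative_fraction"]
    cdf.to_csv(out / "concordance_cdf.tsv", sep="\t", index=False)
    summary = {
        "mean_r": result.mean_r,
        "sd_r": result.sd_r,
        "n_shared_samples": result.n_shared_samples,
        "fraction_above_cutoff": result.fraction_above(config.concordance_cutoff),
        "cutoff": config.concordance_cutoff,
        "control_mean_r": control.mean_r,
        "companion_noise_sd": noise,
    }
    (out / "concordance_summary.json").write_text(json.dumps(summary, indent=2))
    for name in ("concordance_r.tsv", "concordance_cdf.tsv", "concordance_summary.json"):
        _register(manifest, out, name)


def _stage_cluster(config, out: Path, manifest, design, effects) -> None:
    expr = ExpressionMatrix.read_tsv(out / "expression_filtered.tsv", scale="log2")
    dendro = groups.cluster_samples(expr, optimize_leaf_order=True)
    (out / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
    _register(manifest, out, "dendrogram.newick")


def _stage_de(config, out: Path, manifest, design, effects) -> None:
    expr = ExpressionMatrix.read_tsv(out / "expression_filtered.tsv", scale="log2")
    sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tissue_results = groups.one_vs_rest_de(expr, sheet, fdr=config.fdr)
    de_tissue = pd.concat(tissue_results.values(), ignore_index=True)
    de_tissue.to_csv(out / "de_tissue.tsv", sep="\t", index=False)

    mutations = pd.read_csv(out / "mutations.tsv", sep="\t")
    mut_frames = []
    for gene in sorted(mutations["gene"].unique()):
        try:
            mut_frames.append(
                groups.mutation_de(
                    expr, mutations, gene, min_mutants=config.min_mutants, fdr=config.fdr
                )
            )
        except ConfigurationError as exc:
            warnings.warn(str(exc))
    de_mut = (
        pd.concat(mut_frames, ignore_index=True)
        if mut_frames
        else pd.DataFrame(columns=["feature", "group", "diff", "s2", "df", "t", "p", "q", "significant"])
    )
    de_mut.to_csv(out / "de_mutation.tsv", sep="\t", index=False)

    # heatmap matrix: top-k lowest-p features per tissue, z-scaled by row
    heat_feats: list[str] = []
    for tissue in sorted(tissue_results):
        for f in groups.top_k_by_p(tissue_results[tissue], config.top_k):
            if f not in heat_feats:
                heat_feats.append(f)
    heat = groups.z_scale_rows(expr.subset_features(heat_feats))
    heat.write_tsv(out / "heatmap_z.tsv")
    for name in ("de_tissue.tsv", "de_mutation.tsv", "heatmap_z.tsv"):
        _register(manifest, out, name)


def _stage_phenotype(config, out: Path, manifest, design, effects) -> None:
    expr = ExpressionMatrix.read_tsv(out / "expression_filtered.tsv", scale="log2")
    sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    pheno = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    screens = []
    kde_frames = []
    robustness = {}
    for param in sorted(pheno["parameter"].unique()):
        values = pheno.loc[pheno["parameter"] == param, "value"].to_numpy()
        kde = phenotype.gaussian_kde(phenotype.log2_zscore(values))
        kde_frames.append(
            pd.DataFrame(
                {"parameter": param, "x": kde.grid, "density": kde.density}
            )
        )
        screen = phenotype.correlation_screen(
            expr, pheno, param, cutoff=config.phenotype_cutoff_primary
        )
        screens.append(screen)
        if "leukemia" in set(sheet["tissue"]):
            full, reduced, dropped = phenotype.robustness_exclude_group(
                expr, pheno, param, sheet, "leukemia", config.phenotype_cutoff_primary
            )
            robustness[param] = {
                "full_hits": int(full["passes_cutoff"].sum()),
                "reduced_hits": int(reduced["passes_cutoff"].sum()),
                "dropped": dropped,
                "n_modes": kde.n_modes,
            }
    pd.concat(screens, ignore_index=True).to_csv(
        out / "phenotype_screen.tsv", sep="\t", index=False
    )
    pd.concat(kde_frames, ignore_index=True).to_csv(
        out / "phenotype_kde.tsv", sep="\t", index=False
    )
    (out / "phenotype_robustness.json").write_text(json.dumps(robustness, indent=2))
    for name in ("phenotype_screen.tsv", "phenotype_kde.tsv", "phenotype_robustness.json"):
        _register(manifest, out, name)


def _stage_targets(config, out: Path, manifest, design, effects) -> None:
    expr = ExpressionMatrix.read_tsv(out / "expression_filtered.tsv", scale="log2")
    mrna = ExpressionMatrix.read_tsv(out / "mrna_expression.tsv", scale="log2")
    tmap = targets.TargetMap.read_tsv(out / "target_map.tsv")
    mrna_kept = targets.range_filter(mrna, config.mrna_min_range)
    pairs = targets.expand_pairs(
        tmap, set(expr.features), set(mrna_kept.features)
    )
    records = targets.mass_correlations(pairs, expr, mrna_kept, fdr=config.fdr)
    records.to_csv(out / "target_pairs.tsv", sep="\t", index=False)
    summary = targets.permutation_null(
        pairs,
        expr,
        mrna_kept,
        n_perm=config.n_permutations,
        fdr=config.fdr,
        seed=int(config.seeds.get("permutation", 0)),
    )
    n_neg, n_pos, frac_neg = targets.sign_summary(records)
    payload = summary.to_dict()
    payload.update(
        {
            "n_pairs": len(pairs),
            "n_negative": n_neg,
            "n_positive": n_pos,
            "fraction_negative": frac_neg,
            "expected_false_discoveries": targets.expected_false_discoveries(
                summary.observed_significant, config.fdr
            ),
        }
    )
    (out / "permutation_summary.json").write_text(json.dumps(payload, indent=2))
    for name in ("target_pairs.tsv", "permutation_summary.json"):
        _register(manifest, out, name)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "filter": _stage_filter,
    "concordance": _stage_concordance,
    "cluster": _stage_cluster,
    "de": _stage_de,
    "phenotype": _stage_phenotype,
    "targets": _stage_targets,
}
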