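"""Analysis configuration: every numeric constant of the study in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from mirpanel.matrix import ConfigurationError


@dataclass
class AnalysisConfig:
    """Bundle of the analysis constants, with the study's values as defaults.

    Attributes
    ----------
    iqr_multiplier
        Signal-presence threshold is this multiple of the mean per-array IQR
        of linear-scale normalized signals (default 4).
    detection_alpha
        One-sided rank-sum level for present/absent detection calls.
    fdr
        Benjamini-Hochberg false-discovery-rate ceiling for DE and pair
        correlation significance.
    concordance_bin
        Bin width of cumulative Pearson-r distributions (default 0.025).
    concordance_cutoff
        High-concordance cutoff for the fraction of features with r above it.
    phenotype_cutoff_primary, phenotype_cutoff_reporting
        |r| cutoffs for the phenotype correlation screen (0.5 for the main
        call, 0.4 for the wider reporting table).
    rolling_window
        Width of the rolling window for inter-replicate correlation QC.
    n_permutations
        Label permutations for the miRNA-target correlation null.
    min_mutants
        Minimum mutant-line count for a mutation DE contrast.
    mrna_min_range
        Minimum log2 sample range for an mRNA probe to enter pair analysis.
    top_k
        Features with lowest DE p-values kept per group for the heatmap.
    seeds
        Named per-stage seeds; every source of randomness draws from one.
    """

    iqr_multiplier: float = 4.0
    detection_alpha: float = 0.05
    fdr: float = 0.05
    concordance_bin: float = 0.025
    concordance_cutoff: float = 0.75
    phenotype_cutoff_primary: float = 0.5
    phenotype_cutoff_reporting: float = 0.4
    rolling_window: int = 99
    n_permutations: int = 10
    min_mutants: int = 10
    mrna_min_range: float = 1.0
    top_k: int = 8
    seeds: dict = field(default_factory=lambda: {"simulate": 0, "permutation": 0})

    def __post_init__(self) -> None:
        for name in ("detection_alpha", "fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("rolling_window", "n_permutations", "min_mutants", "top_k"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.iqr_multiplier <= 0:
            raise ConfigurationError("iqr_multiplier must be > 0")
        if not 0 < self.concordance_bin <= 2:
            raise ConfigurationError("concordance_bin must lie in (0, 2]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def read_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
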