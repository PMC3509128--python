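"""Shared setup for the numbered analysis drivers.

All drivers write under results/panel/ and share one seeded
configuration, so running 01..07 in order reproduces the full analysis
and re-running any single step reuses the cached upstream outputs.
"""

from pathlib import Path

from mirpanel.config import AnalysisConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"

CONFIG = AnalysisConfig(
    seeds={"simulate": 20260920, "companion": 1, "phenotype": 2, "permutation": 3}
)
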