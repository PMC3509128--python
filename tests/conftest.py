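import numpy as np
import pandas as pd
import pytest

from mirpanel.matrix import ExpressionMatrix
from mirpanel.synthetic import EffectSpec, PanelDesign, simulate_panel


def small_design(**overrides) -> PanelDesign:
    """An 8-sample, 2-tissue, 40-probe panel that keeps tests fast."""
    params = dict(
        n_samples=8,
        tissue_groups=(("A", 4), ("B", 4)),
        n_mirna_probes=40,
        n_background_probes_per_gc_bin=6,
        spots_per_probe=4,
        n_batches=2,
        batches_per_day=(1, 1),
        n_replicate_samples=0,
    )
    params.update(overrides)
    return PanelDesign(**params)


@pytest.fixture(scope="session")
def tiny_panel():
    """One simulated small panel, shared by read-only tests."""
    design = small_design()
    effects = EffectSpec(de_features={"A": (("miR-0001", "miR-0002"), 2.0)})
    spots, annot, sheet, truth = simulate_panel(design, effects, seed=42)
    return design, effects, spots, annot, sheet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_log2_matrix(rng, m=20, n=10, prefix="f") -> ExpressionMatrix:
    data = pd.DataFrame(
        rng.normal(6.0, 1.5, size=(m, n)),
        index=[f"{prefix}{i:03d}" for i in range(m)],
        columns=[f"s{j:02d}" for j in range(n)],
    )
    return ExpressionMatrix(data, scale="log2")
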