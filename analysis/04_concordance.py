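"""Cross-dataset concordance: correlate the filtered panel feature-by-
feature with a simulated second platform, summarize as a cumulative
distribution, and contrast with a sample-label resampling control."""

import importlib
import json

from mirpanel import pipeline

setup = importlib.import_module("00_config")


def main() -> None:
    pipeline.run_all(setup.CONFIG, setup.OUT, stages=["concordance"])
    s = json.loads((setup.OUT / "concordance_summary.json").read_text())
    print(f"mean (SD) per-feature Pearson r over {s['n_shared_samples']} shared "
          f"samples: {s['mean_r']:.2f} ({s['sd_r']:.2f})")
    print(f"fraction of features with r > {s['cutoff']}: "
          f"{s['fraction_above_cutoff']:.2f}")
    print(f"resampling control mean r: {s['control_mean_r']:.3f} "
          "(correspondence destroyed)")


if __name__ == "__main__":
    main()
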