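"""Generate the synthetic 60-line panel with planted ground truth.

Writes the probe-level spot table, probe annotation, sample sheet,
phenotypes, mutation table, target map, companion mRNA matrix, and the
truth JSON under results/panel/.
"""

import importlib

from mirpanel import pipeline

setup = importlib.import_module("00_config")


def main() -> None:
    manifest = pipeline.run_all(setup.CONFIG, setup.OUT, stages=["simulate"])
    print(f"simulated panel written to {setup.OUT}")
    print(f"outputs: {', '.join(manifest.outputs)}")


if __name__ == "__main__":
    main()
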