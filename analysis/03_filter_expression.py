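"""Two-stage expressed-feature selection: drop features absent in every
sample, then features whose linear signal never reaches 4x the mean
per-array IQR."""

import importlib
import json

from mirpanel import pipeline

setup = importlib.import_module("00_config")


def main() -> None:
    pipeline.run_all(setup.CONFIG, setup.OUT, stages=["filter"])
    rep = json.loads((setup.OUT / "filter_report.json").read_text())
    print(f"{rep['n_input']} features -> {rep['n_detected']} detected "
          f"({rep['detected_pct']:.1f}%) -> {len(rep['retained_features'])} retained "
          f"({rep['expressed_pct']:.1f}%)")
    print(f"mean per-array IQR {rep['mean_iqr']:.1f}; presence threshold "
          f"{rep['threshold']:.1f} (= {rep['multiplier']:g} x mean IQR)")


if __name__ == "__main__":
    main()
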