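"""Preprocess the spot table: detection calls, RMA-style background
correction, quantile normalization, median-polish summarization,
replicate selection.  Prints the QC summary a platform run is judged by."""

import importlib
import json

from mirpanel import pipeline

setup = importlib.import_module("00_config")


def main() -> None:
    pipeline.run_all(setup.CONFIG, setup.OUT, stages=["preprocess"])
    qc = json.loads((setup.OUT / "qc.json").read_text())
    print(f"{qc['n_arrays']} arrays summarized to {qc['n_samples']} samples")
    print(f"mean (SD) of per-array 75th percentiles of log2 signal: "
          f"{qc['mean_pct75']:.2f} ({qc['sd_pct75']:.2f})")
    for sample, info in qc["replicate_correlations"].items():
        rs = ", ".join(f"{r:.3f}" for r in info["pairwise_r"])
        print(f"replicates of {sample}: pairwise r = {rs}; kept {info['best']}")


if __name__ == "__main__":
    main()
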