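"""Cluster the samples (uncentered Pearson, average linkage, optimal
leaf order) and test tissue one-vs-rest and mutation differential
expression with moderated t-statistics at FDR 5%."""

import importlib

import pandas as pd

from mirpanel import pipeline

setup = importlib.import_module("00_config")


def main() -> None:
    pipeline.run_all(setup.CONFIG, setup.OUT, stages=["cluster", "de"])
    de = pd.read_csv(setup.OUT / "de_tissue.tsv", sep="\t")
    counts = de[de["significant"]].groupby("group").size()
    total = de["feature"].nunique()
    print(f"tissue one-vs-rest DE over {total} retained features:")
    for tissue, n in counts.items():
        print(f"  {tissue}: {n} significant ({100 * n / total:.0f}%)")
    mut = pd.read_csv(setup.OUT / "de_mutation.tsv", sep="\t")
    if len(mut):
        sig = mut[mut["significant"]]
        print(f"mutation DE: {len(sig)} significant feature(s) "
              f"for {', '.join(sorted(mut['group'].unique()))}")
    print(f"dendrogram: {setup.OUT / 'dendrogram.newick'}")


if __name__ == "__main__":
    main()
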