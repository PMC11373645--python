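#!/usr/bin/env python
"""Candidate regions, literature intersection, GO keywords, comparison.

Collects genes within +/-300 kb of each significant marker for the
binned and semantic analyses, flags regions containing literature
height genes, counts hormone-keyword GO annotations, checks how many
true causal loci were recovered, and lines up regions shared between
the two analyses.
"""

import dataclasses
import importlib.util
from pathlib import Path

import pandas as pd

from spokenpheno.pipeline import Pipeline

spec = importlib.util.spec_from_file_location(
    "sim01", Path(__file__).parent / "01_simulate.py")
sim01 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim01)


def main():
    labels = []
    for method in ("binned", "semantic"):
        cfg = dataclasses.replace(sim01.config, method=method, model="blue")
        pipe = Pipeline(cfg)
        regions = pipe.annotate()
        label = f"{method}_blue"
        labels.append(label)
        lit = pd.read_csv(f"results/run/literature_summary_{label}.tsv", sep="\t")
        kw = pd.read_csv(f"results/run/go_keywords_{label}.tsv", sep="\t")
        print(f"{label}: {len(regions)} candidate regions, "
              f"{int(lit['n_with_literature_gene'].iloc[0])} contain a "
              "literature height gene")
        tot = kw.groupby("keyword")["count"].sum()
        print("  GO keyword annotations: "
              + ", ".join(f"{k}={v}" for k, v in tot.items()))

    causal = pd.read_csv("results/run/truth_causal.tsv", sep="\t")
    for label in labels:
        reg = pd.read_csv(f"results/run/regions_{label}.tsv", sep="\t")
        rec = sum(
            ((reg["chrom"].astype(str) == str(c.chrom))
             & ((reg["pos"] - c.pos).abs() <= 300_000)).any()
            for c in causal.itertuples()
        )
        print(f"{label}: recovered {rec} of {len(causal)} causal loci "
              "within +/-300 kb")

    pipe = Pipeline(sim01.config)
    pairs = pipe.compare(labels[0], labels[1])
    print(f"shared regions between analyses: "
          f"{pairs['marker_a'].nunique()} binned regions overlap "
          f"{pairs['marker_b'].nunique()} semantic regions "
          f"({int(pairs['same_marker'].sum())} pairs share the exact marker)")


if __name__ == "__main__":
    main()
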