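#!/usr/bin/env python
"""Simulate the synthetic field study.

Generates the genotype panel, randomized two-replicate field layout,
heritable height trait with field effects, spoken-style transcripts,
and the annotation/GO/literature stand-ins, all under results/run/.
"""

from spokenpheno.pipeline import Pipeline, PipelineConfig
from spokenpheno.synthetic_data import SimConfig

SEED = 1

config = PipelineConfig(
    outdir="results/run",
    method="binned",
    model="blue",
    seed=SEED,
    sim=SimConfig(
        n_taxa=400, n_chrom=2, markers_per_chrom=1000, rows_per_rep=400,
        n_causal=5, h2=0.6, omit_prob=0.1, seed=SEED,
    ),
)


def main():
    pipe = Pipeline(config)
    pipe.simulate()
    print("simulated study written to results/run/")
    print(f"  taxa: {config.sim.n_taxa}, markers: "
          f"{config.sim.n_chrom * config.sim.markers_per_chrom}, "
          f"causal loci: {config.sim.n_causal}, h2: {config.sim.h2}")
    print(f"  field: {config.sim.n_reps} reps x {config.sim.rows_per_rep} rows "
          f"x {config.sim.n_passes} passes "
          f"= {config.sim.n_reps * config.sim.rows_per_rep * config.sim.n_passes} "
          "spoken observations")


if __name__ == "__main__":
    main()
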