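import numpy as np
import pandas as pd
import pytest

from spokenpheno.phenoscore import default_lexicon
from spokenpheno.synthetic_data import (
    SimConfig,
    generate_transcripts,
    layout_field,
    simulate_genotypes,
    simulate_trait,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_sim():
    """Small but realistic simulated study shared across read-only tests."""
    cfg = SimConfig(
        n_taxa=120, n_chrom=2, markers_per_chrom=150, rows_per_rep=120,
        n_causal=3, h2=0.6, omit_prob=0.1, seed=11,
    )
    geno = simulate_genotypes(cfg)
    layout = layout_field(geno.taxa, cfg)
    trait = simulate_trait(geno, layout, cfg)
    return cfg, geno, layout, trait


@pytest.fixture(scope="session")
def small_transcripts(small_sim, lexicon):
    cfg, geno, layout, trait = small_sim
    obs, truth = generate_transcripts(layout, trait, lexicon, cfg, with_truth=True)
    return obs, truth
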