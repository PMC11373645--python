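"""Simulator: genotypes with block LD, field layout, trait, transcripts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from spokenpheno.synthetic_data import (
    SimConfig,
    _simulate_block,
    field_composition,
    generate_transcripts,
    layout_field,
    simulate_genotypes,
    simulate_trait,
    true_bin,
)


class TestGenotypes:
    def test_dosages_in_range_and_positions_increasing(self, small_sim):
        _, geno, _, _ = small_sim
        vals = geno.dosages[~np.isnan(geno.dosages)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}
        for _, grp in geno.markers.groupby("chrom"):
            assert np.all(np.diff(grp["pos"]) > 0)

    def test_no_ld_limit_mean_correlation_near_zero(self):
        cfg = SimConfig(n_taxa=300, n_chrom=1, markers_per_chrom=80,
                        ld_block_len_bp=0, seed=5)
        geno = simulate_genotypes(cfg)
        C = np.corrcoef(geno.dosages.T)
        off = C[np.triu_indices_from(C, k=1)]
        assert abs(np.mean(off)) < 3 / np.sqrt(cfg.n_taxa)

    def test_perfect_ld_limit(self):
        # switch probability 0 (retention 1) -> identical markers in a block
        rng = np.random.default_rng(0)
        H = _simulate_block(rng, n_hap=200, p=0.3, rhos=np.ones(9))
        assert np.all(H == H[:, [0]])

    def test_empirical_maf_within_band(self):
        cfg = SimConfig(n_taxa=400, n_chrom=1, markers_per_chrom=500,
                        maf_range=(0.1, 0.5), seed=3)
        geno = simulate_genotypes(cfg)
        freq = geno.allele_freq()
        assert np.all(freq >= 0.05) and np.all(freq <= 0.55)

    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_taxa=50, markers_per_chrom=40, seed=9)
        a, b = simulate_genotypes(cfg), simulate_genotypes(cfg)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.markers.equals(b.markers)

    def test_missing_rate(self):
        cfg = SimConfig(n_taxa=200, markers_per_chrom=100, missing_rate=0.1, seed=2)
        geno = simulate_genotypes(cfg)
        assert np.isnan(geno.dosages).mean() == pytest.approx(0.1, abs=0.02)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_taxa=0)
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimConfig(h2=1.5)

    def test_ld_decays_with_distance(self, small_sim):
        _, geno, _, _ = small_sim
        # mean adjacent-pair r2 should exceed mean distant-pair r2
        idx = geno.markers[geno.markers["chrom"] == "1"].index.to_numpy()
        D = geno.dosages[:, idx]
        near, far = [], []
        for j in range(len(idx) - 4):
            c_near = np.corrcoef(D[:, j], D[:, j + 1])[0, 1] ** 2
            c_far = np.corrcoef(D[:, j], D[:, j + 4])[0, 1] ** 2
            near.append(c_near)
            far.append(c_far)
        assert np.nanmean(near) > np.nanmean(far)


class TestLayout:
    def test_trial_composition_gives_720_rows_per_replicate(self):
        panel = [f"P{i:03d}" for i in range(655)]
        taxa, blocks = field_composition(panel)
        assert len(taxa) == 720
        cfg = SimConfig(rows_per_rep=720, n_reps=2, seed=1)
        layout = layout_field(taxa, cfg, blocks)
        counts = layout.table.groupby("replicate").size()
        assert (counts == 720).all()
        assert layout.table["row"].is_unique

    def test_single_rep_bijection(self):
        cfg = SimConfig(rows_per_rep=3, n_reps=1, seed=1)
        layout = layout_field(["A", "B", "C"], cfg)
        assert sorted(layout.table["taxon"]) == ["A", "B", "C"]
        assert sorted(layout.table["row"]) == [1, 2, 3]

    def test_seeded_determinism(self):
        cfg = SimConfig(rows_per_rep=10, seed=4)
        taxa = [f"T{i}" for i in range(10)]
        assert layout_field(taxa, cfg).table.equals(layout_field(taxa, cfg).table)

    def test_wrong_composition_length_rejected(self):
        cfg = SimConfig(rows_per_rep=5)
        with pytest.raises(ValueError):
            layout_field(["A"], cfg)


class TestTrait:
    def test_no_noise_limit_phenotype_equals_genetic(self):
        cfg = SimConfig(n_taxa=60, markers_per_chrom=50, rows_per_rep=60,
                        h2=1.0, var_rep=0, var_row=0, var_resid=0, seed=7)
        geno = simulate_genotypes(cfg)
        layout = layout_field(geno.taxa, cfg)
        trait = simulate_trait(geno, layout, cfg)
        merged = trait.observations.set_index("taxon")
        g = trait.genetic.reindex(merged.index)
        assert np.allclose(merged["value"].to_numpy(), g.to_numpy())

    def test_null_limit_h2_zero(self):
        cfg = SimConfig(n_taxa=400, markers_per_chrom=100, rows_per_rep=400,
                        h2=0.0, seed=8)
        geno = simulate_genotypes(cfg)
        layout = layout_field(geno.taxa, cfg)
        trait = simulate_trait(geno, layout, cfg)
        assert np.all(trait.genetic == 0)

    def test_realized_heritability_near_target(self):
        cfg = SimConfig(n_taxa=400, markers_per_chrom=200, rows_per_rep=400,
                        h2=0.6, seed=13)
        geno = simulate_genotypes(cfg)
        layout = layout_field(geno.taxa, cfg)
        trait = simulate_trait(geno, layout, cfg)
        assert trait.realized_h2() == pytest.approx(0.6, abs=0.1)

    def test_h2_without_causal_markers_rejected(self, small_sim):
        cfg, geno, layout, _ = small_sim
        import dataclasses
        bad = dataclasses.replace(cfg, n_causal=0)
        with pytest.raises(ValueError, match="n_causal"):
            simulate_trait(geno, layout, bad)

    def test_disjoint_layout_rejected(self, small_sim):
        cfg, geno, _, _ = small_sim
        other = layout_field([f"ZZ{i}" for i in range(cfg.rows_per_rep)], cfg)
        with pytest.raises(ValueError, match="overlap"):
            simulate_trait(geno, other, cfg)


class TestTranscripts:
    def test_bin_link_function(self):
        z = np.array([-5, -1, 0, 1, 5])
        assert list(true_bin(z)) == [0, 2, 4, 5, 7]

    @pytest.mark.parametrize("omit,expected", [(0.0, 1.0), (1.0, 0.0)])
    def test_omission_limits(self, small_sim, lexicon, omit, expected):
        import dataclasses
        cfg, geno, layout, trait = small_sim
        cfg = dataclasses.replace(cfg, omit_prob=omit)
        _, truth = generate_transcripts(layout, trait, lexicon, cfg, with_truth=True)
        assert (1 - truth["omitted"]).mean() == expected

    def test_retention_matches_omit_prob(self, small_transcripts):
        _, truth = small_transcripts
        n = len(truth)
        half = 2.576 * np.sqrt(0.1 * 0.9 / n)
        assert abs((~truth["omitted"]).mean() - 0.9) <= half

    def test_noiseless_bins_track_genetic_value(self, lexicon):
        from spokenpheno.phenoscore import score_transcripts_bins
        cfg = SimConfig(n_taxa=150, markers_per_chrom=100, rows_per_rep=150,
                        h2=1.0, var_rep=0, var_row=0, var_resid=0,
                        omit_prob=0.0, noise_sentences=(), seed=21)
        geno = simulate_genotypes(cfg)
        layout = layout_field(geno.taxa, cfg)
        trait = simulate_trait(geno, layout, cfg)
        obs, truth = generate_transcripts(layout, trait, lexicon, cfg, with_truth=True)
        scored = score_transcripts_bins(
            pd.DataFrame({"taxon": truth["taxon"], "text": [o.text for o in obs]}),
            lexicon,
        )
        mean_bin = scored.dropna(subset=["bin"]).groupby("taxon")["bin"].mean()
        rho = spearmanr(mean_bin, trait.genetic.reindex(mean_bin.index)).statistic
        assert rho > 0.8

    def test_transcripts_deterministic(self, small_sim, lexicon):
        cfg, geno, layout, trait = small_sim
        a = generate_transcripts(layout, trait, lexicon, cfg)
        b = generate_transcripts(layout, trait, lexicon, cfg)
        assert a == b
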