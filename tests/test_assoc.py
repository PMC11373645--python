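"""Genotype IO, PCA covariates, marker scan, Bonferroni, LD decay."""

import numpy as np
import pandas as pd
import pytest

from spokenpheno.assoc import (
    bonferroni_threshold,
    compute_pcs,
    ld_decay,
    scan,
    select_window,
)
from spokenpheno.genotypes import (
    GenotypeMatrix,
    read_genotypes,
    write_dosage_tsv,
    write_vcf,
)


def _toy_geno(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n_taxa, n_markers = dosages.shape
    pos = positions if positions is not None else (np.arange(n_markers) + 1) * 100
    markers = pd.DataFrame(
        {"marker": [f"S{i}" for i in range(n_markers)], "chrom": chrom,
         "pos": pos, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix([f"T{i}" for i in range(n_taxa)], markers, dosages)


class TestIO:
    def test_vcf_gt_coding_roundtrip(self, tmp_path):
        dos = np.array([[0, 1, np.nan], [2, 1, 0], [1, np.nan, 2]])
        geno = _toy_geno(dos)
        p = tmp_path / "g.vcf"
        write_vcf(geno, p)
        back = read_genotypes(p, fmt="vcf")
        assert back.taxa == geno.taxa
        assert np.allclose(back.dosages, dos, equal_nan=True)

    def test_dosage_tsv_roundtrip(self, tmp_path, small_sim):
        _, geno, _, _ = small_sim
        p = tmp_path / "g.tsv"
        write_dosage_tsv(geno, p)
        back = read_genotypes(p, fmt="dosage-tsv")
        assert back.taxa == geno.taxa
        assert np.allclose(back.dosages, geno.dosages, equal_nan=True)
        assert back.markers["pos"].equals(geno.markers["pos"])

    def test_subset_by_taxa_and_missing_listed(self, small_sim):
        _, geno, _, _ = small_sim
        sub = geno.subset_taxa(geno.taxa[:5])
        assert sub.n_taxa == 5
        with pytest.raises(KeyError, match="absent"):
            geno.subset_taxa(["NOPE"])

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            _toy_geno(np.zeros((3, 2)), positions=[200, 100])


class TestPCA:
    def test_identical_taxa_give_zero_scores(self):
        dos = np.tile([[0, 1, 2, 1]], (6, 1)).astype(float)
        geno = _toy_geno(dos)
        pcs = compute_pcs(geno, k=2)
        assert np.allclose(pcs.to_numpy(), 0.0)

    def test_all_monomorphic_rejected(self):
        dos = np.tile([[0, 2, 2, 0]], (6, 1)).astype(float)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_pcs(_toy_geno(dos), k=2)

    def test_constant_plus_polymorphic(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(30, 20)).astype(float)
        dos[:, 0] = 1.0  # monomorphic column is dropped, not fatal
        geno = _toy_geno(dos)
        pcs = compute_pcs(geno, k=2)
        assert pcs.shape == (30, 2)

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        n, m = 60, 120
        p1, p2 = 0.1, 0.8
        top = rng.binomial(2, p1, size=(n // 2, m)).astype(float)
        bot = rng.binomial(2, p2, size=(n // 2, m)).astype(float)
        geno = _toy_geno(np.vstack([top, bot]))
        pc1 = compute_pcs(geno, k=2)["PC1"].to_numpy()
        assert np.sign(pc1[: n // 2]).mean() == -np.sign(pc1[n // 2:]).mean()
        assert abs(pc1[: n // 2].mean() - pc1[n // 2:].mean()) > 3 * pc1.std() / 2

    def test_scores_uncorrelated_and_sign_deterministic(self, small_sim):
        _, geno, _, _ = small_sim
        pcs = compute_pcs(geno, k=3)
        cov = np.cov(pcs.to_numpy().T)
        off = cov[np.triu_indices(3, 1)]
        assert np.allclose(off, 0, atol=1e-8 * cov.max())
        assert pcs.equals(compute_pcs(geno, k=3))


class TestScan:
    def test_exact_fit_recovers_effect(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(50, 10)).astype(float)
        geno = _toy_geno(dos)
        pheno = pd.Series(2.0 * dos[:, 3], index=geno.taxa)
        res = scan(geno, pheno)
        row = res.table.set_index("marker").loc["S3"]
        assert row["effect"] == pytest.approx(2.0, abs=1e-10)
        assert row["p"] <= 1e-300

    def test_matches_full_design_ols_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n, m = 80, 50
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        geno = _toy_geno(dos)
        covs = pd.DataFrame(rng.normal(size=(n, 2)), index=geno.taxa,
                            columns=["PC1", "PC2"])
        y = rng.normal(size=n) + 0.3 * dos[:, 0]
        pheno = pd.Series(y, index=geno.taxa)
        res = scan(geno, pheno, covs, min_overlap=30)
        for j in range(m):
            if res.table["skipped"].iloc[j]:
                continue
            X = sm.add_constant(np.column_stack([covs.to_numpy(), dos[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert res.table["p"].iloc[j] == pytest.approx(
                fit.pvalues[-1], rel=1e-8), f"marker {j}"
            assert res.table["effect"].iloc[j] == pytest.approx(
                fit.params[-1], rel=1e-8)

    def test_permutation_null_calibrated(self):
        from spokenpheno.synthetic_data import SimConfig, simulate_genotypes

        cfg = SimConfig(n_taxa=400, n_chrom=1, markers_per_chrom=1000,
                        ld_block_len_bp=0, seed=17)
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(17)
        y = rng.normal(size=geno.n_taxa)
        pheno = pd.Series(rng.permutation(y), index=geno.taxa)
        res = scan(geno, pheno)
        frac = (res.table.loc[~res.table["skipped"], "p"] < 0.05).mean()
        se2 = 2 * np.sqrt(0.05 * 0.95 / res.n_tested)
        assert abs(frac - 0.05) <= se2

    def test_affine_phenotype_invariance(self, small_sim):
        _, geno, _, trait = small_sim
        pheno = trait.taxon_means()
        a = scan(geno, pheno).table["p"]
        b = scan(geno, 3.0 * pheno + 11.0).table["p"]
        assert np.allclose(a, b, rtol=1e-9)

    def test_constant_covariate_column_harmless(self, small_sim):
        _, geno, _, trait = small_sim
        pheno = trait.taxon_means()
        pcs = compute_pcs(geno, 2)
        aug = pcs.assign(const=1.0)
        a = scan(geno, pheno, pcs).table["p"]
        b = scan(geno, pheno, aug).table["p"]
        assert np.allclose(a, b, rtol=1e-6)

    def test_significance_monotone_in_alpha(self, small_sim):
        _, geno, _, trait = small_sim
        pheno = trait.taxon_means()
        loose = scan(geno, pheno, alpha=0.05)
        strict = scan(geno, pheno, alpha=0.001)
        s_loose = set(loose.significant()["marker"])
        s_strict = set(strict.significant()["marker"])
        assert s_strict <= s_loose

    def test_no_overlap_rejected(self, small_sim):
        _, geno, _, _ = small_sim
        pheno = pd.Series([1.0, 2.0], index=["X1", "X2"])
        with pytest.raises(ValueError, match="overlap"):
            scan(geno, pheno)

    def test_monomorphic_markers_skipped_not_zero(self):
        dos = np.ones((40, 3))
        dos[:, 0] = np.arange(40) % 3
        geno = _toy_geno(dos)
        rng = np.random.default_rng(0)
        pheno = pd.Series(rng.normal(size=40), index=geno.taxa)
        res = scan(geno, pheno)
        tab = res.table.set_index("marker")
        assert not tab.loc["S0", "skipped"]
        assert tab.loc["S1", "skipped"] and np.isnan(tab.loc["S1", "p"])


class TestBonferroni:
    @pytest.mark.parametrize(
        "m,expected",
        [(1_000_000, 7.3010), (20, 2.6021), (18_000_000, 8.5563)],
    )
    def test_closed_form(self, m, expected):
        assert bonferroni_threshold(m, 0.05) == pytest.approx(expected, abs=5e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, alpha=1.5)


class TestLD:
    def test_duplicated_marker_pair_r2_one(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        geno = _toy_geno(np.column_stack([col, col]), positions=[100, 200])
        curve = ld_decay(geno, max_dist=1000, bin_width=1000)
        assert curve.table["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_hand_worked_four_taxon_table(self):
        x = np.array([0, 1, 2, 2], dtype=float)
        z = np.array([0, 1, 1, 2], dtype=float)
        geno = _toy_geno(np.column_stack([x, z]), positions=[100, 200])
        curve = ld_decay(geno, max_dist=1000, bin_width=1000)
        r = np.corrcoef(x, z)[0, 1]  # direct correlation formula
        assert curve.table["mean_r2"].iloc[0] == pytest.approx(r**2, abs=1e-12)

    def test_independent_markers_background_r2(self):
        from spokenpheno.synthetic_data import SimConfig, simulate_genotypes

        cfg = SimConfig(n_taxa=400, n_chrom=1, markers_per_chrom=200,
                        ld_block_len_bp=0, seed=23)
        geno = simulate_genotypes(cfg)
        curve = ld_decay(geno, max_dist=50_000_000, bin_width=50_000_000)
        mean_r2 = (curve.table["mean_r2"] * curve.table["n_pairs"]).sum() / \
            curve.table["n_pairs"].sum()
        assert mean_r2 < 0.01

    def test_decay_curve_and_window_selection(self, small_sim):
        _, geno, _, _ = small_sim
        curve = ld_decay(geno, max_dist=2_000_000, bin_width=100_000)
        w = select_window(curve, r2_threshold=0.2)
        assert w % 50_000 == 0
        assert 50_000 <= w <= 2_000_000

    def test_window_fallback_when_no_crossing(self):
        from spokenpheno.assoc import LDDecayCurve
        t = pd.DataFrame({"dist_mid": [25e3, 75e3], "mean_r2": [0.9, 0.8],
                          "n_pairs": [10, 10]})
        assert select_window(LDDecayCurve(t)) == 300_000

    def test_no_pairs_rejected(self):
        geno = _toy_geno(np.zeros((4, 1)))
        with pytest.raises(ValueError):
            ld_decay(geno)
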