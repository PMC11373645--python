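"""BLUE / BLUP / multinomial adjusted means."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from spokenpheno.adjusted_means import (
    fit_blue,
    fit_blup,
    fit_multinomial,
    reml_crossed,
)


def _balanced(values_by_taxon, reps=(1, 2)):
    rows = []
    rown = 1
    for rep_i, rep in enumerate(reps):
        for taxon, vals in values_by_taxon.items():
            rows.append((taxon, rep, rown, vals[rep_i]))
            rown += 1
    return pd.DataFrame(rows, columns=["taxon", "replicate", "row", "value"])


class TestBlue:
    def test_balanced_design_equals_raw_means(self):
        tab = _balanced({"A": (10, 12), "B": (20, 22)})
        out = fit_blue(tab)
        assert out.values["A"] == pytest.approx(11.0, rel=1e-10)
        assert out.values["B"] == pytest.approx(21.0, rel=1e-10)

    def test_shift_equivariance(self):
        tab = _balanced({"A": (10, 12), "B": (20, 25), "C": (5, 9)})
        base = fit_blue(tab).values
        shifted = tab.assign(value=tab["value"] + 7.5)
        assert np.allclose(fit_blue(shifted).values, base + 7.5)

    def test_unbalanced_matches_ols_emm_oracle(self):
        # A in both reps, B only rep 1, C only rep 2
        tab = pd.DataFrame(
            {
                "taxon": ["A", "A", "B", "C"],
                "replicate": [1, 2, 1, 2],
                "row": [1, 2, 3, 4],
                "value": [10.0, 14.0, 20.0, 31.0],
            }
        )
        out = fit_blue(tab).values
        # independent oracle: statsmodels OLS + prediction over the
        # full taxon x replicate grid, averaged over replicates
        import statsmodels.formula.api as smf

        fit = smf.ols("value ~ C(taxon) + C(replicate)", tab).fit()
        grid = pd.DataFrame(
            [(t, r) for t in ["A", "B", "C"] for r in [1, 2]],
            columns=["taxon", "replicate"],
        )
        pred = fit.predict(grid)
        emm = pred.groupby(grid["taxon"]).mean()
        assert np.allclose(out.sort_index(), emm.sort_index(), rtol=1e-8)

    def test_row_order_and_label_invariance(self):
        tab = _balanced({"A": (1, 3), "B": (6, 4), "C": (9, 11)})
        shuffled = tab.sample(frac=1, random_state=0)
        assert np.allclose(fit_blue(shuffled).values.sort_index(),
                           fit_blue(tab).values.sort_index())

    def test_confounded_design_rejected(self):
        # taxon A only in rep 1, B only in rep 2: taxon aliases replicate
        tab = pd.DataFrame(
            {"taxon": ["A", "A", "B", "B"], "replicate": [1, 1, 2, 2],
             "row": [1, 2, 3, 4], "value": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="confounded|connected"):
            fit_blue(tab)


class TestBlup:
    def test_constant_data_collapses(self):
        tab = _balanced({"A": (5.0, 5.0), "B": (5.0, 5.0), "C": (5.0, 5.0)})
        out = fit_blup(tab)
        assert np.allclose(out.values, 5.0)
        assert all(v == pytest.approx(0.0, abs=1e-8)
                   for v in out.variance_components.values())

    def test_known_ratio_shrinkage_closed_form(self):
        # one observation per level: BLUP deviation = lambda * raw deviation
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        gamma = 1.5  # s2_taxon / s2_resid
        lam = gamma / (1 + gamma)
        comps, mu, blups, _ = reml_crossed(
            y, {"taxon": np.arange(40)}, fixed_gammas={"taxon": gamma}
        )
        expected = lam * (y - y.mean())
        assert np.allclose(blups["taxon"], expected, atol=1e-8)

    def test_shrinkage_inequality(self, small_sim):
        _, _, _, trait = small_sim
        tab = trait.observations
        out = fit_blup(tab)
        gm = tab["value"].mean()
        raw = tab.groupby("taxon")["value"].mean()
        dev_blup = (out.values - gm).abs()
        dev_raw = (raw.reindex(out.values.index) - gm).abs()
        assert (dev_blup <= dev_raw + 1e-8).all()

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        n_taxa, n_rep = 40, 2
        g = rng.normal(0, 1.5, n_taxa)
        rows = []
        rid = 0
        for rep in range(n_rep):
            for t in range(n_taxa):
                row_eff = rng.normal(0, 0.7)
                for _ in range(2):
                    rows.append((f"T{t}", rep, rid, g[t] + 0.4 * rep + row_eff
                                 + rng.normal(0, 1.0)))
                rid += 1
        tab = pd.DataFrame(rows, columns=["taxon", "replicate", "row", "value"])
        ours = fit_blup(tab)
        m = smf.mixedlm(
            "value ~ 1", tab, groups=np.ones(len(tab)),
            vc_formula={"taxon": "0 + C(taxon)", "replicate": "0 + C(replicate)",
                        "row": "0 + C(row)"},
        ).fit(reml=True)
        ref = dict(zip(["replicate", "row", "taxon"], m.vcomp))
        for k in ("taxon", "row"):
            assert ours.variance_components[k] == pytest.approx(ref[k], abs=0.05, rel=0.05)
        assert ours.variance_components["resid"] == pytest.approx(m.scale, rel=0.05)

    def test_variance_component_recovery(self):
        from spokenpheno.synthetic_data import (
            SimConfig, layout_field, simulate_genotypes, simulate_trait)

        h2 = 4.0 / 6.5  # sigma2: taxon 4, rep 1, row 0.5, resid 1
        cfg = SimConfig(n_taxa=400, n_chrom=1, markers_per_chrom=200,
                        rows_per_rep=400, h2=h2, var_rep=1.0, var_row=0.5,
                        var_resid=1.0, seed=1)
        geno = simulate_genotypes(cfg)
        layout = layout_field(geno.taxa, cfg)
        trait = simulate_trait(geno, layout, cfg)
        out = fit_blup(trait.observations)
        truth = {"taxon": 4.0, "replicate": 1.0, "row": 0.5, "resid": 1.0}
        for k, v in truth.items():
            assert out.variance_components[k] == pytest.approx(v, rel=0.3), k


class TestMultinomial:
    def test_degenerate_taxon_pinned_to_its_bin(self):
        rng = np.random.default_rng(0)
        rows = []
        for t in range(10):
            for rep in (1, 2):
                for _ in range(3):
                    b = 6 if t == 0 else int(rng.integers(0, 8))
                    rows.append((f"T{t}", rep, 0, b))
        tab = pd.DataFrame(rows, columns=["taxon", "replicate", "row", "bin"])
        out = fit_multinomial(tab)
        assert out.values["T0"] == pytest.approx(6.0, abs=0.1)

    def test_uniform_bins_give_midpoint(self):
        rows = []
        for t in ("A", "B"):
            for rep in (1, 2):
                for b in range(8):
                    rows.append((t, rep, 0, b))
        tab = pd.DataFrame(rows, columns=["taxon", "replicate", "row", "bin"])
        out = fit_multinomial(tab)
        assert out.values["A"] == pytest.approx(3.5, abs=0.05)

    def test_single_bin_degenerate_warns(self):
        tab = pd.DataFrame(
            {"taxon": ["A", "B"], "replicate": [1, 1], "row": [1, 2], "bin": [4, 4]}
        )
        with pytest.warns(UserWarning):
            out = fit_multinomial(tab)
        assert np.allclose(out.values, 4.0)

    def test_expected_bins_track_blue(self, small_sim, lexicon):
        from spokenpheno.phenoscore import score_transcripts_bins
        from spokenpheno.synthetic_data import generate_transcripts
        cfg, _, layout, trait = small_sim
        obs, truth = generate_transcripts(layout, trait, lexicon, cfg, with_truth=True)
        df = pd.DataFrame(
            {"taxon": truth["taxon"], "replicate": truth["replicate"],
             "row": truth["row"], "text": [o.text for o in obs]}
        )
        scored = score_transcripts_bins(df, lexicon).dropna(subset=["bin"])
        scored = scored.assign(bin=scored["bin"].astype(int))
        mult = fit_multinomial(scored)
        blue = fit_blue(scored.assign(value=scored["bin"].astype(float)))
        rho = spearmanr(mult.values.sort_index(), blue.values.sort_index()).statistic
        assert rho > 0.9
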