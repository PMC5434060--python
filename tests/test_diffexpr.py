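"""Normalization, NB GLM fitting (vs statsmodels oracle), LRT and MDS."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from thermoscreen import diffexpr, syndata
from thermoscreen.containers import CountMatrix, ModelSpec


def small_design(n_reps=3):
    model = ModelSpec()
    sheet = model.sample_sheet(n_reps)
    return model, sheet


class TestCpmAndFilter:
    def test_cpm_hand_values(self):
        counts = np.array([[5, 0], [10, 2], [0, 8]])
        lib = np.array([1e6, 2e6])
        out = diffexpr.cpm(counts, lib)
        assert out[0, 0] == 5.0
        assert out[2, 0] == 0.0
        assert out[1, 1] == pytest.approx(1.0)
        assert out[2, 1] == pytest.approx(4.0)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.cpm(np.ones((2, 2)), np.array([1e6, 0.0]))

    def test_boundary_gene_kept(self):
        # lib size 4e6 -> 0.25 CPM needs exactly 1 count; 6 samples at the
        # boundary, the rest below
        model, sheet = small_design()
        counts = pd.DataFrame(
            np.zeros((3, 36), dtype=int), index=["a", "b", "c"], columns=sheet.index
        )
        counts.iloc[0, :6] = 1          # exactly 0.25 CPM in exactly 6 samples
        counts.iloc[2, :5] = 1          # only 5 samples
        filler = pd.DataFrame(          # keeps all library sizes at 4e6
            np.full((1, 36), 0, dtype=int), index=["lib"], columns=sheet.index
        )
        filler.iloc[0] = 4_000_000 - counts.sum(axis=0)
        cm = CountMatrix(pd.concat([counts, filler]), sheet)
        kept = diffexpr.filter_low_expression(cm, min_cpm=0.25, min_samples=6)
        assert "a" in kept
        assert "b" not in kept          # all-zero gene dropped
        assert "c" not in kept

    def test_matches_per_gene_loop_oracle(self):
        cfg = syndata.CountSimConfig(n_genes=300, seed=2)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        cm = CountMatrix(counts, sheet)
        kept = set(diffexpr.filter_low_expression(cm))
        lib = counts.sum(axis=0)
        for gene in counts.index:
            n_ok = sum(
                counts.loc[gene, s] * 1e6 / lib[s] >= 0.25 for s in counts.columns
            )
            assert (gene in kept) == (n_ok >= 6)


class TestRle:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        sf = diffexpr.rle_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(200, 4)) + 1)
        doubled = counts.copy()
        doubled[0] = counts[0] * 2
        sf1 = diffexpr.rle_size_factors(counts)
        sf2 = diffexpr.rle_size_factors(doubled)
        # factors are defined up to overall scale (the geometric-mean
        # reference moves too): the doubled sample's relative factor doubles
        assert sf2[0] / sf2[1] == pytest.approx(2 * sf1[0] / sf1[1])
        assert np.allclose(sf2[1:] / sf2[1], sf1[1:] / sf1[1])

    def test_five_gene_hand_computation(self):
        counts = pd.DataFrame(
            {"s1": [2, 4, 6, 8, 10], "s2": [4, 8, 12, 16, 20]}, dtype=float
        )
        sf = diffexpr.rle_size_factors(counts)
        # every gene ratio is 1/sqrt(2) in s1 and sqrt(2) in s2
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
        assert sf["s2"] == pytest.approx(np.sqrt(2))

    def test_no_all_positive_gene_raises(self):
        counts = pd.DataFrame({"s1": [0, 3], "s2": [5, 0]})
        with pytest.raises(ValueError):
            diffexpr.rle_size_factors(counts)


class TestNestedGlm:
    def test_coefficients_match_statsmodels_oracle(self):
        model, sheet = small_design()
        cfg = syndata.CountSimConfig(n_genes=12, dispersion=0.2, seed=4)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        fit = diffexpr.fit_nested_model(counts, model, sheet, dispersions=0.2)
        X = model.design_matrix(sheet)
        offset = np.log(counts.sum(axis=0).to_numpy())
        for g in range(12):
            sm_fit = sm.GLM(
                counts.iloc[g].to_numpy(),
                X.to_numpy(),
                family=sm.families.NegativeBinomial(alpha=0.2),
                offset=offset,
            ).fit()
            assert np.allclose(
                fit.coef.iloc[g].to_numpy(), sm_fit.params, atol=1e-4
            ), g

    def test_additive_data_cell_means_recovered(self):
        # counts exactly multiplicative in stage and temperature: the nested
        # model is saturated for them and near-Poisson fitting interpolates
        model, sheet = small_design()
        mu = {}
        for sid, row in sheet.iterrows():
            mu[sid] = (
                100.0
                * (2.0 if row["stage"] == 42 else 1.0)
                * (3.0 if row["temperature"] == 25 else 1.0)
            )
        counts = pd.DataFrame({sid: [v] for sid, v in mu.items()}, index=["g"])
        fit = diffexpr.fit_nested_model(
            counts, model, sheet, dispersions=1e-6,
        )
        assert np.allclose(fit.mu[0], counts.iloc[0].to_numpy(), rtol=1e-4)

    def test_offset_shift_moves_only_intercepts(self):
        model, sheet = small_design()
        cfg = syndata.CountSimConfig(n_genes=8, seed=5)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        sf = diffexpr.rle_size_factors(counts)
        fit1 = diffexpr.fit_nested_model(counts, model, sheet, sf, 0.1)
        fit2 = diffexpr.fit_nested_model(counts, model, sheet, 2.0 * sf, 0.1)
        icols = [c for c in fit1.coef.columns if c.startswith("l_")]
        others = [c for c in fit1.coef.columns if not c.startswith("l_")]
        assert np.allclose(fit1.coef[others], fit2.coef[others], atol=1e-6)
        assert np.allclose(
            fit1.coef[icols] - fit2.coef[icols], np.log(2.0), atol=1e-6
        )

    def test_planted_coefficient_recovery_grid(self):
        # logFC bias < 10% of the true effect across effect x dispersion grid
        model = ModelSpec()
        for effect in (1.0, 2.0):
            for disp in (0.05, 0.4):
                cfg = syndata.CountSimConfig(
                    n_genes=800, frac_de_per_locality=0.15,
                    log2_effect_size=effect, dispersion=disp, seed=17,
                )
                counts, sheet, truth = syndata.simulate_counts(cfg)
                sf = diffexpr.rle_size_factors(counts)
                fit = diffexpr.fit_nested_model(counts, model, sheet, sf, disp)
                tr = truth[truth.locality == "CAT"].set_index("gene")
                rec = fit.coef.loc[tr.index, "t_CAT25"] / np.log(2)
                bias = (rec - tr["log2_effect"]).mean()
                assert abs(bias) < 0.1 * effect, (effect, disp, bias)


class TestDispersion:
    def test_poisson_counts_give_tiny_dispersion(self):
        model = ModelSpec()
        cfg = syndata.CountSimConfig(n_genes=400, dispersion=0.0, seed=6)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        common, tagwise = diffexpr.estimate_dispersion(counts, model, sheet)
        assert np.median(tagwise) < 0.01

    def test_nb_dispersion_recovery(self):
        model = ModelSpec()
        cfg = syndata.CountSimConfig(n_genes=2000, dispersion=0.4, seed=7)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        common, _ = diffexpr.estimate_dispersion(counts, model, sheet)
        assert common == pytest.approx(0.4, abs=0.05)

    def test_infinite_prior_collapses_to_common(self):
        model = ModelSpec()
        cfg = syndata.CountSimConfig(n_genes=100, dispersion=0.2, seed=8)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        common, tagwise = diffexpr.estimate_dispersion(
            counts, model, sheet, prior_df=np.inf
        )
        assert np.allclose(tagwise, common)


class TestTemperatureLrt:
    def test_constant_gene_has_zero_statistic(self):
        model, sheet = small_design()
        counts = pd.DataFrame(
            np.full((1, len(sheet)), 50, dtype=int), index=["g"], columns=sheet.index
        )
        res = diffexpr.test_temperature_effect(counts, model, sheet, "TAT", None, 0.1)
        assert res.loc["g", "lr_stat"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc["g", "pvalue"] == pytest.approx(1.0, abs=1e-4)

    def test_invariant_to_permutation_within_cell(self):
        model, sheet = small_design()
        cfg = syndata.CountSimConfig(n_genes=30, seed=9)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        cell = sheet.query(
            "locality == 'CAT' and stage == 36 and temperature == 25"
        ).index.tolist()
        permuted = counts.copy()
        permuted[cell] = counts[list(reversed(cell))].to_numpy()
        r1 = diffexpr.test_temperature_effect(counts, model, sheet, "CAT", None, 0.1)
        r2 = diffexpr.test_temperature_effect(permuted, model, sheet, "CAT", None, 0.1)
        assert np.allclose(r1["lr_stat"], r2["lr_stat"], atol=1e-6)

    def test_planted_genes_rank_above_null(self):
        model = ModelSpec()
        cfg = syndata.CountSimConfig(
            n_genes=600, frac_de_per_locality=0.1, log2_effect_size=2.0,
            dispersion=0.1, seed=10,
        )
        counts, sheet, truth = syndata.simulate_counts(cfg)
        sf = diffexpr.rle_size_factors(counts)
        res = diffexpr.test_temperature_effect(counts, model, sheet, "TAT", sf, 0.1)
        planted = res.index.isin(truth.loc[truth.locality == "TAT", "gene"])
        lr = res["lr_stat"].to_numpy()
        from scipy.stats import rankdata

        ranks = rankdata(lr)
        auc = (ranks[planted].mean() - (planted.sum() + 1) / 2) / (~planted).sum()
        assert auc > 0.9

    def test_bh_monotone_in_threshold(self):
        model = ModelSpec()
        cfg = syndata.CountSimConfig(n_genes=200, frac_de_per_locality=0.2, seed=11)
        counts, sheet, _ = syndata.simulate_counts(cfg)
        res = diffexpr.test_temperature_effect(counts, model, sheet, "CAT", None, 0.1)
        assert (res["padj"] >= res["pvalue"] - 1e-12).all()
        assert (res["padj"] <= 1.0).all()
        n_strict = (res["padj"] <= 0.01).sum()
        n_loose = (res["padj"] <= 0.1).sum()
        assert n_strict <= n_loose


class TestMds:
    def test_duplicate_samples_collapse(self):
        rng = np.random.default_rng(12)
        base = rng.poisson(40, size=(300,))
        counts = pd.DataFrame(
            {"a": base, "b": base, "c": rng.poisson(40, size=300)}
        )
        coords = diffexpr.mds_logfc(counts, top_k=100)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-6)

    def test_euclidean_three_sample_exactness(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords = diffexpr.classical_mds(D, k=2)
        rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(rec, D, atol=1e-9)

    def test_locality_separates_more_than_temperature(self, screen_data):
        from sklearn.metrics import silhouette_score

        counts = screen_data.counts
        sheet = screen_data.samples
        sf = diffexpr.rle_size_factors(counts)
        coords = diffexpr.mds_logfc(counts, sf).to_numpy()
        sil_loc = silhouette_score(coords, sheet["locality"])
        sil_temp = silhouette_score(coords, sheet["temperature"])
        assert sil_loc > sil_temp
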