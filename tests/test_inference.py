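"""Mixed-model inference: BH against an independent oracle, exact
recovery on degenerate data, adjusted means under imbalance, contrasts,
correlations, rankings and plasticity."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from droughtrings.inference import (ModelSpec, bh_adjust,
                                    climate_correlations,
                                    fit_population_model,
                                    lsmeans_by_provenance,
                                    pairwise_contrasts, plasticity_contrast,
                                    standardize_rankings)
from droughtrings.synthetic import (DesignSpec, GeneratorParams, TraitParams,
                                    generate_design, simulate_trait)


def bh_stepup_oracle(p):
    """Independent hand-stepped BH implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def _tp(mean=0.0, offsets=(0, 0, 0, 0), **kw):
    return TraitParams(
        mean=mean, region_offsets=dict(zip(("LE", "CI", "SI", "TE"),
                                           offsets)),
        site_offsets=(0.0, 0.0, 0.0), **kw)


class TestBhAdjust:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_stepup_oracle(p),
                                       atol=1e-12)

    def test_adjusted_at_least_raw_and_weakly_order_preserving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone, ties ok


class TestPopulationModel:
    def test_zero_noise_region_means_recovered_exactly(self):
        spec = DesignSpec(seed=0)
        design = generate_design(spec)
        tp = _tp(mean=10.0, offsets=(-1.0, 0.0, 0.5, 2.0))
        df = simulate_trait(design, spec, tp, seed=0)
        fit = fit_population_model(df, ModelSpec(response="value"))
        expected = {"LE": 9.0, "CI": 10.0, "SI": 10.5, "TE": 12.0}
        for region, mean in expected.items():
            assert fit.lsmeans[region] == pytest.approx(mean, abs=1e-8)

    def test_single_level_fixed_effect_rejected(self):
        df = pd.DataFrame({"value": [1.0, 2.0], "region": "LE",
                           "site_id": "S1", "block_id": "B1",
                           "tree_id": ["a", "b"]})
        with pytest.raises(ValueError, match="2 levels"):
            fit_population_model(df, ModelSpec(response="value"))

    def test_noisy_fit_uses_mixed_model_and_reports_aic(self):
        spec = DesignSpec(seed=3)
        design = generate_design(spec)
        tp = _tp(mean=0.0, offsets=(-0.5, 0, 0, 0.5), block_sd=0.3,
                 tree_sd=0.4, resid_sd=1.0)
        df = simulate_trait(design, spec, tp, seed=3)
        fit = fit_population_model(df, ModelSpec(response="value"))
        assert fit.method == "mixedlm" and fit.converged
        assert np.isfinite(fit.aic)
        assert fit.df_method.startswith("wald-z")


class TestLsMeans:
    def test_balanced_zero_noise_lsmeans_equal_raw_means(self):
        spec = DesignSpec(seed=1)
        design = generate_design(spec)
        df = simulate_trait(design, spec, _tp(mean=4.0), seed=1)
        lsm = lsmeans_by_provenance(df, ["value"])
        raw = df.groupby("provenance_id")["value"].mean()
        np.testing.assert_allclose(lsm["value"].sort_index(),
                                   raw.sort_index(), atol=1e-8)

    def test_twenty_provenances_in_twenty_rows_out(self, tables, design):
        df = tables["isotopes"].merge(design, on="tree_id")
        lsm = lsmeans_by_provenance(df, ["d13c_permil"])
        assert len(lsm) == 20

    def test_imbalance_adjusted_away_when_block_effect_nonzero(self):
        # two provenances x two blocks, one tree each, zero noise;
        # dropping P2's tree in block B2 moves the raw mean but the
        # adjusted mean stays at the generating provenance value
        prov_eff = {"P1": 0.0, "P2": 1.0}
        block_eff = {"B1": 0.5, "B2": -0.5}
        rows = [(f"{p}-{b}", p, "S1", b, prov_eff[p] + block_eff[b])
                for p in prov_eff for b in block_eff]
        df = pd.DataFrame(rows, columns=["tree_id", "provenance_id",
                                         "site_id", "block_id", "value"])
        df = df[df["tree_id"] != "P2-B2"]
        raw = df[df["provenance_id"] == "P2"]["value"].mean()
        assert raw == pytest.approx(1.5)  # biased by the block it sits in
        lsm = lsmeans_by_provenance(df, ["value"])
        assert lsm.loc["P2", "value"] == pytest.approx(1.0, abs=1e-8)

    def test_provenance_without_observations_warns_and_is_excluded(self):
        rows = [("t1", "P1", "S1", "B1", 1.0), ("t2", "P1", "S1", "B2", 2.0),
                ("t3", "P2", "S1", "B1", 3.0), ("t4", "P2", "S1", "B2", 4.0),
                ("t5", "P3", "S1", "B1", np.nan)]
        df = pd.DataFrame(rows, columns=["tree_id", "provenance_id",
                                         "site_id", "block_id", "value"])
        with pytest.warns(UserWarning, match="P3"):
            lsm = lsmeans_by_provenance(df, ["value"])
        assert "P3" not in lsm.index


class TestContrasts:
    def test_four_regions_give_six_contrasts(self):
        spec = DesignSpec(seed=2)
        design = generate_design(spec)
        df = simulate_trait(design, spec,
                            _tp(offsets=(0, 1, 2, 3), resid_sd=0.1), seed=2)
        ct = pairwise_contrasts(fit_population_model(
            df, ModelSpec(response="value")))
        assert len(ct) == 6
        assert (ct["p_adj"] >= ct["p"] - 1e-12).all()

    def test_large_shift_makes_all_its_contrasts_significant(self):
        spec = DesignSpec(seed=4)
        design = generate_design(spec)
        df = simulate_trait(design, spec,
                            _tp(offsets=(10.0, 0, 0, 0), resid_sd=0.1),
                            seed=4)
        ct = pairwise_contrasts(fit_population_model(
            df, ModelSpec(response="value")))
        involving_le = ct[(ct["group1"] == "LE") | (ct["group2"] == "LE")]
        assert involving_le["significant"].all()


class TestCorrelations:
    def test_exact_linear_trait_has_unit_correlation(self):
        clim = pd.DataFrame({"provenance_id": list("abcde"),
                             "mat_c": [1, 2, 3, 4, 5.0]})
        tr = clim.rename(columns={"mat_c": "growth"})
        tr["growth"] = 2 * tr["growth"] + 1
        out = climate_correlations(tr, clim, on=["provenance_id"],
                                   trait_cols=["growth"],
                                   climate_cols=["mat_c"])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_perfect_negative_example(self):
        clim = pd.DataFrame({"k": [1, 2, 3], "x": [1, 2, 3.0]})
        tr = pd.DataFrame({"k": [1, 2, 3], "y": [6, 4, 2.0]})
        out = climate_correlations(tr, clim, on=["k"], trait_cols=["y"],
                                   climate_cols=["x"])
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_fewer_than_three_pairs_flagged_undefined(self):
        clim = pd.DataFrame({"k": [1, 2], "x": [1, 2.0]})
        tr = pd.DataFrame({"k": [1, 2], "y": [3, 4.0]})
        out = climate_correlations(tr, clim, on=["k"], trait_cols=["y"],
                                   climate_cols=["x"])
        assert out.loc[0, "undefined"] and np.isnan(out.loc[0, "r"])

    def test_invariant_to_input_row_order(self):
        rng = np.random.default_rng(0)
        clim = pd.DataFrame({"k": range(10), "x": rng.normal(size=10)})
        tr = pd.DataFrame({"k": range(10), "y": rng.normal(size=10)})
        a = climate_correlations(tr, clim, on=["k"], trait_cols=["y"],
                                 climate_cols=["x"])
        b = climate_correlations(tr.sample(frac=1, random_state=1), clim,
                                 on=["k"], trait_cols=["y"],
                                 climate_cols=["x"])
        assert a.loc[0, "r"] == pytest.approx(b.loc[0, "r"])


class TestRankingsAndPlasticity:
    def test_pooled_zscores_standardized(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"region": np.repeat(list("ABCD"), 25),
                           "t": rng.normal(3, 2, 100)})
        out = standardize_rankings(df, ["t"])
        weighted = (out["z_mean"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_offsets_give_symmetric_region_means(self):
        df = pd.DataFrame({"region": ["A"] * 50 + ["B"] * 50,
                           "t": [1.0] * 50 + [3.0] * 50})
        out = standardize_rankings(df, ["t"])
        z = out.set_index("region")["z_mean"]
        assert z["A"] == pytest.approx(-z["B"])

    def test_zero_variance_trait_flagged(self):
        df = pd.DataFrame({"region": list("AB"), "t": [1.0, 1.0]})
        out = standardize_rankings(df, ["t"])
        assert out["zero_variance"].all()

    def test_lowest_region_ranks_lowest_on_generated_traits(self, tables,
                                                            design):
        df = tables["isotopes"].merge(design, on="tree_id")
        tree = df.groupby(["tree_id", "region"], as_index=False).mean(
            numeric_only=True)
        out = standardize_rankings(tree, ["d13c_permil", "d18o_permil"])
        for _, grp in out.groupby("trait"):
            z = grp.set_index("region")["z_mean"]
            assert z.idxmin() == "LE"  # generator puts LE lowest

    def test_identical_years_give_zero_contrast(self):
        df = pd.DataFrame({"region": ["A"] * 4, "year": [2000, 2000,
                                                         2002, 2002],
                           "t": [1.0, 2.0, 1.0, 2.0]})
        out = plasticity_contrast(df, ["t"], dry_year=2002, wet_year=2000)
        assert out.loc[0, "contrast"] == pytest.approx(0.0)

    def test_contrast_antisymmetric_under_year_swap(self, tables, design):
        df = tables["isotopes"].merge(design, on="tree_id")
        a = plasticity_contrast(df, ["d13c_permil"], 2002, 2000)
        b = plasticity_contrast(df, ["d13c_permil"], 2000, 2002)
        np.testing.assert_allclose(a["contrast"], -b["contrast"])

    def test_missing_year_is_an_error(self):
        df = pd.DataFrame({"region": ["A"], "year": [2000], "t": [1.0]})
        with pytest.raises(ValueError, match="2002"):
            plasticity_contrast(df, ["t"], 2002, 2000)

    def test_generator_ci_has_largest_d13c_plasticity(self, tables, design):
        df = tables["isotopes"].merge(design, on="tree_id")
        out = plasticity_contrast(df, ["d13c_permil"], 2002, 2000)
        z = out.set_index("region")["contrast"]
        assert z.idxmax() == "CI"
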