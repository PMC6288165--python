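"""The generator must reproduce the trial's design arithmetic exactly
and expose a recoverable linear model."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from droughtrings.synthetic import (ATMOSPHERE_FIXTURE, DesignSpec,
                                    GeneratorParams, TraitParams,
                                    generate_atmosphere, generate_design,
                                    simulate_measurements, simulate_trait)


def _flat_tp(mean=0.0, offsets=(0, 0, 0, 0), **kw):
    return TraitParams(
        mean=mean,
        region_offsets=dict(zip(("LE", "CI", "SI", "TE"), offsets)),
        site_offsets=(0.0, 0.0, 0.0), **kw)


class TestDesign:
    def test_default_design_has_117_trees(self, design):
        assert design["tree_id"].nunique() == 117

    def test_full_factorial_without_missing_is_120(self):
        d = generate_design(DesignSpec(missing_trees=()))
        assert len(d) == 4 * 5 * 3 * 2 * 1 == 120

    def test_missing_tree_dropped_for_all_years(self, default_spec, tables):
        gone = set(default_spec.missing_trees)
        assert not gone & set(tables["isotopes"]["tree_id"])

    def test_unknown_missing_id_is_named_in_error(self):
        with pytest.raises(ValueError, match="NOPE-S1-B1"):
            generate_design(DesignSpec(missing_trees=("NOPE-S1-B1",)))

    @pytest.mark.parametrize("kwargs", [
        {"sites": 0}, {"provenances_per_region": 0},
        {"years": (2005, 1996)},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DesignSpec(**kwargs)

    def test_same_seed_gives_identical_tables(self, default_spec, design,
                                              tables):
        again = simulate_measurements(design, default_spec,
                                      GeneratorParams())
        for name in tables:
            pdt.assert_frame_equal(tables[name], again[name])

    def test_different_seed_same_skeleton_different_values(self, design,
                                                           tables):
        other = simulate_measurements(design, DesignSpec(seed=321),
                                      GeneratorParams())
        pdt.assert_frame_equal(tables["design"], other["design"])
        assert not np.allclose(tables["isotopes"]["d13c_permil"],
                               other["isotopes"]["d13c_permil"])


class TestMeasurements:
    def test_record_count_is_trees_times_years(self, design, tables):
        assert len(tables["isotopes"]) == 117 * 10 == 1170
        assert len(tables["ring_widths"]) == 1170 * 4

    def test_ring_widths_positive(self, tables):
        assert (tables["ring_widths"]["ring_width_mm"] > 0).all()

    def test_every_ring_has_cells(self, tables):
        per_ring = tables["cells"].groupby(["tree_id", "year"]).size()
        assert len(per_ring) == 1170 and (per_ring >= 1).all()

    def test_zero_noise_zero_offsets_gives_grand_mean(self, design,
                                                      default_spec):
        params = GeneratorParams().zeroed()
        params = replace(
            params,
            d13c_permil=_flat_tp(mean=-26.0, drought_mode="add"),
            d18o_permil=_flat_tp(mean=22.0, drought_mode="add"))
        out = simulate_measurements(design, default_spec, params)
        assert np.allclose(out["isotopes"]["d13c_permil"], -26.0)
        assert np.allclose(out["isotopes"]["d18o_permil"], 22.0)

    def test_region_offsets_shift_group_means_exactly(self, design,
                                                      default_spec):
        params = replace(
            GeneratorParams().zeroed(),
            d13c_permil=_flat_tp(mean=-26.0, offsets=(0, 1, 1, 0),
                                 drought_mode="add"))
        out = simulate_measurements(design, default_spec, params)
        iso = out["isotopes"].merge(design, on="tree_id")
        means = iso.groupby("region")["d13c_permil"].mean()
        assert means["CI"] == means["SI"] == pytest.approx(-25.0)
        assert means["LE"] == means["TE"] == pytest.approx(-26.0)

    def test_drought_year_growth_dips_under_zero_noise(self, design,
                                                       default_spec):
        params = GeneratorParams().zeroed()
        out = simulate_measurements(design, default_spec, params)
        rw = out["ring_widths"]
        dr = rw.loc[rw["year"] == 2002, "ring_width_mm"].mean()
        other = rw.loc[rw["year"] != 2002, "ring_width_mm"].mean()
        assert dr < other

    def test_drought_year_must_be_inside_design_years(self, design,
                                                      default_spec):
        params = replace(GeneratorParams(), drought_year=1990)
        with pytest.raises(ValueError, match="drought_year"):
            simulate_measurements(design, default_spec, params)

    def test_negative_sd_rejected_at_parse_time(self):
        with pytest.raises(ValueError, match="resid_sd"):
            _flat_tp(resid_sd=-1.0)


class TestSimulateTrait:
    def test_deterministic_and_linear(self, design, default_spec):
        tp = _flat_tp(mean=5.0, offsets=(-0.5, 0, 0, 0.5))
        a = simulate_trait(design, default_spec, tp, seed=7)
        b = simulate_trait(design, default_spec, tp, seed=7)
        pdt.assert_frame_equal(a, b)
        means = a.groupby("region")["value"].mean()
        assert means["TE"] - means["LE"] == pytest.approx(1.0)


class TestAtmosphere:
    def test_one_row_per_year(self):
        atm = generate_atmosphere(range(1996, 2006))
        assert len(atm) == 10
        assert atm["ca_ppm"].is_monotonic_increasing
        assert atm["d13c_air_permil"].is_monotonic_decreasing

    def test_linear_model_with_zero_slope_is_constant(self):
        atm = generate_atmosphere(range(1996, 2006), ca0=360.0, ca_slope=0.0)
        assert (atm["ca_ppm"] == 360.0).all()

    def test_year_outside_fixture_coverage_errors(self):
        with pytest.raises(KeyError, match="1200"):
            generate_atmosphere([1200])

    def test_fixture_round_trip_through_csv(self, tmp_path):
        atm = generate_atmosphere(sorted(ATMOSPHERE_FIXTURE))
        path = tmp_path / "atmosphere.csv"
        atm.to_csv(path, index=False)
        back = pd.read_csv(path)
        pdt.assert_frame_equal(atm, back)
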