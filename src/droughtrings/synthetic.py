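"""Synthetic common-garden trial generator.

Emulates a lodgepole pine provenance trial: 4 regional populations x
5 provenances x 3 sites x 2 blocks x 1 tree, observed over 10 years
(1996-2005) with 3 trees missing, a 2002 drought whose growth, isotope
and anatomy response differs by population, and random effects for
block, tree and distance from the apex.

All measurement tables are produced under a known (hence recoverable)
linear model

    value = grand mean + region offset + provenance effect + site offset
            + block effect + tree effect + year effect
            (+ drought term in the drought year) + residual

so that the downstream mixed-model stage can be validated by parameter
recovery, and every count downstream is exact design arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "TraitParams",
    "GeneratorParams",
    "generate_design",
    "simulate_measurements",
    "generate_atmosphere",
    "ATMOSPHERE_FIXTURE",
]


# Synthetic stand-in for the Mauna Loa annual-mean CO2 and flask
# d13C_air series: values approximate the published magnitudes and
# trends (ppm rising ~1.9/yr, d13C_air declining ~0.025 permil/yr) but
# are not the observatory records themselves.
ATMOSPHERE_FIXTURE: dict[int, tuple[float, float]] = {
    year: (
        round(354.4 + 1.9 * (year - 1990) + 0.012 * (year - 1990) ** 2, 2),
        round(-7.80 - 0.025 * (year - 1990), 3),
    )
    for year in range(1990, 2011)
}


_DEFAULT_MISSING = ("CI2-S1-B2", "SI4-S3-B1", "TE1-S2-B2")


@dataclass(frozen=True)
class DesignSpec:
    """Factorial layout of the trial.

    Defaults reproduce the study design: 4 regions x 5 provenances x
    3 sites x 2 blocks x 1 tree over 1996-2005, minus 3 trees.
    """

    regions: tuple[str, ...] = ("LE", "CI", "SI", "TE")
    provenances_per_region: int = 5
    sites: int = 3
    blocks_per_site: int = 2
    trees_per_provenance_block: int = 1
    years: tuple[int, int] = (1996, 2005)
    missing_trees: tuple[str, ...] = _DEFAULT_MISSING
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            len(self.regions),
            self.provenances_per_region,
            self.sites,
            self.blocks_per_site,
            self.trees_per_provenance_block,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError("year range is empty")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1


@dataclass(frozen=True)
class TraitParams:
    """Generating parameters for a single trait.

    ``drought_effect`` maps region label to a multiplier
    (``drought_mode='mult'``) or an additive shift (``'add'``) applied
    in the drought year only.
    """

    mean: float
    region_offsets: Mapping[str, float]
    site_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)
    prov_sd: float = 0.0
    block_sd: float = 0.0
    tree_sd: float = 0.0
    year_sd: float = 0.0
    resid_sd: float = 0.0
    drought_effect: Mapping[str, float] = field(default_factory=dict)
    drought_mode: str = "mult"

    def __post_init__(self) -> None:
        for name in ("prov_sd", "block_sd", "tree_sd", "year_sd", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drought_mode not in ("mult", "add"):
            raise ValueError("drought_mode must be 'mult' or 'add'")


def _tp(mean, offs, drought, mode="mult", **kw) -> TraitParams:
    return TraitParams(
        mean=mean,
        region_offsets=dict(zip(("LE", "CI", "SI", "TE"), offs)),
        drought_effect=dict(zip(("LE", "CI", "SI", "TE"), drought)),
        drought_mode=mode,
        **kw,
    )


@dataclass(frozen=True)
class GeneratorParams:
    """Default generating model for all measurement tables.

    Trait means and dispersions are configurable stand-ins (the trial's
    variance components were never published); the sign pattern of the
    drought response mirrors the field observations: the far-southern
    (TE) population thickens walls, shrinks lumens and cuts cell number
    under drought, the northern (LE) population thins its walls, and
    the central populations (CI, SI) show the strongest isotopic
    enrichment.
    """

    ring_width_mm: TraitParams = field(default_factory=lambda: _tp(
        2.2, (-0.4, 0.3, 0.2, -0.1), (0.60, 0.62, 0.62, 0.55),
        site_offsets=(0.1, 0.0, -0.1), prov_sd=0.12, block_sd=0.08,
        tree_sd=0.18, year_sd=0.10, resid_sd=0.15))
    hi_cm: TraitParams = field(default_factory=lambda: _tp(
        38.0, (-6.0, 4.0, 3.0, -2.0), (0.70, 0.72, 0.72, 0.68),
        site_offsets=(1.5, 0.0, -1.5), prov_sd=1.5, block_sd=1.0,
        tree_sd=2.5, year_sd=1.5, resid_sd=2.5))
    # grand mean chosen so ci/ca stays inside (0, 1) under the
    # discrimination constants: whole-wood d13C near -24 permil maps to
    # ci/ca ~ 0.92 and keeps iWUE positive across the noise range
    d13c_permil: TraitParams = field(default_factory=lambda: _tp(
        -24.0, (-0.5, 0.5, 0.3, 0.0), (0.20, 1.20, 1.00, 0.60), mode="add",
        site_offsets=(0.1, 0.0, -0.1), prov_sd=0.12, block_sd=0.08,
        tree_sd=0.20, year_sd=0.15, resid_sd=0.25))
    d18o_permil: TraitParams = field(default_factory=lambda: _tp(
        22.0, (-0.6, 0.6, 0.4, 0.1), (0.15, 0.90, 0.80, 0.45), mode="add",
        site_offsets=(0.1, 0.0, -0.1), prov_sd=0.15, block_sd=0.10,
        tree_sd=0.25, year_sd=0.20, resid_sd=0.30))
    lumen_um: TraitParams = field(default_factory=lambda: _tp(
        28.0, (-2.0, 2.0, 1.5, -1.0), (0.97, 0.96, 0.96, 0.85),
        site_offsets=(0.5, 0.0, -0.5), prov_sd=0.6, block_sd=0.4,
        tree_sd=1.0, year_sd=0.5, resid_sd=1.0))
    wall_um: TraitParams = field(default_factory=lambda: _tp(
        2.8, (-0.25, 0.10, 0.10, 0.20), (0.90, 1.02, 1.02, 1.15),
        site_offsets=(0.05, 0.0, -0.05), prov_sd=0.06, block_sd=0.04,
        tree_sd=0.10, year_sd=0.05, resid_sd=0.10))
    cells_per_row: TraitParams = field(default_factory=lambda: _tp(
        24.0, (-2.0, 2.0, 1.0, 0.0), (0.90, 0.90, 0.90, 0.70),
        site_offsets=(1.0, 0.0, -1.0), prov_sd=0.8, block_sd=0.5,
        tree_sd=1.2, year_sd=0.8, resid_sd=1.5))

    drought_year: int = 2002
    # ring-width age trend: multiplicative saturating factor
    # 1 + age_trend_coeff * min(age / age_plateau, 1)
    age_trend_coeff: float = 0.10
    age_plateau: float = 25.0
    plant_year: int = 1974
    # larger conduits further below the apex (um per m)
    apex_gradient_um_per_m: float = 0.8
    # shared latent controlling d13C/d18O residual coupling (stomatal
    # signal); 0 = independent residuals
    isotope_coupling: float = 0.7
    # between-radius measurement scatter (mm) around the tree-year mean
    radius_sd: float = 0.05
    # within-row cell-to-cell scatter as a fraction of the ring mean
    cell_cv: float = 0.08
    # slope of growth-trait provenance effects on seed-origin MAT (units
    # of trait per degree C), creating a recoverable adaptation cline
    climate_slope: float = 0.05
    ring_width_floor: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.isotope_coupling <= 1):
            raise ValueError("isotope_coupling must be in [0, 1]")
        if self.radius_sd < 0 or self.cell_cv < 0:
            raise ValueError("dispersion parameters must be >= 0")

    def zeroed(self) -> "GeneratorParams":
        """Copy with every SD, trend and coupling set to 0 (degenerate
        deterministic generator; handy for exactness tests)."""
        traits = {}
        for name in _TRAIT_FIELDS:
            tp = getattr(self, name)
            traits[name] = replace(
                tp, prov_sd=0.0, block_sd=0.0, tree_sd=0.0, year_sd=0.0,
                resid_sd=0.0)
        return replace(
            self, age_trend_coeff=0.0, apex_gradient_um_per_m=0.0,
            isotope_coupling=0.0, radius_sd=0.0, cell_cv=0.0,
            climate_slope=0.0, **traits)


_TRAIT_FIELDS = (
    "ring_width_mm", "hi_cm", "d13c_permil", "d18o_permil",
    "lumen_um", "wall_um", "cells_per_row",
)


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Enumerate the factorial design and drop the missing trees.

    Returns a tree-level table (tree_id, region, provenance_id,
    site_id, block_id). Deterministic: the skeleton depends only on the
    spec, not on its seed.
    """
    rows = []
    for region in spec.regions:
        for p in range(1, spec.provenances_per_region + 1):
            prov = f"{region}{p}"
            for s in range(1, spec.sites + 1):
                for b in range(1, spec.blocks_per_site + 1):
                    for t in range(1, spec.trees_per_provenance_block + 1):
                        tid = f"{prov}-S{s}-B{b}"
                        if spec.trees_per_provenance_block > 1:
                            tid += f"-T{t}"
                        rows.append((tid, region, prov, f"S{s}", f"B{b}"))
    design = pd.DataFrame(
        rows, columns=["tree_id", "region", "provenance_id", "site_id",
                       "block_id"])
    if design["tree_id"].duplicated().any():
        raise AssertionError("tree identifiers must be unique")
    known = set(design["tree_id"])
    for tid in spec.missing_trees:
        if tid not in known:
            raise ValueError(f"missing tree id {tid!r} is not in the design")
    design = design[~design["tree_id"].isin(spec.missing_trees)]
    return design.reset_index(drop=True)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent reproducible substream per table/effect label.
    hash() is salted per-process for str, so use a stable digest."""
    digest = sum(ord(c) * 131 ** i for i, c in enumerate(label)) % (2**31)
    return np.random.default_rng([seed, digest])


def _trait_effects(design: pd.DataFrame, spec: DesignSpec, tp: TraitParams,
                   rng: np.random.Generator,
                   prov_climate_shift: pd.Series | None = None
                   ) -> pd.DataFrame:
    """Tree-by-year table of the linear-model value for one trait
    (everything except the residual, which callers draw so they can
    correlate residuals across traits)."""
    provs = sorted(design["provenance_id"].unique())
    blocks = sorted((design["site_id"] + ":" + design["block_id"]).unique())
    trees = design["tree_id"].tolist()
    years = spec.year_list

    prov_eff = dict(zip(provs, rng.normal(0.0, tp.prov_sd, len(provs))))
    block_eff = dict(zip(blocks, rng.normal(0.0, tp.block_sd, len(blocks))))
    tree_eff = dict(zip(trees, rng.normal(0.0, tp.tree_sd, len(trees))))
    year_eff = dict(zip(years, rng.normal(0.0, tp.year_sd, len(years))))

    site_ids = sorted(design["site_id"].unique())
    site_off = dict(zip(site_ids, tp.site_offsets))

    rec = []
    for row in design.itertuples(index=False):
        base = (
            tp.mean
            + tp.region_offsets.get(row.region, 0.0)
            + prov_eff[row.provenance_id]
            + (0.0 if prov_climate_shift is None
               else float(prov_climate_shift.get(row.provenance_id, 0.0)))
            + site_off.get(row.site_id, 0.0)
            + block_eff[f"{row.site_id}:{row.block_id}"]
            + tree_eff[row.tree_id]
        )
        for year in years:
            rec.append((row.tree_id, year, base + year_eff[year]))
    out = pd.DataFrame(rec, columns=["tree_id", "year", "value"])
    return out


def _apply_drought(values: pd.DataFrame, design: pd.DataFrame,
                   tp: TraitParams, drought_year: int) -> pd.DataFrame:
    region = design.set_index("tree_id")["region"]
    out = values.copy()
    mask = out["year"] == drought_year
    eff = out.loc[mask, "tree_id"].map(region).map(
        lambda r: tp.drought_effect.get(r, 1.0 if tp.drought_mode == "mult"
                                        else 0.0))
    if tp.drought_mode == "mult":
        out.loc[mask, "value"] = out.loc[mask, "value"] * eff.to_numpy()
    else:
        out.loc[mask, "value"] = out.loc[mask, "value"] + eff.to_numpy()
    return out


def _provenance_climate(spec: DesignSpec, rng: np.random.Generator
                        ) -> pd.DataFrame:
    """1961-1990 normals at seed origin: a latitudinal cline from the
    cold northern (LE) to warm far-southern (TE) margin."""
    base_mat = {"LE": -1.0, "CI": 3.0, "SI": 5.0, "TE": 8.0}
    rows = []
    for region in spec.regions:
        for p in range(1, spec.provenances_per_region + 1):
            mat = base_mat.get(region, 3.0) + 0.5 * (p - 3) \
                + rng.normal(0, 0.3)
            mapm = 600 - 25 * mat + rng.normal(0, 30)
            msp = 280 - 8 * mat + rng.normal(0, 15)
            rows.append((f"{region}{p}", round(mat, 2), round(mapm, 1),
                         round(msp, 1)))
    return pd.DataFrame(
        rows, columns=["provenance_id", "mat_c", "map_mm", "msp_mm"])


def _site_climate(spec: DesignSpec, params: GeneratorParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Annual weather at the planting sites; the drought year carries a
    one-standard-deviation precipitation deficit."""
    rows = []
    for s in range(1, spec.sites + 1):
        site_mat = 4.0 + 0.7 * (s - 2)
        site_map = 550.0 - 40.0 * (s - 2)
        for year in spec.year_list:
            t = site_mat + rng.normal(0, 0.6)
            p = site_map + rng.normal(0, 55.0)
            if year == params.drought_year:
                t += 1.0
                p -= 110.0  # ~2 annual-scatter SDs below normal
            rows.append((f"S{s}", year, round(t, 2), round(max(p, 50.0), 1)))
    return pd.DataFrame(
        rows, columns=["site_id", "year", "mat_c", "map_mm"])


def simulate_trait(design: pd.DataFrame, spec: DesignSpec, tp: TraitParams,
                   seed: int, label: str = "trait",
                   drought_year: int | None = None) -> pd.DataFrame:
    """Simulate a single trait (tree_id, year, value) under the linear
    model, without generating the full measurement tables.

    Used for parameter-recovery and type-I simulations, where only one
    response per replicate is needed.
    """
    rng = _rng(seed, label)
    vals = _trait_effects(design, spec, tp, rng)
    if drought_year is not None:
        vals = _apply_drought(vals, design, tp, drought_year)
    if tp.resid_sd > 0:
        vals["value"] = vals["value"] + rng.normal(0, tp.resid_sd, len(vals))
    return vals.merge(design, on="tree_id")


def generate_atmosphere(years: Sequence[int], *,
                        fixture: Mapping[int, tuple[float, float]] | None = None,
                        ca0: float | None = None, ca_slope: float = 0.0,
                        d13c0: float = -8.0, d13c_slope: float = 0.0
                        ) -> pd.DataFrame:
    """Annual atmospheric CO2 (ppm) and d13C_air (permil) series.

    By default reads the bundled fixture; pass ``ca0`` to switch to a
    linear synthetic model instead.
    """
    years = list(years)
    if not years:
        raise ValueError("year range is empty")
    rows = []
    if ca0 is not None:
        y0 = years[0]
        for y in years:
            rows.append((y, ca0 + ca_slope * (y - y0),
                         d13c0 + d13c_slope * (y - y0)))
    else:
        table = ATMOSPHERE_FIXTURE if fixture is None else fixture
        for y in years:
            if y not in table:
                raise KeyError(
                    f"year {y} outside atmospheric fixture coverage")
            ca, d13 = table[y]
            rows.append((y, ca, d13))
    return pd.DataFrame(rows, columns=["year", "ca_ppm", "d13c_air_permil"])


def _cells_for_ring(rng: np.random.Generator, n_rows: int, n_cells_mean: float,
                    lumen_mean: float, wall_mean: float, cell_cv: float
                    ) -> list[tuple[int, int, float, float]]:
    """Cell rows for one ring: lumen tapers and walls thicken from the
    earlywood (position 1) towards the latewood side; row means equal
    the ring means when cell_cv = 0."""
    rows = []
    for row_id in range(1, n_rows + 1):
        n = max(1, int(round(n_cells_mean + (rng.normal(0, 1.0)
                                             if cell_cv > 0 else 0.0))))
        pos = (np.arange(1, n + 1) - 0.5) / n
        lumen_prof = lumen_mean * (1.4 - 0.8 * pos)
        wall_prof = wall_mean * (0.8 + 0.4 * pos)
        if cell_cv > 0:
            lumen_prof = lumen_prof * rng.normal(1.0, cell_cv, n)
            wall_prof = wall_prof * rng.normal(1.0, cell_cv, n)
        lumen_prof = np.maximum(lumen_prof, 1.0)
        wall_prof = np.maximum(wall_prof, 0.2)
        for i in range(n):
            rows.append((row_id, i + 1, float(lumen_prof[i]),
                         float(wall_prof[i])))
    return rows


def simulate_measurements(design: pd.DataFrame, spec: DesignSpec,
                          params: GeneratorParams | None = None
                          ) -> dict[str, pd.DataFrame]:
    """Generate every measurement table for a design.

    Returns a dict of DataFrames: ``ring_widths``, ``heights``,
    ``cells``, ``isotopes``, ``atmosphere``, ``site_climate``,
    ``provenance_climate``. One seed (spec.seed) drives a reproducible
    substream per table so tables can be regenerated independently.
    """
    params = params or GeneratorParams()
    if not (spec.years[0] <= params.drought_year <= spec.years[1]):
        raise ValueError("drought_year outside the design years")
    years = spec.year_list

    prov_clim = _provenance_climate(spec, _rng(spec.seed, "prov_climate"))
    mat_centered = prov_clim.set_index("provenance_id")["mat_c"]
    mat_centered = mat_centered - mat_centered.mean()
    growth_shift = params.climate_slope * mat_centered

    def trait(name: str, climate_linked: bool = False) -> pd.DataFrame:
        tp = getattr(params, name)
        vals = _trait_effects(
            design, spec, tp, _rng(spec.seed, name),
            growth_shift if climate_linked else None)
        return _apply_drought(vals, design, tp, params.drought_year)

    # --- growth -----------------------------------------------------
    width = trait("ring_width_mm", climate_linked=True)
    age = width["year"] - params.plant_year
    age_factor = 1.0 + params.age_trend_coeff * np.minimum(
        age / params.age_plateau, 1.0)
    width["value"] = width["value"] * age_factor
    rng_w = _rng(spec.seed, "ring_width_resid")
    width["value"] += rng_w.normal(0, params.ring_width_mm.resid_sd,
                                   len(width))

    rng_r = _rng(spec.seed, "radii")
    radii = []
    for row in width.itertuples(index=False):
        for radius_id in range(1, 5):
            w = row.value + (rng_r.normal(0, params.radius_sd)
                             if params.radius_sd > 0 else 0.0)
            radii.append((row.tree_id, row.year, radius_id,
                          max(w, params.ring_width_floor)))
    ring_widths = pd.DataFrame(
        radii, columns=["tree_id", "year", "radius_id", "ring_width_mm"])

    hi = trait("hi_cm", climate_linked=True)
    rng_h = _rng(spec.seed, "hi_resid")
    hi["value"] += rng_h.normal(0, params.hi_cm.resid_sd, len(hi))
    hi["value"] = hi["value"].clip(lower=1.0)
    # distance from apex at breast height = stem height above 1.3 m;
    # trees were already well past breast height at the window start
    heights = hi.rename(columns={"value": "hi_cm"}).copy()
    start_height_m = 0.01 * heights.groupby("tree_id")["hi_cm"].transform(
        "mean") * (years[0] - params.plant_year)
    heights["height_m"] = (
        start_height_m
        + 0.01 * heights.groupby("tree_id")["hi_cm"].cumsum())
    heights["distance_from_apex_m"] = (heights["height_m"] - 1.3).clip(
        lower=0.1)

    # --- isotopes (coupled residuals: shared stomatal latent) --------
    d13 = trait("d13c_permil")
    d18 = trait("d18o_permil")
    rng_iso = _rng(spec.seed, "isotope_resid")
    n = len(d13)
    c = params.isotope_coupling
    latent = rng_iso.normal(0, 1, n)
    e13 = c * latent + np.sqrt(1 - c**2) * rng_iso.normal(0, 1, n)
    e18 = c * latent + np.sqrt(1 - c**2) * rng_iso.normal(0, 1, n)
    d13["value"] += params.d13c_permil.resid_sd * e13
    d18 = d18.merge(d13[["tree_id", "year"]], on=["tree_id", "year"])
    d18["value"] += params.d18o_permil.resid_sd * e18
    isotopes = d13.rename(columns={"value": "d13c_permil"}).merge(
        d18.rename(columns={"value": "d18o_permil"}), on=["tree_id", "year"])

    # --- anatomy ----------------------------------------------------
    lumen = trait("lumen_um")
    lumen = lumen.merge(
        heights[["tree_id", "year", "distance_from_apex_m"]],
        on=["tree_id", "year"])
    lumen["value"] += (params.apex_gradient_um_per_m
                       * lumen["distance_from_apex_m"])
    wall = trait("wall_um")
    ncell = trait("cells_per_row")
    rng_a = _rng(spec.seed, "anatomy_resid")
    lumen["value"] = np.maximum(
        lumen["value"] + rng_a.normal(0, params.lumen_um.resid_sd, len(lumen)),
        2.0)
    wall["value"] = np.maximum(
        wall["value"] + rng_a.normal(0, params.wall_um.resid_sd, len(wall)),
        0.3)
    ncell["value"] = np.maximum(
        ncell["value"] + rng_a.normal(0, params.cells_per_row.resid_sd,
                                      len(ncell)),
        1.0)

    rng_c = _rng(spec.seed, "cells")
    anat = lumen.rename(columns={"value": "lumen"}).merge(
        wall.rename(columns={"value": "wall"}), on=["tree_id", "year"]).merge(
        ncell.rename(columns={"value": "ncell"}), on=["tree_id", "year"])
    cell_rows = []
    for row in anat.itertuples(index=False):
        for row_id, idx, lu, wa in _cells_for_ring(
                rng_c, 4, row.ncell, row.lumen, row.wall, params.cell_cv):
            cell_rows.append((row.tree_id, row.year, row_id, idx, lu, wa))
    cells = pd.DataFrame(
        cell_rows, columns=["tree_id", "year", "row_id", "cell_index",
                            "lumen_diameter_um", "wall_thickness_um"])

    atmosphere = generate_atmosphere(years)
    site_climate = _site_climate(spec, params, _rng(spec.seed, "site_climate"))

    return {
        "design": design.copy(),
        "ring_widths": ring_widths,
        "heights": heights[["tree_id", "year", "hi_cm", "height_m",
                            "distance_from_apex_m"]],
        "cells": cells,
        "isotopes": isotopes,
        "atmosphere": atmosphere,
        "site_climate": site_climate,
        "provenance_climate": prov_clim,
    }


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, int]:
    """Write each table as UTF-8 CSV with a header row; returns row
    counts per table (used by the run manifest)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
        counts[name] = len(df)
    return counts
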