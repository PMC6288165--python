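"""End-to-end orchestration: simulate (or load) the trial tables, derive
growth/anatomy/isotope traits, compute drought indices, run the
population inference, and write every output CSV plus a run manifest.

CSV is the canonical interchange (UTF-8, header row, '.' decimal);
column names are part of the public contract. Logs go to stderr; result
tables are never interleaved with logs. Reruns with the same config and
seed are byte-identical (the manifest excludes timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import summarize_rings
from .drought import DroughtWindows, drought_indices
from .inference import (ModelSpec, climate_correlations,
                        fit_population_model, lsmeans_by_provenance,
                        pairwise_contrasts, plasticity_contrast,
                        standardize_rankings)
from .isotopes import dual_isotope_diagnosis, iwue_table
from .ring_metrics import compute_bai
from .synthetic import (DesignSpec, GeneratorParams, generate_design,
                        simulate_measurements, write_tables)

log = logging.getLogger("droughtrings")

TABLE_NAMES = ("design", "ring_widths", "heights", "cells", "isotopes",
               "atmosphere", "site_climate", "provenance_climate")

TREE_YEAR_TRAITS = ["bai_mm2", "hi_cm", "dh_um", "mean_wall_um",
                    "mean_lumen_um", "d13c_permil", "d18o_permil",
                    "iwue_umol_mol"]
INDEX_TRAITS = ["resistance", "recovery", "resilience",
                "relative_resilience"]
ANATOMY_TRAITS = {"dh_um", "mean_wall_um", "mean_lumen_um"}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/run"
    simulate: bool = True
    input_dir: str | None = None
    design: DesignSpec = field(default_factory=DesignSpec)
    params: GeneratorParams = field(default_factory=GeneratorParams)
    windows: DroughtWindows = field(default_factory=DroughtWindows)
    alpha: float = 0.05
    level: str = "region"
    dry_year: int = 2002
    wet_year: int = 2000
    heatmap: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("seed", "out_dir", "simulate", "input_dir", "alpha",
                    "level", "dry_year", "wet_year", "heatmap", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "design" in raw:
            d = dict(raw["design"])
            for k in ("regions", "missing_trees"):
                if k in d:
                    d[k] = tuple(d[k])
            if "years" in d:
                d["years"] = tuple(d["years"])
            kwargs["design"] = DesignSpec(**d)
        if "params" in raw:
            scalars = {k: v for k, v in raw["params"].items()}
            kwargs["params"] = replace(GeneratorParams(), **scalars)
        if "windows" in raw:
            w = raw["windows"]
            kwargs["windows"] = DroughtWindows(
                frozenset(range(w["pre"][0], w["pre"][1] + 1)),
                frozenset({w["drought"]} if np.isscalar(w["drought"])
                          else w["drought"]),
                frozenset(range(w["post"][0], w["post"][1] + 1)))
        cfg = cls(**kwargs)
        if not cfg.simulate and not cfg.input_dir:
            raise ValueError("config must enable simulation or name an "
                             "input_dir of measurement tables")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "design": repr(self.design),
             "params": repr(self.params), "windows": repr(self.windows),
             "alpha": self.alpha, "level": self.level,
             "dry_year": self.dry_year, "wet_year": self.wet_year},
            sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_tables(input_dir) -> dict[str, pd.DataFrame]:
    """Read the canonical measurement CSVs from a directory."""
    input_dir = Path(input_dir)
    tables = {}
    for name in TABLE_NAMES:
        path = input_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"required input table missing: {path}")
        tables[name] = pd.read_csv(path)
    return tables


def derive_traits(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Growth, anatomy, iWUE and the merged tree-by-year trait table."""
    growth = compute_bai(tables["ring_widths"], heights=tables["heights"])
    anatomy = summarize_rings(tables["cells"], heights=tables["heights"])
    iwue = iwue_table(tables["isotopes"], tables["atmosphere"])

    traits = (growth.merge(anatomy, on=["tree_id", "year"], how="outer")
              .merge(iwue, on=["tree_id", "year"], how="outer")
              .merge(tables["design"], on="tree_id", how="left"))
    return {"growth": growth, "anatomy": anatomy, "iwue": iwue,
            "traits": traits}


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order and write all outputs.

    Returns the run manifest (also written as manifest.json). A stage
    failure aborts with the failing stage named.
    """
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            spec = replace(config.design, seed=config.seed)
            design = generate_design(spec)
            tables = simulate_measurements(design, spec, config.params)
        else:
            tables = load_tables(config.input_dir)
        counts = write_tables(tables, out / "data")
        log.info("%s: %d trees, %d tables", stage,
                 len(tables["design"]), len(tables))

        stage = "traits"
        derived = derive_traits(tables)
        traits = derived["traits"]

        stage = "drought_indices"
        indices = drought_indices(derived["growth"], config.windows)
        tree_level = (traits.groupby(
            ["tree_id", "region", "provenance_id", "site_id", "block_id"],
            as_index=False)[TREE_YEAR_TRAITS].mean()
            .merge(indices, on="tree_id"))

        stage = "stats"
        contrast_frames = []
        for trait in TREE_YEAR_TRAITS:
            mspec = ModelSpec(response=trait, fixed=config.level,
                              include_apex=trait in ANATOMY_TRAITS,
                              alpha=config.alpha)
            fit = fit_population_model(traits, mspec)
            contrast_frames.append(pairwise_contrasts(fit))
        for trait in INDEX_TRAITS:
            mspec = ModelSpec(response=trait, fixed=config.level,
                              alpha=config.alpha)
            fit = fit_population_model(tree_level, mspec)
            contrast_frames.append(pairwise_contrasts(fit))
        contrasts = pd.concat(contrast_frames, ignore_index=True)

        lsm = lsmeans_by_provenance(
            traits, TREE_YEAR_TRAITS,
            include_apex_for=ANATOMY_TRAITS).reset_index()
        origin_corr = climate_correlations(
            lsm, tables["provenance_climate"], on=["provenance_id"],
            trait_cols=TREE_YEAR_TRAITS,
            climate_cols=["mat_c", "map_mm", "msp_mm"])
        origin_corr.insert(0, "climate_of", "seed_origin")

        annual = (traits.groupby(
            ["provenance_id", "site_id", "year"], as_index=False)
            [["bai_mm2", "hi_cm"]].mean())
        site_corr = climate_correlations(
            annual, tables["site_climate"], on=["site_id", "year"],
            trait_cols=["bai_mm2", "hi_cm"],
            climate_cols=["mat_c", "map_mm"])
        site_corr.insert(0, "climate_of", "planting_site")
        correlations = pd.concat([origin_corr, site_corr],
                                 ignore_index=True)

        rankings = standardize_rankings(
            tree_level, TREE_YEAR_TRAITS + INDEX_TRAITS,
            group_col=config.level)

        plast_traits = ["d13c_permil", "d18o_permil", "mean_wall_um",
                        "mean_lumen_um", "dh_um", "bai_mm2"]
        plasticity = plasticity_contrast(
            traits, plast_traits, dry_year=config.dry_year,
            wet_year=config.wet_year, group_col=config.level)

        dual = dual_isotope_diagnosis(traits, group_cols=[config.level],
                                      alpha=config.alpha)

        stage = "write"
        outputs = {
            "growth": derived["growth"], "anatomy": derived["anatomy"],
            "iwue": derived["iwue"], "traits": traits,
            "drought_indices": indices, "tree_level": tree_level,
            "contrasts": contrasts, "correlations": correlations,
            "rankings": rankings, "plasticity": plasticity,
            "dual_isotope": dual, "provenance_lsmeans": lsm,
        }
        counts.update(write_tables(outputs, out))
        n_annual = len(annual)

        if config.heatmap:
            stage = "heatmap"
            _write_heatmap(origin_corr, out / "origin_climate_heatmap.png")

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "df_method": "wald-z (normal approximation)",
            "row_counts": counts,
            "n_trees": int(len(tables["design"])),
            "n_tree_year_records": int(
                traits[["tree_id", "year"]].drop_duplicates().shape[0]),
            "n_provenance_site_year": int(n_annual),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("run complete: %d trait rows", manifest["n_tree_year_records"])
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_heatmap(corr: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = corr.pivot(index="trait", columns="climate_var", values="r")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=45)
    ax.set_yticks(range(grid.shape[0]), grid.index)
    fig.colorbar(im, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def validate_tables(directory) -> list[str]:
    """Schema, key-uniqueness, unit-range and cross-table referential
    checks over a directory of measurement CSVs. Returns the list of
    violations (empty = clean)."""
    directory = Path(directory)
    violations: list[str] = []
    try:
        tables = load_tables(directory)
    except FileNotFoundError as exc:
        return [str(exc)]

    design = tables["design"]
    if design["tree_id"].duplicated().any():
        violations.append("design: duplicate tree_id")
    known = set(design["tree_id"])

    for name in ("ring_widths", "heights", "cells", "isotopes"):
        orphans = set(tables[name]["tree_id"]) - known
        if orphans:
            violations.append(
                f"{name}: tree_id not in design: {sorted(orphans)[:5]}")

    rw = tables["ring_widths"]
    if (rw["ring_width_mm"] < 0).any():
        violations.append("ring_widths: negative ring width")
    if not rw["radius_id"].isin([1, 2, 3, 4]).all():
        violations.append("ring_widths: radius_id outside 1..4")
    if rw.duplicated(["tree_id", "year", "radius_id"]).any():
        violations.append("ring_widths: duplicate (tree, year, radius) key")

    cells = tables["cells"]
    if (cells["lumen_diameter_um"] <= 0).any():
        violations.append("cells: non-positive lumen diameter")
    if (cells["wall_thickness_um"] <= 0).any():
        violations.append("cells: non-positive wall thickness")

    iso = tables["isotopes"]
    if not iso["d13c_permil"].between(-40, 0).all():
        violations.append("isotopes: d13C outside plausible (-40, 0) permil")
    if not iso["d18o_permil"].between(0, 40).all():
        violations.append("isotopes: d18O outside plausible (0, 40) permil")
    if iso.duplicated(["tree_id", "year"]).any():
        violations.append("isotopes: duplicate (tree, year) key")

    atm = tables["atmosphere"]
    if (atm["ca_ppm"] <= 0).any():
        violations.append("atmosphere: non-positive CO2 concentration")
    return violations
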