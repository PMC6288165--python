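"""Tracheid anatomy summaries: lumen/wall means, cell counts and the
hydraulic diameter D_h = sum(d^5)/sum(d^4), the flow-weighted mean
conduit diameter that weights each conduit by its Hagen-Poiseuille
conductance contribution (d^4)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["hydraulic_diameter", "summarize_rings", "tracheidogram"]


def hydraulic_diameter(d) -> float:
    """D_h = sum(d^5) / sum(d^4) over lumen diameters ``d`` (um).

    A power-mean-type average dominated by the widest conduits: equal
    diameters give D_h = d, and D_h >= mean(d) always. Degree-1
    homogeneous: scaling every diameter by c scales D_h by c.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("no lumen diameters given")
    if np.any(d <= 0):
        raise ValueError("lumen diameters must be > 0")
    return float(np.sum(d**5) / np.sum(d**4))


def summarize_rings(cells: pd.DataFrame,
                    heights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-ring anatomy summary from the long cell table.

    Means are unweighted over all cells pooled across the ring's
    measured rows (so the pooled mean is the cell-count-weighted average
    of row means); D_h uses the pooled lumen diameters.

    Parameters
    ----------
    cells : DataFrame (tree_id, year, row_id, cell_index,
        lumen_diameter_um, wall_thickness_um).
    heights : optional (tree_id, year, distance_from_apex_m) merged on.

    Returns
    -------
    DataFrame (tree_id, year, n_cells, n_rows, cells_per_row,
    mean_lumen_um, mean_wall_um, dh_um [, distance_from_apex_m]).
    """
    if cells.empty:
        raise ValueError("cell table is empty")
    if (cells["lumen_diameter_um"] <= 0).any() or \
            (cells["wall_thickness_um"] <= 0).any():
        raise ValueError("non-positive cell measurement encountered")

    def _one(grp: pd.DataFrame) -> pd.Series:
        n_rows = grp["row_id"].nunique()
        return pd.Series({
            "n_cells": len(grp),
            "n_rows": n_rows,
            "cells_per_row": len(grp) / n_rows,
            "mean_lumen_um": grp["lumen_diameter_um"].mean(),
            "mean_wall_um": grp["wall_thickness_um"].mean(),
            "dh_um": hydraulic_diameter(grp["lumen_diameter_um"]),
        })

    summary = (cells.groupby(["tree_id", "year"], sort=True)
               .apply(_one, include_groups=False).reset_index())
    summary["n_cells"] = summary["n_cells"].astype(int)
    summary["n_rows"] = summary["n_rows"].astype(int)
    if heights is not None:
        summary = summary.merge(
            heights[["tree_id", "year", "distance_from_apex_m"]],
            on=["tree_id", "year"], how="left")
    return summary


def tracheidogram(cells: pd.DataFrame,
                  group_cols: list[str] | None = None) -> pd.DataFrame:
    """Mean lumen diameter and wall thickness as a function of the
    1-based cell position from the earlywood side, with standard errors,
    optionally per group (e.g. region x year).

    Positions observed only once get an undefined (NaN) SE and are
    flagged ``single_obs``.
    """
    keys = (group_cols or []) + ["cell_index"]
    agg = cells.groupby(keys).agg(
        n=("lumen_diameter_um", "size"),
        mean_lumen_um=("lumen_diameter_um", "mean"),
        se_lumen_um=("lumen_diameter_um", "sem"),
        mean_wall_um=("wall_thickness_um", "mean"),
        se_wall_um=("wall_thickness_um", "sem"),
    ).reset_index()
    agg["single_obs"] = agg["n"] == 1
    return agg
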