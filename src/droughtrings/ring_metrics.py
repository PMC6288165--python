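"""Basal area increment (BAI) and height increments from ring widths.

Ring widths are measured on up to four radii per stem disk. Widths are
averaged across radii first, then cumulated to a radius series, and the
annual increment of the circular cross-section gives

    BAI_t = pi * (r_t^2 - r_{t-1}^2),   r_t = inner_radius + sum_{s<=t} w_s

which telescopes to sum(BAI) = pi * (r_T^2 - r_0^2).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["bai_from_widths", "compute_bai", "total_basal_area",
           "read_rwl"]


def bai_from_widths(mean_widths, inner_radius: float = 0.0) -> np.ndarray:
    """BAI series (mm^2) from a chronological mean ring-width series (mm).

    ``inner_radius`` is the radius at the start of the series; it MUST
    be given explicitly for series that do not start at the pith.
    """
    w = np.asarray(mean_widths, dtype=float)
    if w.size == 0:
        return np.array([])
    if np.any(w < 0):
        raise ValueError("ring widths must be >= 0")
    if inner_radius < 0:
        raise ValueError("inner radius must be >= 0")
    r = inner_radius + np.cumsum(w)
    prev = np.concatenate([[inner_radius], r[:-1]])
    return math.pi * (r**2 - prev**2)


def compute_bai(ring_widths: pd.DataFrame, *, inner_radius: float = 0.0,
                allow_gaps: bool = False,
                heights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tree growth table from the long ring-width table.

    Parameters
    ----------
    ring_widths : DataFrame with columns tree_id, year, radius_id,
        ring_width_mm (>= 1 radius per tree-year).
    inner_radius : radius (mm) preceding the first year of every series;
        0 means the series starts at the pith.
    allow_gaps : if False (default), a missing calendar year inside a
        tree's series is an error.
    heights : optional (tree_id, year, hi_cm) table merged onto the
        output.

    Returns
    -------
    DataFrame (tree_id, year, mean_width_mm, cum_radius_mm, bai_mm2
    [, hi_cm]).
    """
    if (ring_widths["ring_width_mm"] < 0).any():
        raise ValueError("negative ring width encountered")
    mean_w = (ring_widths.groupby(["tree_id", "year"], sort=True)
              ["ring_width_mm"].mean().rename("mean_width_mm").reset_index())
    out = []
    for tree_id, grp in mean_w.groupby("tree_id", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if not allow_gaps and len(years) > 1 and np.any(np.diff(years) != 1):
            raise ValueError(f"gap in year series for tree {tree_id}")
        bai = bai_from_widths(grp["mean_width_mm"].to_numpy(), inner_radius)
        grp = grp.assign(
            cum_radius_mm=inner_radius + grp["mean_width_mm"].cumsum(),
            bai_mm2=bai)
        out.append(grp)
    growth = pd.concat(out, ignore_index=True)
    if heights is not None:
        growth = growth.merge(heights[["tree_id", "year", "hi_cm"]],
                              on=["tree_id", "year"], how="left")
    return growth


def total_basal_area(growth: pd.DataFrame) -> pd.Series:
    """Sum of BAI per tree; equals pi*(r_T^2 - r_0^2) exactly for a
    series cumulated from its inner radius (telescoping check)."""
    if growth.empty:
        return pd.Series(dtype=float)
    return growth.groupby("tree_id")["bai_mm2"].sum()


def read_rwl(path) -> pd.DataFrame:
    """Read a Tucson/decadal RWL ring-width file into the long table.

    Values are in 0.01 mm and converted to mm on ingest; the
    series-terminating sentinel (999 or -9999) ends a series. The series
    ID is used as tree_id with radius_id 1.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if len(line) < 12 or not line[:8].strip():
                continue
            sid = line[:8].strip()
            try:
                decade = int(line[8:12])
            except ValueError:
                continue
            fields = line[12:].split()
            for i, tok in enumerate(fields):
                v = int(tok)
                if v in (999, -9999):
                    break
                rows.append((sid, decade + i, 1, v / 100.0))
    if not rows:
        raise ValueError(f"no ring-width data parsed from {path}")
    return pd.DataFrame(
        rows, columns=["tree_id", "year", "radius_id", "ring_width_mm"])
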