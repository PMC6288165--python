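"""Super-epoch drought-tolerance indices on per-tree growth series.

The four Lloret-style indicators compare arithmetic window means of a
growth variable (BAI by default) around a drought event:

    resistance          Rt  = Dr / PreDr
    recovery            Rc  = PostDr / Dr
    resilience          Rs  = PostDr / PreDr
    relative resilience RRs = (PostDr - Dr) / PreDr

where PreDr, Dr and PostDr are the means over the pre-drought, drought
and post-drought windows. The identities Rs = Rt * Rc and
RRs = Rs - Rt hold exactly, and all four are invariant to rescaling the
series by a positive constant. Default windows: pre 1999-2001, drought
2002, post 2003-2005.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DroughtWindows", "assign_windows", "drought_indices",
           "flag_dry_years"]


@dataclass(frozen=True)
class DroughtWindows:
    pre: frozenset = field(default_factory=lambda: frozenset({1999, 2000, 2001}))
    drought: frozenset = field(default_factory=lambda: frozenset({2002}))
    post: frozenset = field(default_factory=lambda: frozenset({2003, 2004, 2005}))

    def __post_init__(self) -> None:
        pre, dr, post = map(frozenset, (self.pre, self.drought, self.post))
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "drought", dr)
        object.__setattr__(self, "post", post)
        if not (pre and dr and post):
            raise ValueError("all windows must be non-empty")
        if pre & dr or pre & post or dr & post:
            raise ValueError("windows must be pairwise disjoint")

    @property
    def all_years(self) -> frozenset:
        return self.pre | self.drought | self.post


def assign_windows(years, drought_year: int, width: int = 3
                   ) -> DroughtWindows:
    """Symmetric windows of ``width`` years on either side of the
    drought year, restricted to the available ``years``."""
    years = set(int(y) for y in years)
    if drought_year not in years:
        raise ValueError(f"drought year {drought_year} not in series")
    pre = {y for y in range(drought_year - width, drought_year) if y in years}
    post = {y for y in range(drought_year + 1, drought_year + width + 1)
            if y in years}
    if len(pre) < width or len(post) < width:
        raise ValueError(
            f"need {width} years on each side of {drought_year}; "
            f"found {len(pre)} pre and {len(post)} post")
    return DroughtWindows(frozenset(pre), frozenset({drought_year}),
                          frozenset(post))


def _window_mean(grp: pd.DataFrame, years: frozenset, value_col: str,
                 name: str, tree_id) -> float:
    have = set(grp["year"])
    missing = years - have
    if missing:
        raise ValueError(
            f"tree {tree_id}: missing {name} year(s) "
            + ", ".join(str(y) for y in sorted(missing)))
    return float(grp.loc[grp["year"].isin(years), value_col].mean())


def drought_indices(growth: pd.DataFrame,
                    windows: DroughtWindows | None = None,
                    value_col: str = "bai_mm2") -> pd.DataFrame:
    """Per-tree drought indices from an annual growth table.

    Parameters
    ----------
    growth : DataFrame (tree_id, year, <value_col>); BAI by default but
        any positive growth variable (e.g. height increment) works.
    windows : window spec; defaults to pre 1999-2001 / 2002 / post
        2003-2005.

    Returns
    -------
    DataFrame (tree_id, pre_mean, drought_mean, post_mean, resistance,
    recovery, resilience, relative_resilience).
    """
    windows = windows or DroughtWindows()
    rows = []
    for tree_id, grp in growth.groupby("tree_id", sort=True):
        pre = _window_mean(grp, windows.pre, value_col, "pre-drought", tree_id)
        dr = _window_mean(grp, windows.drought, value_col, "drought", tree_id)
        post = _window_mean(grp, windows.post, value_col, "post-drought",
                            tree_id)
        if pre <= 0 or dr <= 0:
            raise ValueError(
                f"tree {tree_id}: non-positive window mean; indices undefined")
        rows.append({
            "tree_id": tree_id,
            "pre_mean": pre,
            "drought_mean": dr,
            "post_mean": post,
            "resistance": dr / pre,
            "recovery": post / dr,
            "resilience": post / pre,
            "relative_resilience": (post - dr) / pre,
        })
    return pd.DataFrame(rows)


def flag_dry_years(site_climate: pd.DataFrame, normal_mean: float,
                   normal_sd: float, threshold: float = -1.0,
                   precip_col: str = "map_mm") -> pd.DataFrame:
    """Flag years whose precipitation z-score against a long-term normal
    falls below ``threshold`` (a convenience check; the headline
    analysis uses a fixed drought year)."""
    if normal_sd <= 0:
        raise ValueError("normal SD must be > 0")
    out = site_climate.copy()
    out["precip_z"] = (out[precip_col] - normal_mean) / normal_sd
    out["dry"] = out["precip_z"] < threshold
    return out
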