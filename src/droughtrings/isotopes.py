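"""Stable-isotope algebra and intrinsic water-use efficiency.

delta notation expresses a heavy/light isotope ratio R as a per-mil
deviation from a reference standard:

    delta = (R_sample / R_reference - 1) * 1000

Tree-ring d13C together with the atmospheric CO2 concentration c_a and
d13C of air yields the intercellular-to-ambient CO2 ratio and the
intrinsic water-use efficiency (assimilation per unit stomatal
conductance):

    ci/ca = (d13C_plant - d13C_air + a) / (b - a)
    iWUE  = A / g_s = c_a * (1 - ci/ca) * 0.625

with a = -4.4 permil (kinetic diffusion fractionation at the stomata)
and b = -27 permil (fractionation at the site of carboxylation). A and
g_s are never computed individually, only their ratio.

A positive within-group correlation between d13C and d18O indicates
that d13C is governed more by stomatal conductance than by
photosynthetic capacity (the dual-isotope rule): stomatal closure
enriches both isotopes, while a change in photosynthetic rate alone
moves d13C but not d18O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiscriminationConstants",
    "delta_from_ratios",
    "ratio_from_delta",
    "ci_ca_ratio",
    "iwue",
    "iwue_table",
    "dual_isotope_diagnosis",
]


@dataclass(frozen=True)
class DiscriminationConstants:
    """Carbon-isotope discrimination constants (permil) and the
    conversion factor relating CO2 and water vapour diffusivities."""

    a: float = -4.4
    b: float = -27.0
    conversion: float = 0.625

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("a and b must differ")


def delta_from_ratios(r_sample: float, r_reference: float) -> float:
    """delta (permil) from sample and reference heavy/light ratios."""
    r_sample, r_reference = float(r_sample), float(r_reference)
    if r_sample <= 0 or r_reference <= 0:
        raise ValueError("isotope ratios must be > 0")
    return (r_sample / r_reference - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_reference: float) -> float:
    """Inverse of :func:`delta_from_ratios` (round-trip identity)."""
    if r_reference <= 0:
        raise ValueError("reference ratio must be > 0")
    if delta <= -1000.0:
        raise ValueError("delta must be > -1000 permil")
    return (delta / 1000.0 + 1.0) * r_reference


def ci_ca_ratio(d13c_plant, d13c_air,
                constants: DiscriminationConstants | None = None):
    """ci/ca from plant and air d13C; no clamping (out-of-range values
    are flagged downstream, never silently truncated)."""
    c = constants or DiscriminationConstants()
    return (np.asarray(d13c_plant, dtype=float) - np.asarray(d13c_air)
            + c.a) / (c.b - c.a)


def iwue(ci_ca, c_a, constants: DiscriminationConstants | None = None):
    """Intrinsic water-use efficiency (umol CO2 per mol H2O)."""
    c = constants or DiscriminationConstants()
    c_a = np.asarray(c_a, dtype=float)
    if np.any(c_a <= 0):
        raise ValueError("atmospheric CO2 must be > 0")
    return c_a * (1.0 - np.asarray(ci_ca, dtype=float)) * c.conversion


def iwue_table(isotopes: pd.DataFrame, atmosphere: pd.DataFrame,
               constants: DiscriminationConstants | None = None
               ) -> pd.DataFrame:
    """Join per-ring d13C with the annual atmospheric record by calendar
    year and derive ci/ca and iWUE.

    Rows whose ci/ca falls outside [0, 1] get ``flag='ci_ca_range'``;
    a ring year missing from the atmospheric record is an error naming
    the year.
    """
    missing = set(isotopes["year"]) - set(atmosphere["year"])
    if missing:
        raise KeyError(
            "no atmospheric record for year(s): "
            + ", ".join(str(y) for y in sorted(missing)))
    merged = isotopes.merge(atmosphere, on="year", how="left")
    merged["ci_ca"] = ci_ca_ratio(
        merged["d13c_permil"], merged["d13c_air_permil"], constants)
    merged["iwue_umol_mol"] = iwue(merged["ci_ca"], merged["ca_ppm"],
                                   constants)
    merged["flag"] = np.where(
        (merged["ci_ca"] < 0) | (merged["ci_ca"] > 1), "ci_ca_range", "")
    cols = ["tree_id", "year", "d13c_permil", "d18o_permil", "ci_ca",
            "iwue_umol_mol", "flag"]
    return merged[[c for c in cols if c in merged.columns]]


def dual_isotope_diagnosis(data: pd.DataFrame,
                           group_cols: list[str] | None = None,
                           alpha: float = 0.05,
                           method: str = "pearson") -> pd.DataFrame:
    """Classify the d13C/d18O relationship per group.

    A significant positive correlation is labelled ``stomatal-control``
    (both isotopes enriched together points to stomatal closure), a
    significant negative one ``photosynthesis-control``, anything else
    ``indeterminate``. Constant series are indeterminate with a warning
    flag rather than an error.

    Returns a table (group cols, n, r, p, label, warning).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    def _one(grp: pd.DataFrame) -> pd.Series:
        x = grp["d13c_permil"].to_numpy(dtype=float)
        y = grp["d18o_permil"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            return pd.Series({"n": len(x), "r": np.nan, "p": np.nan,
                              "label": "indeterminate",
                              "warning": "fewer than 3 pairs"})
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return pd.Series({"n": len(x), "r": np.nan, "p": np.nan,
                              "label": "indeterminate",
                              "warning": "constant series"})
        r, p = corr(x, y)
        if p < alpha and r > 0:
            label = "stomatal-control"
        elif p < alpha and r < 0:
            label = "photosynthesis-control"
        else:
            label = "indeterminate"
        return pd.Series({"n": len(x), "r": float(r), "p": float(p),
                          "label": label, "warning": ""})

    if group_cols:
        out = (data.groupby(group_cols).apply(_one, include_groups=False)
               .reset_index())
    else:
        out = _one(data).to_frame().T
    out["n"] = out["n"].astype(int)
    return out
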