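"""Predictor preparation and collinearity screening.

Two jobs: (1) turn projected metric coordinates into along-shore / in-offshore
position covariates by rotating about the centroid (default +14°, counter-
clockwise, matching a coastline inclined against the grid) and min-max
normalizing each axis to [0, 1]; (2) variance-inflation-factor screening —
stepwise removal of the highest-VIF variable until all VIFs fall below a
conservative threshold (default 5), followed by pruning of aggregation
families (min/max/median/mean variants of one base quantity) down to a single
surviving representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_VIF_THRESHOLD = 5.0


@dataclass
class ScreenReport:
    """Ordered removal log plus the retained variables and their final VIFs."""

    removed: list[tuple[str, float, str]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed": [
                {"variable": v, "vif": (None if np.isinf(x) else x), "rule": r}
                for v, x, r in self.removed
            ],
            "retained": list(self.retained),
            "final_vifs": {k: (None if np.isinf(v) else v)
                           for k, v in self.final_vifs.items()},
        }


def rotate_and_normalize(coords: np.ndarray, angle_deg: float = 14.0) -> np.ndarray:
    """Rotate (easting, northing) pairs about their centroid and min-max
    normalize each rotated axis to [0, 1].

    Positive angles rotate counter-clockwise.  Pairwise orderings along each
    rotated axis are preserved by the monotone normalization.  A degenerate
    axis (all values identical after rotation) maps to 0 with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points for min-max normalization")
    theta = np.radians(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    centred = coords - coords.mean(axis=0)
    rotated = centred @ rot.T
    out = np.empty_like(rotated)
    for j in range(2):
        lo, hi = rotated[:, j].min(), rotated[:, j].max()
        if hi > lo:
            out[:, j] = (rotated[:, j] - lo) / (hi - lo)
        else:
            warnings.warn(f"axis {j} is constant after rotation; mapped to 0")
            out[:, j] = 0.0
    return out


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R²_j), with R²_j
    from an OLS of column j on all other columns plus an intercept.

    Perfectly collinear columns get ``inf`` (flagged, not an error).
    """
    if table.shape[1] < 2:
        raise ValueError("VIF needs at least two columns")
    if table.shape[0] <= table.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    const = table.columns[table.nunique() <= 1]
    if len(const):
        raise ValueError(f"constant column(s): {list(const)}")
    out = {}
    X = table.to_numpy(dtype=float)
    for j, name in enumerate(table.columns):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def screen_vif(table: pd.DataFrame,
               threshold: float = DEFAULT_VIF_THRESHOLD) -> ScreenReport:
    """Stepwise VIF screening: repeatedly drop the single highest-VIF column
    and recompute, until every VIF is below ``threshold`` (or only one column
    remains).  Ties go to the later column, so the result is deterministic
    given input ordering."""
    report = ScreenReport()
    cols = list(table.columns)
    while len(cols) >= 2:
        vifs = vif(table[cols])
        worst = _argmax_last(vifs)
        # an infinite threshold disables screening entirely
        if np.isinf(threshold) or vifs[worst] < threshold:
            break
        report.removed.append((worst, float(vifs[worst]), f"VIF>{threshold:g}"))
        cols.remove(worst)
    report.retained = cols
    report.final_vifs = dict(vif(table[cols])) if len(cols) >= 2 else {c: 1.0 for c in cols}
    return report


def prune_families(table: pd.DataFrame, families: dict[str, list[str]],
                   report: ScreenReport | None = None) -> ScreenReport:
    """Among surviving variables, keep a single representative per aggregation
    family (e.g., {Max.Chl, Mean.Chl, ...} of the same base quantity) by
    repeatedly dropping the family member with the highest VIF."""
    cols = list(report.retained) if report is not None else list(table.columns)
    out = ScreenReport(removed=list(report.removed) if report is not None else [])
    while True:
        crowded = [
            [m for m in members if m in cols]
            for members in families.values()
        ]
        crowded = [m for m in crowded if len(m) > 1]
        if not crowded or len(cols) < 2:
            break
        vifs = vif(table[cols])
        candidates = [m for fam in crowded for m in fam]
        worst = _argmax_last(vifs[candidates])
        out.removed.append((worst, float(vifs[worst]), "family-pruned"))
        cols.remove(worst)
    out.retained = cols
    out.final_vifs = dict(vif(table[cols])) if len(cols) >= 2 else {c: 1.0 for c in cols}
    return out


def _argmax_last(s: pd.Series) -> str:
    """Index of the maximum; ties resolved to the last occurrence."""
    vmax = s.max()
    return s[s == vmax].index[-1]
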