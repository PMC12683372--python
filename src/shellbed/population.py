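"""Population-size estimators with propagated standard errors.

Three estimators of the total number of individuals in the 0-10 m domain,
in increasing order of model use:

* Method 1 — design-based stratified extrapolation: mean observed density
  (presences and absences) per zone x depth stratum times stratum area,
  with the classical stratified-sampling variance (Cochran).
* Method 2 — occupancy-informed: mean observed density *when present* per
  zone x stratum times the area predicted occupied, the latter averaged over
  the per-bootstrap-iteration cut-off thresholds {t_b}; threshold spread and
  density-mean variance combine by first-order product propagation.
* Method 3 — fully model-based: the bias-corrected count map is summed over
  cells above each t_b, and the mean sum is divided by the mean calibration
  ratio rho (predicted/observed individuals on omitted sites); SEs of both
  means propagate through the ratio.

Biomass converts individuals to tonnes with a species mean individual weight
w (grams) and its SE: B = N w, SE(B)² = N² SE(w)² + w² SE(N)².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seascape import Seascape

logger = logging.getLogger(__name__)

DEPTH_STRATA = [(0.0, 0.5), (0.5, 3.0), (3.0, 6.0), (6.0, 10.0)]
N_ZONES = 5
ZONE_LABELS = "ABCDE"


@dataclass
class ZoneStratification:
    """Zones (equal partitions of coastal position Y) crossed with depth
    strata; per-cell areas come from the masked grid at cell_size²."""

    areas: pd.DataFrame          # index (zone, stratum) -> area m²
    zone_of: np.ndarray          # per-cell zone label ('' off-mask)
    stratum_of: np.ndarray       # per-cell stratum label ('' off-mask)
    cell_area: float
    depth_strata: list[tuple[float, float]] = field(
        default_factory=lambda: list(DEPTH_STRATA))

    @property
    def total_area(self) -> float:
        return float(self.areas["area"].sum())


def stratum_label(depth: float,
                  strata: list[tuple[float, float]] = DEPTH_STRATA) -> str:
    """Half-open depth strata [a, b); the last stratum is closed above."""
    for i, (lo, hi) in enumerate(strata):
        last = i == len(strata) - 1
        if lo <= depth < hi or (last and depth == hi):
            return f"{lo:g}-{hi:g}m"
    return ""


def zone_label(y: float, n_zones: int = N_ZONES) -> str:
    """Equal-width zones along the coastal position Y in [0, 1]."""
    k = min(int(y * n_zones), n_zones - 1)
    return ZONE_LABELS[k]


def build_stratification(seascape: Seascape, n_zones: int = N_ZONES,
                         depth_strata=None) -> ZoneStratification:
    strata = list(depth_strata or DEPTH_STRATA)
    depth = seascape.covariates["depth"]
    Y = seascape.covariates["Y"]
    mask = seascape.mask
    zone_of = np.full(seascape.shape, "", dtype=object)
    stratum_of = np.full(seascape.shape, "", dtype=object)
    it = np.argwhere(mask)
    for r, c in it:
        zone_of[r, c] = zone_label(Y[r, c], n_zones)
        stratum_of[r, c] = stratum_label(depth[r, c], strata)
    rows = []
    for z in ZONE_LABELS[:n_zones]:
        for lo, hi in strata:
            s = f"{lo:g}-{hi:g}m"
            n_cells = int(np.sum((zone_of == z) & (stratum_of == s)))
            rows.append({"zone": z, "stratum": s,
                         "area": n_cells * seascape.cell_area})
    areas = pd.DataFrame(rows).set_index(["zone", "stratum"])
    return ZoneStratification(areas=areas, zone_of=zone_of,
                              stratum_of=stratum_of,
                              cell_area=seascape.cell_area,
                              depth_strata=strata)


@dataclass
class PopulationEstimate:
    method: int
    total: float
    se: float
    breakdown: pd.DataFrame | None = None   # per (zone, stratum), Methods 1-2
    per_iteration: np.ndarray | None = None  # {S_b}, Method 3
    notes: list[str] = field(default_factory=list)


def _assign_strata(survey: pd.DataFrame, strat: ZoneStratification
                   ) -> pd.DataFrame:
    df = survey.copy()
    df["_zone"] = [zone_label(y, len(strat.areas.index.levels[0]))
                   for y in df["Y"]]
    df["_stratum"] = [stratum_label(d, strat.depth_strata) for d in df["depth"]]
    return df[df["_stratum"] != ""]


def method1(survey: pd.DataFrame, strat: ZoneStratification,
            species: str) -> PopulationEstimate:
    """Stratified extrapolation of mean observed density (zeros included).

    Empty (zone, stratum) cells borrow the depth-stratum mean pooled across
    zones; strata with fewer than 2 sites use the pooled stratum variance.
    All borrowings are recorded in ``notes``.
    """
    dens_col = f"density_{species}" if f"density_{species}" in survey else species
    df = _assign_strata(survey, strat)
    notes: list[str] = []
    rows = []
    # pooled per depth stratum across zones (fallbacks)
    pooled_mean = df.groupby("_stratum")[dens_col].mean()
    pooled_var = df.groupby("_stratum")[dens_col].var(ddof=1)
    for (z, s), row in strat.areas.iterrows():
        area = row["area"]
        sub = df[(df["_zone"] == z) & (df["_stratum"] == s)][dens_col]
        n = len(sub)
        if area == 0:
            rows.append({"zone": z, "stratum": s, "area": 0.0, "n": n,
                         "mean_density": 0.0, "var_density": 0.0, "total": 0.0,
                         "var_total": 0.0})
            continue
        if n == 0:
            mean = float(pooled_mean.get(s, 0.0))
            var = float(pooled_var.get(s, 0.0))
            n_eff = max(int((df["_stratum"] == s).sum()), 1)
            notes.append(f"{z}/{s}: no sites; pooled depth-stratum mean used")
            logger.warning("method1: empty stratum %s/%s, pooled mean", z, s)
        else:
            mean = float(sub.mean())
            var = float(sub.var(ddof=1)) if n >= 2 else float(pooled_var.get(s, 0.0))
            n_eff = n if n >= 2 else max(int((df["_stratum"] == s).sum()), 1)
            if n < 2:
                notes.append(f"{z}/{s}: n<2; pooled stratum variance used")
        if not np.isfinite(var):
            var = 0.0
        rows.append({"zone": z, "stratum": s, "area": area, "n": n,
                     "mean_density": mean, "var_density": var,
                     "total": area * mean, "var_total": area**2 * var / n_eff})
    bd = pd.DataFrame(rows).set_index(["zone", "stratum"])
    return PopulationEstimate(method=1, total=float(bd["total"].sum()),
                              se=float(np.sqrt(bd["var_total"].sum())),
                              breakdown=bd, notes=notes)


def _occupied_area_by_cell(strat: ZoneStratification, scores: np.ndarray,
                           thresholds: np.ndarray) -> dict:
    """Occupied area per (zone, stratum) for each threshold."""
    out = {}
    for z, s in strat.areas.index:
        sel = (strat.zone_of == z) & (strat.stratum_of == s)
        cell_scores = scores[sel]
        areas = np.array([np.sum(cell_scores >= t) * strat.cell_area
                          for t in thresholds])
        out[(z, s)] = areas
    return out


def method2(survey: pd.DataFrame, strat: ZoneStratification, species: str,
            score_raster: np.ndarray, thresholds: np.ndarray
            ) -> PopulationEstimate:
    """Presence-site mean densities times predicted occupied area.

    The occupied area in each (zone, stratum) is computed for every bootstrap
    threshold t_b and averaged; its spread and the presence-density variance
    combine by first-order product propagation, summed over strata assuming
    independence.
    """
    dens_col = f"density_{species}" if f"density_{species}" in survey else species
    thresholds = np.asarray(thresholds, float)
    if thresholds.size == 0:
        raise ValueError("need at least one threshold")
    df = _assign_strata(survey, strat)
    pres = df[df[dens_col] > 0]
    pooled_mean = pres.groupby("_stratum")[dens_col].mean()
    pooled_var = pres.groupby("_stratum")[dens_col].var(ddof=1)
    occ = _occupied_area_by_cell(strat, score_raster, thresholds)
    notes: list[str] = []
    rows = []
    for (z, s), row in strat.areas.iterrows():
        areas_b = occ[(z, s)]
        a_mean = float(areas_b.mean())
        a_var = float(areas_b.var(ddof=1)) if thresholds.size > 1 else 0.0
        sub = pres[(pres["_zone"] == z) & (pres["_stratum"] == s)][dens_col]
        n = len(sub)
        if n == 0:
            if s in pooled_mean.index and np.isfinite(pooled_mean[s]):
                d = float(pooled_mean[s])
                dv = float(pooled_var.get(s, 0.0))
                nd = max(int((pres["_stratum"] == s).sum()), 1)
                notes.append(f"{z}/{s}: no presence sites; pooled mean used")
            else:
                d, dv, nd = 0.0, 0.0, 1
                notes.append(f"{z}/{s}: no presence sites anywhere; contributes 0")
        else:
            d = float(sub.mean())
            dv = float(sub.var(ddof=1)) if n >= 2 else float(pooled_var.get(s, 0.0))
            nd = n if n >= 2 else max(int((pres["_stratum"] == s).sum()), 1)
        if not np.isfinite(dv):
            dv = 0.0
        var_mean_d = dv / nd
        total = a_mean * d
        var_total = a_mean**2 * var_mean_d + d**2 * a_var
        rows.append({"zone": z, "stratum": s, "occupied_area": a_mean,
                     "var_area": a_var, "mean_density_present": d, "n_present": n,
                     "total": total, "var_total": var_total})
    bd = pd.DataFrame(rows).set_index(["zone", "stratum"])
    return PopulationEstimate(method=2, total=float(bd["total"].sum()),
                              se=float(np.sqrt(bd["var_total"].sum())),
                              breakdown=bd, notes=notes)


def method3(count_raster: np.ndarray, score_raster: np.ndarray,
            thresholds: np.ndarray, rho: np.ndarray,
            mask: np.ndarray | None = None) -> PopulationEstimate:
    """Model-based total: threshold-delimited count-map sums calibrated by
    the mean predicted/observed ratio.

    N = mean_b(S_b) / mean_b(rho_b) with S_b the count-map sum over cells
    scoring >= t_b.  The bootstrap spreads of {S_b} and {rho_b} estimate the
    sampling SEs of the two statistics (iterations re-use the same survey, so
    the spread itself -- not the spread / sqrt(B) -- is the uncertainty) and
    propagate through the ratio to first order.
    """
    counts = np.asarray(count_raster, float)
    scores = np.asarray(score_raster, float)
    if counts.shape != scores.shape:
        raise ValueError("count and score rasters are misaligned")
    if mask is not None:
        counts = np.where(mask, counts, 0.0)
        scores = np.where(mask, scores, -np.inf)
    thresholds = np.asarray(thresholds, float)
    rho = np.asarray(rho, float)
    rho_ok = rho[np.isfinite(rho)]
    if rho_ok.size == 0:
        raise ValueError("all calibration ratios are undefined")
    S = np.array([np.nansum(np.where(scores >= t, counts, 0.0))
                  for t in thresholds])
    S_mean = float(S.mean())
    rho_mean = float(rho_ok.mean())
    se_S = float(S.std(ddof=1)) if S.size > 1 else 0.0
    se_rho = float(rho_ok.std(ddof=1)) if rho_ok.size > 1 else 0.0
    total = S_mean / rho_mean
    var = (se_S / rho_mean) ** 2 + (S_mean * se_rho / rho_mean**2) ** 2
    return PopulationEstimate(method=3, total=total, se=float(np.sqrt(var)),
                              per_iteration=S)


def biomass(estimate: PopulationEstimate, mean_weight_g: float,
            se_weight_g: float = 0.0) -> tuple[float, float]:
    """Convert an abundance estimate to tonnes via a mean individual weight
    (grams): B = N w / 1e6, SE(B)² = N² SE(w)² + w² SE(N)² (then g -> t)."""
    if mean_weight_g <= 0:
        raise ValueError("mean individual weight must be positive")
    n_hat, se_n = estimate.total, estimate.se
    b_g = n_hat * mean_weight_g
    se_g = np.sqrt(n_hat**2 * se_weight_g**2 + mean_weight_g**2 * se_n**2)
    return float(b_g / 1e6), float(se_g / 1e6)
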