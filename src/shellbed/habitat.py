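"""Post-prediction ecological summaries.

Given the predicted presence and density maps, these helpers tabulate where
the species live: occupancy and abundance by 0.5 m depth bin and exposure
class (sheltered < 10⁴, exposed otherwise), species co-occurrence percentages
over the masked grid, central depth ranges (the shortest contiguous run of
bins holding a given share of predicted abundance), and variable importance /
partial dependence of the fitted models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .seascape import MAX_DEPTH, Seascape

EXPOSURE_SPLIT = 1e4
DEPTH_BIN = 0.5


def subsample_cells(seascape: Seascape, layers: dict[str, np.ndarray],
                    n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Uniform without-replacement sample of masked cells with covariates and
    prediction layers attached.  If n exceeds the mask size the whole mask is
    returned with a warning."""
    mask = seascape.mask
    idx = np.flatnonzero(mask)
    if n >= idx.size:
        if n > idx.size:
            warnings.warn(f"requested {n} cells but mask has {idx.size}; using all")
        chosen = idx
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(idx, size=n, replace=False)
    rr, cc = np.unravel_index(chosen, seascape.shape)
    data = {"row": rr, "col": cc}
    for name, band in seascape.covariates.items():
        data[name] = band[rr, cc]
    for name, band in layers.items():
        if band.shape != seascape.shape:
            raise ValueError(f"layer {name!r} misaligned with the seascape")
        data[name] = band[rr, cc]
    return pd.DataFrame(data)


def _depth_bins() -> np.ndarray:
    return np.arange(0.0, MAX_DEPTH + DEPTH_BIN, DEPTH_BIN)


def stratify(cells: pd.DataFrame, species: list[str],
             exposure_split: float = EXPOSURE_SPLIT) -> pd.DataFrame:
    """Occupancy and abundance summary per depth bin x exposure class.

    Expects per-species columns ``presence_<sp>`` (0/1) and ``density_<sp>``.
    Returns available cell counts, occupied proportion, mean density, and the
    share of each species' total abundance per bin; shares sum to 1 over all
    bins x classes.  Empty bins show NaN proportions.
    """
    edges = _depth_bins()
    df = cells.copy()
    df["depth_bin"] = pd.cut(df["depth"], edges, right=False,
                             include_lowest=True)
    df.loc[df["depth"] == MAX_DEPTH, "depth_bin"] = df["depth_bin"].cat.categories[-1]
    df["exposure_class"] = np.where(df["exposure"] < exposure_split,
                                    "sheltered", "exposed")
    rows = []
    totals = {sp: df[f"density_{sp}"].sum() for sp in species}
    grouped = df.groupby(["depth_bin", "exposure_class"], observed=False)
    for (b, e), sub in grouped:
        rec = {"depth_bin": b, "exposure_class": e, "available": len(sub)}
        for sp in species:
            if len(sub) == 0:
                rec[f"occupancy_{sp}"] = np.nan
                rec[f"mean_density_{sp}"] = np.nan
                rec[f"share_{sp}"] = 0.0
            else:
                rec[f"occupancy_{sp}"] = float(sub[f"presence_{sp}"].mean())
                rec[f"mean_density_{sp}"] = float(sub[f"density_{sp}"].mean())
                rec[f"share_{sp}"] = (float(sub[f"density_{sp}"].sum() / totals[sp])
                                      if totals[sp] > 0 else 0.0)
        rows.append(rec)
    return pd.DataFrame(rows)


def overlap_table(layers: dict[str, np.ndarray],
                  mask: np.ndarray) -> pd.DataFrame:
    """Percentages of masked cells in every presence combination of the given
    binary layers, plus per-species total occupancy T and percent-alone.

    The combination percentages sum to 100 exactly (they partition the mask).
    """
    names = list(layers)
    for name, lay in layers.items():
        if lay.shape != mask.shape:
            raise ValueError(f"layer {name!r} misaligned with the mask")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("empty mask")
    stack = np.stack([np.asarray(layers[k], bool)[mask] for k in names])
    # combination id: bit i set iff species i present
    combo_id = np.zeros(n_mask, dtype=int)
    for i in range(len(names)):
        combo_id |= stack[i].astype(int) << i
    rows = []
    for cid in range(2 ** len(names)):
        members = [names[i] for i in range(len(names)) if cid >> i & 1]
        pct = 100.0 * np.sum(combo_id == cid) / n_mask
        rows.append({"combination": "+".join(members) if members else "none",
                     "percent": float(pct), "_id": cid})
    tab = pd.DataFrame(rows)
    summary = {}
    for i, name in enumerate(names):
        t = float(tab.loc[[cid >> i & 1 == 1 for cid in tab["_id"]], "percent"].sum())
        alone = float(tab.loc[tab["_id"] == (1 << i), "percent"].iloc[0])
        summary[name] = {"T": t, "alone_pct_of_occupied": 100.0 * alone / t if t > 0 else np.nan}
    tab.attrs["species_summary"] = summary
    return tab.drop(columns="_id")


def central_range(shares: pd.Series, mass: float = 0.80) -> tuple[float, float]:
    """Shortest contiguous run of depth bins containing at least ``mass`` of
    the predicted abundance; ties break toward the shallower start.

    ``shares`` is indexed by bin lower edge (metres) in increasing order and
    sums to 1.
    """
    if not 0.0 < mass <= 1.0:
        raise ValueError("mass must be in (0, 1]")
    v = shares.to_numpy(dtype=float)
    edges = shares.index.to_numpy(dtype=float)
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise ValueError("shares must sum to 1")
    n = v.size
    best = None  # (length, start_idx, end_idx)
    for i in range(n):
        acc = 0.0
        for j in range(i, n):
            acc += v[j]
            if acc >= mass - 1e-12:
                length = j - i + 1
                if best is None or length < best[0]:
                    best = (length, i, j)
                break
    if best is None:
        best = (n, 0, n - 1)
    _, i, j = best
    width = edges[1] - edges[0] if n > 1 else DEPTH_BIN
    return float(edges[i]), float(edges[j] + width)


def importance_and_partials(model, data: pd.DataFrame, covariates: list[str],
                            y: np.ndarray | None = None,
                            grid_resolution: int = 20,
                            ) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Variable importance scaled to max 100 plus partial dependence curves.

    Uses the learner's internal impurity importance when exposed; otherwise
    permutation importance against the supplied response ``y``.  Partial
    dependence at a grid value g is the mean prediction over the data with
    the focal variable fixed at g.
    """
    X = data[covariates]
    if hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    elif y is not None:
        from sklearn.inspection import permutation_importance
        r = permutation_importance(model, X.to_numpy(float), np.asarray(y),
                                   n_repeats=5, random_state=0)
        imp = np.maximum(r.importances_mean, 0.0)
    else:
        raise ValueError("model exposes no internal importance; pass y for "
                         "permutation importance")
    top = imp.max()
    scaled = pd.Series(100.0 * imp / top if top > 0 else imp, index=covariates)

    predict = (lambda A: model.predict_proba(A)[:, 1]) \
        if hasattr(model, "predict_proba") else model.predict
    partials = {}
    base = X.to_numpy(dtype=float)
    for j, name in enumerate(covariates):
        lo, hi = X[name].min(), X[name].max()
        grid = np.linspace(lo, hi, grid_resolution) if hi > lo else np.array([lo])
        means = np.empty(grid.size)
        work = base.copy()
        for g_i, g in enumerate(grid):
            work[:, j] = g
            means[g_i] = float(np.mean(predict(work)))
        partials[name] = pd.DataFrame({name: grid, "partial_dependence": means})
    return scaled, partials
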