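"""Bootstrap 0.632+ model validation engine.

Models are refit on B bootstrap samples (size n, with replacement) and scored
both on their own sample ("apparent", per-iteration) and on the omitted
out-of-bag sites.  The 0.632+ estimator then blends the full-data apparent
value with the mean out-of-bag value, weighting by the relative overfitting
rate against a no-information rate gamma:

    R = (oob' - apparent) / (gamma - apparent)   clipped to [0, 1]
    w = 0.632 / (1 - 0.368 R)
    best = (1 - w) * apparent + w * oob'         (oob' = gamma-capped OOB)

All arithmetic runs on a loss scale; gain metrics (AUC, accuracy, ...) are
converted via 1 - value and converted back.  The engine is model-agnostic: a
fitter is any callable (train_frame, random_state) -> (predict_fn, aux_dict),
and whatever auxiliary parameters it returns (cut-off thresholds, calibration
ratios, correction coefficients) are collected per iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import metrics as _m

logger = logging.getLogger(__name__)

PredictFn = Callable[[pd.DataFrame], np.ndarray]
Fitter = Callable[[pd.DataFrame, int], tuple[PredictFn, dict]]


@dataclass
class MetricDef:
    """A named metric with its orientation and no-information rule.

    ``func(obs, pred, aux)`` returns the metric (NaN when undefined for the
    data at hand).  ``noinfo`` is either an analytic constant on the metric's
    own scale or a callable ``(obs, pred) -> gamma``.
    """

    name: str
    func: Callable[[np.ndarray, np.ndarray, dict], float]
    orientation: str  # "gain" (larger better) or "loss" (smaller better)
    noinfo: float | Callable[[np.ndarray, np.ndarray], float]

    def __post_init__(self) -> None:
        if self.orientation not in ("gain", "loss"):
            raise ValueError("orientation must be 'gain' or 'loss'")


@dataclass
class BootResult:
    """Raw per-iteration bootstrap records."""

    indices: list[np.ndarray]
    apparent: pd.DataFrame          # B x metrics, each model on its own sample
    oob: pd.DataFrame               # B x metrics, each model on omitted sites
    aux: list[dict]                 # per-iteration auxiliary parameters
    gamma: dict[str, float]         # per-metric no-information rate
    oob_sizes: np.ndarray
    n_missing: dict[str, int] = field(default_factory=dict)
    oob_mean_prediction: np.ndarray | None = None  # per-site averaged OOB preds


@dataclass
class PerfReport:
    """Per-metric apparent / out-of-bag / 0.632+ best-estimate summary."""

    table: pd.DataFrame  # rows: metrics; cols: apparent, oob_mean, best, ...

    def to_dict(self) -> dict:
        return {k: {m: (None if pd.isna(v) else float(v)) for m, v in row.items()}
                for k, row in self.table.to_dict(orient="index").items()}


def no_information(observed, predictions, metric: MetricDef,
                   aux: dict | None = None) -> float:
    """No-information rate gamma for a metric: the analytic constant if the
    metric declares one, otherwise the declared rule evaluated on the
    full-data observations and predictions."""
    if callable(metric.noinfo):
        return float(metric.noinfo(np.asarray(observed), np.asarray(predictions)))
    return float(metric.noinfo)


def binary_noinfo(loss: bool = True) -> Callable:
    """Misclassification no-information rule gamma = p(1-q) + (1-p)q, with p
    the observed and q the predicted positive rate.  With ``loss=False`` the
    accuracy-scale complement 1 - gamma is returned."""
    def rule(obs, pred):
        p = float(np.mean(np.asarray(obs) == 1))
        q = float(np.mean(np.asarray(pred) == 1))
        g = p * (1 - q) + (1 - p) * q
        return g if loss else 1.0 - g
    return rule


def allpairs_noinfo(loss_func: Callable[[np.ndarray, np.ndarray], float],
                    max_pairs: int = 4_000_000) -> Callable:
    """No-information rule for a continuous loss: the loss evaluated over all
    observation-prediction pairings (subsampled above ``max_pairs``)."""
    def rule(obs, pred):
        obs = np.asarray(obs, float)
        pred = np.asarray(pred, float)
        n = obs.size
        if n * n <= max_pairs:
            oo = np.repeat(obs, n)
            pp = np.tile(pred, n)
        else:  # pragma: no cover - large-n fallback
            rng = np.random.default_rng(0)
            oo = rng.choice(obs, size=max_pairs)
            pp = rng.choice(pred, size=max_pairs)
        return float(loss_func(oo, pp))
    return rule


def err632plus(apparent: float, oob: float, gamma: float,
               orientation: str = "loss") -> float:
    """The 0.632+ best estimate from a full-data apparent value, a mean
    out-of-bag value and a no-information rate, all on the same scale."""
    if orientation == "gain":
        return 1.0 - err632plus(1.0 - apparent, 1.0 - oob, 1.0 - gamma, "loss")
    if not all(np.isfinite([apparent, oob, gamma])):
        return np.nan
    oob_c = min(oob, gamma)
    if gamma <= apparent:
        # no headroom between apparent and chance: maximal-overfit convention
        # only when the OOB value is actually worse than the apparent one
        r = 1.0 if (gamma == apparent and oob > apparent) else 0.0
        if r == 1.0:
            logger.info("err632plus: gamma == apparent with oob > apparent; R set to 1")
    else:
        r = np.clip((oob_c - apparent) / (gamma - apparent), 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    return float((1.0 - w) * apparent + w * oob_c)


def _eval_metrics(mdefs, obs, pred, aux) -> dict[str, float]:
    return {m.name: float(m.func(np.asarray(obs), np.asarray(pred), aux))
            for m in mdefs}


def bootstrap_fit(data: pd.DataFrame, fitter: Fitter, response: str,
                  mdefs: list[MetricDef], B: int = 100, seed: int = 0,
                  collect_oob_predictions: bool = False,
                  ) -> tuple[BootResult, PerfReport]:
    """Run the 0.632+ engine for one model stage.

    The fitter is called once on the full data (its apparent performance
    anchors the estimator) and once per bootstrap sample.  Iterations whose
    out-of-bag set leaves a metric undefined (e.g., a missing class) are
    excluded from that metric's mean with a logged count.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(data)
    rng = np.random.default_rng(seed)
    y = data[response].to_numpy()

    predict_full, aux_full = fitter(data, int(rng.integers(2**31)))
    pred_full = np.asarray(predict_full(data))
    apparent_full = _eval_metrics(mdefs, y, pred_full, aux_full)
    gamma = {m.name: no_information(y, pred_full, m) for m in mdefs}

    idx_all = np.arange(n)
    records_app, records_oob, auxes, indices = [], [], [], []
    oob_sizes = np.empty(B, dtype=int)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=int)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        oob_idx = np.setdiff1d(idx_all, idx)
        oob_sizes[b] = oob_idx.size
        train = data.iloc[idx]
        predict_b, aux_b = fitter(train, int(rng.integers(2**31)))
        auxes.append(aux_b)
        indices.append(idx)
        records_app.append(_eval_metrics(mdefs, y[idx], predict_b(train), aux_b))
        if oob_idx.size:
            oob_frame = data.iloc[oob_idx]
            pred_oob = np.asarray(predict_b(oob_frame))
            records_oob.append(_eval_metrics(mdefs, y[oob_idx], pred_oob, aux_b))
            if collect_oob_predictions:
                oob_sum[oob_idx] += pred_oob
                oob_cnt[oob_idx] += 1
        else:  # pragma: no cover - vanishingly rare
            records_oob.append({m.name: np.nan for m in mdefs})

    app_df = pd.DataFrame(records_app)
    oob_df = pd.DataFrame(records_oob)
    n_missing = {m.name: int(oob_df[m.name].isna().sum()) for m in mdefs}
    for name, k in n_missing.items():
        if k:
            logger.info("metric %s undefined on %d/%d OOB sets", name, k, B)

    oob_mean_pred = None
    if collect_oob_predictions:
        with np.errstate(invalid="ignore"):
            oob_mean_pred = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)

    boot = BootResult(indices=indices, apparent=app_df, oob=oob_df, aux=auxes,
                      gamma=gamma, oob_sizes=oob_sizes, n_missing=n_missing,
                      oob_mean_prediction=oob_mean_pred)

    rows = {}
    for m in mdefs:
        oob_vals = oob_df[m.name].dropna()
        oob_mean = float(oob_vals.mean()) if len(oob_vals) else np.nan
        best = err632plus(apparent_full[m.name], oob_mean, gamma[m.name],
                          m.orientation)
        rows[m.name] = {
            "apparent": apparent_full[m.name],
            "apparent_iter_mean": float(app_df[m.name].mean()),
            "oob_mean": oob_mean,
            "oob_sd": float(oob_vals.std(ddof=1)) if len(oob_vals) > 1 else np.nan,
            "oob_q025": float(oob_vals.quantile(0.025)) if len(oob_vals) else np.nan,
            "oob_q975": float(oob_vals.quantile(0.975)) if len(oob_vals) else np.nan,
            "gamma": gamma[m.name],
            "best": best,
        }
    return boot, PerfReport(table=pd.DataFrame(rows).T)


# ---------------------------------------------------------------------------
# stock metric sets
# ---------------------------------------------------------------------------

def _thresholded(stat: str):
    """Confusion-matrix metric on scores, using the iteration's own fitted
    cut-off threshold (aux['threshold'])."""
    def func(obs, pred, aux):
        t = (aux or {}).get("threshold", 0.5)
        return _m.confusion_metrics(obs, np.asarray(pred) >= t)[stat]
    return func


def occurrence_metric_set() -> list[MetricDef]:
    """AUC plus thresholded sensitivity / specificity / accuracy / TSS."""
    def q_rule(stat):
        # permutation expectation of each confusion metric given the predicted
        # positive rate; with a prevalence-matched threshold that rate equals
        # the observed prevalence, so gamma is taken from the observed labels
        def rule(obs, pred):
            q = float(np.mean(np.asarray(obs) == 1))
            return {"sensitivity": q, "specificity": 1 - q}[stat]
        return rule

    return [
        MetricDef("AUC", lambda o, p, a: _m.auc(o, p), "gain", 0.5),
        MetricDef("sensitivity", _thresholded("sensitivity"), "gain",
                  q_rule("sensitivity")),
        MetricDef("specificity", _thresholded("specificity"), "gain",
                  q_rule("specificity")),
        MetricDef("accuracy", _thresholded("accuracy"), "gain",
                  binary_noinfo(loss=False)),
        MetricDef("TSS", _thresholded("TSS"), "gain", 0.0),
    ]


def abundance_metric_set() -> list[MetricDef]:
    """Untransformed-scale regression metrics (Spearman rho, Pearson r, R²,
    RMSE) for density predictions."""
    def reg(stat):
        return lambda o, p, a: _m.regression_metrics(o, p)[stat]

    rmse_pairs = allpairs_noinfo(lambda o, p: float(np.sqrt(np.mean((o - p) ** 2))))
    return [
        MetricDef("spearman_rho", reg("spearman_rho"), "gain", 0.0),
        MetricDef("pearson_r", reg("pearson_r"), "gain", 0.0),
        MetricDef("R2", reg("R2"), "gain", 0.0),
        MetricDef("RMSE", reg("RMSE"), "loss", rmse_pairs),
    ]
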