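"""Performance metrics for occurrence and abundance models.

Binary metrics follow the usual confusion-matrix definitions (sensitivity,
specificity, accuracy, TSS = sens + spec - 1); AUC is computed by the
Mann-Whitney pair formulation with ties counted one half.  Regression metrics
report Pearson r, Spearman rho, R² (squared Pearson r) and RMSE.  Metrics that
are undefined for the data at hand (a missing class, a constant vector) come
back as NaN rather than raising, so the bootstrap engine can flag-and-skip.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def confusion_metrics(observed, predicted) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and TSS from two binary vectors.

    Metrics whose denominator class is absent are NaN.
    """
    obs = np.asarray(observed).astype(int)
    pred = np.asarray(predicted).astype(int)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    tp = int(np.sum((obs == 1) & (pred == 1)))
    fn = int(np.sum((obs == 1) & (pred == 0)))
    tn = int(np.sum((obs == 0) & (pred == 0)))
    fp = int(np.sum((obs == 0) & (pred == 1)))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    acc = (tp + tn) / obs.size
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "TSS": sens + spec - 1.0}


def auc(observed, scores) -> float:
    """Mann-Whitney AUC: the fraction of (positive, negative) pairs ranked
    correctly, ties counting 0.5.  NaN if only one class is present."""
    obs = np.asarray(observed).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(obs == 1))
    n_neg = obs.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = stats.rankdata(s)  # average ranks handle ties
    u = ranks[obs == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def regression_metrics(observed, predicted) -> dict[str, float]:
    """Pearson r, Spearman rho, R² (= r²) and RMSE."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("need at least 3 pairs")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return {"pearson_r": np.nan, "spearman_rho": np.nan,
                "R2": np.nan, "RMSE": rmse}
    r = float(stats.pearsonr(obs, pred).statistic)
    rho = float(stats.spearmanr(obs, pred).statistic)
    return {"pearson_r": r, "spearman_rho": rho, "R2": r * r, "RMSE": rmse}
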