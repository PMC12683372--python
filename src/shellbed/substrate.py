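"""Zero-one-inflated proportional substrate cover models.

Visually estimated covers of hard rock (P_HARD) and soft mud (P_SOFT) live on
[0, 1] with heavy point masses at both ends, so the response is decomposed
into three parts: P(cover = 0), P(cover = 1 | cover > 0), and the interior
mean on (0, 1) fitted on the logit scale.  Each part is a boosted-tree
component (learning rate 0.05 by default, stopping iteration chosen by
internal validation-set early stopping), and the expected cover is the
mixture

    E[cover] = p1 + (1 - p0 - p1) * mu .

Only physical covariates (depth, slope, exposure, position, SAV analog) are
offered to these models; the predicted covers then feed the occurrence and
abundance stages as covariates in their own right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor

from .metrics import regression_metrics

logger = logging.getLogger(__name__)

#: covariates of a physical nature offered to the substrate models
PHYSICAL_COVARIATES = ["depth", "slope", "exposure", "X", "Y", "SAV"]


@dataclass
class SubstrateConfig:
    learning_rate: float = 0.05
    max_iterations: int = 2000
    max_depth: int = 3
    early_stopping_rounds: int = 20
    validation_fraction: float = 0.2
    random_state: int = 0


class _ConstantModel:
    """Fallback component when a class or the interior is degenerate."""

    def __init__(self, value: float):
        self.value = float(value)

    def predict_proba(self, X):
        p1 = np.full(len(X), self.value)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return np.full(len(X), self.value)


def _fit_classifier(X, y, cfg: SubstrateConfig):
    if len(np.unique(y)) < 2:
        return _ConstantModel(float(np.mean(y))), 0
    model = GradientBoostingClassifier(
        learning_rate=cfg.learning_rate, n_estimators=cfg.max_iterations,
        max_depth=cfg.max_depth, n_iter_no_change=cfg.early_stopping_rounds,
        validation_fraction=cfg.validation_fraction, random_state=cfg.random_state,
    )
    model.fit(X, y)
    return model, model.n_estimators_


def _fit_regressor(X, y, cfg: SubstrateConfig):
    if np.ptp(y) == 0 or len(y) < 10:
        return _ConstantModel(float(np.mean(y))), 0
    model = GradientBoostingRegressor(
        learning_rate=cfg.learning_rate, n_estimators=cfg.max_iterations,
        max_depth=cfg.max_depth, n_iter_no_change=cfg.early_stopping_rounds,
        validation_fraction=cfg.validation_fraction, random_state=cfg.random_state,
    )
    model.fit(X, y)
    return model, model.n_estimators_


@dataclass
class ZOIBFit:
    """Fitted three-part cover model."""

    covariates: list[str]
    model_zero: object          # P(cover = 0)
    model_one: object           # P(cover = 1 | cover > 0)
    model_interior: object      # logit-scale interior mean
    m_stop: dict[str, int] = field(default_factory=dict)
    train_ranges: pd.DataFrame | None = None

    def predict_components(self, grid: pd.DataFrame) -> pd.DataFrame:
        """Per-cell p0, p1, interior mean mu, expected cover, and an
        extrapolation flag for cells outside the training hull."""
        X = grid[self.covariates].to_numpy(dtype=float)
        p0 = self.model_zero.predict_proba(X)[:, 1]
        p1_cond = self.model_one.predict_proba(X)[:, 1]
        p1 = (1.0 - p0) * p1_cond  # unconditional mass at full cover
        mu = expit(self.model_interior.predict(X))
        expected = p1 + (1.0 - p0 - p1) * mu
        out = pd.DataFrame({
            "p0": p0, "p1": p1, "mu": mu,
            "expected_cover": np.clip(expected, 0.0, 1.0),
        }, index=grid.index)
        if self.train_ranges is not None:
            lo = self.train_ranges.loc["min"].to_numpy()
            hi = self.train_ranges.loc["max"].to_numpy()
            out["extrapolated"] = ((X < lo) | (X > hi)).any(axis=1)
        return out


def fit_substrate(survey: pd.DataFrame, response: str,
                  covariates: list[str] | None = None,
                  config: SubstrateConfig | None = None) -> ZOIBFit:
    """Fit the three-part cover model to observed covers in [0, 1].

    The mass-at-one component is fitted conditionally on cover > 0, so the
    predicted masses always satisfy p0 + p1 <= 1.  With no interior
    observations the interior component degenerates to the midpoint and
    predictions fall back on the two point masses (logged).
    """
    cfg = config or SubstrateConfig()
    covs = covariates or [c for c in PHYSICAL_COVARIATES if c in survey.columns]
    y = survey[response].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("covers must lie in [0, 1]")
    X = survey[covs].to_numpy(dtype=float)

    is_zero = (y == 0).astype(int)
    model_zero, m0 = _fit_classifier(X, is_zero, cfg)
    pos = y > 0
    if pos.sum() > 0:
        model_one, m1 = _fit_classifier(X[pos], (y[pos] == 1).astype(int), cfg)
    else:
        model_one, m1 = _ConstantModel(0.0), 0
    interior = (y > 0) & (y < 1)
    if interior.sum() > 0:
        eps = 1e-6
        z = logit(np.clip(y[interior], eps, 1 - eps))
        model_interior, mi = _fit_regressor(X[interior], z, cfg)
    else:
        logger.warning("no interior cover observations; interior mean fixed at 0.5")
        model_interior, mi = _ConstantModel(0.0), 0
    ranges = pd.DataFrame(
        {c: [survey[c].min(), survey[c].max()] for c in covs}, index=["min", "max"]
    )
    return ZOIBFit(covariates=covs, model_zero=model_zero, model_one=model_one,
                   model_interior=model_interior,
                   m_stop={"zero": m0, "one": m1, "interior": mi},
                   train_ranges=ranges)


def predict_cover(fit: ZOIBFit, grid: pd.DataFrame) -> pd.DataFrame:
    """Expected cover and component probabilities on a covariate table."""
    return fit.predict_components(grid)


def substrate_metrics(fit: ZOIBFit, sites: pd.DataFrame,
                      response: str) -> dict[str, float]:
    """R² between predicted expected cover and observed cover, plus the
    accuracies of calling the 0% and 100% point masses at p >= 0.5."""
    if len(sites) == 0:
        raise ValueError("evaluation set is empty")
    comp = fit.predict_components(sites)
    y = sites[response].to_numpy(dtype=float)
    reg = regression_metrics(y, comp["expected_cover"].to_numpy()) if len(y) >= 3 \
        else {"R2": np.nan}
    zero_obs = (y == 0)
    one_obs = (y == 1)
    # undefined when the point-mass class never occurs in the evaluation set
    acc0 = float(np.mean((comp["p0"] >= 0.5) == zero_obs)) if zero_obs.any() else np.nan
    acc1 = float(np.mean((comp["p1"] >= 0.5) == one_obs)) if one_obs.any() else np.nan
    return {"R2": reg["R2"], "zero_acc": acc0, "one_acc": acc1}
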