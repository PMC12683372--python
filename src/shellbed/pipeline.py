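"""End-to-end orchestration: screen -> substrate -> occurrence -> abundance
-> population estimates -> habitat summaries.

`run_pipeline` takes a seascape + survey (real or simulated), runs every
stage in order with all randomness derived from a single seed, and returns a
report bundle (also serializable to JSON/CSV).  Two runs from the same
config produce identical numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as _ab
from . import habitat as _hab
from . import occurrence as _occ
from . import population as _pop
from . import predictors as _pred
from . import substrate as _sub
from .seascape import Seascape

logger = logging.getLogger(__name__)

#: model covariates offered after screening (P_HARD/P_SOFT are replaced by
#: the substrate-model predictions when those models are run)
DEFAULT_COVARIATES = ["depth", "exposure", "X", "Y", "slope", "P_HARD",
                      "P_SOFT", "SAV", "Max.Chl", "Min.Sal", "Max.SPM",
                      "Med.Temp"]


@dataclass
class RunConfig:
    species: list[str]
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    B: int = 100
    cv_k: int = 10
    cv_repeats: int = 10
    seed: int = 0
    tune: bool = False
    occurrence_grid: dict = field(default_factory=lambda: {
        "learning_rate": [0.1], "n_estimators": [150], "min_samples_leaf": [10]})
    abundance_grid: dict = field(default_factory=lambda: {
        "learning_rate": [0.1], "n_estimators": [150], "min_samples_leaf": [10]})
    vif_threshold: float = 5.0
    fit_substrate: bool = False
    n_zones: int = 5
    subsample_n: int = 10_000
    # mean individual weights in grams (dry, wet) with SEs, per species
    weights: dict = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        # weight entries arrive as 2-element lists from YAML
        for sp, w in (raw.get("weights") or {}).items():
            raw["weights"][sp] = {k: tuple(v) for k, v in w.items()}
        return cls(**raw)


@dataclass
class SpeciesResult:
    occurrence: _occ.OccurrenceFit
    abundance: _ab.AbundanceFit | None
    score_raster: np.ndarray
    presence_raster: np.ndarray
    density_raster: np.ndarray | None
    count_raster: np.ndarray | None
    estimates: dict[int, _pop.PopulationEstimate]
    biomass: dict[str, tuple[float, float]]


@dataclass
class ReportBundle:
    config: RunConfig
    screen: _pred.ScreenReport
    substrate: dict
    species: dict[str, SpeciesResult]
    stratification: _pop.ZoneStratification
    habitat: pd.DataFrame | None
    overlap: pd.DataFrame | None

    def summary(self) -> dict:
        from . import __version__
        out = {
            "run": {"seed": self.config.seed, "B": self.config.B,
                    "shellbed_version": __version__},
            "covariates_retained": self.screen.retained,
            "species": {},
        }
        for sp, res in self.species.items():
            d = {
                "performance": res.occurrence.report.to_dict(),
                "mean_threshold": res.occurrence.mean_threshold,
                "estimates": {
                    f"method{m}": {"total": e.total, "se": e.se}
                    for m, e in res.estimates.items()},
                "biomass_t": {k: {"total": v[0], "se": v[1]}
                              for k, v in res.biomass.items()},
            }
            if res.abundance is not None:
                d["abundance_performance"] = res.abundance.report.to_dict()
                d["corrections"] = {"a": res.abundance.a, "b": res.abundance.b,
                                    "D": res.abundance.D}
            out["species"][sp] = d
        return out

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.summary(), indent=2,
                                                    default=float))
        (out / "screen.json").write_text(json.dumps(self.screen.to_dict(), indent=2))
        if self.habitat is not None:
            self.habitat.to_csv(out / "habitat_summary.csv", index=False)
        if self.overlap is not None:
            self.overlap.to_csv(out / "overlap_table.csv", index=False)
        for sp, res in self.species.items():
            np.savez_compressed(out / f"rasters_{sp}.npz",
                                score=res.score_raster,
                                presence=res.presence_raster,
                                **({"density": res.density_raster,
                                    "count": res.count_raster}
                                   if res.density_raster is not None else {}))


def run_pipeline(seascape: Seascape, survey: pd.DataFrame,
                 config: RunConfig) -> ReportBundle:
    """Execute the full analysis on one seascape + survey."""
    rng = np.random.default_rng(config.seed)
    mask = seascape.mask
    grid_table = seascape.table(mask_only=True)

    # --- predictor screening ------------------------------------------------
    covs = [c for c in config.covariates if c in survey.columns]
    screen = _pred.screen_vif(survey[covs], threshold=config.vif_threshold)
    covariates = screen.retained
    logger.info("screening retained %d/%d covariates", len(covariates), len(covs))

    # --- substrate cover models --------------------------------------------
    substrate_out: dict = {}
    if config.fit_substrate:
        sub_survey = survey.dropna(subset=["cover_hard", "cover_soft"])
        for response, name in (("cover_hard", "P_HARD"), ("cover_soft", "P_SOFT")):
            fit = _sub.fit_substrate(
                sub_survey, response,
                config=_sub.SubstrateConfig(random_state=int(rng.integers(2**31))))
            pred = _sub.predict_cover(fit, grid_table)
            band = np.zeros(seascape.shape)
            band[grid_table["row"], grid_table["col"]] = pred["expected_cover"]
            substrate_out[name] = {
                "fit": fit,
                "metrics": _sub.substrate_metrics(fit, sub_survey, response),
                "raster": band,
            }
            # predicted covers replace the raw bands for downstream models
            grid_table[name] = pred["expected_cover"].to_numpy()

    strat = _pop.build_stratification(seascape, n_zones=config.n_zones)

    # --- per-species occurrence, abundance, population ----------------------
    species_results: dict[str, SpeciesResult] = {}
    layers_presence: dict[str, np.ndarray] = {}
    cell_layers: dict[str, np.ndarray] = {}
    for sp in config.species:
        occ_cfg = _occ.OccurrenceConfig(
            grid=config.occurrence_grid,
            cv=_occ.CVSpec(k=config.cv_k, repeats=config.cv_repeats,
                           seed=int(rng.integers(2**31))),
            tune=config.tune, B=config.B, seed=int(rng.integers(2**31)))
        occ_fit = _occ.occurrence_pipeline(survey, sp, covariates, occ_cfg)
        scores = np.zeros(seascape.shape)
        scores[grid_table["row"], grid_table["col"]] = \
            occ_fit.predict_probability(grid_table)
        presence = _occ.classify(scores, occ_fit.mean_threshold) & mask

        ab_fit = None
        density_raster = count_raster = None
        estimates: dict[int, _pop.PopulationEstimate] = {}
        estimates[1] = _pop.method1(survey, strat, sp)
        estimates[2] = _pop.method2(survey, strat, sp,
                                    np.where(mask, scores, -np.inf),
                                    occ_fit.thresholds)
        try:
            ab_cfg = _ab.AbundanceConfig(
                grid=config.abundance_grid, cv_k=config.cv_k,
                cv_repeats=config.cv_repeats, tune=config.tune,
                B=config.B, seed=int(rng.integers(2**31)))
            ab_fit = _ab.abundance_pipeline(survey, sp, covariates,
                                            p_presence=occ_fit.p_presence,
                                            config=ab_cfg)
            gt = grid_table.copy()
            # grid cells are out-of-bag for every iteration: bootstrap-mean
            # probability matches the averaged-OOB covariate used in training
            gt["P_presence"] = occ_fit.predict_probability_mean(grid_table)
            pred = ab_fit.predict(gt, cell_area=seascape.cell_area)
            density_raster = np.zeros(seascape.shape)
            density_raster[gt["row"], gt["col"]] = pred["density"]
            count_raster = density_raster * seascape.cell_area
            estimates[3] = _pop.method3(count_raster,
                                        np.where(mask, scores, -np.inf),
                                        occ_fit.thresholds, ab_fit.rho,
                                        mask=mask)
        except ValueError as exc:
            logger.warning("abundance stage skipped for %s: %s", sp, exc)

        bio: dict[str, tuple[float, float]] = {}
        w = config.weights.get(sp)
        if w and 3 in estimates:
            for kind in ("dry", "wet"):
                if kind in w:
                    mean_w, se_w = w[kind]
                    bio[kind] = _pop.biomass(estimates[3], mean_w, se_w)
        elif w:
            logger.warning("biomass for %s omitted (no Method 3 estimate)", sp)

        species_results[sp] = SpeciesResult(
            occurrence=occ_fit, abundance=ab_fit, score_raster=scores,
            presence_raster=presence, density_raster=density_raster,
            count_raster=count_raster, estimates=estimates, biomass=bio)
        layers_presence[sp] = presence
        cell_layers[f"presence_{sp}"] = presence.astype(float)
        cell_layers[f"density_{sp}"] = (
            np.where(presence, density_raster, 0.0) if density_raster is not None
            else presence.astype(float))

    # --- habitat summaries --------------------------------------------------
    cells = _hab.subsample_cells(seascape, cell_layers, n=config.subsample_n,
                                 seed=int(rng.integers(2**31)))
    habitat = _hab.stratify(cells, config.species)
    overlap = (_hab.overlap_table(layers_presence, mask)
               if len(layers_presence) >= 2 else None)

    bundle = ReportBundle(config=config, screen=screen, substrate=substrate_out,
                          species=species_results, stratification=strat,
                          habitat=habitat, overlap=overlap)
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
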