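# shellbed

Hurdle occurrence–abundance distribution modelling and population-size
estimation for epifaunal bivalves (mussels, oysters) on shallow coastal
grids, with bootstrap 0.632+ validation throughout.

## The problem

Managers of coastal habitats need defensible answers to "how many mussels /
oysters live out there, and where?" from heterogeneous survey data: camera
tows and hand quadrats, stratified by depth and wave exposure, covering a
few hundred sites on a domain of millions of 10 × 10 m cells. `shellbed`
implements the full chain from survey table to population total:

1. **Predictor screening** — coordinate rotation (default 14°) + min-max
   normalization into along-shore (Y) / in-offshore (X) positions, and
   stepwise VIF screening (threshold 5) with aggregation-family pruning.
2. **Substrate cover** — zero-one-inflated proportional cover of hard and
   soft bottom: P(cover = 0), P(cover = 1 | > 0), and a boosted interior
   mean on the logit scale; E[cover] = p₁ + (1 − p₀ − p₁)·μ.
3. **Occurrence** — gradient-boosted classifiers scored by AUC, with a
   prevalence-matched cut-off per bootstrap iteration: t chosen so the
   modelled prevalence equals the observed prevalence (not Youden).
4. **Abundance** — boosted regression of ln(density) at presence sites
   (with the averaged out-of-bag occurrence probability as an extra
   covariate), recalibrated by a regression of observed on estimated
   values (corrected = a + b·pred) and Duan's smearing factor
   D = mean(exp(residual)) for the back-transform.
5. **Validation** — everything runs under a bootstrap 0.632+ engine:
   R = (oob′ − apparent)/(γ − apparent), w = 0.632/(1 − 0.368 R),
   best = (1 − w)·apparent + w·oob′, with γ the no-information rate.
6. **Population totals** — three estimators with propagated SEs:
   stratified mean-density extrapolation (Method 1, Cochran), occupied-area
   × presence-density (Method 2), and threshold-delimited count-map sums
   calibrated by the mean predicted/observed ratio ρ (Method 3), plus
   biomass conversion (N̂·w̄ with SE propagation).
7. **Habitat summaries** — occupancy/abundance by 0.5 m depth bin and
   exposure class (sheltered < 10⁴), species overlap tables, central 80%
   depth ranges, variable importance and partial dependence.

A first-class synthetic-seascape generator (`shellbed.seascape`) produces
autocorrelated covariate grids, known hurdle truth layers, and stratified
two-method surveys, so every stage — including the population estimators'
coverage — is testable against exact truth without any external data.

## Worked example

```python
import shellbed as sb

sea = sb.generate_seascape(nrows=150, ncols=150, seed=12)
truth = sb.generate_truth(sea, sb.default_species_params()["mytilus"], seed=13)
survey = sb.sample_sites(sea, {"mytilus": truth},
                         sb.default_design(800, seed=14, seascape=sea))
cfg = sb.RunConfig(species=["mytilus"], B=25, seed=15,
                   covariates=["depth", "exposure", "X", "Y", "slope",
                               "P_HARD", "P_SOFT"],
                   weights={"mytilus": {"dry": (0.79, 0.05)}})
bundle = sb.run_pipeline(sea, survey, cfg)
```

Running `examples/07_population_estimates.py` (the script around the code
above) prints:

```
true total: 4.75 M individuals

Method 1:    4.74 M +/-  0.41 M (-0.0 SE from truth)
Method 2:    4.97 M +/-  0.40 M (+0.5 SE from truth)
Method 3:    5.37 M +/-  0.94 M (+0.7 SE from truth)

biomass from Method 3: 4 +/- 1 t dry weight, 110 +/- 21 t wet weight
```

All three estimators bracket the known simulated total within about one
reported standard error; Method 3's interval here carries the bootstrap
spread of both the cut-off thresholds and the calibration ratios. The other
`examples/*.py` scripts walk each capability the same way (simulation, VIF
screening, the 0.632+ engine on a memorizing model, substrate covers,
thresholds, retransformation corrections, habitat summaries); each prints
the numbers it computes with a line on how to read them.

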