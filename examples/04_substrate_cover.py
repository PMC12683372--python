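"""Zero-one-inflated substrate cover modelling.

Visually estimated covers of hard bottom pile up at exactly 0 and 1, so the
model has three parts: P(cover=0), P(cover=1 | >0), and the interior mean on
the logit scale. The expected cover is the mixture p1 + (1-p0-p1)*mu, and is
evaluated by R-squared plus the accuracy of calling the two point masses.
"""

import numpy as np

import shellbed as sb

sea = sb.generate_seascape(nrows=100, ncols=100, seed=3)
truths = {sp: sb.generate_truth(sea, p, seed=30 + i)
          for i, (sp, p) in enumerate(sb.default_species_params().items())}
survey = sb.sample_sites(sea, truths, sb.default_design(600, seed=4, seascape=sea))

fit = sb.fit_substrate(survey, "cover_hard")
print("stopping iterations per component:", fit.m_stop)

grid = sea.table()
pred = sb.predict_cover(fit, grid)
print(f"predicted expected hard cover: mean {pred['expected_cover'].mean():.2f}, "
      f"P(cover=0) mean {pred['p0'].mean():.2f}, P(cover=1) mean {pred['p1'].mean():.2f}")

metrics = sb.substrate_metrics(fit, survey, "cover_hard")
print(f"R^2 {metrics['R2']:.2f} | 0-Acc {metrics['zero_acc']:.2f} | "
      f"1-Acc {metrics['one_acc']:.2f}")
truth_cov = grid["P_HARD"].to_numpy()
r = np.corrcoef(pred["expected_cover"], truth_cov)[0, 1]
print(f"correlation with the true generating cover field: {r:.2f}")
# the predicted covers feed the occurrence/abundance stages as covariates
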