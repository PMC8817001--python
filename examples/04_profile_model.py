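"""Fit and validate the strategic-profile -> ability model.

Simulates a training cohort, compresses each player's three strategy rates
to two PCA features (S1, S2), regresses ability on them, then predicts the
ability of an independent validation cohort and reports the relative-error
percentiles.
"""

from tacitcoord import (
    default_population,
    fit_ability_model,
    fit_pca,
    ica_scores,
    predict_ica,
    retained_variance,
    simulate_population,
    validate,
)
from tacitcoord.stats import strategic_profiles

train = simulate_population(default_population(n_agents=93, seed=1))
profiles = strategic_profiles(train).dropna()
ability = ica_scores(train)[profiles.index]

pca = fit_pca(profiles)
print("retained variance (%):",
      [round(retained_variance(profiles, pca, m), 2) for m in (1, 2, 3)])
# how much of the standardized profile variance the top 1/2/3 components keep

model = fit_ability_model(pca.project(profiles)[:, :2], ability.to_numpy())
print(f"iCA = {model.intercept:.4f} + {model.coef_s1:.4f}*S1 "
      f"+ {model.coef_s2:.4f}*S2   (R^2 = {model.r_squared:.3f})")

holdout = simulate_population(default_population(n_agents=33, seed=2))
h_profiles = strategic_profiles(holdout).dropna()
h_ability = ica_scores(holdout)[h_profiles.index]
report = validate(predict_ica(h_profiles, pca, model), h_ability.to_numpy())
print(f"relative |error| percentiles: 25th {report.p25:.2f}%  "
      f"median {report.p50:.2f}%  75th {report.p75:.2f}%")
# per-player |observed - predicted| / observed, in percent, on unseen agents
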