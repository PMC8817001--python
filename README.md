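# tacitcoord

Modeling individual ability in **tacit coordination games**.

In a tacit coordination game two players are rewarded for making the same
choice without communicating.  In the "Assign Circles" family, a board shows
two squares and a handful of circles on a grid; each player attaches every
circle to one square, and a point is scored only when both players produced
the identical full assignment.  People solve these games far better than
chance by converging on *focal points* — solutions made salient by simple
selection rules — and they differ persistently in how well they do it
("Schelling's competence").

`tacitcoord` is a library for quantifying that ability and linking it to
players' strategic profiles:

* **Rule engine** — the three classic selection rules (*closeness*: each
  circle to its nearer square; *accession*: each coherent group of adjacent
  circles to its nearer square; *equality*: split the circles in half at a
  vertical line), each applicable only when it implies a unique assignment.
* **Coordination statistics** — per game, the coordination index
  `CI = Σ m_j(m_j−1) / (N(N−1))` (probability two random players coincide);
  per player, the individual coordination ability `iCA` (mean pairwise
  agreement with every other player over the fixed games), game tags
  `GT ∈ {−1, 0, +1}` per rule, and strategy rates
  `SR = #followed / #available` forming the strategic profile
  (SR_closeness, SR_equality, SR_accession).
* **Ability distribution** — Hartigan's dip test of unimodality (implemented
  in-package, bootstrap p-values) and least-squares fits of
  `Σ aᵢ·exp(−((x−bᵢ)/cᵢ)²)` to the score histogram, with the number of
  components chosen by an RSS elbow and corroborated by the silhouette
  index.
* **Profile → ability model** — z-score the three strategy rates, PCA, keep
  the top two components (S1, S2), regress `iCA = β₀ + β₁S1 + β₂S2`, and
  validate on an independent cohort with relative-absolute-error
  percentiles.
* **Synthetic populations** — seeded agent cohorts (propensity-weighted rule
  choice plus uniform noise, stratified into ability groups) so the entire
  pipeline runs and is tested without any behavioral data.

## Worked example

```python
from tacitcoord import (
    default_population, simulate_population, fit_pca, fit_ability_model,
    predict_ica, validate, ica_scores,
)
from tacitcoord.pipeline import score_cohort
from tacitcoord.stats import strategic_profiles

matrix = simulate_population(default_population(n_agents=93, seed=1))
scores, per_game = score_cohort(matrix)
print(per_game.loc["g01", ["ci", "random_ci"]].round(4).to_dict())

profiles = strategic_profiles(matrix).dropna()
pca = fit_pca(profiles)
model = fit_ability_model(pca.project(profiles)[:, :2],
                          ica_scores(matrix)[profiles.index].to_numpy())
print(round(model.intercept, 4), round(model.coef_s1, 4), round(model.r_squared, 3))
```

prints

```
{'ci': 0.6005, 'random_ci': 0.25}
0.4437 0.0712 0.836
```

On the first fixed board, two simulated players agree 60% of the time versus
the 25% expected from uniform guessing — rule-guided agents coordinate far
above chance.  The fitted model says a player one unit along the dominant
profile direction S1 (roughly "follows all rules more") gains ≈ 0.07 iCA,
and the compressed two-feature profile explains ≈ 84% of the ability
variance in this cohort.

The `examples/` scripts walk through each capability (rules on a board,
scoring a cohort, distribution shape, the profile model); a thin CLI mirrors
them (`tacitcoord simulate | rules | score | fit-distribution | fit-model |
predict | validate | run`).

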