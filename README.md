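# growthmix

Tools for estimating how an early-life exposure relates to subsequent
growth in longitudinal data, built around a head-to-head comparison of
two model families that encode the exposure–growth relationship in
fundamentally different ways:

* **Linear mixed-effects model (LME)** — a *deterministic* mechanism.
  With repeated outcomes `y_i` on subject `i` at ages `t_i`,

  ```
  y_i = X_i β + Z_i u_i + ε_i,    u_i ~ N(0, G),  ε_i ~ N(0, σ²I)
  ```

  where `X_i` holds a time basis (linear, polynomial, or B-spline) plus
  main effects and basis×exposure interaction terms, so a unit change in
  the baseline exposure shifts each growth coefficient by a fixed
  amount.  Fitted by plain maximum likelihood on the profiled deviance.

* **Growth mixture model (GMM)** — a *stochastic* mechanism.  Growth
  heterogeneity is captured by K latent classes, each with its own mean
  curve `X_i β_k`; the exposure enters a multinomial-logistic model for
  class membership,

  ```
  f(y_i | w_i) = Σ_k π_k(w_i) N(y_i; X_i β_k, Z_i G Z_i' + σ²I),
  π_k(w) = exp(w'γ_k) / Σ_l exp(w'γ_l),   γ_K = 0,
  ```

  so exposure shifts the *probability* of following a growth pattern.
  Fitted by a multi-start EM algorithm; K chosen by BIC over 2..5.
  Exposure effects are reported as ratios `exp(γ_k)` comparing each
  class's membership probability to the reference class (on a log2
  exposure scale, the multiplicative change per doubling).

The package grew out of the childhood-BMI setting (J-shaped curves with
an adiposity rebound, prenatal chemical exposures such as phthalate
metabolites, cohorts of a few hundred children) and ships a synthetic
data generator for eight data-generating conditions crossing mechanism
(deterministic/stochastic) × growth form (linear/quadratic) × exposure
form (monotonic/non-monotonic), together with the metrics used to
compare fitted models: BIC, out-of-sample MSE, and grid-averaged mean
absolute error of the mean surface (MAE) and of the growth velocity
surface (MAVE).  Audience: biostatisticians and environmental
epidemiologists weighing interaction-term mixed models against latent
class growth models.

## Worked example

```python
import numpy as np
from growthmix import (BasisSpec, GMMOptions, MeanModelSpec,
                       MembershipModelSpec, RandomEffectsSpec,
                       default_condition, fit_gmm, fit_lme,
                       generate_dataset, membership_ratio)

# stochastic condition: 3 latent linear growth classes, membership
# log-odds increasing in the exposure w2
cond = default_condition(2, seed=3)
data = generate_dataset(cond, "training", 0)

lme = fit_lme(data,
              MeanModelSpec(basis=BasisSpec("linear"), modifiers=("w1", "w2")),
              RandomEffectsSpec("all"))
print(f"LME  loglik={lme.loglik:.1f}  BIC={lme.bic:.1f}")

gmm = fit_gmm(data, MeanModelSpec(basis=BasisSpec("linear")),
              RandomEffectsSpec("intercept_only"),
              MembershipModelSpec(("w1", "w2")), K=3,
              options=GMMOptions(n_starts=3, seed=1))
print(f"GMM  loglik={gmm.loglik:.1f}  BIC={gmm.bic:.1f}")
print(gmm.betas.round(2))
r = membership_ratio(gmm, 1, "w2", delta=1.0, level=0.90)
print(f"class 1 vs {gmm.K}: ratio {r['ratio']:.2f} "
      f"(90% CI {r['lower']:.2f}, {r['upper']:.2f})")
```

Output:

```
LME  loglik=-2056.3  BIC=4167.8
GMM  loglik=-1978.6  BIC=4034.5
   Intercept     t
0      18.59  0.70
1      14.51  0.19
2      16.55  0.47
class 1 vs 3: ratio 1.43 (90% CI 1.08, 1.89)
```

The mixture recovers the three generating curves (intercepts 18.5 /
14.5 / 16.5, slopes 0.7 / 0.2 / 0.45) and its BIC beats the
interaction-term LME on this stochastically generated data.  The ratio
says: per unit increase in `w2`, the odds of following the steepest
growth pattern rather than the reference pattern rise by an estimated
43% (90% CI 8%–89%).

A command-line interface wraps the same functionality:

```
growthmix simulate --type 2 --seed 3 --out data.csv
growthmix fit-gmm --data data.csv --config model.yaml --k 3 --id-col id
growthmix derive --data data.csv --exposure w2
growthmix benchmark --config bench.yaml --out results/
```

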