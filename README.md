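# krillab

Stage-structured population modelling and environmental attribution for
Antarctic krill (*Euphausia superba*) — or any species whose annual
monitoring data distinguish larvae, juveniles and adults.

## The problem

Krill abundance at the Western Antarctic Peninsula fluctuates by more than
two orders of magnitude across 4–5-year cycles, and there is no consensus on
what drives recruitment: food (chlorophyll), ice cover, temperature,
hemispheric climate modes (SAM/ENSO), or density-dependent competition
between cohorts. `krillab` implements a three-stage analysis that separates
these hypotheses:

1. **Time-constant null model.** Stage abundances L (larvae), J (juveniles),
   A (adults), in ind/m², evolve by

   ```
   dL/dt = R(A) f_sum(t) − r f_spr(t) L − m_L L
   dJ/dt = r f_spr(t) L − r f_wnt(t) J − m_J J
   dA/dt = r f_wnt(t) J − m_A A
   ```

   Stage transitions run at rate `r` but only while a smooth periodic
   window function `f(t, t0) = exp(−[sin π(t−t0) / sin(πτ/2)]^{2m} ln 2)`
   is open (duration τ ≈ 0.2 yr; egg production in summer, larva→juvenile in
   spring, juvenile→adult in winter). Because the windows never overlap, no
   cohort can skip a stage within one season, and the solution depends only
   weakly on `r` — the fraction failing to transit is ρ = e^(−rτ) ≈ 0.002 at
   the default r = 30/yr, τ = 0.2 yr. Egg production follows the generalized
   Deriso–Schnute stock–recruitment function

   ```
   R(A) = L_max · A · (1 − β_γ L_max A / G_max)^{1/γ},
   β_γ = γ / (γ+1)^{1+1/γ}
   ```

   which interpolates from Beverton–Holt (γ = −1, saturating — no intercohort
   competition) to Ricker (γ → 0⁻, dome-shaped — competition for a shared
   resource), with initial slope `L_max` and supremum exactly `G_max`.

2. **Minimal annual loss anomalies.** Interannual climate variability enters
   as year- and cohort-specific mortality deviations
   `m'_{k,Y} = m_k exp(δ_{k,Y})` applied over each cohort's biological year
   (larvae: Nov Y−1 – Oct Y; juveniles: Aug Y−1 – Jul Y). The δ are estimated
   by minimizing a weighted log-scale least-squares misfit to the observed
   1 January abundances plus a ridge penalty λ_r Σ δ² — the *smallest*
   anomalies that reconcile model and data. Restart cycles of the bounded
   search double as a confidence ensemble: an anomaly is significant when
   ≥95% of near-optimal cycles agree on its sign.

3. **Attribution.** The fitted anomalies are screened against monthly
   environmental series (Pearson correlations over a 16-month window,
   September of Y−1 through December of Y) and regressed on them with a
   grouped **fused LASSO**: an L1 penalty yields sparse coefficients and a
   quadratic penalty on differences between adjacent months within each
   factor block yields smooth, interpretable monthly effect profiles.
   Hyperparameters come from K-fold cross-validation; all 15 non-empty
   subsets of the four candidate drivers are compared by CV error with a 2%
   near-tie rule favoring fewer factors; bootstrap resampling of years gives
   90% coefficient bands.

A seeded synthetic-study generator (`krillab.synthetic`) emulates the
statistical shape of the real monitoring inputs — 27 annual observations
with lognormal noise, seasonal monthly environments with AR(1) interannual
anomalies, loss anomalies from a known sparse linear model, overdispersed
station tables — so the whole pipeline is testable end-to-end without any
data download.

## Worked example

```python
import numpy as np
from krillab import model as mc
from krillab.envstats import recruit_vs_adult

for name in ("BH", "RK"):
    jan1 = mc.simulate(mc.PRESETS[name], years=27).jan1
    cv = np.std(jan1.A[5:26]) / np.mean(jan1.A[5:26])
    _, r = recruit_vs_adult(jan1)
    print(name, "adult CV(yrs 5-25) =", round(float(cv), 3),
          " lag-1 log corr =", round(float(r), 3))
```

prints

```
BH adult CV(yrs 5-25) = 0.016  lag-1 log corr = -0.74
RK adult CV(yrs 5-25) = 0.302  lag-1 log corr = -0.996
```

i.e. with time-constant parameters the Beverton–Holt preset settles to a
fixed point (adult coefficient of variation 1.6%) while the Ricker preset
sustains multi-year oscillations (CV 30%) and a strongly negative
relationship between adults and next-year recruits — the dynamical
signature of intercohort competition.

The full pipeline runs from the command line:

```bash
krillab run-all --seed 1 --out runs/demo          # synthetic study, all stages
krillab simulate --preset RK --years 27 --out runs/sim
krillab make-fixtures --seed 5 --out fixtures/    # toy study CSVs
```

`run-all` writes every intermediate table (observations, environment,
fitted parameters, anomalies with significance flags, correlation screens,
LASSO selection reports, coefficient bands, permutation distributions) and
a `summary.json` with the fitted costs, selected factor subsets and R².

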