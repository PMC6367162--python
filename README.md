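# bethedge

Delayed germination in desert annual plants is the textbook example of
evolutionary bet-hedging: by germinating only a fraction *g* of its
seed bank each year, a species trades mean reproductive success for
lower variance across unpredictable rainfall years. `bethedge`
implements a complete, tested pipeline for predicting evolutionarily
stable germination fractions (ESSs) for Sonoran Desert winter annuals
from their responses to precipitation, and for asking which
life-history traits shape those strategies.

The package is aimed at evolutionary ecologists and life-history
modellers who want a reproducible implementation of the
precipitation-driven seed-bank ESS analysis, or a scaffold to extend it
(different environments, different species, different yield models).

## The model

**Yield from rainfall (hurdle model).** In a year with precipitation
*P*, a germinated individual reproduces at all with probability

    pi = logistic(alpha1 + beta1 * ln(P + 1))

and, conditional on clearing that reproductive hurdle, produces a
low-density yield that is linear on the log-log scale:

    ln(K) = log_alpha2 + beta2 * ln(P + 1)

Failure years carry the yield K = 0.5 (a zero-seed year after the
conventional +0.5 offset), so K < 1 marks failure and K >= 1 success.
The binomial stage is fitted by GLM/IRLS and the yield stage by OLS, in
three nested forms (per-species lines, common slope, common intercept)
with AIC/BIC/likelihood-ratio comparison and pairwise Wald tests.

**Seed-bank dynamics.** Seed density n_t per m^2 follows

    n_{t+1} = g K_t s_new n_t / (1 + a g n_t) + (1 - g) s_old n_t

with fresh-seed survival s_new, dormant-seed survival s_old and a
competition coefficient a. When the low-density stochastic growth rate
r = E[ln(g K s_new + (1-g) s_old)] is positive, the density converges
to a unique stationary distribution, approximated by one long run.

**ESS germination fraction.** A rare mutant g~ invading a resident g
at stationarity grows at

    r(g, g~) = E[ ln( g~ K_t s_new / (1 + a g n_t) + (1 - g~) s_old ) ]

The ESS solves h(g) = (d r / d g~)(g, g) = 0; invasion fitness is
concave in g~, so an interior root is unique. The solver evaluates the
analytic selection gradient over one shared yield stream (common random
numbers) and bisects; `verify_ess` then checks uninvadability over a
mutant grid.

**Trait regressions.** Logit ESS values (or observed germination
fractions) are regressed on three standardized traits — reproductive
intercept alpha1, log-yield slope beta2 and dormant-seed survival
s_old — reporting standardized coefficients and adjusted R^2.

A parameter table for ten Sonoran Desert annuals (MOBE ... EVMU) ships
with the package; the precipitation record behind it is not
redistributable, so `bethedge.synthetic` provides a calibrated
lognormal winter-rainfall surrogate plus generators for observation
tables and whole communities, making every stage testable end to end.

## Worked example

Solve the ESS for all ten packaged species under the calibrated winter
surrogate and regress logit ESS on the standardized traits:

```
$ bethedge find-ess --burn-in 1000 --years 50000 --seed 41 --out-dir out
MOBE: g_ess=0.9123 (interior)
ERCI: g_ess=0.9478 (interior)
STMI: g_ess=0.6935 (interior)
SCBA: g_ess=0.7823 (interior)
ERLA: g_ess=0.7610 (interior)
PLPA: g_ess=0.8562 (interior)
ERTE: g_ess=0.7546 (interior)
PLIN: g_ess=0.8569 (interior)
PERE: g_ess=0.7873 (interior)
EVMU: g_ess=0.3931 (interior)
trait regression: adj R2=0.727 coefs={'alpha1': 0.289, 'beta2': -0.353, 's_old': -0.674}
```

Every species has an interior ESS: each hedges its bets, keeping part
of the seed bank dormant. The spread is wide — EVMU, with the safest
seed bank (s_old = 0.828), germinates only ~39% of its seeds per year,
while MOBE, with the riskiest bank (s_old = 0.273), germinates ~91%.
The regression quantifies that pattern: dormant-seed survival has the
largest standardized effect (−0.67; safer banks mean stronger
hedging), wet-year yield responsiveness beta2 pushes germination down
(−0.35) and dry-year reproductive success alpha1 pushes it up (+0.29),
together explaining ~73% (adjusted R^2) of the variance in logit ESS.

The same analysis is available from Python:

```python
from bethedge import packaged_species, winter_precip_model, find_ess

sp = packaged_species()[4]              # ERLA
res = find_ess(sp, winter_precip_model(), seed=41)
print(res.g_ess, res.boundary_flag)     # 0.761 interior
```

Other subcommands: `generate` (synthetic species/precipitation/
observation tables), `fit-hurdle` (two-stage fit with model-form
comparison), `simulate` (one resident trajectory), `regress-traits`.

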