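# Methods

## The carbon-balance model

A tomato fruit is treated as three carbon pools (g C): soluble-sugar
carbon `C_sol`, starch carbon `C_sta`, and structural carbon `C_str`
(cell walls, proteins, organic acids — not reconvertible to sugars).
Carbon enters as phloem-imported sucrose and leaves as respired CO2:

```
dC_sol/dt = k0·dC_sup/dt + k5·C_sta − (k3(t) + k5m(t) + k6(t))·C_sol
dC_sta/dt = k5m(t)·C_sol − k5·C_sta
dC_str/dt = k3(t)·C_sol
dC_rep/dt = k6(t)·C_sol = q_g·dDW/dt + q_m·DW·Q10^((T−20)/10)
```

Respiration splits into a growth component proportional to the dry-weight
growth rate and a maintenance component proportional to standing dry
weight with a Q10 temperature response, so `k6(t)` is directly calculable
and never a free parameter.  Mass conservation ties the supply flux to
growth: `c_DW·dDW/dt = dC_sup/dt − dC_rep/dt`.

Fixed parameters (all config-overridable):

| symbol | meaning | default | unit |
|--------|---------|---------|------|
| `c_DW` | carbon per g dry mass | 0.44 | g C/g DW |
| `q_g`  | growth respiration coefficient | 0.088 | g C/g DW |
| `q_m`  | maintenance respiration at 20 °C | 0.000168 | g C/g DW/h |
| `Q10`  | maintenance temperature ratio | 1.4 | — |
| `k0`   | phloem import fraction | 1 | — |
| `k5`   | starch → sugar conversion rate | 0.296517337 | 1/day |

`k5` is held constant because the starch-degrading enzymes (amylase,
starch phosphorylase) vary little over tomato fruit development.  Its
published value carries no explicit time unit; per day is adopted as a
config default because it matches the rate's magnitude relative to the
~40-day observation window, and is not asserted as more than that.

## Units and integration

The internal clock is hours (the respiration constants are per hour);
user-facing rate series are per day, and the conversion lives in exactly
one function (`per_day_to_per_hour`).  Integration is fixed-step 4th
order Runge–Kutta, default 1 h: the system is smooth and linear in the
pools, so adaptive stepping buys nothing and fixed steps keep runs
bit-reproducible.  Growth, temperature and rate schedules are linearly
interpolated between grid points.  If aggressive rates transiently drive
a pool below zero, it is clipped at 0 and a warning logged.  Conservation
(`Δ(ΣC pools) = C_sup − C_rep`) holds to rounding error in the tests.

## Observations to carbon pools

Assays give soluble-sugar and starch mass per 100 g fresh weight; carbon
masses use the compound-class carbon fractions — 0.40 for soluble sugar
(hexose stoichiometry, 72/180; tomato soluble sugar is predominantly
glucose + fructose) and 72/162 ≈ 0.444 for starch.  Both are
config-exposed since they are modelling choices, not measurements.
Structural carbon is the remainder of `c_DW·DW`; records implying
negative structural carbon signal assay error and are excluded with a
log entry rather than clipped, because silent clipping would bias the
downstream `k3` estimates.  Pool percentages are fractions of total
fruit carbon (the published per-treatment rows sum to 100 under that
reading, which the tests verify).

## Rate inversion

Given smooth pool trajectories, the conversion coefficients follow
algebraically:

```
k3(t)  = (dC_str/dt) / C_sol
k5m(t) = k5·C_sta/C_sol + (dC_sta/dt) / C_sol
```

Pools are smoothed by local quadratic regression with tricube weights;
replicates are pooled into one regression per treatment.  Degree 2 gives
first derivatives unbiased for the curvature typical of sigmoids; the
derivative is the analytic first derivative of the local polynomial.
The bandwidth is a fraction of the observed age span, default 0.6 —
appropriate for the sparse 8-age design; dense data support much smaller
values (the noiseless round-trip tests use 0.15–0.25).  Numerical
guards: `C_sol` is floored at 1e-6 g before division; negative rate
estimates are floored at 0 but kept raw in diagnostics columns; rates
are reported on the interior 80 % of the age span because
local-regression derivatives are unreliable at boundaries (smoothed
*values* remain available on the full span).

## Identifiability of k5

With `k3(t)` and `k5m(t)` free functions, `k5` is structurally
unidentifiable: substituting the inversion formulas back into the
balance equations reproduces the smoothed pools exactly for *any* `k5`.
The data bound `k5` only from below — candidates well under the value
that generated the data drive the derived `k5m(t)` negative near
maturation, the non-negativity floor engages, and simulated starch
decays too slowly.  `calibrate_k5` therefore scans the search interval,
detects an uninformative (flat) objective when starch is absent, and
otherwise returns the smallest candidate whose error is within a small
band of the plateau minimum: the most parsimonious starch-breakdown
rate consistent with the trajectories.  A parametric alternative
(exponentially decaying `k5m`) was evaluated and is equally degenerate —
the classic exchangeability of two-compartment exponential rates — so
the plateau-edge rule was kept.  Consequently the calibration is
accurate to roughly 10 % on clean dense data and should be read as a
lower-edge estimate, not a well-posed least-squares optimum.

## Synthetic data

The generator emulates the study conditions: a 4-water × 2-potassium
factorial sampled at 34, 37, 48, 57, 58, 65, 66 and 73 days after
anthesis with 3 replicates.  Dry and fresh weight are logistic in age
(control asymptotes 7 g DW / 140 g FW), with per-treatment multipliers
reproducing the observed orderings (control FW largest; potassium
raising DW, FW and soluble sugar).  Allocation uses anchored logistics:
the soluble fraction rises 9 % → 45 % of total carbon over the sampled
window and the structural fraction falls 75 % → 53 %, leaving starch as
the residual, 16 % → 2 %.  The soluble fraction at the first sampled age
is set to 9 % (= 100 − 16 − 75) so the three fractions sum to one
hundred; the slightly higher early-soluble share sometimes quoted for
younger fruit is attributed to ages before the first sample.  Treatment
shifts multiply the soluble curve and are absorbed by the structural
curve, so starch is common to all treatments (no water effect on starch,
matching the observations).  Measurement noise is multiplicative
lognormal, mean-preserving, CV 5 %, independent across FW, DW, SSC and
STC — positive-valued assays with roughly constant CV.  Temperature is
a daily sinusoid between 14.8 and 29.1 °C.  One global seed spawns an
independent substream per treatment so adding treatments never
reshuffles existing draws.

What the generator does *not* emulate: per-truss effects (ages are
collapsed to one axis, as the analysis assumes), water-balance/dilution
dynamics, individual sugars, or the exact published treatment means
(only orderings and the fraction endpoints are targeted).  Passing
recovery tests therefore show the pipeline recovers the structure it
assumes, not that field data meet those assumptions.

## Treatment statistics

The factorial ANOVA is the balanced fixed-effects decomposition computed
from cell means by inclusion–exclusion (Möbius sums over factor
subsets); in a balanced design sequential and marginal sums of squares
coincide, so the Type I/II/III question does not arise, and unbalanced
tables are rejected with a pointer to a balanced subset.  Tests verify
the decomposition against a model-matrix projection oracle and against
an independent OLS-ANOVA implementation, and check the null type-I error
of the water effect by simulation.  Fisher's LSD is applied without
family-wise correction, as the procedure prescribes; the compact letter
display is assembled by insert-and-absorb, letters ordered by descending
means ("a" = largest).  Kruskal–Wallis uses the tie-corrected H with a
chi-square reference distribution.

## Problem sizes

Defaults keep every stage desk-scale: 192 observations per generated
dataset, inversion grids of ~40 ages, RK4 at 1-h steps over the 39-day
window, 50-seed repetition loops for stochastic recovery checks and 500
null simulations for the type-I-error check.

## Known limitations

* `k5` calibration is a bounded, one-sided estimate (see above).
* Rate estimates at the window edges are suppressed by design; nothing
  is claimed about conversion rates before 34 or after ~69 DAA.
* The generator's effect multipliers are fixed study conditions, not
  fitted quantities; they reproduce orderings, not published means.
* Soil-water dynamics are not modelled; irrigation arithmetic operates
  on supplied moisture readings only.
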