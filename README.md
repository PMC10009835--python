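# champs-traj

Group-based trajectory modelling of children's weekly sports participation.

Cohort studies that prompt parents weekly ("how many times did your child
take part in organised sport last week? 0–7, or 8 = more than seven")
produce long, bounded, irregularly observed participation histories from
age 6 to 16. This package identifies latent developmental subgroups in
such data and relates them to baseline motor performance. It is written
for epidemiologists and biostatisticians who want the full pipeline —
simulation, aggregation, mixture fitting, model choice, scoring,
association — as tested, scriptable Python rather than a statistical
plugin.

## The model

Average weekly participation per month, y_it ∈ [0, 8], is modelled as a
**censored-normal group-based trajectory model**: each latent group
*j* = 1…G has a cubic mean curve on scaled age,
μ_j(a) = β_j0 + β_j1 a + β_j2 a² + β_j3 a³, and y_it is a normal variable
with SD σ censored below at 0 and above at 8 (the "8" answer means *more
than seven*). Group membership has probabilities π_j (multinomial logits,
group 1 reference); a model with G groups has 5G free parameters.
Estimation is maximum likelihood by EM with analytic-gradient
quasi-Newton M-steps. Model choice uses AIC/BIC (on observations and on
children), per-group APPA (> 0.7) and OCC (> 5), minimum group size, and
child-level k-fold / leave-one-out cross-validation. Baseline motor tests
become sex- and age-stratified z-scores, composites and tertiles; the
association between composites and trajectory group is a multinomial
logit reported as relative risk ratios (RRR) with cluster-robust
(sandwich) confidence intervals.

## Worked example

```python
import numpy as np
from champs_traj import (
    CohortConfig, generate_cohort, TrajectorySpec, fit_gbtm, selection_table,
)
from champs_traj.sms_aggregation import (
    aggregate_weekly_to_monthly, exclude_sparse_children,
)

roster, weekly, motor, truth = generate_cohort(CohortConfig(
    n_children=200, n_groups=3, membership_logits=(0.3, -0.2),
    motor_effects=(-0.6, 0.0, 0.6), end_month="2012-06", rng_seed=7,
))
panel = aggregate_weekly_to_monthly(weekly, roster=roster)
panel, excluded = exclude_sparse_children(panel)
report = selection_table(panel, g_range=range(1, 5), cv_schemes=(2,), seed=7)
print(report.table[["G", "k", "BIC_children", "APPA_min", "min_group_n", "CV_2"]]
      .round(2).to_string(index=False))
print("recommended G:", report.recommended())
```

prints

```
 G  k  BIC_children  APPA_min  min_group_n  CV_2
 1  5      -7794.57      1.00          199  1.64
 2 10      -6038.17      1.00           51  1.06
 3 15      -3208.34      1.00           47  0.42
 4 20      -3216.26      0.75           15  0.42
recommended G: 3
```

The three-group model wins: the cross-validated prediction distance (mean
absolute error between held-out months and the trained group curves,
posterior-weighted) drops from 1.64 sessions/week at G=1 to 0.42 at G=3
and is flat thereafter, every group keeps an APPA of 1.00 (children are
assigned essentially without ambiguity), and G=4 buys no predictive gain
while splitting off a marginal group with a weaker APPA of 0.75. `fit_gbtm(panel, TrajectorySpec(3))` then
returns the fitted curves, posteriors and assignments;
`predict_trajectory` draws the expected trajectories on the 0–8 scale
with 95% point-wise bands.

The same stages are available from the shell:

```bash
champs-traj simulate --config cohort.yaml --seed 7 --out sim/
champs-traj aggregate --weekly sim/weekly_responses.csv --roster sim/roster.csv --out panel.csv
champs-traj select --panel panel.csv --gmin 1 --gmax 5 --cv 2 --seed 7 --out report.csv
champs-traj run --config pipeline.yaml     # full pipeline with manifest
```

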