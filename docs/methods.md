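# Methods

## The model

`champs_traj` implements group-based trajectory modelling (GBTM) for a
bounded count-like outcome: average weekly participation in organised
leisure-time sport, observed monthly from age 6 to 16. GBTM is a finite
mixture in which each latent group *j* (of *G*) follows its own polynomial
mean curve over age and carries a membership probability π_j. Because the
weekly question is answered on a 0–7 scale with "8" standing for *more than
seven*, the monthly average lives on [0, 8] with genuine point masses at
both ends. The outcome is therefore modelled as a **censored normal**
(Tobit-type) variable: a latent normal y\* with mean
μ_j(a) = β_j0 + β_j1 a + β_j2 a² + β_j3 a³ (a = affinely scaled age) and
shared residual SD σ is observed exactly inside (0, 8) and piled onto the
limits outside. The per-observation log density is

- log Φ((0 − μ)/σ) when y = 0,
- log (1 − Φ((8 − μ)/σ)) when y = 8,
- log φ((y − μ)/σ) − log σ otherwise,

computed through `scipy.special.log_ndtr` so it remains accurate for
|z| well past 40. A child's group-conditional likelihood multiplies its
non-missing months (valid under MCAR: missing months are simply dropped
from the product); the mixture likelihood sums over groups with weights
π_j parameterised as multinomial logits with group 1 as reference.

Free parameters: G(order+1) polynomial coefficients, G−1 logits, one σ —
5G for the default cubic specification. σ is shared across groups and time
because the parameter-count bookkeeping of the reporting convention this
package follows (5 coefficients-equivalents per group) is only consistent
with a single σ.

## Estimation

`fit_gbtm` maximises the likelihood by generalised EM:

- **E-step:** posterior membership w_ij ∝ π_j L_ij via log-sum-exp.
- **M-step:** π_j = mean of w_ij (closed form); (β, log σ) by L-BFGS-B on
  the posterior-weighted censored-normal regression with analytic
  gradients. Starting the inner optimiser at the current parameters makes
  every iteration non-decreasing in the observed-data log-likelihood,
  which is asserted in tests.
- **Starts:** the first start partitions children by k-means on their mean
  outcome (scikit-learn); additional starts use random partitions. The
  best final likelihood wins. The seed is recorded in the fit.
- **Convergence:** |Δℓ| < 1e−6 on three consecutive iterations, at most
  500 iterations. Non-convergence of every start raises, carrying the best
  partial fit.
- **Labelling:** groups are relabelled in increasing order of the mean
  fitted trajectory on the observed scale, so "group 1" is always the
  least active. Modal assignment breaks posterior ties toward the lowest
  group index.

Age is affinely mapped onto [−1, 1] over the observed range before the
polynomial design is built (cubic designs on raw ages 6–16 are badly
conditioned); coefficients are reported on the scaled axis together with
the transform.

Trajectories on the observed scale use the clipped-normal expectation
E[y] = 0·Φ(a) + 8·(1−Φ(b)) + μ(Φ(b)−Φ(a)) − σ(φ(b)−φ(a)); point-wise 95%
bands come from the delta method with the observed information of the full
mixture likelihood (finite differences of the analytic gradient).

## Model choice

`selection_table` reports, per candidate G: AIC = ℓ − k and
BIC = ℓ − (k/2) ln n at two n's (observations and children; larger is
better in this convention), per-group APPA (mean posterior among modally
assigned children; adequacy > 0.7), OCC (posterior odds over prior odds
using estimated π̂_j, not modal shares; adequacy > 5), the smallest modal
group, and child-level cross-validated prediction distances.

The CV distance is not standard and had to be defined: per held-out
observation we use the **posterior-weighted mean absolute error** between
the observed y and each trained group curve on the observed scale, with
the held-out child's posteriors computed from its own data under the
trained model. This uses only trained-model quantities and reduces to
|y − curve| when assignment is certain. Modal and marginal (π-weighted)
variants are available behind the `scheme` flag. One random child-level
split is drawn per k (k = 2, 10, 50 in the original design, plus
leave-one-out); the split seed does not seed the per-fold fits, so k = n
is exactly LOO for any seed.

`recommend_groups` returns the smallest G that passes the adequacy flags
and whose CV distance is within 5% of the best — the "decrease has
stabilised" reading of the CV curve. The minimum-group-size flag defaults
to 25 in `selection_table`; the pipeline derives it adaptively
(n_children/50, capped at 25) so small simulated cohorts are judged on the
same relative footing as a ~1,500-child cohort.

## Covariates and association

The six motor tests are oriented so larger is better (shuttle-run seconds
are multiplied by −1), standardised within sex × age-band strata (sample
SD, n−1; default bands 6–7, 8–9, 10–11, 12–14, configurable), and averaged
into composites: health (hand grip, Andersen), coordination (vertical
jump, shuttle run, backward balance, precision throw), total (all six).
Composites average the available members by default (a per-child
missing-count is reported; complete-case behaviour is a flag). Tertiles
cut at the empirical order-statistic 1/3 and 2/3 quantiles with ties
assigned downward — with distinct values and n divisible by 3 the groups
are equal; with heavy ties the lower groups absorb the tied values, and
all-equal input is entirely "low".

Association uses multinomial logistic regression (statsmodels `MNLogit`)
of the modal group assignment on indicator-coded covariates, group 1 as
outcome reference. This two-stage approach (fit trajectories, then treat
the modal assignment as data) ignores classification uncertainty; with
APPA near 1 — the regime the adequacy rules enforce — the bias is small.
Inference uses the cluster-robust sandwich A⁻¹(Σ_c s_c s_cᵀ)A⁻¹ built from
per-observation scores summed within clusters (schools by default), with
the M/(M−1) small-sample factor. statsmodels' own cluster covariance
additionally applies an (n−1)/(n−k) degrees-of-freedom factor; the package
applies only M/(M−1), and the test suite pins the exact relationship. The
overall p-value is a likelihood-ratio chi-square against the nested null.

## The synthetic cohort generator

No public version of the original cohort exists, so the generator is the
test bed, at two fidelity levels.

`generate_cohort` emulates the raw data structure: ~1,500 children (default)
entering at ages 5–13 into an open cohort over Aug-2009–Jun-2014; weekly
prompts suspended for two Christmas weeks and six summer weeks (~44 prompt
weeks/year); five latent groups with default shares ≈ 13.5/27/29/22/8.5%
and cubic latent curves anchored to qualitative reference shapes (a
flat near-zero group, a low decreasing group, three increasing groups, the
steepest peaking near 4.4 sessions/week around age 13–14 and ending near
3.5); weekly counts are the latent normal rounded and clipped to 0–8 ("8"
stored literally, meaning more than seven); response rate 0.75/week and
dropout hazard 0.005/month (not reported for the original study; chosen
once as plausible for a parent-SMS design, and configurable); motor tests
from sex- and age-dependent baselines plus a single latent fitness factor
whose group shifts induce the monotone performance gradient, with the
shuttle run loading negatively (fitter is faster).

`generate_model_faithful_panel` draws monthly outcomes *exactly* from the
censored-normal mixture (no rounding, optional MCAR missingness) for clean
parameter-recovery experiments: with rounding, the generating process is
not the fitted model and recovery is only approximate.

What passing tests do **not** show about real data: the generator has no
school-level clustering of participation, no seasonal structure beyond the
holiday gaps, MCAR (not informative) missingness, static per-child sport
repertoires, and group-mean curves that are exactly cubic. Recovery and
CV results on these cohorts demonstrate correctness of the machinery, not
robustness to real-world misspecification.

## Numerical choices and problem sizes

- Censored log-density via `log_ndtr`; tail ratios φ/Φ as
  exp(logpdf − logcdf) to avoid 0/0.
- Inner M-step: L-BFGS-B, ftol 1e−12, gtol 1e−8, ≤100 iterations.
- Posterior rows checked to sum to 1 within 1e−10.
- Observed information by central differences (step 1e−5) of the analytic
  gradient; covariance by (pseudo)inverse.
- Recovery experiments use 600 children × 60 monthly points × 5
  replicates; CV-curve experiments 150 children × 30 points with k = 2 —
  sizes at which the Monte-Carlo error of every reported metric is an
  order of magnitude below its acceptance margin, while a full run stays
  in the tens of seconds.

## Known limitations

- Group-specific σ, time-varying covariates in the mean, non-polynomial
  shapes and one-stage (joint trajectory + covariate) estimation are out
  of scope.
- The EM surface is multimodal; with few starts on poorly separated data
  the fit can be a local optimum (more starts via `n_starts`).
- LOO cross-validation refits once per child and is only practical for
  small cohorts; the k-fold schemes are the intended tool at scale.
- Tertile tie-handling (downward) matters only with heavily tied
  composites; alternative conventions would shift boundary children.
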