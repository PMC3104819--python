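# Methods

## The two risk models

**Mixture model.** For outcome group g ∈ {affected, unaffected} and CRL x ∈
[45, 84] mm, the NT density is

f_g(t | x) = π_g(x) · φ_trunc(t; μ_g, σ_g) + (1 − π_g(x)) · ℓ(t; m(x), σ_dep),

where ℓ is the density of 10^N with N ~ Normal(m(x), σ_dep²),
m(x) = a + b·x + c·x² (log₁₀ units), and φ_trunc is a Gaussian in NT
millimetres truncated at zero and renormalised. NT is a positive length, so
the untruncated Gaussian would place mass on negative NT (≈10⁻³ at the
default μ/σ) and the mixture would not integrate to one over its support;
truncation at zero removes that defect while changing densities in the bulk
by less than one part in 10³. The affected CRL-dependent component is the
unaffected one by construction; π is constant (0.94) for affected
pregnancies and declines linearly in CRL between the anchors π(45) = 0.12,
π(84) = 0.03 for unaffected ones (a logistic-in-CRL interpolation is
available via the `form` switch; the linear form is the default because the
specification of the curve is only through its two endpoints and
monotonicity).

**MoM method.** The unaffected median curve med(x) solves
F_unaff(med(x) | x) = ½ by bracketed Brent root-finding (|F − ½| < 10⁻⁸;
bulk conversion uses a 157-point monotone-cubic interpolant of exact roots,
interpolation error ≪ 10⁻⁶ mm). A pregnancy's MoM is t/med(x). For each
completed week w ∈ {11, 12, 13} with CRL anchor x_w ∈ {49, 62, 76} mm, the
single-Gaussian log₁₀-MoM parameters per group are the exact moments of the
mixture at the anchor:

mean = ∫ log₁₀(t/med(x_w)) f_g(t|x_w) dt,  sd² = ∫ (·−mean)² f_g(t|x_w) dt.

The lognormal component's moments are closed-form; the truncated-Gaussian
component is integrated by adaptive quadrature (absolute tolerance 10⁻¹⁰)
over (0, μ + 12σ). Integration covers the full support: truncation limits
clamp *observations* at scoring time, they do not censor the distribution
itself. Week membership partitions CRL as [45,55) → 11, [55,69) → 12,
[69,84] → 13 (each anchor interior to its interval; config-overridable).

**Likelihood ratios and risk.** Both methods clamp the observation to the
configured truncation limits (default 0.6–6.0 mm on the NT scale) before
evaluating densities, so LRs are constant beyond the limits — the standard
guard against extreme risks from poorly supported tails. Posterior risk is
prior odds × LR, with the maternal-age prior a config input (the packaged
curve is a stand-in lookup table in the style of published age-risk
regressions; every cross-method comparison is invariant to this choice).
Risks print as "1 in n", one decimal below n = 10, integer otherwise.

## Estimation

The ten distribution parameters are fitted per outcome group by EM.
E-step: responsibilities of the CRL-independent component. M-step, each
piece an exact (or numerically maximised, warm-started) weighted update, so
the observed-data log-likelihood is nondecreasing:

- log-quadratic coefficients: weighted least squares of log₁₀ NT on
  (1, x, x²); σ_dep from the weighted residual variance;
- truncated-Gaussian component: weighted MLE via Nelder–Mead on
  (μ, log σ) — the objective depends on the data only through Σw, Σwt, Σwt²,
  so each evaluation is O(1);
- unaffected proportion anchors (p₄₅, p₈₄): Bernoulli likelihood of the
  responsibilities with the linear form fixed, maximised by L-BFGS-B with
  analytic gradient, bounds [10⁻⁴, 0.8];
- affected proportion: responsibility mean.

Defaults: 10 random restarts (independent-component mean seeded at a random
upper quantile of the data, proportion ~ U[0.02, 0.3] for unaffected,
U[0.6, 0.98] for affected), 500 iterations, log-likelihood tolerance 10⁻⁷,
SD floors at 10⁻⁴ of the data scale. The affected fit holds the
CRL-dependent component fixed at the unaffected fit's values, enforcing the
structural tie. Divergent restarts (a vanishing component) are discarded;
if all diverge the fit fails with diagnostics.

## Synthetic cohorts

The generator emulates a routine screening programme: by default 104
affected and 22,284 unaffected pregnancies, CRL ~ Uniform(45, 84) mm and
maternal age ~ Triangular(15, 29, 45) years (both stand-ins — the cohort the
models were built for does not publish these distributions), component
membership Bernoulli in the configured proportions, NT by inverse-CDF from
the selected component. One master seed spawns independent substreams per
(status, variable), so enlarging a cohort leaves already-drawn records
unchanged. The generator does *not* simulate measurement error, operator or
machine effects, age–outcome dependence, or twins; passing tests therefore
demonstrate internal consistency of the two scoring methods under the
mixture truth, not screening performance on real populations — in
particular, because maternal age is drawn independently of outcome,
calibration checks use a constant prior equal to the cohort prevalence.

## Evaluation conventions

- ROC by threshold sweep over pooled unique scores, "score ≥ threshold" is
  screen-positive; DR-at-FPR and FPR-at-DR read out as conservative step
  functions by default (no interpolation rule is assumed), with a linear
  interpolation mode available.
- Quintile calibration: category boundaries at the quintiles of risk among
  affected pregnancies, remainder records to the higher-risk categories
  (104 affected → 21/21/21/21/20 top-down), boundary-equal risks to the
  higher-risk side; each category reports the affected count, the median
  estimated risk over all its pregnancies, and observed prevalence.
  Degenerate boundaries (tied risks spanning categories) raise an error
  naming the tie mass.
- Median risks per status use the lower-median convention for even counts.
- Sensitivity analysis (MoM scoring path only): the derived affected median
  MoM shifted ±20% (an additive log₁₀(1.2) shift of the affected log-MoM
  mean) and the affected/unaffected SDs scaled ±20%, with the DR/FPR table
  recomputed per scenario.

## Numerical choices and limitations

- Mixture CDF/density evaluations are closed-form (scipy normal
  functions); no quadrature enters scoring.
- Support upper bound for root-finding and normalisation checks:
  max(μ + 10σ over independent components, 10^(m(x)+8σ_dep)).
- The fitted model's permutation invariance holds to floating-point
  summation-order accuracy (~10⁻⁵ relative), not bitwise.
- Parameter values in `data/synthetic_defaults.yaml` are a synthetic
  parameter set chosen to be clinically plausible (median NT 1.20→1.90 mm
  across CRL, affected distribution centred at 2.75 mm); they are the
  package's generative truth for simulations, not estimates from any
  dataset. Derived MoM parameters are pure integration results; robust
  (outlier-resistant) re-estimation from raw data is out of scope, with the
  ±20% sensitivity analysis covering the gap such estimation would open.
- Problem sizes used in the test suite (up to 2×10⁷ Monte-Carlo draws for
  density oracles, 20 replicate fits at 25,000 records) were chosen so
  Monte-Carlo standard errors sit well inside the asserted tolerances.
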